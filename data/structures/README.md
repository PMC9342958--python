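# Structure files

Place the monomer/polymer PDB entries for the three CBM death-fold domains
here (`.pdb` or `.cif`, lower- or upper-case file names):

| domain     | monomer | polymer |
|------------|---------|---------|
| BCL10 CARD | 2MB9    | 6BZE    |
| CARD9 CARD | 6E26    | 6N2P    |
| MALT1 DD   | 2G7R    | 6GK2    |

One-time download:

```
for id in 2mb9 6bze 6e26 6n2p 2g7r 6gk2; do
    curl -O https://files.rcsb.org/download/${id}.cif
done
```

These files are required by `analysis/05_structure_rmsd.py`, by
`nucleokit rmsd`, and by the monomer-vs-polymer RMSD tests; everything else
in the package runs without them.
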