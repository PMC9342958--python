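#!/usr/bin/env python
"""Monomer-vs-polymer C-alpha RMSD for the three CBM death-fold domains.

Compares the soluble monomer structure of each death fold against one
protomer of its polymer structure (BCL10 CARD: 2MB9 vs 6BZE; CARD9 CARD:
6E26 vs 6N2P; MALT1 DD: 2G7R vs 6GK2).  A large RMSD means the subunit must
refold substantially to join the polymer — the structural correlate of a
conformational nucleation barrier.

The PDB entries are not bundled; download them once (any of .pdb/.cif) into
data/structures/, e.g.:

    for id in 2mb9 6bze 6e26 6n2p 2g7r 6gk2; do
        curl -O https://files.rcsb.org/download/${id}.cif
    done

then re-run this script.  Writes results/structure/rmsd.json.
"""

import json
from pathlib import Path

from nucleokit import structure

ROOT = Path(__file__).resolve().parent.parent
STRUCTURE_DIR = ROOT / "data" / "structures"
OUT = ROOT / "results" / "structure"

results = {}
missing = []
for domain, (mono_id, poly_id) in structure.DEATH_FOLD_PAIRS.items():
    mono = structure.find_structure_file(mono_id, STRUCTURE_DIR)
    poly = structure.find_structure_file(poly_id, STRUCTURE_DIR)
    if mono is None or poly is None:
        missing.append(f"{domain}: {mono_id}/{poly_id}")
        continue
    plain = structure.best_protomer_comparison(mono, poly, trim=False)
    trimmed = structure.best_protomer_comparison(mono, poly, trim=True)
    results[domain] = {
        "monomer": mono_id, "polymer": poly_id,
        "rmsd_all_pairs": plain.rmsd, "n_pairs": plain.n_pairs,
        "rmsd_trimmed": trimmed.rmsd, "n_pairs_trimmed": trimmed.n_pairs,
    }
    print(
        f"{domain:12s} {mono_id} vs {poly_id}: "
        f"RMSD {plain.rmsd:.3f} A over {plain.n_pairs} pairs "
        f"(trimmed {trimmed.rmsd:.3f} A over {trimmed.n_pairs})"
    )

if missing:
    print("structure files not found for:")
    for m in missing:
        print(f"  {m}")
    print(f"download the entries into {STRUCTURE_DIR} (see module docstring)")

if results:
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "rmsd.json").write_text(json.dumps(results, indent=2))
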