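# nucleokit

Quantitative toolkit for **nucleation-limited protein assembly switches** —
the mechanism by which adaptor proteins such as BCL10 (of the
CARD–BCL10–MALT1 signalosome) hold cells in a poised, supersaturated state
and then activate NF-κB in all-or-none fashion once a single nucleation
event occurs.

It is written for quantitative cell biologists and biophysicists who work
with DAmFRET-style flow cytometry (per-cell FRET vs. expression across ~4
decades of concentration), single-cell reporter assays, fluorescence
microscopy of puncta/translocation, and death-fold domain structures.

## What it computes

**DAmFRET nucleation-barrier statistics.** Per-cell AmFRET
(FRET intensity / acceptor intensity) is scored against a negative gate
built from a monomer-only control (per-expression-bin 0.99 quantile).  The
expression axis is divided into 64 logarithmically spaced bins and the
fraction of cells above the gate is fit to a Weibull function

```
F(c) = A · (1 − 2^−(c/EC50)^δ)
```

parameterized so that `F(EC50) = A/2`: **EC50** is the median concentration
at which nucleation has occurred and the dimensionless shape **δ** is a
proxy for the conformational contribution to the nucleation barrier.
Profiles are classified as `monomer`, `continuous` (assembly tracks
concentration, no appreciable barrier) or `discontinuous` (bimodal AmFRET
with monomer- and polymer-containing cells overlapping in expression — the
supersaturation signature).

**Stochastic switch kinetics.** Per-cell nucleation is a Poisson process
with hazard `λ = (k_spont + k_stim·dose) · max(0, (c−c_sat)/c_sat)^γ`:
zero at or below the solubility limit, rising with supersaturation and
stimulus.  Nucleated cells switch a reporter fully ON from a dose- and
concentration-independent distribution, so dose controls the *probability*,
never the magnitude, of activation.

**Image quantification.** Synthetic microscopy fields (diffuse / punctate /
filament cells with known ground truth), threshold segmentation, per-cell
coefficient of variation (punctum call at CV > 0.8), nuclear/cytoplasmic
integrated-density ratios, and CV time courses with peak and
return-to-baseline kinetics.

**Structure comparison.** Cα extraction from PDB/mmCIF, residue pairing by
global sequence alignment, and Kabsch (proper-rotation least-squares) RMSD
between the soluble monomer and a polymer protomer of a death-fold domain,
with an optional outlier-trimming mode.

All cytometry quantities are in arbitrary units; no molar calibration is
claimed.  A first-class synthetic-data generator
(`nucleokit.synthetic_cytometry`, `nucleokit.imaging.render_field`)
produces event tables and image fields with the statistical structure the
analyses assume, so every step is testable end to end.

## Worked example

```python
from nucleokit import damfret
from nucleokit import synthetic_cytometry as syn

control = syn.simulate_population(
    syn.PopulationParams(n_cells=200_000, archetype="monomer", rng_seed=0)
)
gate = damfret.build_negative_gate(control)           # 0.99-quantile negative gate

sample = syn.simulate_population(
    syn.PopulationParams(n_cells=500_000, ec50_true=100.0, delta_true=6.0, rng_seed=1)
)
bins = damfret.bin_fraction_assembled(sample, gate)   # 64 log-spaced bins
fit = damfret.fit_weibull(
    bins, n_boot=200, bin_average=True, log_smear_sd=0.05,
    false_positive_rate=1 - gate.quantile,
)
fit.profile_class = damfret.classify_profile(sample, gate, fit)

scale = sample.metadata["acceptor_per_concentration"]
print(f"profile class : {fit.profile_class}")
print(f"EC50          : {fit.ec50 / scale:.1f} a.u. "
      f"(95% CI {fit.ci['ec50'][0] / scale:.1f}-{fit.ci['ec50'][1] / scale:.1f})")
print(f"delta         : {fit.delta:.2f} "
      f"(95% CI {fit.ci['delta'][0]:.2f}-{fit.ci['delta'][1]:.2f})")
```

prints

```
profile class : discontinuous
EC50          : 100.0 a.u. (95% CI 99.7-100.3)
delta         : 5.98 (95% CI 5.87-6.09)
```

i.e. the analysis recovers the generating EC50 = 100 a.u. and δ = 6 from a
half-million-event sample, and recognises the profile as a
nucleation-limited (discontinuous) transition.

## Analysis scripts and CLI

The `analysis/` directory holds numbered drivers that run the full study on
synthetic data and write tables under `results/`:

```
analysis/01_simulate_damfret.py        # event tables for every archetype
analysis/02_fit_nucleation_barriers.py # gates, bins, Weibull fits, t-tests
analysis/03_switch_kinetics.py         # binary dose response, spontaneous onset
analysis/04_image_quantification.py    # puncta calls, translocation, CV kinetics
analysis/05_structure_rmsd.py          # monomer-vs-polymer Cα RMSD
```

The same operations are available from a single CLI:
`nucleokit simulate | analyze | switch | image-sim | image-quant | rmsd | run`.

### Structure files

The monomer/polymer structure pairs (BCL10 CARD: 2MB9 vs 6BZE; CARD9 CARD:
6E26 vs 6N2P; MALT1 DD: 2G7R vs 6GK2) are not bundled.  Download them once
into `data/structures/` (`.pdb` or `.cif`, lower- or upper-case names), e.g.

```
cd data/structures
for id in 2mb9 6bze 6e26 6n2p 2g7r 6gk2; do
    curl -O https://files.rcsb.org/download/${id}.cif
done
```

after which `analysis/05_structure_rmsd.py`, `nucleokit rmsd` and the
structure tests run entirely offline.

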