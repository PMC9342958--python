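#!/usr/bin/env python
"""Simulate DAmFRET samples for each assembly archetype.

Generates one ~5e5-event sample per archetype (monomer control, constitutive
oligomer, threshold polymer, nucleation-limited polymer) plus a seeded-in-
trans copy of the nucleated sample, and writes them under results/events/.
The nucleated sample should show the supersaturation signature — assembled
and unassembled cells overlapping in expression — while the seeded copy
collapses to fully assembled above the saturation onset.
"""

from pathlib import Path

import numpy as np

from nucleokit import io as nio
from nucleokit import synthetic_cytometry as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "events"
OUT.mkdir(parents=True, exist_ok=True)

SAMPLES = {
    "monomer_control": syn.PopulationParams(archetype="monomer", rng_seed=101),
    "constitutive_oligomer": syn.PopulationParams(
        archetype="constitutive_oligomer", plateau=0.9, amfret_high_mean=0.25, rng_seed=102
    ),
    "threshold_polymer": syn.PopulationParams(
        archetype="threshold_polymer", c_star=100.0, ramp_decades=1.0, rng_seed=103
    ),
    "nucleated_polymer": syn.PopulationParams(
        archetype="nucleated_polymer", ec50_true=100.0, delta_true=3.0, rng_seed=104
    ),
    "nucleated_polymer_seeded": syn.PopulationParams(
        archetype="nucleated_polymer", ec50_true=100.0, delta_true=3.0,
        seeded=True, rng_seed=104,
    ),
}

for name, params in SAMPLES.items():
    table = syn.simulate_population(params)
    nio.write_events_csv(table, OUT / f"{name}.csv")
    c = table.data["concentration"].to_numpy()
    a = table.truth_assembled
    frac = a.mean()
    overlap = np.log10(c[~a].max() / c[a].min()) if a.any() and (~a).any() else 0.0
    print(
        f"{name:28s} n={len(table):>7d} assembled={frac:6.1%} "
        f"expression-overlap={overlap:5.2f} decades"
    )
print(f"\nwrote event tables to {OUT}")
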