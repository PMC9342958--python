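"""Synthetic single-cell DAmFRET event generator.

The generator emulates the statistical structure of a DAmFRET experiment:
a protein fused to a green-to-red photoconvertible fluorophore is expressed
from a construct whose copy number varies cell-to-cell, sampling roughly
four decades of intracellular concentration.  A fixed fraction ``p`` of
molecules is photoconverted to the FRET-acceptor (red) form; the remainder
stay in the donor (green) form.  Cells in which the protein has assembled
show high FRET-channel signal relative to acceptor intensity (AmFRET),
cells with only monomer show none, and — for a nucleation-limited protein —
the two populations overlap in expression with a striking paucity of cells
at intermediate AmFRET, because polymerization runs to completion quickly
once a nucleus forms.

Four assembly archetypes are provided:

``monomer``
    never assembles (negative control, e.g. the fluorophore alone).
``constitutive_oligomer``
    a fixed fraction ``A`` of cells carries low-grade assemblies at every
    concentration (no nucleation barrier at the cellular level).
``threshold_polymer``
    assembles deterministically above a solubility threshold ``c_star``
    with at most a slight discontinuity (CARD9-CARD-like behaviour).
``nucleated_polymer``
    probability of containing polymer follows a Weibull function of
    concentration, F(c) = A * (1 - 2**-(c/EC50)**delta), so EC50 is
    literally the median concentration at which nucleation has occurred.

Seeding in trans (a condensed template supplied by a second construct) is
modelled by forcing assembly in every cell whose concentration exceeds a
saturation-onset concentration well below EC50, reflecting that a seed
removes the nucleation barrier but cannot drive assembly below solubility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from nucleokit.events import EventTable

log = logging.getLogger(__name__)

ARCHETYPES = ("monomer", "constitutive_oligomer", "threshold_polymer", "nucleated_polymer")

#: events per flow sample (experiments of this kind collect ~5e5 events)
DEFAULT_N_CELLS = 500_000


@dataclass
class PopulationParams:
    """Parameters of one simulated expression population.

    Concentrations and intensities are in arbitrary units (a.u.).  Channel
    gains and noise levels default to values that give the monomer control
    an AmFRET standard deviation of ~0.05 at mid-expression.
    """

    n_cells: int = DEFAULT_N_CELLS
    c_min: float = 1.0
    c_max: float = 1e4  # four decades, mimicking plasmid copy-number variation
    photoconversion_fraction: float = 0.1
    archetype: str = "nucleated_polymer"
    ec50_true: float = 100.0
    delta_true: float = 3.0
    c_star: float = 100.0
    amfret_low_mean: float = 0.0
    amfret_low_sd: float = 0.03
    amfret_high_mean: float = 0.55
    amfret_high_sd: float = 0.05
    noise_floor: float = 1.0
    plateau: float = 1.0
    seeded: bool = False
    seed_onset_factor: float = 0.1  # seeded cells assemble above ec50_true * this
    ramp_decades: float = 0.0  # >0: assembled AmFRET ramps low->high over this many decades
    gain_acceptor: float = 20.0
    gain_donor: float = 10.0
    donor_loss: float = 0.3  # donor quench per unit of true AmFRET
    detection_cv: float = 0.05  # lognormal multiplicative noise per channel
    fret_noise_rel: float = 0.04  # additive FRET-channel noise, relative to acceptor
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}")
        if not (0 < self.c_min <= self.c_max):
            raise ValueError("require 0 < c_min <= c_max")
        if not (0 < self.photoconversion_fraction < 1):
            raise ValueError("photoconversion fraction must lie in (0, 1)")
        if self.amfret_high_mean <= self.amfret_low_mean:
            raise ValueError("amfret_high_mean must exceed amfret_low_mean")
        if not (0 < self.plateau <= 1):
            raise ValueError("plateau must lie in (0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.delta_true < 0:
            raise ValueError("delta_true must be >= 0")


def sample_expression(params: PopulationParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-cell concentrations, log-uniform on [c_min, c_max]."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if params.n_cells == 0:
        return np.empty(0)
    lo, hi = np.log(params.c_min), np.log(params.c_max)
    return np.exp(rng.uniform(lo, hi, size=params.n_cells))


def assembly_probability(c: float | np.ndarray, params: PopulationParams) -> float | np.ndarray:
    """Probability that a cell at concentration ``c`` contains assembled protein.

    For the nucleated archetype this is the Weibull form
    F(c) = A * (1 - 2**-(c/EC50)**delta), chosen so that F(EC50) = A/2.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("concentration must be positive")
    A = params.plateau
    if params.archetype == "monomer":
        out = np.zeros_like(c_arr)
    elif params.archetype == "constitutive_oligomer":
        out = np.full_like(c_arr, A)
    elif params.archetype == "threshold_polymer":
        out = np.where(c_arr > params.c_star, A, 0.0)
    else:  # nucleated_polymer
        with np.errstate(over="ignore"):
            out = A * (1.0 - np.exp2(-((c_arr / params.ec50_true) ** params.delta_true)))
    return float(out) if np.isscalar(c) else out


def _onset_concentration(params: PopulationParams) -> float:
    """Concentration above which an in-trans seed drives assembly."""
    if params.archetype == "threshold_polymer":
        return params.c_star * params.seed_onset_factor
    return params.ec50_true * params.seed_onset_factor


def simulate_population(params: PopulationParams) -> EventTable:
    """Simulate one flow sample of ``params.n_cells`` events.

    Channel model (all a.u.):

    * acceptor  = gain_a * p * c * LN(detection_cv) + N(0, noise_floor)
    * donor     = gain_d * (1-p) * c * (1 - donor_loss * a_true) * LN(detection_cv)
                  + N(0, noise_floor)
    * fret      = a_true * acceptor + N(0, fret_noise_rel * acceptor + noise_floor)

    where a_true is drawn from the low (monomer) or high (polymer) AmFRET
    component according to the cell's assembled state, so that measured
    AmFRET = fret/acceptor is bimodal with few intermediate cells.
    """
    rng = np.random.default_rng(params.rng_seed)
    c = sample_expression(params, rng)
    n = c.size
    if n:
        assembled = rng.random(n) < assembly_probability(c, params)
    else:
        assembled = np.zeros(0, dtype=bool)
    if params.seeded:
        assembled = assembled | (c > _onset_concentration(params))

    high_mean = np.full(n, params.amfret_high_mean)
    if params.ramp_decades > 0 and n:
        # graded assemblies: mean AmFRET of assembled cells climbs from the
        # low to the high level over `ramp_decades` above the onset
        onset = params.c_star if params.archetype == "threshold_polymer" else params.ec50_true
        t = np.clip(np.log10(np.maximum(c, 1e-300) / onset) / params.ramp_decades, 0.0, 1.0)
        high_mean = params.amfret_low_mean + t * (params.amfret_high_mean - params.amfret_low_mean)

    a_true = np.where(
        assembled,
        rng.normal(high_mean, params.amfret_high_sd, n),
        rng.normal(params.amfret_low_mean, params.amfret_low_sd, n),
    )

    p = params.photoconversion_fraction
    ln_sd = params.detection_cv
    acceptor = (
        params.gain_acceptor * p * c * rng.lognormal(0.0, ln_sd, n)
        + rng.normal(0.0, params.noise_floor, n)
    )
    donor = (
        params.gain_donor * (1 - p) * c * (1 - params.donor_loss * np.clip(a_true, 0, None))
        * rng.lognormal(0.0, ln_sd, n)
        + rng.normal(0.0, params.noise_floor, n)
    )
    fret = a_true * acceptor + rng.normal(
        0.0, params.fret_noise_rel * np.abs(acceptor) + params.noise_floor, n
    )

    data = pd.DataFrame(
        {
            "donor": np.maximum(donor, 0.0),
            "acceptor": acceptor,  # may rarely dip <= 0 at the noise floor; analysis flags those
            "fret": fret,
            "truth_assembled": assembled,
            "concentration": c,
        }
    )
    meta = {
        "construct": params.archetype,
        "archetype": params.archetype,
        "generator": asdict(params),
        "seed": params.rng_seed,
        "acceptor_per_concentration": params.gain_acceptor * p,
    }
    return EventTable(data, meta)


def attach_reporter(
    table: EventTable,
    on_mean: float = 1000.0,
    on_sd: float = 0.25,
    off_mean: float = 10.0,
    off_sd: float = 0.5,
    rng_seed: int | None = None,
) -> EventTable:
    """Attach a binary transcriptional-reporter channel.

    Assembled cells draw from the ON distribution, unassembled cells from the
    OFF distribution.  Both are lognormal with median ``*_mean`` and log-sd
    ``*_sd``; the ON distribution is independent of expression level and of
    any stimulus covariate — assembly raises the *probability*, never the
    magnitude, of the response.  ``*_mean == 0`` gives exactly zero signal.
    """
    if not table.has_truth:
        raise ValueError("attach_reporter requires a table with truth_assembled flags")
    if rng_seed is None:
        rng_seed = int(table.metadata.get("seed", 0)) + 7_777
    rng = np.random.default_rng(rng_seed)
    assembled = table.truth_assembled
    n = len(table)

    def draw(median: float, sd: float) -> np.ndarray:
        if median == 0:
            return np.zeros(n)
        if sd == 0:
            return np.full(n, median)
        return median * rng.lognormal(0.0, sd, n)

    reporter = np.where(assembled, draw(on_mean, on_sd), draw(off_mean, off_sd))
    out = table.copy()
    out.data["reporter"] = reporter
    out.metadata["reporter_params"] = {
        "on_mean": on_mean, "on_sd": on_sd, "off_mean": off_mean, "off_sd": off_sd,
        "rng_seed": rng_seed,
    }
    return out
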