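"""DAmFRET quantification: gating, binning, Weibull fits and profile classes.

The analysis mirrors the standard DAmFRET workflow: per-cell AmFRET
(FRET intensity / acceptor intensity) is plotted against acceptor intensity
(a proxy for expression level); a negative gate built from a monomer-only
control marks the AmFRET range of unassembled protein; the expression axis
is divided into 64 logarithmically spaced bins and the fraction of cells
above the negative gate is computed per bin; that fraction-versus-expression
profile is fit to a Weibull function

    F(c) = A * (1 - 2**-(c / EC50)**delta)

so that F(EC50) = A/2: EC50 is the median concentration at which nucleation
has occurred, and the dimensionless shape delta is a proxy for the
conformational contribution to the nucleation barrier.  Profiles are finally
classified as ``monomer`` (nothing assembles), ``discontinuous`` (bimodal
AmFRET with broad expression overlap between monomer- and polymer-containing
cells — the signature of a nucleation-limited transition from a
supersaturated state) or ``continuous`` (assembly tracks concentration with
no appreciable barrier).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from nucleokit.events import EventTable

log = logging.getLogger(__name__)

N_BINS_DEFAULT = 64
NEGATIVE_GATE_QUANTILE = 0.99
MIN_BIN_OCCUPANCY = 50


# ---------------------------------------------------------------------------
# AmFRET and gating
# ---------------------------------------------------------------------------

def compute_amfret(fret: np.ndarray, acceptor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AmFRET = fret / acceptor, with a validity mask.

    Events with acceptor <= 0 have no defined AmFRET; they are flagged
    invalid (mask False, value NaN) rather than silently zeroed.
    """
    fret = np.asarray(fret, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    valid = acceptor > 0
    out = np.full(fret.shape, np.nan)
    np.divide(fret, acceptor, out=out, where=valid)
    return out, valid


def amfret_of(table: EventTable) -> tuple[np.ndarray, np.ndarray]:
    return compute_amfret(table.fret, table.acceptor)


@dataclass
class GateSpec:
    """Expression window plus a per-bin negative-gate AmFRET boundary."""

    expression_min: float = 0.0
    expression_max: float = np.inf
    quantile: float = NEGATIVE_GATE_QUANTILE
    bin_edges: np.ndarray | None = None  # geometric edges of the control binning
    boundary: np.ndarray | None = None  # per-bin AmFRET upper bound
    global_boundary: float = np.inf  # fallback for sparse/out-of-range bins
    fallback_bins: list[int] = field(default_factory=list)

    def boundary_at(self, acceptor: np.ndarray) -> np.ndarray:
        """Negative-gate boundary evaluated at each event's acceptor intensity."""
        acceptor = np.asarray(acceptor, dtype=float)
        if self.bin_edges is None or self.boundary is None:
            return np.full(acceptor.shape, self.global_boundary)
        idx = np.searchsorted(self.bin_edges, acceptor, side="right") - 1
        out = np.full(acceptor.shape, self.global_boundary)
        inside = (idx >= 0) & (idx < len(self.boundary))
        out[inside] = self.boundary[idx[inside]]
        return out


def gate_events(table: EventTable, gate: GateSpec | None = None) -> EventTable:
    """Retain double-positive events within the expression window.

    Synthetic events carry no scatter channels, so gating reduces to
    donor > 0, acceptor > 0 and acceptor within the expression window.
    Counts in/out are recorded in the returned table's metadata.
    """
    if gate is None:
        gate = GateSpec()
    acceptor = table.acceptor
    keep = (table.donor > 0) & (acceptor > 0)
    keep &= (acceptor >= gate.expression_min) & (acceptor <= gate.expression_max)
    out = table.subset(keep, gating={"n_in": int(keep.sum()), "n_out": int((~keep).sum())})
    if len(out) == 0:
        warnings.warn("gating removed every event", stacklevel=2)
    return out


def geometric_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo = float(np.min(values))
    hi = float(np.max(values))
    if lo <= 0:
        raise ValueError("geometric binning requires positive values")
    if lo == hi:  # degenerate range: one nominal bin around the point mass
        return np.array([lo * 0.999, hi * 1.001])
    return np.geomspace(lo, hi, n_bins + 1)


def build_negative_gate(
    monomer_control: EventTable,
    quantile: float = NEGATIVE_GATE_QUANTILE,
    n_bins: int = N_BINS_DEFAULT,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
) -> GateSpec:
    """Per-expression-bin AmFRET quantile boundary from a monomer-only control.

    Bins with fewer than ``min_occupancy`` control events inherit the global
    quantile; which bins fell back is recorded for provenance.
    """
    if not (0.5 < quantile < 1):
        raise ValueError("quantile must lie in (0.5, 1)")
    gated = gate_events(monomer_control)
    if len(gated) == 0:
        raise ValueError("monomer control is empty after gating")
    amfret, valid = amfret_of(gated)
    acceptor = gated.acceptor[valid]
    amfret = amfret[valid]
    edges = geometric_edges(acceptor, n_bins)
    idx = np.clip(np.searchsorted(edges, acceptor, side="right") - 1, 0, len(edges) - 2)
    global_boundary = float(np.quantile(amfret, quantile))
    boundary = np.full(len(edges) - 1, global_boundary)
    fallback = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n_b = int(sel.sum())
        if n_b >= min_occupancy:
            boundary[b] = float(np.quantile(amfret[sel], quantile))
        elif n_b > 0:
            fallback.append(b)
    return GateSpec(
        quantile=quantile,
        bin_edges=edges,
        boundary=boundary,
        global_boundary=global_boundary,
        fallback_bins=fallback,
    )


# ---------------------------------------------------------------------------
# Binned fraction assembled
# ---------------------------------------------------------------------------

@dataclass
class BinTable:
    """Fraction of cells above the negative gate in geometric expression bins."""

    edges: np.ndarray
    centers: np.ndarray
    n_total: np.ndarray
    n_assembled: np.ndarray

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_assembled / self.n_total, np.nan)

    @property
    def occupied(self) -> np.ndarray:
        return self.n_total > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "center": self.centers,
                "n_total": self.n_total,
                "n_assembled": self.n_assembled,
                "fraction": self.fraction,
            }
        )


def bin_fraction_assembled(
    table: EventTable,
    gate: GateSpec,
    n_bins: int = N_BINS_DEFAULT,
    range_quantiles: tuple[float, float] = (0.001, 0.999),
) -> BinTable:
    """64-bin fraction-assembled profile of a gated event table.

    Bin edges span the robust acceptor range (``range_quantiles``) so that a
    handful of noise-floor events cannot stretch the geometric binning; the
    few events outside that range are dropped.
    """
    gated = gate_events(table, gate)
    if len(gated) == 0:
        raise ValueError("no events to bin after gating")
    amfret, valid = amfret_of(gated)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("excluding %d events with non-positive acceptor", n_invalid)
    acceptor = gated.acceptor[valid]
    amfret = amfret[valid]
    lo_q, hi_q = np.quantile(acceptor, range_quantiles)
    in_range = (acceptor >= lo_q) & (acceptor <= hi_q)
    acceptor, amfret = acceptor[in_range], amfret[in_range]
    above = amfret > gate.boundary_at(acceptor)
    edges = geometric_edges(acceptor, n_bins)
    idx = np.clip(np.searchsorted(edges, acceptor, side="right") - 1, 0, len(edges) - 2)
    n_bins_eff = len(edges) - 1
    n_total = np.bincount(idx, minlength=n_bins_eff)
    n_assembled = np.bincount(idx, weights=above.astype(float), minlength=n_bins_eff).astype(int)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return BinTable(edges=edges, centers=centers, n_total=n_total, n_assembled=n_assembled)


# ---------------------------------------------------------------------------
# Weibull fitting
# ---------------------------------------------------------------------------

def weibull_fraction(c: np.ndarray, ec50: float, delta: float, plateau: float = 1.0) -> np.ndarray:
    """F(c) = A * (1 - 2**-(c/EC50)**delta); F(EC50) = A/2."""
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore"):
        return plateau * (1.0 - np.exp2(-((c / ec50) ** delta)))


@dataclass
class WeibullFit:
    ec50: float
    delta: float
    plateau: float
    residual_norm: float
    n_bins_used: int
    n_events: int
    censored: bool = False
    profile_class: str | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "ec50": None if self.censored else self.ec50,
            "delta": None if self.censored else self.delta,
            "plateau": self.plateau,
            "residual_norm": self.residual_norm,
            "n_bins_used": self.n_bins_used,
            "n_events": self.n_events,
            "censored": self.censored,
            "profile_class": self.profile_class,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_boot": self.n_boot,
        }


def _model_factory(
    centers: np.ndarray,
    edges_lo: np.ndarray | None,
    edges_hi: np.ndarray | None,
    log_smear_sd: float = 0.0,
    false_positive_rate: float = 0.0,
):
    """Predicted bin fraction at each measured-expression bin.

    Optionally (a) Simpson-averages the Weibull over the bin instead of
    evaluating at the geometric center, (b) convolves it with a lognormal
    measurement kernel of log-sd ``log_smear_sd`` (Gauss-Hermite quadrature):
    under log-uniform expression sampling, the assembled fraction observed at
    measured intensity a is E[F(c) | a], i.e. F smeared by the detection
    noise, and a steep profile fitted without the kernel reads too shallow;
    and (c) accounts for the gate's known false-positive floor — a quantile-q
    negative gate passes unassembled cells at rate alpha = 1 - q, so the
    observed fraction is alpha + (1 - alpha) * F.
    """
    if log_smear_sd > 0:
        z, w = np.polynomial.hermite_e.hermegauss(7)
        w = w / w.sum()
        shifts = np.exp(log_smear_sd * z)

        def F(c: np.ndarray, ec50: float, delta: float, A: float) -> np.ndarray:
            return (w[:, None] * weibull_fraction(c[None, :] * shifts[:, None], ec50, delta, A)).sum(axis=0)

    else:
        F = lambda c, ec50, delta, A: weibull_fraction(c, ec50, delta, A)  # noqa: E731

    if edges_lo is None:

        def raw(ec50: float, delta: float, A: float) -> np.ndarray:
            return F(centers, ec50, delta, A)

    else:

        def raw(ec50: float, delta: float, A: float) -> np.ndarray:
            return (
                F(edges_lo, ec50, delta, A)
                + 4.0 * F(centers, ec50, delta, A)
                + F(edges_hi, ec50, delta, A)
            ) / 6.0

    if false_positive_rate <= 0:
        return raw
    alpha = false_positive_rate

    def model(ec50: float, delta: float, A: float) -> np.ndarray:
        return alpha + (1.0 - alpha) * raw(ec50, delta, A)

    return model


def _wls_fit(
    centers: np.ndarray,
    fractions: np.ndarray,
    weights: np.ndarray,
    fit_plateau: bool,
    x0_list: Sequence[np.ndarray],
    model=None,
) -> tuple[np.ndarray, float]:
    """Weighted least squares over log-EC50, log-delta (and logit-plateau)."""
    if model is None:
        model = _model_factory(centers, None, None)
    sw = np.sqrt(weights)
    ndim = 3 if fit_plateau else 2

    def resid(x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):  # wild optimizer excursions are harmless
            ec50, delta = np.exp(x[0]), np.exp(x[1])
            A = 1.0 / (1.0 + np.exp(-x[2])) if fit_plateau else 1.0
        return sw * (model(ec50, delta, A) - fractions)

    best, best_cost = None, np.inf
    for x0 in x0_list:
        x0 = np.asarray(x0, dtype=float)
        if x0.size < ndim:
            x0 = np.concatenate([x0, np.zeros(ndim - x0.size)])
        try:
            sol = optimize.least_squares(resid, x0[:ndim], method="lm", max_nfev=2000)
        except Exception:  # singular start etc.
            continue
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    if best is None:
        raise RuntimeError("Weibull fit failed to converge from every start")
    if best.size < 3:
        best = np.concatenate([best, [np.inf]])  # logit(A)=inf -> A=1
    return best, best_cost


def _starts(centers: np.ndarray, fit_plateau: bool) -> list[np.ndarray]:
    log_ec50 = np.log(np.geomspace(centers.min(), centers.max(), 6))
    log_delta = np.log([0.3, 1.0, 3.0, 8.0])
    a0 = 0.0  # logit(0.5)
    return [
        np.array([le, ld, a0]) for le in log_ec50 for ld in log_delta
    ]


def _binomial_nll_fit(bins: BinTable, fit_plateau: bool, x0: np.ndarray) -> tuple[np.ndarray, float]:
    """Event-wise binomial maximum likelihood on the same bins (optional path)."""
    occ = bins.occupied
    centers, n, k = bins.centers[occ], bins.n_total[occ], bins.n_assembled[occ]
    ndim = 3 if fit_plateau else 2

    def nll(x: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            ec50, delta = np.exp(x[0]), np.exp(x[1])
            A = 1.0 / (1.0 + np.exp(-x[2])) if fit_plateau else 1.0
        p = np.clip(weibull_fraction(centers, ec50, delta, A), 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    sol = optimize.minimize(
        nll, np.asarray(x0)[:ndim], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    x = sol.x if sol.x.size == 3 else np.concatenate([sol.x, [np.inf]])
    return x, float(sol.fun)


def fit_weibull(
    bins: BinTable,
    fit_plateau: bool = False,
    n_boot: int = 200,
    rng_seed: int = 0,
    method: str = "wls",
    min_bins: int = 8,
    bin_average: bool = False,
    log_smear_sd: float = 0.0,
    false_positive_rate: float = 0.0,
) -> WeibullFit:
    """Fit the Weibull fraction-assembled model to a bin table.

    Default is weighted least squares on (bin center, fraction) with weights
    equal to bin occupancy, multi-started over a grid of log-EC50 and
    log-delta.  ``method="binomial"`` instead maximizes the event-wise
    binomial likelihood on the same bins.  ``bin_average=True`` compares each
    bin's fraction against the Weibull model averaged over the bin (Simpson
    rule in log-concentration) rather than evaluated at the geometric center,
    removing the discretization bias on steep profiles.  Bootstrap confidence
    intervals resample events (equivalently, multinomial over per-bin outcome
    counts, bins held fixed).

    All-zero profiles are censored as class ``monomer``: EC50 and delta are
    then reported as undefined, never extrapolated.
    """
    occ = bins.occupied
    n_occ = int(occ.sum())
    n_events = int(bins.n_total.sum())
    if n_occ < min_bins:
        raise ValueError(f"need >= {min_bins} occupied bins, got {n_occ}")
    span = bins.centers[occ].max() / bins.centers[occ].min()
    if span < 10:
        raise ValueError("occupied bins must span more than one decade of expression")

    centers = bins.centers[occ]
    fractions = bins.fraction[occ]
    weights = bins.n_total[occ].astype(float)
    e_lo = bins.edges[:-1][occ] if bin_average else None
    e_hi = bins.edges[1:][occ] if bin_average else None
    model = _model_factory(centers, e_lo, e_hi, log_smear_sd, false_positive_rate)

    overall = bins.n_assembled.sum() / max(n_events, 1)
    alpha = max(false_positive_rate, 0.0)
    overall = max(0.0, (overall - alpha) / (1.0 - alpha))  # excess over the gate floor
    if overall < 0.01 and fractions.max() < alpha + 0.05:
        return WeibullFit(
            ec50=np.nan, delta=np.nan, plateau=0.0,
            residual_norm=float(np.sqrt(np.sum(weights * fractions**2))),
            n_bins_used=n_occ, n_events=n_events, censored=True, profile_class="monomer",
        )

    x, cost = _wls_fit(
        centers, fractions, weights, fit_plateau, _starts(centers, fit_plateau), model=model
    )
    if method == "binomial":
        x, cost = _binomial_nll_fit(bins, fit_plateau, x)
    elif method != "wls":
        raise ValueError(f"unknown fit method {method!r}")
    ec50, delta = float(np.exp(x[0])), float(np.exp(x[1]))
    plateau = float(1.0 / (1.0 + np.exp(-x[2]))) if fit_plateau else 1.0

    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        # event-level bootstrap with bins preserved == multinomial over the
        # 2 * n_bins (bin, assembled?) outcome categories
        counts = np.concatenate([bins.n_assembled[occ], bins.n_total[occ] - bins.n_assembled[occ]])
        probs = counts / counts.sum()
        boot_params = []
        for _ in range(n_boot):
            draw = rng.multinomial(n_events, probs)
            k_b = draw[: n_occ].astype(float)
            n_b = k_b + draw[n_occ:]
            keep = n_b > 0
            if keep.sum() < min_bins:
                continue
            frac_b = k_b[keep] / n_b[keep]
            model_b = _model_factory(
                centers[keep],
                e_lo[keep] if bin_average else None,
                e_hi[keep] if bin_average else None,
                log_smear_sd,
                false_positive_rate,
            )
            try:
                xb, _ = _wls_fit(centers[keep], frac_b, n_b[keep], fit_plateau, [x], model=model_b)
            except RuntimeError:
                continue
            Ab = 1.0 / (1.0 + np.exp(-xb[2])) if fit_plateau else 1.0
            boot_params.append((np.exp(xb[0]), np.exp(xb[1]), Ab))
        if boot_params:
            arr = np.asarray(boot_params)
            for name, col in zip(("ec50", "delta", "plateau"), arr.T):
                lo, hi = np.quantile(col, [0.025, 0.975])
                ci[name] = (float(lo), float(hi))

    return WeibullFit(
        ec50=ec50, delta=delta, plateau=plateau,
        residual_norm=float(np.sqrt(2 * cost)),
        n_bins_used=n_occ, n_events=n_events, ci=ci, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Profile classification
# ---------------------------------------------------------------------------

def classify_profile(
    table: EventTable,
    gate: GateSpec,
    fit: WeibullFit,
    dip_threshold: float = 0.5,
    overlap_decades: float = 1.0,
    min_events: int = 200,
    coexist_min: int = 3,
    n_bins: int = N_BINS_DEFAULT,
) -> str:
    """Classify a DAmFRET profile as monomer / continuous / discontinuous.

    ``discontinuous`` requires both (a) a bimodal AmFRET histogram within the
    expression decade around EC50 (relative dip at the inter-mode midpoint
    above ``dip_threshold``) and (b) assembled and unassembled cells
    coexisting over at least ``overlap_decades`` of expression — together
    the signature of nucleation-limited assembly from a supersaturated pool.

    Both the monomer rule and the coexistence test are corrected for the
    negative gate's expected false-positive floor alpha = 1 - quantile:
    ``monomer`` means the *excess* assembled fraction over that floor is
    below 1%, and a bin only counts as containing assembled cells when its
    above-gate count exceeds the binomial background at three sigma.
    """
    gated = gate_events(table, gate)
    amfret, valid = amfret_of(gated)
    acceptor = gated.acceptor[valid]
    amfret = amfret[valid]
    if amfret.size == 0:
        return "indeterminate"
    above = amfret > gate.boundary_at(acceptor)
    alpha = 1.0 - gate.quantile
    excess = (above.mean() - alpha) / (1.0 - alpha)
    if excess < 0.01 or fit.censored:
        return "monomer"

    # (b) expression overlap between assembled and unassembled cells
    edges = geometric_edges(acceptor, n_bins)
    idx = np.clip(np.searchsorted(edges, acceptor, side="right") - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    n_tot = np.bincount(idx, minlength=nb)
    n_above = np.bincount(idx, weights=above.astype(float), minlength=nb)
    n_below = np.bincount(idx, weights=(~above).astype(float), minlength=nb)
    background = n_tot * alpha + 3.0 * np.sqrt(np.maximum(n_tot * alpha * (1 - alpha), 0.0))
    coexist = (n_above >= np.maximum(coexist_min, background)) & (n_below >= coexist_min)
    bin_width_dec = np.log10(edges[1] / edges[0])
    overlap = float(coexist.sum() * bin_width_dec)

    # (a) bimodality in the decade around EC50
    if np.isfinite(fit.ec50):
        lo, hi = fit.ec50 / np.sqrt(10), fit.ec50 * np.sqrt(10)
    else:
        lo, hi = np.quantile(acceptor, [0.25, 0.75])
    window = (acceptor >= lo) & (acceptor <= hi)
    if window.sum() < min_events:
        return "indeterminate"
    a_w = amfret[window]
    above_w = above[window]
    dip = 0.0
    if above_w.any() and (~above_w).any():
        hist, h_edges = np.histogram(a_w, bins=40)
        hist = np.convolve(hist, np.ones(3) / 3, mode="same")  # light smoothing
        h_centers = 0.5 * (h_edges[:-1] + h_edges[1:])
        b = float(np.median(gate.boundary_at(acceptor[window])))
        below_side = h_centers <= b
        if below_side.any() and (~below_side).any():
            low_peak_i = int(np.argmax(np.where(below_side, hist, -1)))
            high_peak_i = int(np.argmax(np.where(~below_side, hist, -1)))
            mid = 0.5 * (h_centers[low_peak_i] + h_centers[high_peak_i])
            mid_i = int(np.argmin(np.abs(h_centers - mid)))
            peak = min(hist[low_peak_i], hist[high_peak_i])
            if peak > 0:
                dip = 1.0 - hist[mid_i] / peak
    if dip > dip_threshold and overlap >= overlap_decades:
        return "discontinuous"
    return "continuous"


# ---------------------------------------------------------------------------
# Replicate comparison
# ---------------------------------------------------------------------------

def compare_fits(
    fits: dict[str, Sequence[WeibullFit]], reference: str | None = None
) -> pd.DataFrame:
    """Group means +/- sd of EC50 and delta with Welch t-tests vs. a reference.

    ``fits`` maps group label -> replicate fits.  Groups with a single
    replicate get a descriptive row only (no p-value).
    """
    if len(fits) < 2:
        raise ValueError("need at least two groups to compare")
    if reference is None:
        reference = next(iter(fits))
    ref_vals = {
        p: np.array([getattr(f, p) for f in fits[reference] if not f.censored])
        for p in ("ec50", "delta")
    }
    rows = []
    for group, reps in fits.items():
        row: dict = {"group": group, "n_replicates": len(reps)}
        for p in ("ec50", "delta"):
            vals = np.array([getattr(f, p) for f in reps if not f.censored])
            row[f"{p}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{p}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            if group == reference or len(reps) < 2 or len(fits[reference]) < 2:
                row[f"{p}_p_value"] = np.nan
            else:
                if np.allclose(vals.mean(), ref_vals[p].mean()) and np.allclose(
                    vals.std(ddof=1), 0
                ) and np.allclose(ref_vals[p].std(ddof=1), 0):
                    row[f"{p}_p_value"] = 1.0  # identical degenerate groups
                else:
                    t = stats.ttest_ind(vals, ref_vals[p], equal_var=False)
                    row[f"{p}_p_value"] = float(t.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
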