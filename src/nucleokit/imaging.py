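"""Synthetic microscopy fields and puncta / translocation quantification.

The renderer draws disk-shaped cells with inner-disk nuclei on a jittered
grid.  The protein channel of each cell is ``diffuse`` (flat), ``punctate``
(a few bright Gaussian spots holding most of the intensity) or ``filament``
(an anisotropic line segment); an optional p65-style channel splits its
integrated density between nucleus and cytoplasm at a set ratio.  Photon
(Poisson) and read (Gaussian) noise are applied to every channel.

Quantification follows the standard workflow: threshold segmentation of
cells and nuclei, then per-cell metrics —

* CV (coefficient of variation): sd/mean of in-mask pixel intensities;
  cells with CV above 0.8 are called punctum-positive.
* nuc/cyt ratio: nuclear over cytoplasmic integrated density, the readout
  of transcription-factor nuclear translocation.
* CV time course: per-cell CV per frame with peak time and
  return-to-baseline time, for transient-clustering kinetics.

Segmentation is deliberately pluggable: any label image (e.g. produced by a
learned segmenter on real data) can be passed wherever masks are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

CV_THRESHOLD = 0.8  # punctum call: CV above this value
STATES = ("diffuse", "punctate", "filament")


@dataclass
class CellField:
    """Rendered field: channel images plus ground-truth masks and states."""

    protein: np.ndarray
    nucleus: np.ndarray
    p65: np.ndarray | None
    cell_labels: np.ndarray  # ground-truth label image, 0 = background
    nucleus_labels: np.ndarray
    states: list[str]
    nc_ratios_true: list[float]
    pixel_size_um: float = 0.2


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def render_field(
    n_cells: int = 16,
    state_mix: dict[str, float] | None = None,
    shape: tuple[int, int] = (512, 512),
    cell_radius: float = 18.0,
    nucleus_radius: float = 8.0,
    total_intensity: float = 100_000.0,
    spot_fraction: float = 0.8,
    n_spots: int = 3,
    spot_sigma: float = 1.5,
    filament_fraction: float = 0.7,
    background: float = 5.0,
    read_noise_sd: float = 2.0,
    nc_ratio: float | Sequence[float] = 1.0,
    poisson_noise: bool = True,
    rng_seed: int = 0,
) -> CellField:
    """Render a synthetic field of disk cells with known per-cell state.

    ``state_mix`` maps state -> probability and must sum to 1.  Cells are
    placed on a jittered square grid with disjoint masks; asking for more
    cells than the grid holds raises a layout error.
    """
    if state_mix is None:
        state_mix = {"diffuse": 1.0}
    if abs(sum(state_mix.values()) - 1.0) > 1e-9:
        raise ValueError("state_mix must sum to 1")
    if any(s not in STATES for s in state_mix):
        raise ValueError(f"states must be among {STATES}")
    rng = np.random.default_rng(rng_seed)

    pitch = int(np.ceil(2 * cell_radius + 8))
    ny, nx = (shape[0] - pitch // 2) // pitch, (shape[1] - pitch // 2) // pitch
    if n_cells > ny * nx:
        raise ValueError(f"cannot place {n_cells} disjoint cells on a {ny}x{nx} grid")

    protein = np.full(shape, float(background))
    nucleus_ch = np.full(shape, float(background))
    p65_ch = np.full(shape, float(background))
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    slots = [(iy, ix) for iy in range(ny) for ix in range(nx)]
    rng.shuffle(slots)
    names = list(state_mix)
    probs = np.array([state_mix[s] for s in names])
    states: list[str] = []
    ratios = (
        list(np.broadcast_to(np.asarray(nc_ratio, dtype=float), (n_cells,)))
        if np.ndim(nc_ratio) == 0 or len(np.atleast_1d(nc_ratio)) in (1, n_cells)
        else None
    )
    if ratios is None:
        raise ValueError("nc_ratio must be scalar or length n_cells")

    jitter = max(1.0, (pitch - 2 * cell_radius) / 2 - 1)
    for i in range(n_cells):
        iy, ix = slots[i]
        cy = pitch // 2 + iy * pitch + cell_radius + rng.uniform(-jitter, jitter)
        cx = pitch // 2 + ix * pitch + cell_radius + rng.uniform(-jitter, jitter)
        cell = _disk_mask(shape, cy, cx, cell_radius)
        nuc = _disk_mask(shape, cy, cx, nucleus_radius)
        cell_labels[cell] = i + 1
        nucleus_labels[nuc] = i + 1
        state = str(rng.choice(names, p=probs))
        states.append(state)
        area = int(cell.sum())

        if state == "diffuse":
            protein[cell] += total_intensity / area
        elif state == "punctate":
            protein[cell] += (1 - spot_fraction) * total_intensity / area
            yy, xx = np.nonzero(cell)
            for _ in range(n_spots):
                j = rng.integers(len(yy))
                sy, sx = yy[j], xx[j]
                gy, gx = np.ogrid[: shape[0], : shape[1]]
                spot = np.exp(-(((gy - sy) ** 2 + (gx - sx) ** 2) / (2 * spot_sigma**2)))
                spot *= cell
                s = spot.sum()
                if s > 0:
                    protein += spot * (spot_fraction * total_intensity / n_spots / s)
        else:  # filament: bright line through the cell centre
            protein[cell] += (1 - filament_fraction) * total_intensity / area
            theta = rng.uniform(0, np.pi)
            yy, xx = np.mgrid[: shape[0], : shape[1]]
            dy, dx = yy - cy, xx - cx
            along = dy * np.sin(theta) + dx * np.cos(theta)
            perp = dy * np.cos(theta) - dx * np.sin(theta)
            line = (np.abs(along) <= 0.8 * cell_radius) & (np.abs(perp) <= 1.5) & cell
            if line.sum():
                protein[line] += filament_fraction * total_intensity / line.sum()

        # nucleus marker
        nucleus_ch[nuc] += total_intensity / max(int(nuc.sum()), 1)
        # p65 channel at the target nuclear/cytoplasmic integrated-density ratio
        rho = float(ratios[i])
        cyt = cell & ~nuc
        n_area, c_area = int(nuc.sum()), int(cyt.sum())
        total_p65 = total_intensity
        cyt_total = total_p65 / (1 + rho)
        nuc_total = total_p65 - cyt_total
        p65_ch[nuc] += nuc_total / max(n_area, 1)
        p65_ch[cyt] += cyt_total / max(c_area, 1)

    def _noise(img: np.ndarray) -> np.ndarray:
        out = rng.poisson(img).astype(float) if poisson_noise else img.copy()
        out += rng.normal(0.0, read_noise_sd, shape)
        return np.maximum(out, 0.0)

    return CellField(
        protein=_noise(protein),
        nucleus=_noise(nucleus_ch),
        p65=_noise(p65_ch),
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        states=states,
        nc_ratios_true=[float(r) for r in ratios],
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    unresolved: list[int] = field(default_factory=list)  # labels with >1 nucleus


def segment_field(
    field_or_protein: "CellField | np.ndarray",
    nucleus_channel: np.ndarray | None = None,
) -> Segmentation:
    """Global-threshold + connected-component segmentation.

    Components in the protein channel become cells; components in the
    nucleus channel become nuclei, each relabelled to its enclosing cell.
    A cell component containing more than one nucleus (touching cells the
    threshold could not separate) is flagged unresolved.
    """
    if isinstance(field_or_protein, CellField):
        protein = field_or_protein.protein
        nucleus_channel = field_or_protein.nucleus
    else:
        protein = field_or_protein
    if nucleus_channel is None:
        raise ValueError("nucleus channel required for segmentation")
    import warnings as _warnings

    if protein.max() <= 0:
        _warnings.warn("no foreground signal; returning empty segmentation", stacklevel=2)
        z = np.zeros(protein.shape, dtype=np.int32)
        return Segmentation(z, z.copy())
    # log-compress so bright puncta cannot dominate the Otsu split between
    # background and cell body; speckle/hole cleanup instead of smoothing so
    # that noise-free disks are recovered pixel-exactly
    def _mask(img: np.ndarray) -> np.ndarray:
        log_img = np.log1p(np.maximum(img, 0.0))
        m = log_img > filters.threshold_otsu(log_img)
        lab = measure.label(m)
        sizes = np.bincount(lab.ravel())
        m = (lab > 0) & (sizes[lab] >= 32)  # drop noise speckles
        return ndimage.binary_fill_holes(m)

    cells = measure.label(_mask(protein))
    nuclei_cc = measure.label(_mask(nucleus_channel))

    nucleus_labels = np.zeros_like(cells)
    per_cell_nuclei: dict[int, int] = {}
    for region in measure.regionprops(nuclei_cc):
        cy, cx = map(int, region.centroid)
        owner = int(cells[cy, cx])
        if owner == 0:
            continue
        nucleus_labels[nuclei_cc == region.label] = owner
        per_cell_nuclei[owner] = per_cell_nuclei.get(owner, 0) + 1
    unresolved = sorted(lbl for lbl, k in per_cell_nuclei.items() if k > 1)
    return Segmentation(cells.astype(np.int32), nucleus_labels.astype(np.int32), unresolved)


def mean_iou(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean best-match intersection-over-union over ground-truth cells."""
    ious = []
    for lbl in np.unique(true_labels):
        if lbl == 0:
            continue
        t = true_labels == lbl
        cand = np.unique(pred_labels[t])
        cand = cand[cand != 0]
        best = 0.0
        for c in cand:
            p = pred_labels == c
            best = max(best, (t & p).sum() / (t | p).sum())
        ious.append(best)
    return float(np.mean(ious)) if ious else 0.0


# ---------------------------------------------------------------------------
# Per-cell metrics
# ---------------------------------------------------------------------------

def cv_punctum_call(
    mask: np.ndarray,
    channel: np.ndarray,
    threshold: float = CV_THRESHOLD,
    min_pixels: int = 25,
) -> dict:
    """CV = sd/mean of in-mask pixels; punctum call = CV > threshold.

    A zero-mean mask has undefined CV and an indeterminate call (None).
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < min_pixels:
        raise ValueError(f"mask smaller than {min_pixels} pixels")
    px = np.asarray(channel, dtype=float)[mask]
    mean = float(px.mean())
    if mean == 0:
        return {"cv": np.nan, "punctum": None, "mean": 0.0, "n_pixels": px.size}
    cv = float(px.std() / mean)
    return {"cv": cv, "punctum": bool(cv > threshold), "mean": mean, "n_pixels": px.size}


def nuc_cyt_ratio(cell_mask: np.ndarray, nucleus_mask: np.ndarray, channel: np.ndarray) -> float:
    """Nuclear / cytoplasmic integrated density; censored-high if cyt sum is 0."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask must lie within the cell mask")
    cyt = cell_mask & ~nucleus_mask
    if not cyt.any():
        raise ValueError("cytoplasm (cell minus nucleus) is empty")
    ch = np.asarray(channel, dtype=float)
    nuc_sum = float(ch[nucleus_mask].sum())
    cyt_sum = float(ch[cyt].sum())
    if cyt_sum == 0:
        return np.inf  # censored-high: all density nuclear
    return nuc_sum / cyt_sum


def field_metrics(field: CellField, seg: Segmentation | None = None) -> pd.DataFrame:
    """Per-cell CV, punctum call and nuc/cyt ratio for a rendered field."""
    if seg is None:
        seg = Segmentation(field.cell_labels, field.nucleus_labels)
    rows = []
    for lbl in np.unique(seg.cell_labels):
        if lbl == 0:
            continue
        cell = seg.cell_labels == lbl
        nuc = seg.nucleus_labels == lbl
        try:
            frag = cv_punctum_call(cell, field.protein)
        except ValueError:
            continue
        row = {"label": int(lbl), **frag}
        if field.p65 is not None and nuc.any() and (cell & ~nuc).any():
            row["nc_ratio"] = nuc_cyt_ratio(cell, nuc, field.p65)
        rows.append(row)
    return pd.DataFrame(rows)


def cv_timecourse(
    stack: np.ndarray,
    mask: np.ndarray,
    n_baseline: int = 1,
) -> dict:
    """Per-frame CV of one cell over a T x H x W stack, with kinetics summary.

    Baseline is the mean of the first ``n_baseline`` frames; the trace is
    deemed returned to baseline at the first post-peak frame with
    CV <= baseline + 2 * baseline sd (sd 0 when only one baseline frame).
    With fewer than 3 frames only the trace is reported.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be T x H x W")
    mask = np.asarray(mask, dtype=bool)
    trace = np.array(
        [cv_punctum_call(mask, frame)["cv"] for frame in stack]
    )
    out: dict = {"cv_trace": trace}
    if stack.shape[0] < 3:
        return out
    base = trace[:n_baseline]
    base_mean = float(np.nanmean(base))
    base_sd = float(np.nanstd(base)) if n_baseline > 1 else 0.0
    peak_idx = int(np.nanargmax(trace))
    peak_cv = float(trace[peak_idx])
    if peak_cv <= base_mean * 1.05 + 2 * base_sd:  # no excursion above baseline
        out.update(peak_frame=None, peak_cv=peak_cv, return_frame=None, baseline_cv=base_mean)
        return out
    out["peak_frame"] = peak_idx
    out["peak_cv"] = peak_cv
    ret = None
    for t in range(peak_idx + 1, len(trace)):
        if trace[t] <= base_mean + 2 * base_sd:
            ret = t
            break
    out["return_frame"] = ret
    out["baseline_cv"] = base_mean
    return out
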