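"""Monomer-vs-polymer structural comparison via C-alpha Kabsch superposition.

Death-fold domains (CARDs and death domains) polymerize by stacking copies
of a small helical bundle; the conformational change a subunit must undergo
between its soluble monomeric fold and its conformation inside the polymer
is one crude structural correlate of the nucleation barrier.  This module
extracts C-alpha traces from PDB/mmCIF files, pairs residues by global
sequence alignment, and reports the least-squares (Kabsch) RMSD between the
paired C-alpha atoms — optionally with iterative outlier trimming, since
published RMSDs sometimes derive from trimming aligners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

log = logging.getLogger(__name__)


@dataclass
class CalphaChain:
    """C-alpha trace of one chain: residue ids, one-letter codes, coordinates (Å)."""

    residue_ids: list[tuple[str, int, str]]  # (chain, seqnum, insertion code)
    sequence: str
    coords: np.ndarray  # (n, 3)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def load_calpha(
    path: str | Path,
    chain_id: str | None = None,
    model_index: int = 0,
    residue_range: tuple[int, int] | None = None,
) -> CalphaChain:
    """Extract first-altloc C-alpha atoms of one chain.

    NMR ensembles use ``model_index`` (default: first model).  Residues with
    no C-alpha are skipped and logged.  An absent chain or model raises a
    lookup error listing what is available.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if model_index >= len(st):
        raise KeyError(f"model {model_index} not in {path.name}; models: 0..{len(st) - 1}")
    model = st[model_index]
    names = [ch.name for ch in model]
    if chain_id is None:
        chain_id = names[0]
    if chain_id not in names:
        raise KeyError(f"chain {chain_id!r} not in {path.name}; available: {names}")
    chain = model[chain_id]

    ids, seq, xyz = [], [], []
    for res in chain:
        if residue_range is not None and not (residue_range[0] <= res.seqid.num <= residue_range[1]):
            continue
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "A", "\0"):
                ca = atom
                break
        if ca is None:
            if any(a.name == "CA" for a in res):  # only non-first altlocs: take first
                ca = next(a for a in res if a.name == "CA")
            else:
                log.info("skipping %s %s%d: no C-alpha", path.name, chain_id, res.seqid.num)
                continue
        one = gemmi.find_tabulated_residue(res.name)
        letter = one.one_letter_code.upper() if one else "X"
        if not letter.isalpha():
            letter = "X"
        ids.append((chain_id, res.seqid.num, res.seqid.icode or ""))
        seq.append(letter)
        xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not xyz:
        raise ValueError(f"no C-alpha atoms found in {path.name} chain {chain_id}")
    coords = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return CalphaChain(ids, "".join(seq), coords, source=f"{path.name}:{chain_id}")


def map_residues(
    a: CalphaChain,
    b: CalphaChain,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[tuple[int, int]]:
    """Pair residues by global sequence alignment; returns ungapped index pairs."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both chains must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a.sequence, b.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    if not pairs:
        raise ValueError("sequence alignment produced no residue pairs")
    return pairs


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # proper orthonormal 3x3
    translation: np.ndarray  # 3-vector (Å)
    n_pairs: int
    rmsd: float
    trimmed: bool = False
    kept_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "n_pairs": self.n_pairs,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "trimmed": self.trimmed,
        }


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R, translation t minimizing |R P + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rmsd


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    trim: bool = False,
    trim_cutoff: float = 2.0,
    max_trim_cycles: int = 5,
) -> SuperpositionResult:
    """Kabsch superposition RMSD over paired points.

    Default uses every pair with no outlier rejection.  ``trim=True``
    iteratively drops pairs deviating more than ``trim_cutoff`` Å after
    superposition and re-fits (up to ``max_trim_cycles`` cycles), the
    behaviour of common trimming aligners.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if pairs is None:
        if len(A) != len(B):
            raise ValueError("equal-length inputs required when pairs are not given")
        pairs = list(zip(range(len(A)), range(len(B))))
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for superposition")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    P, Q = A[ia], B[ib]
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) geometry")

    keep = np.ones(len(pairs), dtype=bool)
    R, t, rmsd = _kabsch(P, Q)
    trimmed = False
    if trim:
        for _ in range(max_trim_cycles):
            dev = np.linalg.norm((P @ R.T + t) - Q, axis=1)
            # reject clear outliers only: beyond the cutoff AND beyond the
            # bulk of the current deviation distribution
            limit = max(trim_cutoff, float(dev[keep].mean() + 2.0 * dev[keep].std()))
            new_keep = keep & (dev <= limit)
            if new_keep.sum() < 3 or new_keep.sum() == keep.sum():
                break
            keep = new_keep
            R, t, rmsd = _kabsch(P[keep], Q[keep])
            trimmed = True
    kept = [pairs[i] for i in np.nonzero(keep)[0]]
    return SuperpositionResult(
        rotation=R, translation=t, n_pairs=int(keep.sum()), rmsd=rmsd,
        trimmed=trimmed, kept_pairs=kept,
    )


#: monomer vs. polymer-protomer structure pairs of the three CBM death folds
DEATH_FOLD_PAIRS = {
    "BCL10_CARD": ("2mb9", "6bze"),
    "CARD9_CARD": ("6e26", "6n2p"),
    "MALT1_DD": ("2g7r", "6gk2"),
}


def find_structure_file(entry_id: str, search_dir: str | Path) -> Path | None:
    """Locate a downloaded PDB/mmCIF file for an entry id (case-insensitive)."""
    search_dir = Path(search_dir)
    if not search_dir.is_dir():
        return None
    for ext in (".pdb", ".cif", ".ent", ".mmcif"):
        for cand in (entry_id.lower(), entry_id.upper()):
            p = search_dir / f"{cand}{ext}"
            if p.exists():
                return p
    return None


def best_protomer_comparison(
    mono_path: str | Path, poly_path: str | Path, trim: bool = False
) -> SuperpositionResult:
    """Superpose a monomer structure onto the best-matching polymer protomer.

    The polymer chain is the first one covering at least 80% of the monomer
    sequence; if none qualifies, the chain with the most aligned residues.
    """
    mono = load_calpha(mono_path)
    st = gemmi.read_structure(str(Path(poly_path)))
    chains = [ch.name for ch in st[0]]
    best: SuperpositionResult | None = None
    for ch in chains:
        try:
            poly = load_calpha(poly_path, chain_id=ch)
            pairs = map_residues(mono, poly)
            res = kabsch_rmsd(mono.coords, poly.coords, pairs, trim=trim)
        except (ValueError, KeyError):
            continue
        if res.n_pairs >= 0.8 * len(mono):
            return res
        if best is None or res.n_pairs > best.n_pairs:
            best = res
    if best is None:
        raise ValueError(f"no usable protomer chain in {poly_path}")
    return best


def compare_structures(
    ref_path: str | Path,
    mobile_path: str | Path,
    ref_chain: str | None = None,
    mobile_chain: str | None = None,
    ref_model: int = 0,
    mobile_model: int = 0,
    trim: bool = False,
) -> SuperpositionResult:
    """Load two structures, map residues by sequence, and superpose C-alphas."""
    a = load_calpha(ref_path, ref_chain, ref_model)
    b = load_calpha(mobile_path, mobile_chain, mobile_model)
    pairs = map_residues(a, b)
    return kabsch_rmsd(a.coords, b.coords, pairs, trim=trim)
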