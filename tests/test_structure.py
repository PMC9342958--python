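"""Structure contracts: C-alpha extraction, residue mapping, Kabsch RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nucleokit import structure as S


def random_chain(rng, n=12, seq_alphabet="AGVLSTKRDEF"):
    coords = rng.normal(0, 5, (n, 3))
    seq = "".join(rng.choice(list(seq_alphabet), n))
    return coords, seq


class TestLoadCalpha:
    def test_three_residue_order(self, tmp_path, ca_pdb_writer):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        p = ca_pdb_writer(tmp_path / "a.pdb", coords, "AGV")
        chain = S.load_calpha(p)
        assert chain.sequence == "AGV"
        assert np.allclose(chain.coords, coords)

    def test_altloc_a_retained(self, tmp_path, ca_pdb_writer):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        alts = {1: [("A", [1.0, 0.0, 0.0]), ("B", [9.0, 9.0, 9.0])]}
        p = ca_pdb_writer(tmp_path / "alt.pdb", coords, "AGV", altlocs=alts)
        chain = S.load_calpha(p)
        assert len(chain) == 3
        assert np.allclose(chain.coords[1], [1.0, 0.0, 0.0])

    def test_missing_calpha_skipped(self, tmp_path, ca_pdb_writer):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        p = ca_pdb_writer(tmp_path / "gap.pdb", coords, "AGV", skip_ca=(1,))
        chain = S.load_calpha(p)
        assert len(chain) == 2
        assert chain.sequence == "AV"

    def test_absent_chain_lists_available(self, tmp_path, ca_pdb_writer):
        coords = np.zeros((3, 3))
        p = ca_pdb_writer(tmp_path / "c.pdb", np.eye(3), "AGV", chain="A")
        with pytest.raises(KeyError, match="A"):
            S.load_calpha(p, chain_id="Z")


class TestMapResidues:
    def test_identical_sequences_identity_mapping(self, tmp_path, ca_pdb_writer):
        rng = np.random.default_rng(1)
        coords, seq = random_chain(rng, 20)
        a = S.CalphaChain([("A", i, "") for i in range(20)], seq, coords)
        pairs = S.map_residues(a, a)
        assert pairs == [(i, i) for i in range(20)]

    def test_truncated_chain_offset_mapping(self):
        rng = np.random.default_rng(2)
        coords, seq = random_chain(rng, 20)
        a = S.CalphaChain([("A", i, "") for i in range(20)], seq, coords)
        b = S.CalphaChain([("A", i, "") for i in range(5, 20)], seq[5:], coords[5:])
        pairs = S.map_residues(a, b)
        assert pairs == [(i + 5, i) for i in range(15)]

    def test_matches_dynamic_programming_oracle(self):
        # independent Needleman-Wunsch on a low-identity pair
        rng = np.random.default_rng(3)
        seq_a = "".join(rng.choice(list("AGVLST"), 30))
        seq_b = "".join(
            c if rng.random() < 0.3 else rng.choice(list("KRDEF")) for c in seq_a
        )

        def nw_aligned_pairs(x, y, match=1, mismatch=-1, gap=-2):
            n, m = len(x), len(y)
            score = np.zeros((n + 1, m + 1))
            score[:, 0] = gap * np.arange(n + 1)
            score[0, :] = gap * np.arange(m + 1)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = match if x[i - 1] == y[j - 1] else mismatch
                    score[i, j] = max(
                        score[i - 1, j - 1] + s, score[i - 1, j] + gap, score[i, j - 1] + gap
                    )
            # count aligned (ungapped) pairs along one optimal traceback
            i, j, pairs = n, m, 0
            while i > 0 and j > 0:
                s = match if x[i - 1] == y[j - 1] else mismatch
                if score[i, j] == score[i - 1, j - 1] + s:
                    pairs += 1
                    i, j = i - 1, j - 1
                elif score[i, j] == score[i - 1, j] + gap:
                    i -= 1
                else:
                    j -= 1
            return score[n, m], pairs

        a = S.CalphaChain([("A", i, "") for i in range(30)], seq_a, np.zeros((30, 3)))
        b = S.CalphaChain([("A", i, "") for i in range(30)], seq_b, np.zeros((30, 3)))
        pairs = S.map_residues(a, b)
        oracle_score, oracle_pairs = nw_aligned_pairs(seq_a, seq_b)
        assert len(pairs) == oracle_pairs

    def test_empty_chain_rejected(self):
        a = S.CalphaChain([], "", np.zeros((0, 3)))
        with pytest.raises(ValueError):
            S.map_residues(a, a)


class TestKabschRmsd:
    def test_self_superposition_identity(self):
        rng = np.random.default_rng(4)
        P = rng.normal(0, 3, (10, 3))
        res = S.kabsch_rmsd(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 3, (10, 3))
        R = Rotation.from_euler("zyx", [0.4, -1.2, 2.0]).as_matrix()
        Q = P @ R.T + np.array([3.0, -1.0, 7.0])
        res = S.kabsch_rmsd(P, Q)
        assert res.rmsd < 1e-10
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        P, Q = rng.normal(0, 3, (8, 3)), rng.normal(0, 3, (8, 3))
        assert S.kabsch_rmsd(P, Q).rmsd == pytest.approx(S.kabsch_rmsd(Q, P).rmsd, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_superposed_never_worse_than_raw(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = rng.normal(0, 3, (6, 3)), rng.normal(0, 3, (6, 3))
        raw = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
        assert S.kabsch_rmsd(P, Q).rmsd <= raw + 1e-12

    def test_invariant_to_premotion_of_input(self):
        rng = np.random.default_rng(7)
        P, Q = rng.normal(0, 3, (9, 3)), rng.normal(0, 3, (9, 3))
        R = Rotation.from_euler("xyz", [1.0, 0.2, -0.5]).as_matrix()
        moved = P @ R.T + np.array([5.0, 5.0, 5.0])
        assert S.kabsch_rmsd(moved, Q).rmsd == pytest.approx(S.kabsch_rmsd(P, Q).rmsd, abs=1e-9)

    def test_matches_rotation_space_brute_force(self):
        # independent route: coarse Euler-angle grid + Nelder-Mead refinement
        rng = np.random.default_rng(8)
        P, Q = rng.normal(0, 3, (5, 3)), rng.normal(0, 3, (5, 3))
        P0, Q0 = P - P.mean(0), Q - Q.mean(0)

        def cost(angles):
            R = Rotation.from_euler("zyx", angles).as_matrix()
            return float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))

        grid = np.linspace(-np.pi, np.pi, 13)
        best = min(
            ((a, b, c) for a in grid for b in grid[:7] for c in grid),
            key=lambda ang: cost(list(ang)),
        )
        ref = minimize(cost, list(best), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12}).fun
        assert S.kabsch_rmsd(P, Q).rmsd == pytest.approx(ref, abs=1e-3)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(9)
        P, Q = rng.normal(0, 3, (20, 3)), rng.normal(0, 3, (20, 3))
        _, scipy_rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert S.kabsch_rmsd(P, Q).rmsd == pytest.approx(scipy_rssd / np.sqrt(20), rel=1e-9)

    def test_reflection_not_allowed(self):
        rng = np.random.default_rng(10)
        P = rng.normal(0, 3, (7, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored
        res = S.kabsch_rmsd(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0.1

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            S.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            S.kabsch_rmsd(line, line)

    def test_trim_mode_drops_injected_outlier(self):
        rng = np.random.default_rng(11)
        P = rng.normal(0, 5, (20, 3))
        Q = P.copy()
        Q[0] += 30.0  # gross outlier
        plain = S.kabsch_rmsd(P, Q)
        trimmed = S.kabsch_rmsd(P, Q, trim=True)
        assert trimmed.trimmed
        assert trimmed.n_pairs == 19
        assert trimmed.rmsd < plain.rmsd


class TestCompareStructures:
    def test_end_to_end_rigid_pair(self, tmp_path, ca_pdb_writer):
        rng = np.random.default_rng(12)
        coords, seq = random_chain(rng, 15)
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        a = ca_pdb_writer(tmp_path / "mono.pdb", coords, seq)
        b = ca_pdb_writer(tmp_path / "poly.pdb", coords @ R.T + [1, 2, 3], seq)
        res = S.compare_structures(a, b)
        assert res.n_pairs == 15
        # PDB format rounds coordinates to 1e-3 A
        assert res.rmsd < 2e-3
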