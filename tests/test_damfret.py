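"""Analysis contracts: AmFRET, gating, binning, Weibull fit, classification."""

import numpy as np
import pandas as pd
import pytest

from nucleokit import damfret
from nucleokit import synthetic_cytometry as syn
from nucleokit.events import EventTable


def make_table(donor, acceptor, fret, **extra):
    df = pd.DataFrame({"donor": donor, "acceptor": acceptor, "fret": fret, **extra})
    return EventTable(df)


class TestComputeAmfret:
    def test_ratio(self):
        am, valid = damfret.compute_amfret(np.array([500.0, 0.0]), np.array([2000.0, 100.0]))
        assert am[0] == pytest.approx(0.25)
        assert am[1] == 0.0
        assert valid.all()

    def test_zero_acceptor_flagged_not_zeroed(self):
        am, valid = damfret.compute_amfret(np.array([10.0]), np.array([0.0]))
        assert not valid[0]
        assert np.isnan(am[0])


class TestGateEvents:
    def test_identity_when_all_inside(self):
        t = make_table([1.0] * 5, [10.0] * 5, [1.0] * 5)
        out = damfret.gate_events(t, damfret.GateSpec(expression_min=1, expression_max=100))
        assert len(out) == 5

    def test_empty_result_warns(self):
        t = make_table([1.0] * 5, [10.0] * 5, [1.0] * 5)
        with pytest.warns(UserWarning):
            out = damfret.gate_events(t, damfret.GateSpec(expression_min=1e6))
        assert len(out) == 0

    def test_window_retains_expected_fraction(self):
        rng = np.random.default_rng(0)
        n = 20_000
        acceptor = np.where(rng.random(n) < 0.1, 0.5, 10.0)  # 10% below window
        t = make_table(np.ones(n), acceptor, np.zeros(n))
        out = damfret.gate_events(t, damfret.GateSpec(expression_min=1.0))
        assert len(out) / n == pytest.approx(0.90, abs=0.01)


class TestNegativeGate:
    def test_degenerate_constant_control(self):
        t = make_table(np.ones(8000), np.geomspace(1, 1000, 8000), None)
        t.data["fret"] = 0.02 * t.data["acceptor"]  # constant AmFRET = 0.02
        gate = damfret.build_negative_gate(t)
        occupied = [b for b in range(len(gate.boundary)) if b not in gate.fallback_bins]
        assert np.allclose(gate.boundary[occupied], 0.02)

    def test_sparse_bins_fall_back_to_global_quantile(self):
        rng = np.random.default_rng(1)
        # 10 stray events two decades above the bulk -> sparse upper bins
        acceptor = np.concatenate([rng.uniform(10, 100, 5000), rng.uniform(9000, 10000, 10)])
        fret = rng.normal(0, 0.02, acceptor.size) * acceptor
        gate = damfret.build_negative_gate(make_table(np.ones(acceptor.size), acceptor, fret))
        assert gate.fallback_bins  # provenance recorded
        assert np.isfinite(gate.global_boundary)

    def test_empty_control_raises(self):
        t = make_table(np.zeros(10), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                damfret.build_negative_gate(t)

    def test_held_out_exceedance_matches_quantile(self, negative_gate):
        held = syn.simulate_population(
            syn.PopulationParams(n_cells=100_000, archetype="monomer", rng_seed=991)
        )
        g = damfret.gate_events(held, negative_gate)
        am, valid = damfret.amfret_of(g)
        exceed = float((am[valid] > negative_gate.boundary_at(g.acceptor[valid])).mean())
        assert exceed == pytest.approx(0.01, abs=0.003)


class TestBinFractionAssembled:
    def test_simple_fraction_arithmetic(self):
        acceptor = np.full(10, 50.0)
        fret = np.array([10.0] * 3 + [0.0] * 7)  # 3 of 10 above a 0.1 boundary
        t = make_table(np.ones(10), acceptor, fret)
        gate = damfret.GateSpec(global_boundary=0.1)
        bins = damfret.bin_fraction_assembled(t, gate, range_quantiles=(0.0, 1.0))
        occ = bins.occupied
        assert bins.n_total[occ].sum() == 10
        assert bins.fraction[occ][bins.n_total[occ] > 0][0] == pytest.approx(0.3)

    def test_all_above_boundary(self):
        rng = np.random.default_rng(2)
        acceptor = rng.uniform(10, 1000, 5000)
        t = make_table(np.ones(5000), acceptor, 0.5 * acceptor)
        bins = damfret.bin_fraction_assembled(t, damfret.GateSpec(global_boundary=0.1))
        assert np.allclose(bins.fraction[bins.occupied], 1.0)

    def test_empty_bins_have_undefined_fraction(self):
        acceptor = np.concatenate([np.full(100, 10.0), np.full(100, 1000.0)])
        t = make_table(np.ones(200), acceptor, np.zeros(200))
        bins = damfret.bin_fraction_assembled(
            t, damfret.GateSpec(global_boundary=0.1), range_quantiles=(0.0, 1.0)
        )
        assert np.isnan(bins.fraction[~bins.occupied]).all()


def noise_free_bins(ec50=10.0, delta=3.0, plateau=1.0, n_bins=64, n_per_bin=1000):
    centers = np.geomspace(0.1, 1000, n_bins)
    edges = np.geomspace(centers[0] / 1.05, centers[-1] * 1.05, n_bins + 1)
    frac = damfret.weibull_fraction(centers, ec50, delta, plateau)
    n_total = np.full(n_bins, n_per_bin)
    return damfret.BinTable(
        edges=edges, centers=centers, n_total=n_total,
        n_assembled=np.round(frac * n_per_bin).astype(int),
    )


class TestFitWeibull:
    def test_noise_free_recovery_to_machine_precision(self):
        centers = np.geomspace(0.1, 1000, 64)
        frac = damfret.weibull_fraction(centers, 10.0, 3.0)
        bins = damfret.BinTable(
            edges=np.geomspace(0.095, 1050, 65), centers=centers,
            n_total=np.full(64, 1000), n_assembled=np.zeros(64, int),
        )
        # bypass integer rounding: fit directly on exact fractions
        x, _ = damfret._wls_fit(centers, frac, np.full(64, 1000.0), False,
                                damfret._starts(centers, False))
        assert np.exp(x[0]) == pytest.approx(10.0, rel=1e-6)
        assert np.exp(x[1]) == pytest.approx(3.0, rel=1e-6)

    def test_optimizer_matches_log_grid_scan(self):
        centers = np.geomspace(0.1, 1000, 64)
        frac = damfret.weibull_fraction(centers, 10.0, 3.0)
        w = np.full(64, 1000.0)
        x, cost = damfret._wls_fit(centers, frac, w, False, damfret._starts(centers, False))

        def sse(ec50, delta):
            return float(np.sum(w * (damfret.weibull_fraction(centers, ec50, delta) - frac) ** 2))

        grid_e = np.geomspace(1, 100, 200)
        grid_d = np.geomspace(0.3, 30, 200)
        grid_best = min(sse(e, d) for e in grid_e for d in grid_d)
        assert 2 * cost <= grid_best + 1e-12

    def test_all_zero_profile_censored_as_monomer(self):
        bins = noise_free_bins(plateau=1.0)
        bins.n_assembled[:] = 0
        fit = damfret.fit_weibull(bins, n_boot=0)
        assert fit.censored and fit.profile_class == "monomer"
        assert np.isnan(fit.ec50) and np.isnan(fit.delta)

    def test_plateau_recovered_when_fit(self):
        bins = noise_free_bins(ec50=10, delta=3, plateau=0.6, n_per_bin=100_000)
        fit = damfret.fit_weibull(bins, fit_plateau=True, n_boot=0)
        assert fit.plateau == pytest.approx(0.6, rel=1e-3)
        assert fit.ec50 == pytest.approx(10.0, rel=1e-3)

    def test_too_few_bins_rejected(self):
        bins = noise_free_bins()
        bins.n_total[5:] = 0
        with pytest.raises(ValueError):
            damfret.fit_weibull(bins)

    def test_bootstrap_ci_brackets_point_estimate(self):
        bins = noise_free_bins(n_per_bin=500)
        fit = damfret.fit_weibull(bins, n_boot=50, rng_seed=3)
        lo, hi = fit.ci["ec50"]
        assert lo <= fit.ec50 <= hi

    def test_equivariance_under_intensity_rescaling(self, negative_gate, monomer_control):
        t = syn.simulate_population(
            syn.PopulationParams(n_cells=200_000, ec50_true=50.0, delta_true=3.0, rng_seed=41)
        )
        bins = damfret.bin_fraction_assembled(t, negative_gate)
        fit = damfret.fit_weibull(bins, n_boot=0)

        k = 3.7
        t2 = t.copy()
        t2.data["acceptor"] *= k
        t2.data["fret"] *= k  # AmFRET unchanged
        ctrl2 = monomer_control.copy()
        ctrl2.data["acceptor"] *= k
        ctrl2.data["fret"] *= k
        gate2 = damfret.build_negative_gate(ctrl2)
        fit2 = damfret.fit_weibull(damfret.bin_fraction_assembled(t2, gate2), n_boot=0)
        assert fit2.ec50 / fit.ec50 == pytest.approx(k, rel=0.02)
        assert fit2.delta == pytest.approx(fit.delta, rel=0.05)

    def test_estimator_consistency_in_sample_size(self, negative_gate):
        # median absolute parameter error shrinks as n grows
        sizes = [10_000, 100_000, 500_000]
        med_err = []
        for n in sizes:
            errs = []
            for seed in range(11):
                t = syn.simulate_population(
                    syn.PopulationParams(n_cells=n, ec50_true=100.0, delta_true=3.0, rng_seed=500 + seed)
                )
                scale = t.metadata["acceptor_per_concentration"]
                bins = damfret.bin_fraction_assembled(t, negative_gate)
                fit = damfret.fit_weibull(
                    bins, n_boot=0, bin_average=True, log_smear_sd=0.05,
                    false_positive_rate=1 - negative_gate.quantile,
                )
                errs.append(abs(fit.ec50 / scale - 100.0) / 100.0 + abs(fit.delta - 3.0) / 3.0)
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]

    def test_binomial_method_agrees_with_wls(self):
        bins = noise_free_bins(n_per_bin=2000)
        wls = damfret.fit_weibull(bins, n_boot=0)
        mle = damfret.fit_weibull(bins, n_boot=0, method="binomial")
        assert mle.ec50 == pytest.approx(wls.ec50, rel=0.02)
        assert mle.delta == pytest.approx(wls.delta, rel=0.05)


class TestClassifyProfile:
    def fit_and_classify(self, params, gate):
        t = syn.simulate_population(params)
        bins = damfret.bin_fraction_assembled(t, gate)
        fit = damfret.fit_weibull(
            bins, n_boot=0, bin_average=True, false_positive_rate=1 - gate.quantile
        )
        return damfret.classify_profile(t, gate, fit)

    def test_monomer_archetype(self, negative_gate):
        p = syn.PopulationParams(n_cells=100_000, archetype="monomer", rng_seed=61)
        assert self.fit_and_classify(p, negative_gate) == "monomer"

    def test_nucleated_archetype_discontinuous(self, negative_gate):
        p = syn.PopulationParams(n_cells=500_000, rng_seed=62)  # generator defaults
        assert self.fit_and_classify(p, negative_gate) == "discontinuous"

    def test_threshold_ramp_continuous(self, negative_gate):
        p = syn.PopulationParams(
            n_cells=200_000, archetype="threshold_polymer", c_star=100.0,
            ramp_decades=1.0, rng_seed=63,
        )
        assert self.fit_and_classify(p, negative_gate) == "continuous"


class TestSeedingCollapse:
    def test_seeded_sample_assembled_everywhere_above_onset(self, negative_gate):
        p = syn.PopulationParams(n_cells=200_000, ec50_true=100.0, seeded=True, rng_seed=64)
        t = syn.simulate_population(p)
        scale = t.metadata["acceptor_per_concentration"]
        bins = damfret.bin_fraction_assembled(t, negative_gate)
        onset_acceptor = p.ec50_true * p.seed_onset_factor * scale
        sel = bins.occupied & (bins.edges[:-1] > onset_acceptor * 1.5)
        assert np.all(bins.fraction[sel] >= 0.99)


class TestCompareFits:
    @staticmethod
    def fit(ec50, delta):
        return damfret.WeibullFit(
            ec50=ec50, delta=delta, plateau=1.0, residual_norm=0.0,
            n_bins_used=64, n_events=1000,
        )

    def test_identical_groups_p_one(self):
        reps = [self.fit(10.0, 3.0), self.fit(10.5, 3.1), self.fit(9.5, 2.9)]
        out = damfret.compare_fits({"ref": reps, "same": list(reps)})
        row = out.set_index("group").loc["same"]
        assert row["ec50_p_value"] == pytest.approx(1.0)

    def test_separated_groups_detected(self, negative_gate):
        groups = {}
        for label, ec50 in (("ref", 10.0), ("variant", 100.0)):
            fits = []
            for rep in range(3):
                t = syn.simulate_population(
                    syn.PopulationParams(
                        n_cells=100_000, ec50_true=ec50, delta_true=3.0, rng_seed=700 + rep
                    )
                )
                bins = damfret.bin_fraction_assembled(t, negative_gate)
                fits.append(damfret.fit_weibull(bins, n_boot=0))
            groups[label] = fits
        out = damfret.compare_fits(groups, reference="ref")
        assert out.set_index("group").loc["variant", "ec50_p_value"] < 0.01

    def test_single_replicate_descriptive_only(self):
        out = damfret.compare_fits({"ref": [self.fit(10, 3), self.fit(11, 3)], "solo": [self.fit(20, 4)]})
        row = out.set_index("group").loc["solo"]
        assert np.isnan(row["ec50_p_value"])
        assert row["ec50_mean"] == pytest.approx(20.0)
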