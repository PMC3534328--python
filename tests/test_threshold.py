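"""Quadratic threshold model: fitting, prediction, selection, iteration."""

import numpy as np
import pytest

from aflpselect import (
    FixedThresholdSelector,
    MovingThresholdSelector,
    ThresholdModel,
    ValidationError,
    fit_threshold_model,
    iterate_selection,
    locus_error_rates,
    predict_threshold,
    select_by_model,
    select_fixed,
    simulate_dataset,
    SimulationConfig,
)
from aflpselect.error_rates import LocusStats


def stats_from_xy(x, y):
    return [
        LocusStats(f"L{i}", float(xi), int(round(yi * 1000)), 1000)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def stats_from_rates(rates, freq=0.2):
    return [
        LocusStats(f"L{i}", freq, int(round(r * 100)), 100)
        for i, r in enumerate(rates)
    ]


class TestFitThresholdModel:
    def test_interpolates_noiseless_quadratic_exactly(self):
        x = np.arange(0.1, 1.0, 0.1)
        y = 0.10 + 0.50 * x - 0.30 * x**2
        mod = fit_threshold_model(stats_from_xy(x, y))
        assert (mod.b0, mod.b1, mod.b2) == pytest.approx((0.10, 0.50, -0.30), abs=1e-10)
        assert mod.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_frozen_normal_equations_oracle(self):
        # oracle: solve(X'X, X'y) on these six points, computed separately
        x = [0.05, 0.10, 0.20, 0.35, 0.50, 0.70]
        y = [0.02, 0.09, 0.16, 0.28, 0.27, 0.24]
        mod = fit_threshold_model(stats_from_xy(x, y))
        assert (mod.b0, mod.b1, mod.b2) == pytest.approx(
            (-0.0362307013, 1.2993381207, -1.3020308924), abs=1e-8
        )
        assert mod.r_squared == pytest.approx(0.98146078, abs=1e-6)

    def test_constant_response_gives_flat_curve_r2_zero(self):
        x = [0.1, 0.3, 0.5, 0.7]
        mod = fit_threshold_model(stats_from_xy(x, [0.07] * 4))
        assert (mod.b0, mod.b1, mod.b2) == pytest.approx((0.07, 0.0, 0.0), abs=1e-10)
        assert mod.r_squared == 0.0

    def test_undefined_loci_excluded_from_fit(self):
        x = np.arange(0.1, 1.0, 0.1)
        y = 0.10 + 0.50 * x - 0.30 * x**2
        stats = stats_from_xy(x, y) + [LocusStats("bad", 0.5, 0, 0)]
        assert fit_threshold_model(stats).n_loci_fit == len(x)

    def test_rank_deficient_design_errors(self):
        with pytest.raises(ValidationError, match="distinct frequencies"):
            fit_threshold_model(stats_from_xy([0.2] * 5, [0.1, 0.2, 0.1, 0.2, 0.1]))

    def test_too_few_loci_errors(self):
        with pytest.raises(ValidationError, match=">= 4"):
            fit_threshold_model(stats_from_xy([0.1, 0.2, 0.3], [0.1, 0.2, 0.1]))


class TestPredictThreshold:
    def test_quadratic_arithmetic(self):
        mod = ThresholdModel(0.0053, 1.18, -1.11, 0.786, 1e-4, 2711)
        assert predict_threshold(mod, 0.5) == pytest.approx(0.3178)

    def test_negative_prediction_clamped_to_zero(self):
        mod = ThresholdModel(-0.0020, 0.82, -0.72, 0.844, 1e-4, 1173)
        assert mod.raw(0.001) < 0
        assert predict_threshold(mod, 0.001) == 0.0

    def test_zero_model_predicts_zero_everywhere(self):
        mod = ThresholdModel(0.0, 0.0, 0.0, 0.0, 1.0, 0)
        assert predict_threshold(mod, 0.7) == 0.0


class TestSelectByModel:
    def test_agrees_with_brute_force_comparison(self):
        rng = np.random.default_rng(21)
        mod = ThresholdModel(0.01, 0.9, -0.8, 0.5, 1e-3, 20)
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0, 0.5, 20)
        stats = stats_from_xy(x, y)
        res = select_by_model(stats, mod)
        for s in stats:
            thr = max(0.0, 0.01 + 0.9 * s.present_freq - 0.8 * s.present_freq**2)
            if s.error_rate > thr:
                assert s.locus_id in res.removed
            else:
                assert s.locus_id in res.kept
        assert set(res.kept) | set(res.removed) == {s.locus_id for s in stats}
        assert not set(res.kept) & set(res.removed)

    def test_tie_at_prediction_is_kept(self):
        mod = ThresholdModel.fixed(0.25)
        stats = stats_from_rates([0.25, 0.26])
        res = select_by_model(stats, mod)
        assert res.kept == ("L0",) and res.removed == ("L1",)

    def test_zero_error_locus_never_removed_even_under_negative_curve(self):
        mod = ThresholdModel(-0.05, 0.1, -0.1, 0.5, 1e-3, 10)
        stats = [LocusStats("zero", 0.01, 0, 100), LocusStats("one", 0.01, 5, 100)]
        with pytest.warns(UserWarning, match="clamped"):
            res = select_by_model(stats, mod)
        assert "zero" in res.kept and "one" in res.removed
        assert res.clamp_applied

    def test_undefined_error_rate_removed_separately(self):
        mod = ThresholdModel.fixed(0.5)
        stats = stats_from_rates([0.1]) + [LocusStats("nc", 0.2, 0, 0)]
        res = select_by_model(stats, mod)
        assert res.removed_undefined == ("nc",)
        assert "nc" not in res.kept and "nc" not in res.removed

    def test_residual_signs_after_fit_on_same_loci(self):
        """Kept loci sit at/below the curve, removed strictly above; OLS
        residuals with intercept sum to ~0."""
        rng = np.random.default_rng(8)
        x = rng.uniform(0.02, 0.9, 120)
        y = np.clip(0.01 + 1.1 * x - 1.0 * x**2 + rng.normal(0, 0.05, 120), 0, 0.6)
        stats = stats_from_xy(x, y)
        mod = fit_threshold_model(stats)
        res = select_by_model(stats, mod)
        resid = {s.locus_id: s.error_rate - mod.raw(s.present_freq) for s in stats}
        assert all(resid[l] > 0 for l in res.removed)
        assert all(resid[l] <= 1e-12 or mod.raw(
            next(s.present_freq for s in stats if s.locus_id == l)) < 0
            for l in res.kept)
        assert abs(sum(resid.values())) < 1e-6 * len(stats)


class TestSelectFixed:
    def test_strict_inequality(self):
        res = select_fixed(stats_from_rates([0.04, 0.05, 0.06]), 0.05)
        assert res.removed == ("L2",)

    def test_tau_one_removes_nothing(self):
        res = select_fixed(stats_from_rates([0.2, 0.9, 1.0]), 1.0)
        assert res.removed == ()

    def test_brute_force_oracle_and_mean_bound(self):
        rng = np.random.default_rng(31)
        rates = np.round(rng.uniform(0, 0.4, 50), 2)
        stats = stats_from_rates(rates)
        res = select_fixed(stats, 0.10)
        expected_kept = {f"L{i}" for i, r in enumerate(rates) if r <= 0.10}
        assert set(res.kept) == expected_kept
        assert res.mean_error_after <= 0.10


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_loci=800, pops_per_group=6, samples_per_pop=6,
                           replicate_fraction=0.4, seed=77)
    m, reps, _, _ = simulate_dataset(cfg)
    return m, reps


class TestIterateSelection:
    def test_single_round_equals_fit_plus_select(self, sim):
        m, reps = sim
        (res,) = iterate_selection(m, reps, rounds=1, min_loci=10)
        stats = locus_error_rates(m, reps)
        manual = select_by_model(stats, fit_threshold_model(stats))
        assert res.kept == manual.kept and res.removed == manual.removed

    def test_two_rounds_reduce_mean_error_monotonically(self, sim):
        m, reps = sim
        r1, r2 = iterate_selection(m, reps, rounds=2, min_loci=10)
        assert r2.mean_error_after < r1.mean_error_after < r1.mean_error_before

    def test_min_loci_guard_stops_immediately(self, sim):
        m, reps = sim
        with pytest.warns(UserWarning, match="min_loci"):
            results = iterate_selection(m, reps, rounds=1, min_loci=10**6)
        assert results == []

    def test_zero_rounds_errors(self, sim):
        m, reps = sim
        with pytest.raises(ValidationError):
            iterate_selection(m, reps, rounds=0)


class TestSklearnSelectors:
    def test_moving_selector_matches_iterate_selection(self):
        cfg = SimulationConfig(n_loci=300, pops_per_group=3, samples_per_pop=6,
                               replicate_fraction=0.5, seed=5)
        m, reps, _, _ = simulate_dataset(cfg)
        pairs = [(m.sample_index(a), m.sample_index(b)) for a, b in reps.pairs]
        sel = MovingThresholdSelector(replicate_pairs=pairs, rounds=2, min_loci=10)
        Xt = sel.fit(m.calls).transform(m.calls)
        results = iterate_selection(m, reps, rounds=2, min_loci=10)
        kept_idx = sorted(m.locus_ids.index(l) for l in results[-1].kept)
        assert sel.get_support(indices=True).tolist() == kept_idx
        assert Xt.shape == (m.n_samples, len(kept_idx))
        # sklearn param contract
        assert sel.get_params()["rounds"] == 2
        assert type(sel)(**sel.get_params()).rounds == 2

    def test_fixed_selector_keeps_low_error_loci(self):
        cfg = SimulationConfig(n_loci=200, pops_per_group=2, samples_per_pop=8,
                               replicate_fraction=0.5, seed=6)
        m, reps, _, _ = simulate_dataset(cfg)
        pairs = [(m.sample_index(a), m.sample_index(b)) for a, b in reps.pairs]
        sel = FixedThresholdSelector(replicate_pairs=pairs, tau=0.1).fit(m.calls)
        stats = locus_error_rates(m, reps)
        kept = {s.locus_id for s in stats if s.defined and s.error_rate <= 0.1}
        assert {m.locus_ids[i] for i in sel.get_support(indices=True)} == kept
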