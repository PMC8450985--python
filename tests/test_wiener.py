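"""Wiener first-passage-time kernel: densities, probabilities, samplers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cuebias.wiener import (
    WienerParams,
    choice_probability,
    fpt_density,
    fpt_logdensity,
    log_likelihood,
    sample_trials,
    sample_trials_euler,
)

PARAM_GRID = [
    WienerParams(1.0, 2.0, 0.3, 0.5),
    WienerParams(-0.8, 1.2, 0.2, 0.35),
    WienerParams(0.0, 1.0, 0.0, 0.6),
    WienerParams(3.0, 0.8, 0.4, 0.7),
    WienerParams(1.5, 1.2, 0.25, 0.6),
]


def total_absorption(params, upper_limit=200.0):
    return quad(
        lambda t: fpt_density(t, params, "upper") + fpt_density(t, params, "lower"),
        params.ndt,
        upper_limit,
        limit=300,
    )[0]


class TestDensity:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_total_probability_is_one(self, params):
        assert total_absorption(params) == pytest.approx(1.0, abs=1e-6)

    def test_zero_at_and_before_ndt(self):
        p = WienerParams(1.0, 1.5, 0.3, 0.5)
        assert fpt_density(0.3, p, "upper") == 0.0
        assert fpt_density(0.1, p, "lower") == 0.0

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_boundary_symmetry(self, params):
        """f_upper(t; v, w) must equal f_lower(t; -v, 1-w) for all t."""
        flipped = WienerParams(-params.drift, params.boundary, params.ndt, 1 - params.rel_start)
        t = params.ndt + np.array([0.05, 0.2, 0.5, 1.0, 2.0])
        np.testing.assert_allclose(
            fpt_density(t, params, "upper"), fpt_density(t, flipped, "lower"), rtol=1e-10
        )

    def test_series_branches_agree(self):
        """Small-time and large-time expansions match in the central window.

        Both series are recomputed here with generous term counts,
        independently of the production truncation rule.
        """
        from cuebias.wiener import _fw

        def small_time(u, w, K=60):
            k = np.arange(-K, K + 1)
            return np.sum((w + 2 * k) * np.exp(-((w + 2 * k) ** 2) / (2 * u))) / np.sqrt(
                2 * np.pi * u**3
            )

        def large_time(u, w, K=300):
            k = np.arange(1, K + 1)
            return np.pi * np.sum(
                k * np.exp(-(k**2) * np.pi**2 * u / 2) * np.sin(k * np.pi * w)
            )

        for u in (0.05, 0.1, 0.3, 0.5, 1.0):
            for w in (0.3, 0.5, 0.7):
                s, l = small_time(u, w), large_time(u, w)
                assert s == pytest.approx(l, abs=1e-8)
                assert _fw(u, w, 1e-12) == pytest.approx(s, abs=1e-8)

    def test_density_matches_euler_simulation(self):
        """Series density vs an independent Euler path-simulation histogram."""
        p = WienerParams(1.5, 1.2, 0.25, 0.6)
        n = 200_000
        correct, rt = sample_trials_euler(p, n, np.random.default_rng(7), dt=1e-3)
        lo, hi = 0.78, 0.82
        mass = np.mean((rt >= lo) & (rt < hi) & correct)
        se = np.sqrt(mass * (1 - mass) / n) / (hi - lo)
        analytic = quad(lambda t: fpt_density(t, p, "upper"), lo, hi)[0] / (hi - lo)
        assert mass / (hi - lo) == pytest.approx(analytic, abs=3 * se)

    def test_rejects_nonfinite_params(self):
        with pytest.raises(ValueError):
            WienerParams(np.nan, 1.0, 0.2, 0.5)
        with pytest.raises(ValueError):
            WienerParams(1.0, -1.0, 0.2, 0.5)
        with pytest.raises(ValueError):
            WienerParams(1.0, 1.0, 0.2, 1.2)


class TestChoiceProbability:
    def test_drift_free_equals_relative_start(self):
        assert choice_probability(WienerParams(0.0, 2.0, 0.1, 0.5)) == pytest.approx(0.5)
        assert choice_probability(WienerParams(0.0, 2.0, 0.1, 0.3)) == pytest.approx(0.3)

    def test_closed_form_value(self):
        p = WienerParams(1.0, 2.0, 0.3, 0.5)
        expected = (1 - np.exp(-2 * 1 * 2 * 0.5)) / (1 - np.exp(-2 * 1 * 2))
        assert choice_probability(p) == pytest.approx(expected)
        assert choice_probability(p) == pytest.approx(0.8808, abs=1e-4)

    def test_matches_density_integral(self):
        for p in PARAM_GRID:
            mass_up = quad(lambda t: fpt_density(t, p, "upper"), p.ndt, 200, limit=300)[0]
            assert choice_probability(p) == pytest.approx(mass_up, abs=1e-6)

    @given(
        w=st.floats(0.05, 0.95),
        v=st.floats(-3, 3),
        dw=st.floats(0.01, 0.04),
        dv=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_start_and_drift(self, w, v, dw, dv):
        base = choice_probability(WienerParams(v, 1.5, 0.2, w))
        assert choice_probability(WienerParams(v, 1.5, 0.2, w + dw)) > base
        assert choice_probability(WienerParams(v + dv, 1.5, 0.2, w)) > base


class TestSampler:
    def test_support_and_determinism(self):
        p = WienerParams(1.0, 1.5, 0.3, 0.5)
        c1, r1 = sample_trials(p, 500, seed=42)
        c2, r2 = sample_trials(p, 500, seed=42)
        assert np.all(r1 > p.ndt)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(r1, r2)

    def test_choice_fraction_matches_closed_form(self):
        p = WienerParams(1.5, 1.2, 0.25, 0.6)
        n = 100_000
        correct, _ = sample_trials(p, n, seed=9)
        expected = choice_probability(p)
        se = np.sqrt(expected * (1 - expected) / n)
        assert correct.mean() == pytest.approx(expected, abs=3 * se)

    def test_mean_decision_time_matches_integral(self):
        p = WienerParams(1.5, 1.2, 0.25, 0.6)
        shifted = WienerParams(p.drift, p.boundary, 0.0, p.rel_start)
        mean_dt = quad(
            lambda t: t * (fpt_density(t, shifted, "upper") + fpt_density(t, shifted, "lower")),
            0,
            200,
            limit=300,
        )[0]
        n = 100_000
        _, rt = sample_trials(p, n, seed=11)
        dt = rt - p.ndt
        se = dt.std() / np.sqrt(n)
        assert dt.mean() == pytest.approx(mean_dt, abs=3 * se)

    def test_euler_and_inverse_cdf_agree(self):
        p = WienerParams(0.8, 1.0, 0.2, 0.4)
        c1, r1 = sample_trials(p, 40_000, seed=3)
        c2, r2 = sample_trials(p, 40_000, seed=4, method="euler", euler_dt=1e-3)
        assert c1.mean() == pytest.approx(c2.mean(), abs=0.01)
        assert np.median(r1) == pytest.approx(np.median(r2), abs=0.01)

    def test_invalid_inputs(self):
        p = WienerParams(1.0, 1.0, 0.2, 0.5)
        with pytest.raises(ValueError):
            sample_trials(p, 0)
        with pytest.raises(ValueError):
            sample_trials(p, 10, method="nonsense")


class TestLogLikelihood:
    def test_single_trial_equals_log_density(self):
        p = WienerParams(1.2, 1.4, 0.25, 0.55)
        rt = 0.7
        expected = fpt_logdensity(rt, p, "upper")
        got = log_likelihood([rt], [True], [1], p)
        assert got == pytest.approx(expected)
        got_lower = log_likelihood([rt], [False], [2], p)
        assert got_lower == pytest.approx(fpt_logdensity(rt, p, "lower"))

    def test_rt_at_or_below_ndt_gives_neg_inf(self):
        p = WienerParams(1.0, 1.0, 0.3, 0.5)
        assert log_likelihood([0.3], [True], [1], p) == -np.inf
        assert log_likelihood([0.7, 0.2], [True, True], [1, 1], p) == -np.inf

    def test_empty_trials_give_zero(self):
        p = WienerParams(1.0, 1.0, 0.3, 0.5)
        assert log_likelihood([], [], [], p) == 0.0

    def test_additivity(self):
        p = WienerParams(1.0, 1.3, 0.2, 0.5)
        rts = [0.5, 0.8, 1.1]
        total = log_likelihood(rts, [True, False, True], [1, 1, 2], p)
        parts = sum(
            log_likelihood([r], [c], [k], p)
            for r, c, k in zip(rts, [True, False, True], [1, 1, 2])
        )
        assert total == pytest.approx(parts)

    def test_concentrates_at_generating_parameters(self):
        """Log likelihood at truth beats a drift-perturbed alternative."""
        p = WienerParams(1.5, 1.2, 0.25, 0.6)
        perturbed = WienerParams(2.5, 1.2, 0.25, 0.6)
        rng = np.random.default_rng(15)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            c, r = sample_trials(p, 100, seed=rng)
            cond = np.ones(100, dtype=int)
            if log_likelihood(r, c, cond, p) > log_likelihood(r, c, cond, perturbed):
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_mismatched_boundary_or_ndt_rejected(self):
        a = WienerParams(1.0, 1.0, 0.2, 0.5)
        b = WienerParams(1.0, 1.5, 0.2, 0.5)
        with pytest.raises(ValueError):
            log_likelihood([0.5], [True], [1], {1: a, 2: b})
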