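"""Hierarchical model structure, sampler correctness, diagnostics, predictives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuebias.data import StudyData
from cuebias.hierarchical import (
    PriorConfig,
    build_model,
    gelman_rubin,
    load_draws,
    posterior_predict,
    sample_posterior,
)
from cuebias.wiener import WienerParams, log_likelihood


def tiny_study(conds=(1, 2, 3), n_per=30, n_participants=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(1, n_participants + 1):
        for c in conds:
            for _ in range(n_per):
                rows.append((p, 1, c, bool(rng.integers(0, 2)), float(rng.uniform(0.35, 1.2))))
    df = pd.DataFrame(rows, columns=["participant", "block", "condition", "correct", "rt"])
    return StudyData(trials=df)


class TestModelStructure:
    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError, match="unknown model spec"):
            build_model("M4_magic", tiny_study())

    def test_finite_log_posterior_at_feasible_point(self):
        m = build_model("M1_start", tiny_study())
        rng = np.random.default_rng(1)
        g, X = m.initial_point(rng)
        theta = np.concatenate([g, X.ravel()])
        assert np.isfinite(m.log_posterior(theta))

    def test_ndt_at_or_above_min_rt_kills_likelihood(self):
        m = build_model("M1_start", tiny_study())
        rng = np.random.default_rng(2)
        _, X = m.initial_point(rng)
        Xc, _ = m.part_constrain(X)
        Xc[0, m.part_names.index("tau")] = m.data.for_participant(1)["rt"].min() + 0.01
        assert m.loglik(Xc)[0] == -np.inf

    def test_label_swap_symmetry_at_null_effect(self):
        """With theta = 0, swapping valid/invalid labels while mirroring
        beta_p2 -> 1 - beta_p2 leaves the M1 log posterior unchanged."""
        data = tiny_study(conds=(2, 3), seed=3)
        swapped_trials = data.trials.copy()
        swapped_trials["condition"] = swapped_trials["condition"].map({2: 3, 3: 2})
        m1 = build_model("M1_start", data)
        m2 = build_model("M1_start", StudyData(trials=swapped_trials))
        rng = np.random.default_rng(4)
        g, X = m1.initial_point(rng)
        g[m1.group_names.index("theta_start")] = 0.0
        theta_a = np.concatenate([g, X.ravel()])
        X_m = X.copy()
        jb = m1.part_names.index("beta_2")
        X_m[:, jb] = -X_m[:, jb]  # logit mirror: beta -> 1 - beta
        theta_b = np.concatenate([g, X_m.ravel()])
        assert m1.log_posterior(theta_a) == pytest.approx(m2.log_posterior(theta_b), rel=1e-10)

    def test_m3_with_null_effects_nests_single_condition_fit(self):
        data = tiny_study(seed=5)
        m = build_model("M3_both", data)
        rng = np.random.default_rng(6)
        _, X = m.initial_point(rng)
        Xc, _ = m.part_constrain(X)
        Xc[:, 0] = Xc[:, 1] = Xc[:, 2] = 1.1          # equal drift everywhere
        Xc[:, m.part_names.index("beta_2")] = 0.5     # no start bias
        total = m.loglik(Xc).sum()
        pooled = 0.0
        for i, pid in enumerate(m.participants):
            sub = data.for_participant(pid)
            params = WienerParams(1.1, Xc[i, m.part_names.index("alpha")],
                                  Xc[i, m.part_names.index("tau")], 0.5)
            pooled += log_likelihood(
                sub["rt"], sub["correct"], np.ones(len(sub), dtype=int), params
            )
        assert total == pytest.approx(pooled, rel=1e-10)

    def test_beta3_mirror_holds_in_every_draw(self, fitted_m1):
        _, draws = fitted_m1
        b2 = draws.participant_matrix("beta_2")
        W_check = 1.0 - b2
        # beta_3 is derived as 1 - beta_2 inside the likelihood mapping
        model = draws.model
        X = draws.flat()[:, model.d_group:].reshape(-1, model.n_participants, model.d_part)
        Xc, _ = model.part_constrain(X)
        _, _, W, _ = model._vawt(Xc[0])
        np.testing.assert_allclose(W[:, 2], W_check[0], rtol=1e-12)

    def test_min_rt_too_small_rejected(self):
        df = pd.DataFrame(
            [(1, 1, 1, True, 0.04)], columns=["participant", "block", "condition", "correct", "rt"]
        )
        with pytest.raises(ValueError, match="min RT"):
            build_model("M1_start", StudyData(trials=df))


class TestSampler:
    def test_schedule_validation(self):
        m = build_model("M1_start", tiny_study())
        with pytest.raises(ValueError, match="burn_in"):
            sample_posterior(m, n_iter=100, burn_in=100)

    def test_retained_draw_count(self, fitted_m1):
        _, draws = fitted_m1
        assert draws.draws.shape[1] == 900 - 400
        assert draws.n_retained == 2 * 500

    def test_same_seed_reproduces_draws(self):
        data = tiny_study(n_participants=2, n_per=15, seed=7)
        m = build_model("M1_start", data)
        d1 = sample_posterior(m, n_chains=2, n_iter=200, burn_in=100, seed=77)
        d2 = sample_posterior(m, n_chains=2, n_iter=200, burn_in=100, seed=77)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_prior_only_sampling_recovers_prior(self):
        """Without data the sampler must reproduce the prior's moments."""
        m = build_model("M1_start", tiny_study(seed=8), use_likelihood=False)
        d = sample_posterior(m, n_chains=2, n_iter=2500, burn_in=500, seed=88)
        gs = d.group_samples()
        pr = PriorConfig()

        def tmean(loc_scale, bounds):
            loc, scale = loc_scale
            a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
            return stats.truncnorm.mean(a, b, loc=loc, scale=scale)

        assert gs["mu_delta"].mean() == pytest.approx(tmean(pr.mu_delta, (-5, 10)), abs=0.5)
        assert gs["mu_alpha"].mean() == pytest.approx(tmean(pr.mu_alpha, (0.1, 5)), abs=0.3)
        assert gs["mu_tau"].mean() == pytest.approx(tmean(pr.mu_tau, (0.05, 1)), abs=0.1)
        # half-normal(1) mean = sqrt(2/pi)
        assert gs["sigma_delta"].mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.3)
        assert np.median(gs["theta_start"]) == pytest.approx(0.0, abs=0.4)

    def test_theta_not_updated_without_cue_conditions(self):
        """All-neutral data cannot inform the starting-point effect, so the
        theta posterior must stay at its (symmetric, zero-centered) prior."""
        data = tiny_study(conds=(1,), n_per=60, seed=9)
        m = build_model("M1_start", data)
        # theta mixes only through the prior here, so the chain is longer
        d = sample_posterior(m, n_chains=3, n_iter=4000, burn_in=1000, seed=99)
        theta = d.group_samples()["theta_start"]
        q25, q50, q75 = np.percentile(theta, [25, 50, 75])
        assert q25 < 0 < q75
        assert abs(q50) < 0.35
        assert 0.35 < np.mean(theta > 0) < 0.65

    def test_group_start_effect_recovered(self, small_study, fitted_m1):
        cfg, _, participants = small_study
        _, draws = fitted_m1
        true_effect = cfg.truth.theta_start * cfg.truth.sigma_start
        post = draws.extract("start_effect_group").ravel()
        # 12 participants: sampling SE of the group effect ~0.015
        assert post.mean() == pytest.approx(true_effect, abs=0.045)
        sample_mean = (participants["beta_2"] - 0.5).mean()
        assert post.mean() == pytest.approx(sample_mean, abs=0.045)


class TestGelmanRubin:
    def test_convergent_chains_near_one(self):
        rng = np.random.default_rng(10)
        chains = rng.standard_normal((3, 4000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_match_formula(self):
        rng = np.random.default_rng(11)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n + B / (m * n)) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)
        assert gelman_rubin(chains) > 5

    def test_constant_chains_warn(self):
        with pytest.warns(UserWarning, match="within-chain"):
            assert gelman_rubin(np.ones((2, 100))) == 1.0

    def test_single_chain_needs_split(self):
        x = np.random.default_rng(12).standard_normal((1, 1000))
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(x)
        assert gelman_rubin(x, split=True) == pytest.approx(1.0, abs=0.05)

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(13)
        chains = rng.standard_normal((4, 800)) + rng.normal(0, 0.05, (4, 1))
        mine = gelman_rubin(chains, split=True)
        theirs = float(az.rhat(chains, method="split"))
        assert mine == pytest.approx(theirs, abs=0.01)


class TestPosteriorPredictive:
    def test_deterministic_given_seed(self, fitted_m1, small_study):
        _, data, _ = small_study
        _, draws = fitted_m1
        a = posterior_predict(draws, data, n_rep=1, seed=5)
        b = posterior_predict(draws, data, n_rep=1, seed=5)
        pd.testing.assert_frame_equal(a["mean"], b["mean"])

    def test_validity_ordering_in_predictions(self, fitted_m1, small_study):
        _, data, _ = small_study
        _, draws = fitted_m1
        ppc = posterior_predict(draws, data, n_rep=30, seed=6)
        acc = ppc["mean"]["accuracy"]
        assert acc[2] > acc[3]  # valid beats invalid under a positive effect

    def test_bands_bracket_mean(self, fitted_m1, small_study):
        _, data, _ = small_study
        _, draws = fitted_m1
        ppc = posterior_predict(draws, data, n_rep=30, seed=7)
        assert (ppc["band_low"].to_numpy() <= ppc["band_high"].to_numpy()).all()


class TestSerialization:
    def test_save_load_round_trip(self, fitted_m1, tmp_path):
        model, draws = fitted_m1
        draws.save(tmp_path / "d.csv")
        back = load_draws(model, tmp_path / "d.csv")
        np.testing.assert_allclose(back.draws, draws.draws, rtol=1e-12)

    def test_parquet_round_trip_and_compactness(self, fitted_m1, tmp_path):
        model, draws = fitted_m1
        draws.save(tmp_path / "d.parquet")
        draws.save(tmp_path / "d.csv")
        back = load_draws(model, tmp_path / "d.parquet")
        np.testing.assert_allclose(back.draws, draws.draws, rtol=1e-12)
        assert (tmp_path / "d.parquet").stat().st_size < (tmp_path / "d.csv").stat().st_size

    def test_load_rejects_mismatched_model(self, fitted_m1, tmp_path):
        model, draws = fitted_m1
        draws.save(tmp_path / "d.csv")
        other = build_model("M2_drift", model.data)
        with pytest.raises(ValueError, match="parameterization"):
            load_draws(other, tmp_path / "d.csv")
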