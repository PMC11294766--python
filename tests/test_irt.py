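"""D-diffusion IRT model: likelihood, estimation, scoring, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from emaclarity.irt import (DiffusionIRT, occasion_loglik, absolute_drift)
from emaclarity.wiener import fpt_density, sample_fpt


class TestOccasionLoglik:
    def test_additivity_over_items(self):
        b = np.array([-1.0, 0.0, 1.0])
        resp = np.array([1.0, 0.0, 1.0])
        rts = np.array([0.9, 1.4, 0.7])
        theta, alpha, ter = 0.4, 2.0, 0.3
        ll = occasion_loglik(resp, rts, theta, alpha, ter, b)
        per_item = sum(
            np.log(fpt_density(t, theta, bi, alpha, ter=ter,
                               boundary="upper" if r == 1 else "lower"))
            for r, t, bi in zip(resp, rts, b))
        assert ll == pytest.approx(float(per_item), abs=1e-10)

    def test_missing_items_skipped(self):
        b = np.array([-1.0, 0.0, 1.0])
        full = occasion_loglik([1, 0, 1], [0.9, 1.4, 0.7], 0.4, 2.0, 0.3, b)
        part = occasion_loglik([1, np.nan, 1], [0.9, np.nan, 0.7],
                               0.4, 2.0, 0.3, b)
        only_mid = occasion_loglik([np.nan, 0, np.nan],
                                   [np.nan, 1.4, np.nan], 0.4, 2.0, 0.3, b)
        assert full == pytest.approx(part + only_mid)

    def test_all_missing_undefined(self):
        with pytest.raises(ValueError):
            occasion_loglik([np.nan], [np.nan], 0.0, 2.0, 0.3, [0.0])

    def test_finite_argmax_in_theta(self):
        # all items endorsed: loglik rises with theta then falls once the
        # implied speed outpaces the observed RTs
        b = np.array([-1.0, -0.3, 0.4, 1.1])
        resp = np.ones(4)
        rts = np.array([1.2, 1.0, 1.5, 1.1])
        grid = np.linspace(-2, 8, 101)
        ll = [occasion_loglik(resp, rts, th, 2.0, 0.3, b) for th in grid]
        k = int(np.argmax(ll))
        assert 0 < k < len(grid) - 1

    def test_slower_rts_imply_less_accumulation(self):
        """On a 1-item grid, scaling all RTs up moves the joint optimum to a
        smaller alpha * |drift| product (slower information accumulation)."""
        b = np.array([0.0])

        def best_product(scale):
            best, arg = -np.inf, None
            for th in np.linspace(0.05, 3.0, 30):
                for al in np.linspace(0.5, 4.0, 30):
                    ll = occasion_loglik([1.0], [0.8 * scale], th, al, 0.2, b)
                    if ll > best:
                        best, arg = ll, al * abs(th)
            return arg

        assert best_product(3.0) < best_product(1.0)


class TestAbsoluteDrift:
    def test_degenerate_floored(self):
        ad, log_ad = absolute_drift(0.5, [0.5])
        assert ad == 0.0
        assert log_ad == pytest.approx(np.log(1e-6))

    def test_symmetric_pair(self):
        ad, log_ad = absolute_drift(0.0, [-1.0, 1.0])
        assert ad == pytest.approx(1.0)
        assert log_ad == pytest.approx(0.0)

    def test_four_item_arithmetic(self):
        ad, log_ad = absolute_drift(0.5, [-1.0, -0.3, 0.4, 1.1])
        assert ad == pytest.approx((1.5 + 0.8 + 0.1 + 0.6) / 4)
        assert log_ad == pytest.approx(np.log(0.75))

    def test_translation_invariance(self):
        b = np.array([-1.0, -0.3, 0.4, 1.1])
        th = np.array([0.2, -0.7, 1.4])
        _, l1 = absolute_drift(th, b)
        _, l2 = absolute_drift(th + 2.5, b + 2.5)
        assert np.allclose(l1, l2)

    def test_no_items_rejected(self):
        with pytest.raises(ValueError):
            absolute_drift(0.0, [])


class TestModelConstruction:
    def test_nondichotomous_rejected(self):
        with pytest.raises(ValueError):
            DiffusionIRT(np.array([[0.0, 0.5]]), np.array([[1.0, 1.0]]))

    def test_from_dataframe_shape(self, tiny_study):
        from emaclarity.preprocess import to_seconds, filter_rts, dichotomize
        ema, _ = tiny_study
        df = to_seconds(ema)
        df, _ = filter_rts(df)
        aff = dichotomize(df[df["valence"].isin(["NA", "PA"])].copy())
        mod = DiffusionIRT.from_dataframe(aff, "NA")
        assert mod.n_items == 4
        assert mod.nobs == aff[aff.valence == "NA"]["occasion_id"].count() / 4

    def test_degenerate_item_fixed(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(0, 2, (60, 3)).astype(float)
        resp[:, 2] = 1.0  # endorsed by everyone
        rts = 0.4 + rng.exponential(0.5, (60, 3))
        with pytest.warns(UserWarning, match="all-0 or all-1"):
            mod = DiffusionIRT(resp, rts)
        res_b, *_ = mod._unpack(mod.start_params())
        assert res_b[2] == -4.0


class TestLikelihoodProperties:
    def test_label_switch_symmetry(self, model_sim):
        """Negating responses and difficulties mirrors the likelihood."""
        mod = DiffusionIRT(model_sim["responses"], model_sim["rts"],
                           ter_policy="occasion_min", quadrature_nodes=7)
        flipped = DiffusionIRT(1.0 - model_sim["responses"], model_sim["rts"],
                               ter_policy="occasion_min", quadrature_nodes=7)
        params = mod._pack(model_sim["b"], 1.0, np.log(2.0), 0.2, 0.1)
        mirrored = flipped._pack(-model_sim["b"], 1.0, np.log(2.0), 0.2, -0.1)
        assert mod.loglike(params) == pytest.approx(flipped.loglike(mirrored),
                                                    rel=1e-10)

    def test_quadrature_stability_at_optimum(self, model_sim, fitted_small):
        mod15 = DiffusionIRT(model_sim["responses"], model_sim["rts"],
                             ter_policy="global", quadrature_nodes=15)
        mod30 = DiffusionIRT(model_sim["responses"], model_sim["rts"],
                             ter_policy="global", quadrature_nodes=30)
        ll15 = mod15.loglike(fitted_small.params)
        ll30 = mod30.loglike(fitted_small.params)
        # per-occasion quadrature error when doubling the nodes
        assert abs(ll15 - ll30) / mod15.nobs < 1e-3

    def test_kernel_matches_vectorized_path(self, model_sim):
        import emaclarity.irt as irt
        mod = DiffusionIRT(model_sim["responses"][:40], model_sim["rts"][:40],
                           quadrature_nodes=7)
        x = mod.start_params()
        ll_fast = mod.loglikeobs(x)
        have = irt._HAVE_NUMBA
        try:
            irt._HAVE_NUMBA = False
            ll_ref = mod.loglikeobs(x)
        finally:
            irt._HAVE_NUMBA = have
        assert np.allclose(ll_fast, ll_ref, atol=1e-10)


class TestFitAndScores:
    def test_small_recovery(self, model_sim, fitted_small):
        res = fitted_small
        assert res.converged
        rmse = np.sqrt(np.mean((res.item_difficulties - model_sim["b"]) ** 2))
        assert rmse < 0.25  # 600 occasions; full-scale bound is tighter
        assert res.sd_theta == pytest.approx(model_sim["sd_theta"], abs=0.2)
        assert res.ter_global == pytest.approx(model_sim["ter"], abs=0.05)

    def test_eap_scores_track_truth(self, model_sim, fitted_small):
        sc = fitted_small.eap_scores()
        r = np.corrcoef(sc["theta_hat"], model_sim["theta"])[0, 1]
        assert r > 0.6

    def test_eap_direction_for_uniform_rejections(self, fitted_small):
        sc = fitted_small.eap_scores()
        m = fitted_small.model
        all_zero = (np.nansum(np.where(m.mask, m.responses, 0), axis=1) == 0)
        assert sc.loc[all_zero, "theta_hat"].mean() < 0

    def test_prior_only_occasion_scores_at_population_mean(self, fitted_small):
        th, al = fitted_small.prior_eap()
        assert th == pytest.approx(0.0, abs=1e-8)
        # lognormal mean exceeds the median exp(mu)
        assert al >= np.exp(fitted_small.mu_logalpha)

    def test_summary_mentions_key_quantities(self, fitted_small):
        s = fitted_small.summary()
        assert "sd(theta)" in s and "item" in s and "log-likelihood" in s

    def test_information_criteria_consistent(self, fitted_small):
        k = fitted_small.model.k_params
        assert fitted_small.aic == pytest.approx(2 * k - 2 * fitted_small.llf)
        assert fitted_small.bic > fitted_small.aic  # log(600) > 2


class TestPredictiveCheck:
    def test_self_consistency(self, fitted_small):
        """Data generated by the model itself should pass the RT check."""
        chk = fitted_small.predictive_rt_check(n_sim=10_000, seed=1)
        assert (chk["ks_distance"] < 0.05).all()

    def test_detects_planted_contamination(self, model_sim):
        rng = np.random.default_rng(3)
        rts = model_sim["rts"].copy()
        contam = rng.random(rts.shape) < 0.25
        rts[contam] = rng.uniform(0.4, 8.0, contam.sum())
        mod = DiffusionIRT(model_sim["responses"], rts,
                           ter_policy="global", quadrature_nodes=7)
        res = mod.fit(n_starts=1, seed=0)
        chk = res.predictive_rt_check(n_sim=5_000, seed=2)
        assert (chk["ks_distance"] > 0.05).any()

    def test_deterministic_given_seed(self, fitted_small):
        a = fitted_small.predictive_rt_check(n_sim=2_000, seed=9)
        b = fitted_small.predictive_rt_check(n_sim=2_000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_sim_warns(self, fitted_small):
        with pytest.warns(UserWarning, match="n_sim"):
            fitted_small.predictive_rt_check(n_sim=500, seed=0)
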