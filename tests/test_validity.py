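"""Person scoring, partial correlations, FDR, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from emaclarity.validity import (person_scores, intensity_person_scores,
                                 adjusted_correlation, bh_fdr,
                                 power_correlation, validity_table,
                                 DEFAULT_FAMILIES)


def _occasions(n_persons=40, n_occ=25, morning_shift=0.0, seed=0,
               quad_coef=0.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 0.6, n_persons)
    rows = []
    for p in range(n_persons):
        for t in range(n_occ):
            slot = ("morning", "midday", "evening")[t % 3]
            intensity = rng.uniform(0, 100)
            y = (u[p] + rng.normal(0, 0.8)
                 + (morning_shift if slot == "morning" else 0.0)
                 + quad_coef * ((intensity - 50) / 50) ** 2)
            rows.append((f"p{p}", slot, y, intensity))
    return pd.DataFrame(rows, columns=["person_id", "slot", "y", "na_mean"]), u


class TestPersonScores:
    def test_approaches_raw_person_means_without_slot_effects(self):
        df, _ = _occasions(n_persons=30, n_occ=60, seed=1)
        ps = person_scores(df, "y")
        raw = df.groupby("person_id")["y"].mean()
        diff = ps.set_index("person_id")["score"] - raw
        assert np.abs(diff).max() < 0.1

    def test_planted_morning_effect_leaves_midday_scores_unbiased(self):
        base, u = _occasions(n_persons=50, n_occ=30, morning_shift=0.0, seed=2)
        shifted, _ = _occasions(n_persons=50, n_occ=30, morning_shift=0.5, seed=2)
        s0 = person_scores(base, "y").set_index("person_id")["score"]
        s1 = person_scores(shifted, "y").set_index("person_id")["score"]
        # same noise realisations; only the morning shift differs
        assert np.abs(s1 - s0).max() < 0.05

    def test_single_occasion_person_shrunk_toward_grand_mean(self):
        df, _ = _occasions(n_persons=25, n_occ=20, seed=3)
        lone = pd.DataFrame({"person_id": ["solo"], "slot": ["midday"],
                             "y": [4.0], "na_mean": [50.0]})
        ps = person_scores(pd.concat([df, lone], ignore_index=True), "y")
        grand = df["y"].mean()
        score = ps.loc[ps.person_id == "solo", "score"].iloc[0]
        assert abs(score - grand) < abs(4.0 - grand)

    def test_constant_indicator_rejected(self):
        df, _ = _occasions(n_persons=5, n_occ=4, seed=4)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            person_scores(df, "y")


class TestIntensityAdjustment:
    def test_null_intensity_effect_changes_little(self):
        df, _ = _occasions(n_persons=40, n_occ=40, seed=5, quad_coef=0.0)
        plain = person_scores(df, "y").set_index("person_id")["score"]
        adj = intensity_person_scores(df, "y", "na_mean").set_index(
            "person_id")["score"]
        sd = plain.std()
        assert np.abs(adj - plain).max() < 0.02 * sd * 10  # well under 0.2 SD
        assert np.abs(adj - plain).mean() < 0.02 * sd

    def test_between_person_correlations_barely_move(self):
        """Without intensity confounding, adjusting for intensity changes
        indicator-trait correlations only minimally (|dr| < 0.02)."""
        df, u = _occasions(n_persons=60, n_occ=30, seed=15, quad_coef=0.0)
        rng = np.random.default_rng(16)
        trait = 0.4 * u + np.sqrt(1 - 0.16) * rng.standard_normal(len(u))
        ids = [f"p{i}" for i in range(len(u))]
        plain = person_scores(df, "y").set_index("person_id")["score"]
        adj = intensity_person_scores(df, "y", "na_mean").set_index(
            "person_id")["score"]
        r0 = np.corrcoef(plain.loc[ids], trait)[0, 1]
        r1 = np.corrcoef(adj.loc[ids], trait)[0, 1]
        assert abs(r1 - r0) < 0.02

    @pytest.mark.parametrize("coef", [0.8, -0.8])
    def test_planted_quadratic_sign_recovered(self, coef):
        df, _ = _occasions(n_persons=40, n_occ=40, seed=6, quad_coef=coef)
        _, fit = intensity_person_scores(df, "y", "na_mean", return_fit=True)
        assert np.sign(fit.fe_params["_intens2"]) == np.sign(coef)


class TestAdjustedCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        res = adjusted_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_matches_independent_partial_correlation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        z = rng.standard_normal(60)
        x = 0.5 * z + rng.standard_normal(60)
        y = -0.3 * z + rng.standard_normal(60)
        res = adjusted_correlation(x, y, [z])
        ref = pingouin.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                                    x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_collinear_trait_gives_zero_partial(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(50)
        x = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = adjusted_correlation(x, 2.0 * z + 1.0, [z])
        assert res.r == 0.0 and res.p == 1.0

    def test_listwise_deletion(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 2.0])
        res = adjusted_correlation(x, y)
        assert res.n == 5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjusted_correlation([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            adjusted_correlation([1.0] * 10, list(range(10)))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_family(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_families_adjusted_separately(self):
        p = [0.01, 0.02, 0.01, 0.02]
        fam = ["a", "a", "b", "b"]
        out = bh_fdr(p, fam)
        assert np.allclose(out, [0.02, 0.02, 0.02, 0.02])

    def test_nan_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = bh_fdr([0.01, np.nan])
        assert np.isnan(out[1]) and out[0] == pytest.approx(0.01)

    @staticmethod
    def _brute_force(p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            adj[i] = running
        return adj

    def test_matches_brute_force_on_random_families(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            m = rng.integers(1, 12)
            p = rng.random(m)
            assert np.allclose(bh_fdr(p), self._brute_force(p), atol=1e-12)


class TestPower:
    def test_published_worked_example(self):
        assert round(100 * power_correlation(0.20, 196, 0.05)) == 80

    def test_size_at_null_limit(self):
        assert power_correlation(1e-8, 196, 0.05) == pytest.approx(0.05,
                                                                   abs=1e-3)

    def test_monotone_in_n_and_rho(self):
        p1 = power_correlation(0.2, 100)
        p2 = power_correlation(0.2, 400)
        p3 = power_correlation(0.4, 100)
        assert p2 > p1 and p3 > p1

    def test_matches_monte_carlo_rejection_rates(self):
        rng = np.random.default_rng(11)
        for rho, n in [(0.2, 196), (0.3, 100)]:
            rej = 0
            reps = 3000
            for _ in range(reps):
                z = rng.standard_normal(n)
                x = z
                y = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
                _, p = stats.pearsonr(x, y)
                rej += p < 0.05
            assert rej / reps == pytest.approx(power_correlation(rho, n),
                                               abs=0.015)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_correlation(0.2, 3)
        with pytest.raises(ValueError):
            power_correlation(0.0, 100)


class TestValidityTable:
    @staticmethod
    def _person_tables(n=120, seed=12):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        scores = pd.DataFrame({
            "person_id": np.arange(n),
            "na_drift": z + 0.3 * rng.standard_normal(n),
            "na_rt": 0.7 * z + 0.5 * rng.standard_normal(n),
            "base_speed": rng.standard_normal(n),
        })
        traits = pd.DataFrame({
            "person_id": np.arange(n),
            "depression": -0.27 * z + rng.standard_normal(n),
            "anxiety": rng.standard_normal(n),
        })
        return scores, traits

    def test_grid_shape_and_fdr_monotone(self):
        scores, traits = self._person_tables()
        tab = validity_table(scores, traits, ["na_drift", "na_rt"],
                             covariate_cols=["base_speed"])
        assert len(tab) == 4
        assert (tab["p_fdr"] >= tab["p"] - 1e-12).all()

    def test_deterministic(self):
        scores, traits = self._person_tables()
        a = validity_table(scores, traits, ["na_drift"], fdr=True)
        b = validity_table(scores, traits, ["na_drift"], fdr=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_trait_named_error(self):
        scores, traits = self._person_tables()
        with pytest.raises(KeyError, match="nonexistent"):
            validity_table(scores, traits, ["na_drift"],
                           trait_cols=["nonexistent"])

    def test_shared_signal_indicators_correlate(self):
        scores, _ = self._person_tables()
        r = np.corrcoef(scores["na_drift"], scores["na_rt"])[0, 1]
        assert r > 0.3
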