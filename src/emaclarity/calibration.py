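"""Simulation-based calibration of the full measurement pipeline.

Two design-analysis checks:

* ``null_rejection_rate`` — type-I error of the validity grid.  Each
  replicate simulates a small EMA study, builds the four clarity indicators
  (median-RT and log absolute drift, the latter EAP-scored at the known
  generating parameters), scores persons with the mixed model, attaches
  traits with zero true correlation, and counts how often the adjusted
  correlations reject at alpha.  The grand rejection rate should sit at the
  nominal level.

* ``correlation_coverage`` — confidence-interval coverage for a nonzero
  between-person correlation under baseline-speed confounding, at the
  person level (the trait model operates on person means, so replicates
  need not re-simulate occasions).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import preprocess as prep
from .irt import DiffusionIRT, DiffusionIRTResults
from .simulate import (StudyDesign, GeneratorParams, simulate_study,
                       inject_artifacts, default_item_difficulties)
from .validity import adjusted_correlation, person_scores, validity_table

__all__ = ["replicate_person_scores", "null_rejection_rate",
           "correlation_coverage"]

NULL_TRAITS = ["life_satisfaction", "depression", "anxiety",
               "ders_total", "ders_awareness", "ders_clarity"]


def _eap_with_known_params(aff: pd.DataFrame, valence: str,
                           items: dict) -> pd.DataFrame:
    """EAP drift scores at the generating item/population parameters.

    Rows are reshaped directly (the generator emits complete 4-item blocks
    per occasion even when individual RTs were screened out).
    """
    sub = aff[aff["valence"] == valence].sort_values(
        ["person_id", "day", "prompt_idx", "item_id"], kind="mergesort")
    k = len(items[valence])
    resp = sub["dichot"].to_numpy(float).reshape(-1, k)
    rts = sub["rt"].to_numpy(float).reshape(-1, k)
    head = sub.iloc[::k]
    idx = pd.MultiIndex.from_arrays(
        [head["person_id"].to_numpy(), head["occasion_id"].to_numpy()],
        names=["person_id", "occasion_id"])
    mod = DiffusionIRT(resp, rts, occasion_index=idx, quadrature_nodes=11)
    # population dispersion implied by the generator defaults
    pop = GeneratorParams()
    sd_theta = float(np.sqrt(pop.sd_u_theta ** 2
                             + np.exp(pop.sd_log_kappa ** 2)))
    params = mod._pack(np.asarray(items[valence], float), sd_theta,
                       pop.mu_log_alpha,
                       float(np.hypot(pop.sd_log_alpha_person,
                                      pop.sd_log_alpha_occ)), 0.0)
    res = DiffusionIRTResults(mod, params, 0.0, True, 0.0)
    return res.eap_scores()


def replicate_person_scores(seed: int, n_persons: int = 50,
                            n_days: int = 4) -> pd.DataFrame:
    """One simulated study reduced to person-level indicator scores.

    5 prompts/day, so ``n_days=4`` gives the scaled-down 20 occasions per
    person.  Returns person_id, the four indicator scores, and base_speed.
    """
    design = StudyDesign(n_persons=n_persons, n_days=n_days,
                         prompts_per_day=5, frac_five_prompt=1.0)
    ema, truth = simulate_study(design, seed=seed)
    ema, _ = inject_artifacts(ema, seed=seed + 1)
    df = prep.to_seconds(ema)
    df, _ = prep.filter_rts(df)
    aff = prep.dichotomize(df[df["valence"].isin(["NA", "PA"])].copy())
    ind = prep.median_rt_indicators(aff)
    items = default_item_difficulties()
    keys = ["person_id", "occasion_id"]
    for valence, col in (("NA", "na_drift"), ("PA", "pa_drift")):
        sc = _eap_with_known_params(aff, valence, items)
        ind = ind.merge(sc[keys + ["log_ad"]].rename(columns={"log_ad": col}),
                        on=keys, how="left")
    scores = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in ("na_drift", "pa_drift", "na_rt", "pa_rt"):
            s = person_scores(ind, name).rename(columns={"score": name})
            s = s[["person_id", name]]
            scores = s if scores is None else scores.merge(s, on="person_id")
    base = prep.baseline_speed(df)
    return scores.merge(base, on="person_id", how="left")


def null_rejection_rate(n_reps: int = 500, alpha: float = 0.05,
                        seed: int = 0, n_persons: int = 50,
                        n_days: int = 4):
    """Type-I error of the adjusted validity grid under null traits.

    Returns ``(rate, n_tests)`` pooled over replicates.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tot = 0
    for rep in range(n_reps):
        scores = replicate_person_scores(int(rng.integers(2 ** 31 - 1)),
                                         n_persons, n_days)
        traits = pd.DataFrame({"person_id": scores["person_id"]})
        for t in NULL_TRAITS:
            traits[t] = rng.standard_normal(len(scores))
        tab = validity_table(scores, traits,
                             ["na_drift", "pa_drift", "na_rt", "pa_rt"],
                             covariate_cols=["base_speed"], fdr=False)
        n_sig += int((tab["p"] < alpha).sum())
        n_tot += len(tab)
    return n_sig / n_tot, n_tot


def correlation_coverage(n_reps: int = 200, n: int = 196,
                         target: float = -0.27, confound: float = 0.4,
                         seed: int = 0):
    """95% CI coverage of the covariate-adjusted correlation estimate.

    Person-level model: latent clarity z, baseline-speed confounder
    contaminating the indicator and the trait, trait built at the target
    partial correlation with z.  Returns ``(coverage, mean_r)``.
    """
    rng = np.random.default_rng(seed)
    cover = 0
    rs = []
    for _ in range(n_reps):
        z = rng.standard_normal(n)
        bs = rng.standard_normal(n)
        x = z + confound * bs
        y = (target * z + np.sqrt(1 - target ** 2) * rng.standard_normal(n)
             - confound * bs)
        res = adjusted_correlation(x, y, [bs])
        zr = np.arctanh(res.r)
        half = 1.96 / np.sqrt(res.n - 3 - 1)
        lo, hi = np.tanh(zr - half), np.tanh(zr + half)
        cover += lo <= target <= hi
        rs.append(res.r)
    return cover / n_reps, float(np.mean(rs))
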