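"""Between-person validity testing of the clarity indicators.

Person-level scores are obtained from occasion indicators by a linear mixed
model with morning/evening dummies (midday is the reference, so the person
score is the shrunken person mean at a midday prompt).  Each indicator's
person scores are then correlated with trait measures, partialling out
person-level covariates (baseline responding speed, optionally processing
speed):

    r = corr(resid(x | Z), resid(y | Z)),   t = r sqrt((n-2-k)/(1-r^2))

with k covariates.  p-values are optionally Benjamini-Hochberg adjusted
within hypothesis families (one family per indicator x construct group,
e.g. subjective well-being vs emotion regulation).  A Fisher-z power
function for between-person correlations completes the design-analysis
toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidityResult",
    "person_scores",
    "intensity_person_scores",
    "adjusted_correlation",
    "bh_fdr",
    "power_correlation",
    "validity_table",
    "DEFAULT_FAMILIES",
]

# hypothesis families for FDR adjustment: construct groups
DEFAULT_FAMILIES = {
    "life_satisfaction": "subjective_well_being",
    "neuroticism": "subjective_well_being",
    "depression": "subjective_well_being",
    "anxiety": "subjective_well_being",
    "diabetes_distress": "subjective_well_being",
    "ders_total": "emotion_regulation",
    "ders_strategies": "emotion_regulation",
    "ders_nonacceptance": "emotion_regulation",
    "ders_impulse": "emotion_regulation",
    "ders_goals": "emotion_regulation",
    "ders_awareness": "emotion_regulation",
    "ders_clarity": "emotion_regulation",
}


@dataclass(frozen=True)
class ValidityResult:
    indicator_name: str
    trait_name: str
    r: float
    p: float
    n: int
    covariates: tuple
    family: str = ""
    p_fdr: float | None = None


def person_scores(indicators: pd.DataFrame, indicator_col: str,
                  slot_col: str = "slot", person_col: str = "person_id",
                  extra_exog: list[str] | None = None,
                  return_fit: bool = False) -> pd.DataFrame:
    """Mixed-model person scores of one occasion indicator at midday.

    Fits ``indicator ~ morning + evening (+ extras) + (1 | person)`` and
    returns the shrunken person intercepts (fixed intercept + BLUP), i.e.
    model-based person means referenced to a midday prompt.

    ``extra_exog`` columns (already centered as appropriate) support the
    emotional-intensity sensitivity analysis: linear and quadratic terms of
    the occasion mean rating are added at level 1 before scoring.
    """
    df = indicators[[person_col, slot_col, indicator_col]
                    + list(extra_exog or [])].dropna()
    if df[indicator_col].nunique() <= 1:
        raise ValueError(f"indicator {indicator_col!r} is constant; "
                         "person scores undefined")
    import statsmodels.api as sm
    exog = pd.DataFrame({
        "const": 1.0,
        "morning": (df[slot_col] == "morning").astype(float),
        "evening": (df[slot_col] == "evening").astype(float),
    }, index=df.index)
    for c in extra_exog or []:
        exog[c] = df[c]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = sm.MixedLM(df[indicator_col], exog, groups=df[person_col])
        fit = mod.fit(reml=True)
    re = fit.random_effects
    icpt = float(fit.fe_params["const"])
    out = pd.DataFrame({
        person_col: list(re.keys()),
        "score": [icpt + float(v.iloc[0]) for v in re.values()],
    })
    out["n_occasions"] = out[person_col].map(df.groupby(person_col).size())
    if return_fit:
        return out, fit
    return out


def intensity_person_scores(indicators: pd.DataFrame, indicator_col: str,
                            mean_col: str, person_col: str = "person_id",
                            return_fit: bool = False):
    """Person scores additionally adjusted for emotional intensity:
    the occasion mean rating (centered) and its square enter at level 1."""
    df = indicators.copy()
    c = (df[mean_col] - df[mean_col].mean()) / 50.0  # rescale 0-100 ratings
    df["_intens"] = c
    df["_intens2"] = c ** 2 - (c ** 2).mean()  # centered so the reference
    # occasion is one of average intensity, keeping scores comparable
    return person_scores(df, indicator_col, person_col=person_col,
                         extra_exog=["_intens", "_intens2"],
                         return_fit=return_fit)


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), Z]) if Z.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def adjusted_correlation(x, y, covariates=None, indicator_name: str = "x",
                         trait_name: str = "y", family: str = "") -> ValidityResult:
    """Partial Pearson correlation of x and y given person-level covariates.

    Residual-on-residual correlation after OLS on the covariates (plus
    intercept); the p-value uses a t reference with n - 2 - k degrees of
    freedom.  Rows with any missing value are dropped (listwise).
    """
    cols = {"x": np.asarray(x, float), "y": np.asarray(y, float)}
    covariates = [] if covariates is None else list(covariates)
    for j, c in enumerate(covariates):
        cols[f"c{j}"] = np.asarray(c, float)
    df = pd.DataFrame(cols).dropna()
    k = len(covariates)
    n = len(df)
    if n < 4 + k:
        raise ValueError("too few complete cases for a partial correlation")
    Z = df[[f"c{j}" for j in range(k)]].to_numpy() if k else np.empty((n, 0))
    xv = df["x"].to_numpy()
    yv = df["y"].to_numpy()
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant variable; correlation undefined")
    rx = _residualize(xv, Z)
    ry = _residualize(yv, Z)
    sx, sy = rx.std(), ry.std()
    # a variable explained exactly by the covariates has no residual signal
    if sx < 1e-10 * xv.std() or sy < 1e-10 * yv.std():
        warnings.warn("zero residual variance after covariate adjustment; "
                      "partial correlation set to 0")
        return ValidityResult(indicator_name, trait_name, 0.0, 1.0, n,
                              tuple(f"c{j}" for j in range(k)) if k else (),
                              family)
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    dfree = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dfree / (1.0 - r ** 2))
        p = float(2 * stats.t.sf(abs(t), dfree))
    return ValidityResult(indicator_name, trait_name, r, p, n,
                          tuple(f"c{j}" for j in range(k)) if k else (),
                          family)


def bh_fdr(p_values, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, applied separately per family.

    NaN p-values are excluded (returned as NaN) with a warning.
    """
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    fam = np.zeros(len(p)) if families is None else np.asarray(families)
    out = np.full(len(p), np.nan)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values excluded from FDR adjustment")
    for f in pd.unique(fam):
        idx = (fam == f) & ~nan
        if idx.any():
            out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def power_correlation(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of a between-person correlation.

    Fisher-z approximation: with z = atanh(rho) and SE 1/sqrt(n-3),
    power = Phi(|z| sqrt(n-3) - z_{1-alpha/2}) + Phi(-|z| sqrt(n-3) - z_{1-alpha/2}).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    zc = stats.norm.ppf(1 - alpha / 2)
    shift = abs(np.arctanh(rho)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(shift - zc) + stats.norm.cdf(-shift - zc))


def validity_table(scores: pd.DataFrame, traits: pd.DataFrame,
                   indicator_cols: list[str], trait_cols: list[str] | None = None,
                   covariate_cols: list[str] | None = None,
                   families: dict | None = None, fdr: bool = True,
                   person_col: str = "person_id") -> pd.DataFrame:
    """Full indicator x trait grid of covariate-adjusted correlations.

    ``scores``: person-level table with one column per indicator (plus any
    covariate columns); ``traits``: person-level trait table.  FDR families
    default to one family per indicator x construct group.
    """
    trait_cols = trait_cols or [c for c in traits.columns if c != person_col]
    covariate_cols = covariate_cols or []
    families = DEFAULT_FAMILIES if families is None else families
    missing = [c for c in trait_cols if c not in traits.columns]
    if missing:
        raise KeyError(f"trait column(s) not found: {missing}")
    merged = scores.merge(traits, on=person_col, how="inner",
                          suffixes=("", "_trait"))
    rows = []
    for ind in indicator_cols:
        for tr in trait_cols:
            fam = f"{ind}|{families.get(tr, 'other')}"
            res = adjusted_correlation(
                merged[ind], merged[tr],
                [merged[c] for c in covariate_cols],
                indicator_name=ind, trait_name=tr, family=fam)
            rows.append({"indicator": ind, "trait": tr, "r": res.r,
                         "p": res.p, "n": res.n, "family": fam,
                         "covariates": ",".join(covariate_cols)})
    out = pd.DataFrame(rows)
    if fdr:
        out["p_fdr"] = bh_fdr(out["p"].to_numpy(), out["family"].to_numpy())
    return out
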