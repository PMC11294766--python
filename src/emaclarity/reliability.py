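"""Between/within-person variance decomposition and prompt-reliability curves.

An occasion-level indicator y_pt (e.g. the sign-flipped median RT or the log
absolute drift at prompt t of person p) is decomposed by a one-way
random-intercept model

    y_pt = mu + u_p + e_pt,   u_p ~ N(0, var_between), e_pt ~ N(0, var_within)

estimated by restricted maximum likelihood.  The intraclass correlation
ICC = var_between / (var_between + var_within) is the reliability of a
single prompt; averaging n prompts gives the Spearman-Brown-type curve

    reliability(n) = var_between / (var_between + var_within / n)

from which the smallest n with reliability >= 0.70 ("acceptable") is read
off.  McDonald omega at each level is computed from a one-factor
minimum-residual decomposition of the between- and within-person item
covariance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "ReliabilityCurve",
    "variance_components",
    "reliability_at_n",
    "reliability_curve",
    "omega_two_level",
    "plot_reliability_curves",
]


@dataclass(frozen=True)
class VarianceComponents:
    indicator_name: str
    var_between: float
    var_within: float
    n_persons: int
    n_occasions_total: int

    @property
    def icc(self) -> float:
        tot = self.var_between + self.var_within
        return self.var_between / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class ReliabilityCurve:
    indicator_name: str
    n_grid: np.ndarray
    rel: np.ndarray
    n_min: int | None          # smallest n with rel >= threshold, None if never
    threshold: float = 0.70


def variance_components(values, person_ids,
                        indicator_name: str = "indicator") -> VarianceComponents:
    """REML one-way random-intercept decomposition of an occasion indicator.

    Missing values are dropped.  Requires at least 2 persons contributing
    at least 2 occasions each; a negative between-person REML estimate is
    truncated at 0 with a warning (MixedLM parameterizes it as non-negative,
    so truncation appears as an estimate at the boundary).
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "g": np.asarray(person_ids)}).dropna()
    n_per = df.groupby("g").size()
    if len(n_per) < 2:
        raise ValueError("variance decomposition needs at least 2 persons")
    if (n_per >= 2).sum() < 2:
        raise ValueError("need at least 2 persons with >= 2 occasions each")
    import statsmodels.formula.api as smf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
    vb = float(fit.cov_re.iloc[0, 0])
    vw = float(fit.scale)
    if vb < 0:
        warnings.warn("negative between-person variance truncated at 0")
        vb = 0.0
    return VarianceComponents(indicator_name, vb, vw,
                              n_persons=int(len(n_per)),
                              n_occasions_total=int(len(df)))


def reliability_at_n(vc: VarianceComponents, n: int) -> float:
    """Between-person reliability of an n-prompt average:
    var_between / (var_between + var_within / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    denom = vc.var_between + vc.var_within / n
    return vc.var_between / denom if denom > 0 else 0.0


def reliability_curve(vc: VarianceComponents, n_max: int = 70,
                      threshold: float = 0.70,
                      n_min_grid: int = 2) -> ReliabilityCurve:
    """Reliability over n = 2..n_max prompts and the smallest acceptable n."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    grid = np.arange(n_min_grid, n_max + 1)
    rel = np.array([reliability_at_n(vc, int(n)) for n in grid])
    above = np.nonzero(rel >= threshold)[0]
    n_min = int(grid[above[0]]) if above.size else None
    return ReliabilityCurve(vc.indicator_name, grid, rel, n_min, threshold)


# ---------------------------------------------------------------------------
# Two-level McDonald omega
# ---------------------------------------------------------------------------

def _smooth_cov(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= 0:
        return S
    warnings.warn("non-positive-definite level covariance matrix; "
                  "eigenvalue smoothing applied")
    vals = np.clip(vals, 1e-10, None)
    return (vecs * vals) @ vecs.T


def _minres_one_factor(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-factor minimum-residual fit: loadings minimizing the squared
    off-diagonal residuals of S - lam lam'."""
    from scipy.optimize import least_squares
    k = S.shape[0]
    iu = np.triu_indices(k, 1)
    vals, vecs = np.linalg.eigh(S)
    lam0 = np.sqrt(max(vals[-1], 1e-8)) * vecs[:, -1]
    if lam0.sum() < 0:
        lam0 = -lam0

    def resid(lam):
        R = S - np.outer(lam, lam)
        return R[iu]

    sol = least_squares(resid, lam0, method="lm")
    lam = sol.x
    if lam.sum() < 0:
        lam = -lam
    psi = np.clip(np.diag(S) - lam ** 2, 0.0, None)
    return lam, psi


def _omega(lam: np.ndarray, psi: np.ndarray) -> float:
    num = lam.sum() ** 2
    return float(num / (num + psi.sum())) if (num + psi.sum()) > 0 else 0.0


def omega_two_level(item_responses: pd.DataFrame, person_col: str = "person_id",
                    item_cols: list[str] | None = None,
                    dichotomized: bool = False):
    """Within- and between-person McDonald omega for an item block.

    ``item_responses``: one row per occasion, item scores in ``item_cols``
    (at least 3).  The item covariance is split into a between part (the
    covariance of person means, with the within part's attenuation removed
    using the harmonic mean cluster size) and a within part (covariance of
    person-centered scores); a one-factor minres model is fitted to each.

    Returns ``(omega_within, omega_between)``.
    """
    if item_cols is None:
        item_cols = [c for c in item_responses.columns if c != person_col]
    if len(item_cols) < 3:
        raise ValueError("omega needs at least 3 items")
    df = item_responses[[person_col] + item_cols].dropna()
    X = df[item_cols].to_numpy(float)
    g = df[person_col].to_numpy()
    means = df.groupby(person_col)[item_cols].transform("mean").to_numpy()
    within = X - means
    S_w = np.cov(within.T, ddof=1)
    pm = df.groupby(person_col)[item_cols].mean()
    n_h = len(df) / len(pm)  # average cluster size
    S_b = np.cov(pm.to_numpy().T, ddof=1) - S_w / n_h
    S_b = _smooth_cov(S_b)
    S_w = _smooth_cov(S_w)
    lam_w, psi_w = _minres_one_factor(S_w)
    lam_b, psi_b = _minres_one_factor(S_b)
    # between-level uniqueness cannot be resolved below the sampling noise
    # of the person means; flooring it keeps omega_between ~ 0 when the
    # between-person item covariance is null
    psi_b = np.maximum(psi_b, np.diag(S_w) / n_h)
    return _omega(lam_w, psi_w), _omega(lam_b, psi_b)


def plot_reliability_curves(curves: list[ReliabilityCurve], ax=None):
    """Reliability as a function of prompts completed, one line per
    indicator, with the acceptability threshold marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(c.n_grid, c.rel, label=c.indicator_name)
    if curves:
        ax.axhline(curves[0].threshold, ls="--", color="grey", lw=1)
    ax.set_xlabel("number of EMA prompts")
    ax.set_ylabel("between-person reliability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
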