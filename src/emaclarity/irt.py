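"""D-diffusion item response theory model for EMA responses and RTs.

The model treats each EMA measurement occasion as an exchangeable unit with
a latent drift level ``theta`` (the momentary affect position, in logits)
and a latent log boundary separation ``log alpha`` (response caution).  For
item ``i`` with difficulty ``b_i``, the binary response and its RT jointly
follow a Wiener first-passage process with drift ``theta - b_i``, boundary
separation ``alpha`` (items share the boundary by default), unbiased start,
and a non-decision time ``ter``:

    P(endorse) = 1 / (1 + exp(-alpha (theta - b_i)))
    RT | boundary ~ ter + Wiener first-passage time

Occasion latents are integrated over a bivariate normal

    (theta, log alpha) ~ N((0, mu_la), [[sd_t^2, rho sd_t sd_la],
                                        [.,       sd_la^2     ]])

by Gauss-Hermite quadrature; item difficulties and the population
parameters are estimated by marginal maximum likelihood.  ``mu_theta`` is
fixed at 0 for identification (the likelihood depends on theta - b_i only,
so a common shift of the latent mean and all difficulties is invisible).

Scoring produces expected-a-posteriori (EAP) drift-level and boundary
estimates per occasion, from which the occasion-level clarity indicator is

    absolute drift = mean_i | theta_hat - b_i |,   log-transformed.

Non-decision time is not estimated jointly by default: the "occasion_min"
policy plugs in 0.95 x the minimum observed RT within the occasion, which
keeps the quadrature two-dimensional while guaranteeing positive decision
times; a single global ter can instead be estimated as a free parameter
(bounded by the 1st RT percentile and just below the smallest observed RT,
outside of which the likelihood is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .wiener import choice_probability, fpt_density, sample_fpt, _f1, _TAU_SWITCH

__all__ = [
    "DiffusionIRT",
    "DiffusionIRTResults",
    "occasion_loglik",
    "absolute_drift",
]

_LOG_TINY = -745.0  # log of smallest positive double

try:
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _ll_kernel(td, sign, mask, v, A, logalpha, logw):  # pragma: no cover
        """Marginal log likelihood per occasion on the quadrature grid.

        td, sign, mask: (O, I); v: (N, I); A, logalpha, logw: (N,)
        """
        O, I = td.shape
        N = A.shape[0]
        out = np.empty(O)
        s = np.empty(N)
        for o in range(O):
            for n in range(N):
                acc = logw[n]
                a = A[n]
                la = logalpha[n]
                for i in range(I):
                    if not mask[o, i]:
                        continue
                    t = td[o, i]
                    vv = v[n, i]
                    tau = t / (a * a)
                    # normalized first-passage density, dual series
                    # (unbiased start w=1/2: even large-time terms vanish)
                    if tau <= 0.35:
                        f1 = 0.0
                        for k in range(-2, 3):
                            wk = 0.5 + 2.0 * k
                            f1 += wk * np.exp(-wk * wk / (2.0 * tau))
                        f1 = f1 / np.sqrt(2.0 * np.pi) / tau ** 1.5
                    else:
                        f1 = 0.0
                        sgn = 1.0
                        for k in range(1, 8, 2):
                            f1 += sgn * k * np.exp(-k * k * np.pi ** 2 * tau / 2.0)
                            sgn = -sgn
                        f1 *= np.pi
                    if f1 < 1e-300:
                        f1 = 1e-300
                    acc += (-2.0 * la - 0.5 * sign[o, i] * vv * a
                            - 0.5 * vv * vv * t + np.log(f1))
                s[n] = acc
            m = s[0]
            for n in range(1, N):
                if s[n] > m:
                    m = s[n]
            tot = 0.0
            for n in range(N):
                tot += np.exp(s[n] - m)
            out[o] = m + np.log(tot)
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def absolute_drift(theta_hat, item_difficulties, floor: float = 1e-6):
    """Occasion clarity: mean absolute distance of the drift-level score
    from the item difficulties, plus its floored log transform.

    Returns ``(ad, log_ad)``; ``log_ad = log(max(ad, floor))``.
    """
    b = np.atleast_1d(np.asarray(item_difficulties, float))
    if b.size < 1:
        raise ValueError("need at least one item difficulty")
    th = np.asarray(theta_hat, float)
    ad = np.mean(np.abs(th[..., None] - b), axis=-1)
    log_ad = np.log(np.maximum(ad, floor))
    return ad, log_ad


def _log_f1(tau: np.ndarray) -> np.ndarray:
    """log of the normalized first-passage density; -inf-safe."""
    f = _f1(tau)
    return np.log(np.maximum(f, 1e-300))


def _item_logdens(td, resp, v, A, logA):
    """Elementwise log density.

    td:   decision time (seconds), any shape broadcastable with v/A
    resp: response in {0,1} (upper boundary = 1)
    v:    drift theta - b
    A:    boundary separation, logA = log(A)
    """
    sign = 1.0 - 2.0 * resp          # +1 for lower boundary, -1 for upper
    tau = td / A ** 2
    return (-2.0 * logA - 0.5 * sign * v * A - 0.5 * v ** 2 * td + _log_f1(tau))


def occasion_loglik(responses, rts, theta, alpha, ter, item_difficulties):
    """Joint response/RT log likelihood of one occasion at fixed latents.

    Missing items (NaN response or RT) are skipped; all-missing occasions
    are undefined and raise.
    """
    resp = np.asarray(responses, float)
    rt = np.asarray(rts, float)
    b = np.asarray(item_difficulties, float)
    if not (resp.shape == rt.shape == b.shape):
        raise ValueError("responses, rts and item difficulties must align")
    keep = ~(np.isnan(resp) | np.isnan(rt))
    if not keep.any():
        raise ValueError("occasion has no usable items")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    td = rt[keep] - ter
    if np.any(td <= 0):
        return -np.inf
    v = theta - b[keep]
    return float(np.sum(_item_logdens(td, resp[keep], v, alpha, np.log(alpha))))


@dataclass
class PopulationParams:
    mu_theta: float
    sd_theta: float
    mu_logalpha: float
    sd_logalpha: float
    rho_theta_logalpha: float
    ter_policy: str = "occasion_min"
    ter_global: float | None = None


class DiffusionIRT:
    """D-diffusion IRT model for one valence's item block.

    Parameters
    ----------
    responses : (n_occasions, n_items) array
        Dichotomized responses in {0, 1}; NaN for missing.
    rts : (n_occasions, n_items) array
        Response times in seconds (already outlier-filtered); NaN missing.
    item_ids : sequence of str, optional
    occasion_index : optional index identifying occasions (e.g. a MultiIndex
        of person_id, occasion_id); carried through to the score table.
    ter_policy : {"occasion_min", "global"}
    ter_frac : float
        For "occasion_min": plug-in ter = ter_frac x min occasion RT.
    quadrature_nodes : int
        Gauss-Hermite nodes per latent dimension.
    """

    def __init__(self, responses, rts, item_ids=None, occasion_index=None,
                 ter_policy: str = "occasion_min", ter_frac: float = 0.95,
                 quadrature_nodes: int = 15):
        resp = np.asarray(responses, float)
        rt = np.asarray(rts, float)
        if resp.ndim != 2 or resp.shape != rt.shape:
            raise ValueError("responses and rts must be 2-d arrays of equal shape")
        if ter_policy not in ("occasion_min", "global"):
            raise ValueError(f"unknown ter_policy {ter_policy!r}")
        mask = ~(np.isnan(resp) | np.isnan(rt) | (rt <= 0))
        usable = mask.any(axis=1)
        if not usable.all():
            resp, rt, mask = resp[usable], rt[usable], mask[usable]
            if occasion_index is not None:
                occasion_index = pd.Index(occasion_index)[usable]
        vals = resp[mask]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("responses must be dichotomized to {0, 1}")
        self.n_dropped_occasions = int((~usable).sum())
        self.responses = resp
        self.rts = rt
        self.mask = mask
        self.nobs, self.n_items = resp.shape
        self.item_ids = list(item_ids) if item_ids is not None else [
            f"item_{j + 1}" for j in range(self.n_items)]
        self.occasion_index = occasion_index
        self.ter_policy = ter_policy
        self.ter_frac = ter_frac
        self.quadrature_nodes = int(quadrature_nodes)
        with np.errstate(all="ignore"):
            occ_min = np.nanmin(np.where(mask, rt, np.nan), axis=1)
        self._occ_min_rt = occ_min
        if ter_policy == "occasion_min":
            self.ter_ = ter_frac * occ_min
        else:
            self.ter_ = None  # estimated
        all_rts = rt[mask]
        self._rt_q01 = float(np.quantile(all_rts, 0.01))
        self._rt_min = float(all_rts.min())
        # items answered identically everywhere cannot pin down b freely
        means = np.array([resp[mask[:, j], j].mean() if mask[:, j].any() else np.nan
                          for j in range(self.n_items)])
        self._item_means = means
        self._degenerate_items = np.isin(means, (0.0, 1.0))
        if self._degenerate_items.any():
            warnings.warn("items with all-0 or all-1 responses; their "
                          "difficulties are fixed at +/-4 logits")
        nodes, weights = np.polynomial.hermite.hermgauss(self.quadrature_nodes)
        self._gh_z = nodes * np.sqrt(2.0)
        self._gh_logw = np.log(weights) - 0.5 * np.log(np.pi)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, valence: str,
                       response_col: str = "dichot", rt_col: str = "rt",
                       **kwargs) -> "DiffusionIRT":
        """Build from a long-format table (person_id, occasion_id, item_id,
        valence, dichotomized response, filtered RT in seconds)."""
        sub = df[df["valence"] == valence]
        if sub.empty:
            raise ValueError(f"no rows with valence {valence!r}")
        wide_r = sub.pivot_table(index=["person_id", "occasion_id"],
                                 columns="item_id", values=response_col,
                                 aggfunc="first")
        wide_t = sub.pivot_table(index=["person_id", "occasion_id"],
                                 columns="item_id", values=rt_col,
                                 aggfunc="first").reindex(columns=wide_r.columns)
        return cls(wide_r.to_numpy(float), wide_t.to_numpy(float),
                   item_ids=list(wide_r.columns),
                   occasion_index=wide_r.index, **kwargs)

    # -- parameter packing ------------------------------------------------

    @property
    def _free_items(self) -> np.ndarray:
        return ~self._degenerate_items

    def _unpack(self, params: np.ndarray):
        nf = int(self._free_items.sum())
        b = np.where(self._degenerate_items,
                     np.where(self._item_means == 1.0, -4.0, 4.0), 0.0)
        b[self._free_items] = params[:nf]
        k = nf
        sd_t = np.exp(params[k]); k += 1
        mu_la = params[k]; k += 1
        sd_la = np.exp(params[k]); k += 1
        rho = np.tanh(params[k]); k += 1
        ter_g = params[k] if self.ter_policy == "global" else None
        return b, sd_t, mu_la, sd_la, rho, ter_g

    def _pack(self, b, sd_t, mu_la, sd_la, rho, ter_g=None) -> np.ndarray:
        parts = [np.asarray(b, float)[self._free_items],
                 [np.log(sd_t), mu_la, np.log(sd_la), np.arctanh(rho)]]
        if self.ter_policy == "global":
            parts.append([ter_g])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    @property
    def k_params(self) -> int:
        return int(self._free_items.sum()) + 4 + (self.ter_policy == "global")

    def start_params(self) -> np.ndarray:
        """Moment-based starting values."""
        p = np.clip(self._item_means, 0.02, 0.98)
        alpha0 = 2.0
        b0 = -np.log(p / (1 - p)) / alpha0
        td0 = np.nanmean(np.where(self.mask, self.rts, np.nan)) - (
            np.nanmean(self.ter_) if self.ter_ is not None else self._rt_q01 * 0.8)
        A0 = 2.0 * np.sqrt(max(td0, 0.05))
        ter_g = min(self._rt_q01, 0.999 * self._rt_min) * 0.9 \
            if self.ter_policy == "global" else None
        return self._pack(b0, 1.0, np.log(max(A0, 0.5)), 0.3, 0.0, ter_g)

    # -- likelihood -------------------------------------------------------

    def _grid(self, sd_t, mu_la, sd_la, rho):
        z = self._gh_z
        z1 = np.repeat(z, z.size)
        z2 = np.tile(z, z.size)
        theta = sd_t * z1
        logalpha = mu_la + sd_la * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
        logw = (np.repeat(self._gh_logw, z.size)
                + np.tile(self._gh_logw, z.size))
        return theta, logalpha, logw

    def loglikeobs(self, params: np.ndarray) -> np.ndarray:
        """Per-occasion marginal log likelihood."""
        b, sd_t, mu_la, sd_la, rho, ter_g = self._unpack(params)
        theta, logalpha, logw = self._grid(sd_t, mu_la, sd_la, rho)
        A = np.exp(logalpha)                       # (N,)
        v = theta[:, None] - b[None, :]            # (N, I)
        ter = self.ter_ if ter_g is None else np.full(self.nobs, ter_g)
        td = self.rts - ter[:, None]               # (O, I)
        bad = self.mask & (td <= 0)
        if bad.any():
            return np.full(self.nobs, -np.inf)
        tds = np.where(self.mask, td, 1.0)
        resp = np.where(self.mask, self.responses, 0.0)
        sign = 1.0 - 2.0 * resp                    # (O, I)
        if _HAVE_NUMBA:
            return _ll_kernel(tds, sign, self.mask, v, A, logalpha, logw)
        # vectorized fallback: log f (O, I, N)
        tau = tds[:, :, None] / (A ** 2)[None, None, :]
        logf = (-2.0 * logalpha[None, None, :]
                - 0.5 * sign[:, :, None] * (v * A[:, None]).T[None, :, :]
                - 0.5 * (v ** 2).T[None, :, :] * tds[:, :, None]
                + _log_f1(tau))
        logf = np.where(self.mask[:, :, None], logf, 0.0)
        s = logf.sum(axis=1) + logw[None, :]       # (O, N)
        m = s.max(axis=1)
        ll = m + np.log(np.exp(s - m[:, None]).sum(axis=1))
        return ll

    def loglike(self, params: np.ndarray) -> float:
        return float(np.sum(self.loglikeobs(params)))

    # -- estimation -------------------------------------------------------

    def _coarse_copy(self, nodes: int) -> "DiffusionIRT":
        cp = DiffusionIRT.__new__(DiffusionIRT)
        cp.__dict__.update(self.__dict__)
        cp.quadrature_nodes = nodes
        gh, w = np.polynomial.hermite.hermgauss(nodes)
        cp._gh_z = gh * np.sqrt(2.0)
        cp._gh_logw = np.log(w) - 0.5 * np.log(np.pi)
        return cp

    def fit(self, start_params=None, n_starts: int = 3, maxiter: int = 300,
            gtol: float = 1e-5, seed: int = 0, jitter_scale: float = 0.3,
            explore_nodes: int = 7) -> "DiffusionIRTResults":
        """Marginal maximum likelihood by quasi-Newton (L-BFGS-B) on the
        transformed parameter space.

        Multi-start: short exploratory runs from ``n_starts`` jittered
        initializations on a coarse ``explore_nodes``-point grid, then a
        full polish from the best candidate at the model's resolution.
        """
        rng = np.random.default_rng(seed)
        x0 = self.start_params() if start_params is None else np.asarray(
            start_params, float)
        bounds = None
        if self.ter_policy == "global":
            hi = min(self._rt_q01, 0.999 * self._rt_min)
            bounds = [(None, None)] * (self.k_params - 1) + [(1e-4, hi)]

        def make_nll(model):
            def nll(x):
                with np.errstate(all="ignore"):
                    val = -model.loglike(x)
                return 1e12 if not np.isfinite(val) else val
            return nll

        coarse = self._coarse_copy(min(explore_nodes, self.quadrature_nodes))
        nll_coarse = make_nll(coarse)
        cand = None
        for s in range(max(1, n_starts)):
            xs = x0 if s == 0 else x0 + jitter_scale * rng.standard_normal(x0.size)
            if self.ter_policy == "global" and bounds is not None:
                xs[-1] = np.clip(xs[-1], 1e-4, bounds[-1][1])
            res = minimize(nll_coarse, xs, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 40, "gtol": gtol, "ftol": 1e-10})
            if cand is None or res.fun < cand.fun:
                cand = res
        best = minimize(make_nll(self), cand.x, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": maxiter, "gtol": gtol,
                                 "ftol": 1e-10})
        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
        converged = bool(best.success) or grad_norm < 1e-3
        if not converged:
            warnings.warn("diffusion IRT fit did not converge "
                          f"(status={best.status}, |grad|={grad_norm:.2e})")
        return DiffusionIRTResults(self, best.x, -best.fun, converged, grad_norm)


class DiffusionIRTResults:
    """Fitted D-diffusion IRT model: estimates, diagnostics, scoring."""

    def __init__(self, model: DiffusionIRT, params: np.ndarray, llf: float,
                 converged: bool, grad_norm: float):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = float(llf)
        self.converged = converged
        self.grad_norm = grad_norm
        (self.item_difficulties, self.sd_theta, self.mu_logalpha,
         self.sd_logalpha, self.rho, self.ter_global) = model._unpack(self.params)
        self.nobs = model.nobs

    # -- information criteria --------------------------------------------

    @property
    def aic(self) -> float:
        return 2 * self.model.k_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.model.k_params * np.log(self.nobs) - 2 * self.llf

    @property
    def population(self) -> PopulationParams:
        return PopulationParams(0.0, self.sd_theta, self.mu_logalpha,
                                self.sd_logalpha, self.rho,
                                self.model.ter_policy, self.ter_global)

    def item_table(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.model.item_ids,
                             "b": self.item_difficulties,
                             "a_item": 1.0,
                             "endorsement_rate": self.model._item_means})

    def summary(self) -> str:
        lines = [
            "D-diffusion IRT model (marginal ML, Gauss-Hermite "
            f"{self.model.quadrature_nodes}x{self.model.quadrature_nodes})",
            f"occasions: {self.nobs}   items: {self.model.n_items}   "
            f"ter policy: {self.model.ter_policy}",
            f"log-likelihood: {self.llf:.3f}   AIC: {self.aic:.1f}   "
            f"BIC: {self.bic:.1f}",
            f"converged: {self.converged}   |grad|: {self.grad_norm:.2e}",
            "",
            "item difficulties (logits):",
        ]
        for iid, b in zip(self.model.item_ids, self.item_difficulties):
            lines.append(f"  {iid:>16s}  b = {b: .3f}")
        lines += [
            "",
            f"sd(theta)      = {self.sd_theta:.3f}",
            f"mu(log alpha)  = {self.mu_logalpha:.3f}  "
            f"(alpha median {np.exp(self.mu_logalpha):.3f})",
            f"sd(log alpha)  = {self.sd_logalpha:.3f}",
            f"rho(theta, log alpha) = {self.rho:.3f}",
        ]
        if self.ter_global is not None:
            lines.append(f"ter (global)   = {self.ter_global:.3f} s")
        return "\n".join(lines)

    # -- scoring ----------------------------------------------------------

    def eap_scores(self, floor: float = 1e-6) -> pd.DataFrame:
        """Expected-a-posteriori occasion scores and clarity indicators.

        Posterior means of theta and alpha per occasion on the fitted
        quadrature grid, plus absolute drift (mean_i |theta_hat - b_i|) and
        its floored log.
        """
        m = self.model
        theta, logalpha, logw = m._grid(self.sd_theta, self.mu_logalpha,
                                        self.sd_logalpha, self.rho)
        A = np.exp(logalpha)
        v = theta[:, None] - self.item_difficulties[None, :]
        ter = (m.ter_ if self.ter_global is None
               else np.full(m.nobs, self.ter_global))
        td = np.where(m.mask, m.rts - ter[:, None], 1.0)
        resp = np.where(m.mask, m.responses, 0.0)
        sign = 1.0 - 2.0 * resp
        tau = td[:, :, None] / (A ** 2)[None, None, :]
        logf = (-2.0 * logalpha[None, None, :]
                - 0.5 * sign[:, :, None] * (v * A[:, None]).T[None, :, :]
                - 0.5 * (v ** 2).T[None, :, :] * td[:, :, None]
                + _log_f1(tau))
        logf = np.where(m.mask[:, :, None], logf, 0.0)
        s = logf.sum(axis=1) + logw[None, :]
        mmax = s.max(axis=1, keepdims=True)
        w = np.exp(s - mmax)
        w /= w.sum(axis=1, keepdims=True)
        theta_hat = w @ theta
        alpha_hat = w @ A
        ad, log_ad = absolute_drift(theta_hat, self.item_difficulties, floor)
        out = pd.DataFrame({"theta_hat": theta_hat, "alpha_hat": alpha_hat,
                            "ter": ter, "ad": ad, "log_ad": log_ad})
        if m.occasion_index is not None:
            out.index = m.occasion_index
            out = out.reset_index()
        return out

    def _posterior_node_weights(self):
        """Per-occasion posterior weights over the quadrature grid, plus the
        grid itself; used for posterior-predictive simulation."""
        m = self.model
        theta, logalpha, logw = m._grid(self.sd_theta, self.mu_logalpha,
                                        self.sd_logalpha, self.rho)
        A = np.exp(logalpha)
        v = theta[:, None] - self.item_difficulties[None, :]
        ter = (m.ter_ if self.ter_global is None
               else np.full(m.nobs, self.ter_global))
        td = np.where(m.mask, m.rts - ter[:, None], 1.0)
        resp = np.where(m.mask, m.responses, 0.0)
        sign = 1.0 - 2.0 * resp
        tau = td[:, :, None] / (A ** 2)[None, None, :]
        logf = (-2.0 * logalpha[None, None, :]
                - 0.5 * sign[:, :, None] * (v * A[:, None]).T[None, :, :]
                - 0.5 * (v ** 2).T[None, :, :] * td[:, :, None]
                + _log_f1(tau))
        logf = np.where(m.mask[:, :, None], logf, 0.0)
        s = logf.sum(axis=1) + logw[None, :]
        w = np.exp(s - s.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        return w, theta, A, ter

    def prior_eap(self):
        """EAP under the prior alone (a hypothetical all-missing occasion):
        the no-data posterior mean, equal to the population means."""
        theta, logalpha, logw = self.model._grid(
            self.sd_theta, self.mu_logalpha, self.sd_logalpha, self.rho)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float(w @ theta), float(w @ np.exp(logalpha))

    # -- diagnostics ------------------------------------------------------

    def predictive_rt_check(self, n_sim: int = 10_000, seed: int = 0,
                            quantiles=(0.10, 0.25, 0.50, 0.75, 0.90)) -> pd.DataFrame:
        """Observed-vs-simulated RT distribution check, per item.

        Posterior-predictive simulation: occasions are drawn with
        replacement, occasion latents are sampled from their posterior over
        the quadrature grid, and Wiener first passages are sampled at those
        latents (with the occasion's ter).  Reports the two-sample
        Kolmogorov-Smirnov distance and quantile tables per item.
        """
        if n_sim < 1000:
            warnings.warn("n_sim < 1000 gives a noisy predictive check")
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(seed)
        w, theta_grid, A_grid, ter_all = self._posterior_node_weights()
        cum_w = np.cumsum(w, axis=1)
        m = self.model
        rows = []
        for j, iid in enumerate(m.item_ids):
            obs = m.rts[m.mask[:, j], j]
            if obs.size == 0:
                continue
            idx = rng.integers(0, m.nobs, n_sim)
            u = rng.random(n_sim)
            node = (cum_w[idx] < u[:, None]).sum(axis=1).clip(0, w.shape[1] - 1)
            v = theta_grid[node] - self.item_difficulties[j]
            A = A_grid[node]
            ter = ter_all[idx]
            _, sim = sample_fpt(v, A, ter, rng)
            ks = ks_2samp(obs, sim).statistic
            row = {"item_id": iid, "ks_distance": float(ks),
                   "n_obs": int(obs.size), "n_sim": int(n_sim)}
            for q in quantiles:
                row[f"obs_q{int(q * 100)}"] = float(np.quantile(obs, q))
                row[f"sim_q{int(q * 100)}"] = float(np.quantile(sim, q))
            rows.append(row)
        return pd.DataFrame(rows)
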