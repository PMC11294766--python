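"""Wiener (drift-diffusion) first-passage-time machinery.

The two-boundary Wiener process with unit diffusion underlies both the
synthetic response-time generator and the D-diffusion IRT likelihood.  A
decision starts midway between two absorbing boundaries separated by ``A``
(the response-caution / boundary-separation parameter) and accumulates
evidence with drift ``v = theta - b`` until one boundary is reached; the
response time is the first-passage time plus a non-decision offset ``ter``.

With an unbiased start the probability of absorbing at the upper boundary is
logistic in ``A * v``, which is exactly the D-diffusion IRT choice model:

    P(upper) = 1 / (1 + exp(-(alpha / a_item) * (theta - b)))

Densities use the classical dual series representation of the first-passage
density (a short-time expansion in Gaussian images and a long-time
eigenfunction expansion), switching representation at a fixed normalized
time so that the truncation error of either series is below 1e-10.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "choice_probability",
    "fpt_density",
    "sample_fpt",
    "simulate_item_trial",
]

# Series truncation.  At the switch point TAU_SWITCH the dropped terms of
# either representation are < 1e-10 of the density scale, so the two
# branches agree to ~1e-10 and the density is continuous across the switch.
_TAU_SWITCH = 0.35
_K_SMALL = 4          # short-time image terms k = -K..K
_K_LARGE = 7          # long-time eigenfunction terms k = 1..K
SERIES_EPS = 1e-10


def _validate_boundary(alpha, a_item) -> float:
    alpha = float(alpha)
    a_item = float(a_item)
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"boundary separation alpha must be positive, got {alpha}")
    if not np.isfinite(a_item) or a_item <= 0:
        raise ValueError(f"item boundary weight a_item must be positive, got {a_item}")
    return alpha / a_item


def choice_probability(theta, b, alpha, a_item: float = 1.0):
    """Probability of endorsing the item (absorbing at the upper boundary).

    Parameters
    ----------
    theta : array_like
        Occasion drift level (logits).
    b : array_like
        Item difficulty (logits).
    alpha : float
        Boundary separation (> 0); response caution.
    a_item : float
        Item boundary weight (> 0, default 1); effective separation is
        ``alpha / a_item``.
    """
    A = _validate_boundary(alpha, a_item)
    return expit(A * (np.asarray(theta, float) - np.asarray(b, float)))


def _f1(tau: np.ndarray, w: float = 0.5) -> np.ndarray:
    """Normalized first-passage density at the lower boundary.

    Density of tau = T / A**2 for a zero-drift unit process on (0, 1)
    started at ``w``; drift and scale are reattached by the callers.
    """
    tau = np.asarray(tau, float)
    out = np.zeros_like(tau)
    pos = tau > 0
    small = pos & (tau <= _TAU_SWITCH)
    large = pos & ~small
    if np.any(small):
        ts = tau[small][..., None]
        k = np.arange(-_K_SMALL, _K_SMALL + 1, dtype=float)
        wk = w + 2.0 * k
        s = np.sum(wk * np.exp(-(wk ** 2) / (2.0 * ts)), axis=-1)
        out[small] = s / np.sqrt(2.0 * np.pi) / tau[small] ** 1.5
    if np.any(large):
        tl = tau[large][..., None]
        k = np.arange(1, _K_LARGE + 1, dtype=float)
        s = np.sum(
            k * np.sin(k * np.pi * w) * np.exp(-(k ** 2) * np.pi ** 2 * tl / 2.0),
            axis=-1,
        )
        out[large] = np.pi * s
    return np.clip(out, 0.0, None)


def fpt_density(t, theta, b, alpha, a_item: float = 1.0, ter: float = 0.0,
                boundary: str = "upper"):
    """Defective first-passage-time density of the decision process.

    Integrates (over t) to ``choice_probability`` for the upper boundary and
    to its complement for the lower one.  Zero for ``t <= ter``.

    Parameters
    ----------
    t : array_like
        Response times in seconds.
    boundary : {"upper", "lower"}
        Which absorbing boundary the observed response corresponds to
        (upper = endorsement / coded 1).
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    A = _validate_boundary(alpha, a_item)
    theta = float(theta)
    b = float(b)
    ter = float(ter)
    if not (np.isfinite(theta) and np.isfinite(b) and np.isfinite(ter)):
        raise ValueError("non-finite diffusion parameters")
    v = theta - b
    if boundary == "upper":
        v = -v  # upper-boundary density = lower-boundary density under reflection
    t = np.asarray(t, float)
    td = t - ter
    tau = np.where(td > 0, td, np.nan) / A ** 2
    with np.errstate(invalid="ignore", over="ignore", under="ignore"):
        dens = (1.0 / A ** 2) * np.exp(-0.5 * v * A - 0.5 * v ** 2 * np.where(td > 0, td, 0.0)) \
            * _f1(np.nan_to_num(tau, nan=-1.0))
    return np.where(td > 0, dens, 0.0)


# ---------------------------------------------------------------------------
# Fast inverse-CDF sampling, used by the bulk synthetic generator.
# In normalized time tau = T / A**2 the conditional first-passage density
# given the absorbing boundary depends on the parameters only through
# mu = A * v, so one fixed tau grid serves every trial.
# ---------------------------------------------------------------------------

_TAU_GRID = np.geomspace(1e-4, 25.0, 512)


def sample_fpt(v, A, ter, rng: np.random.Generator, chunk: int = 20000):
    """Draw (choice, rt) for many independent trials.

    Parameters
    ----------
    v, A, ter : array_like, broadcastable to a common 1-d shape
        Drift (theta - b), boundary separation, non-decision time per trial.
    rng : numpy Generator

    Returns
    -------
    choice : int array in {0, 1}
    rt : float array, seconds (ter + first-passage time)
    """
    v, A, ter = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(A, float), np.asarray(ter, float))
    if np.any(A <= 0):
        raise ValueError("boundary separation must be positive")
    if np.any(ter < 0):
        raise ValueError("non-decision time must be non-negative")
    n = v.size
    v = v.ravel()
    Af = A.ravel()
    terf = ter.ravel()
    mu = Af * v
    p_up = expit(mu)
    choice = (rng.random(n) < p_up).astype(np.int64)
    # signed drift in tau units for the chosen boundary (reflection for upper)
    mu_abs2 = mu ** 2
    tau_out = np.empty(n)
    u = rng.random(n)
    grid = _TAU_GRID
    f1g = _f1(grid)  # shared zero-drift factor
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m2 = mu_abs2[lo:hi, None]
        g = np.exp(-0.5 * m2 * grid[None, :]) * f1g[None, :]
        cdf = np.concatenate(
            [np.zeros((hi - lo, 1)),
             np.cumsum(0.5 * (g[:, 1:] + g[:, :-1]) * np.diff(grid)[None, :], axis=1)],
            axis=1,
        )
        tot = cdf[:, -1:]
        tot[tot <= 0] = 1.0
        cdf /= tot
        uu = u[lo:hi, None]
        idx = np.sum(cdf < uu, axis=1)
        idx = np.clip(idx, 1, grid.size - 1)
        c0 = np.take_along_axis(cdf, (idx - 1)[:, None], axis=1).ravel()
        c1 = np.take_along_axis(cdf, idx[:, None], axis=1).ravel()
        frac = np.where(c1 > c0, (u[lo:hi] - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
        tau_out[lo:hi] = grid[idx - 1] + frac * (grid[idx] - grid[idx - 1])
    rt = terf + Af ** 2 * tau_out
    return choice.reshape(A.shape), rt.reshape(A.shape)


# ---------------------------------------------------------------------------
# Euler-Maruyama random-walk simulation: the slow, code-independent oracle.
# ---------------------------------------------------------------------------

try:  # pragma: no cover - import guard exercised implicitly
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False)(f)
except Exception:  # pragma: no cover
    def _jit(f):
        return f


@_jit
def _euler_walk(n, v, A, dt, seed, t_max):
    choices = np.empty(n, np.int64)
    times = np.empty(n, np.float64)
    np.random.seed(seed)
    sq = np.sqrt(dt)
    for i in range(n):
        x = 0.5 * A
        t = 0.0
        while 0.0 < x < A and t < t_max:
            x += v * dt + sq * np.random.randn()
            t += dt
        choices[i] = 1 if x >= A else 0
        times[i] = t
    return choices, times


def euler_fpt(n: int, v: float, A: float, seed: int, dt: float = 1e-4,
              t_max: float = 60.0):
    """Euler-discretized random-walk draws of (choice, first-passage time).

    Deliberately independent of the series density code; serves as the
    Monte-Carlo oracle in tests and diagnostics.
    """
    if A <= 0:
        raise ValueError("boundary separation must be positive")
    return _euler_walk(int(n), float(v), float(A), float(dt), int(seed), float(t_max))


def simulate_item_trial(theta, b, alpha, ter, seed, a_item: float = 1.0,
                        dt: float = 1e-4):
    """Simulate a single item response by Euler-Maruyama random walk.

    Returns ``(choice, rt)`` with ``choice = 1`` for endorsement and
    ``rt > ter`` in seconds.
    """
    A = _validate_boundary(alpha, a_item)
    ter = float(ter)
    if ter < 0:
        raise ValueError("non-decision time must be non-negative")
    c, t = _euler_walk(1, float(theta) - float(b), A, float(dt), int(seed), 60.0)
    return int(c[0]), ter + float(t[0])
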