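"""Deterministic multivariate-normal rectangle probabilities (small dimension).

Used for the omnibus p-value, which needs P(min_j Y_j <= q) for Y ~ N(0, R)
with R the 6x6 (or smaller) null correlation of the inverse-normal-transformed
component statistics.  The integrator is the Genz separation-of-variables
transform evaluated on a randomly shifted rank-1 lattice whose shifts come
from a fixed internal seed, so repeated calls are bit-identical.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["mvn_lower_tail", "bivariate_lower_tail_log"]

_PRIMES = np.array([2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37], dtype=float)


def _ndtri_clipped(p):
    return special.ndtri(np.clip(p, 1e-300, 1.0 - 1e-16))


def mvn_lower_tail(upper, corr, n_points: int = 4096, n_shifts: int = 12,
                   seed: int = 20240401) -> float:
    """P(Y_1 <= b_1, ..., Y_d <= b_d) for Y ~ N(0, corr).

    Deterministic: the quasi-Monte-Carlo shifts are drawn from ``seed``.
    Absolute accuracy is typically well below 1e-6 for d <= 6.
    """
    b = np.asarray(upper, dtype=float).ravel()
    R = np.asarray(corr, dtype=float)
    d = b.size
    if R.shape != (d, d):
        raise ValueError(f"corr shape {R.shape} does not match {d} limits")
    if d == 1:
        return float(special.ndtr(b[0]))
    # sort limits ascending: integrating the tightest constraint first
    # reduces the variance of the Genz estimator
    order = np.argsort(b)
    b = b[order]
    R = R[np.ix_(order, order)]
    # Cholesky with a tiny jitter fallback for near-singular calibrations
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(R + 1e-10 * np.eye(d))

    rng = np.random.default_rng(seed)
    # Richtmyer lattice: fractional parts of k * sqrt(primes)
    z = np.sqrt(_PRIMES[: d - 1])
    k = np.arange(1, n_points + 1)[:, None]
    base = k * z[None, :]

    e1 = special.ndtr(b[0] / L[0, 0])
    estimates = np.empty(n_shifts)
    for s in range(n_shifts):
        shift = rng.random(d - 1)
        wpts = np.abs(2.0 * np.mod(base + shift[None, :], 1.0) - 1.0)  # baker transform
        f = np.full(n_points, e1)
        y = np.empty((n_points, d - 1))
        e_prev = np.full(n_points, e1)
        for i in range(1, d):
            y[:, i - 1] = _ndtri_clipped(e_prev * wpts[:, i - 1])
            mean = y[:, :i] @ L[i, :i]
            e_i = special.ndtr((b[i] - mean) / L[i, i])
            f *= e_i
            e_prev = e_i
        estimates[s] = f.mean()
    return float(min(max(estimates.mean(), 0.0), 1.0))


def bivariate_lower_tail_log(q: float, rho: float, n_grid: int = 4001) -> float:
    """log P(Y1 <= q, Y2 <= q) for standard bivariate normal, stable at any depth.

    Computed as log of the 1-D integral of phi(y) * Phi((q - rho y)/sqrt(1-rho^2))
    over y <= q, done entirely in log space so that q as deep as -38 (p ~ 1e-300)
    does not underflow.
    """
    if rho >= 1.0 - 1e-12:
        return float(special.log_ndtr(q))
    if rho <= -1.0 + 1e-12:
        return -np.inf if q < 0 else float(np.log(max(2 * special.ndtr(q) - 1.0, 0.0)))
    s = np.sqrt(1.0 - rho * rho)
    # integration range: the integrand's log decays quadratically below q
    width = 40.0
    y = np.linspace(q - width, q, n_grid)
    log_f = -0.5 * y * y - 0.5 * np.log(2 * np.pi) + special.log_ndtr((q - rho * y) / s)
    dy = y[1] - y[0]
    m = log_f.max()
    if not np.isfinite(m):
        return -np.inf
    trapz = np.exp(log_f - m)
    trapz[0] *= 0.5
    trapz[-1] *= 0.5
    return float(m + np.log(trapz.sum() * dy))
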