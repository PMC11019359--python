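"""Distribution of positively weighted sums of independent chi-square(1) variables.

The quadratic PC-combination statistics (WI and VC) are, under the null,
distributed as Q = sum_j w_j * X_j with X_j ~ chi2(1) i.i.d. and weights given
by the module eigenvalues (or their squares).  No closed form exists for
general weights, so the survival function is computed by:

* one weight          -> scaled chi2(1), exact;
* all weights equal   -> scaled chi2(m), exact;
* two weights         -> integration of the closed-form Bessel-I0 density;
* three or more       -> Imhof's characteristic-function inversion, evaluated
                         by summing Gauss-Legendre panels sized to the local
                         oscillation of the integrand;
* far tail            -> Lugannani-Rice saddlepoint approximation.

Vectorised evaluation goes through a monotone interpolant of log-sf built on
a per-instance grid, so scans and Monte-Carlo calibrations pay the
quadrature cost once per eigenvalue profile.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = ["WeightedChi2"]

# weights contributing less than this fraction of the total mean are dropped;
# they shift quantiles by a comparable relative amount only
_WEIGHT_DROP = 1e-10

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


def _imhof_sf(x: float, w: np.ndarray, abs_tol: float = 1e-12,
              max_panels: int = 400_000) -> float:
    """Imhof (1961) inversion for P(Q > x), three or more weights.

    The integrand sin(theta(u)) / (u * rho(u)) oscillates with local phase
    rate |theta'(u)| <= (sum w + x) / 2; panels of length pi over that bound
    are resolved exactly enough by 12-point Gauss-Legendre.  Contributions
    alternate in sign once the envelope decays, so the sum is stopped when a
    run of panels is below tolerance.
    """
    sw = float(np.sum(w))
    panel = np.pi / (0.5 * max(sw, x, 1e-3))
    total = 0.0
    u0 = 0.0
    batch = 256
    small_run = 0
    for _ in range(max_panels // batch):
        # nodes for `batch` consecutive panels at once
        starts = u0 + panel * np.arange(batch)[:, None]
        u = starts + (0.5 * panel) * (_GL_NODES[None, :] + 1.0)
        lu = w[:, None, None] * u[None, :, :]
        theta = 0.5 * np.arctan(lu).sum(axis=0) - 0.5 * x * u
        log_rho = 0.25 * np.log1p(lu * lu).sum(axis=0)
        f = np.sin(theta) / u * np.exp(-log_rho)
        contrib = (0.5 * panel) * (f @ _GL_WEIGHTS)
        total += contrib.sum()
        u0 += panel * batch
        small = np.abs(contrib) < abs_tol
        # stop once the last panels of the batch are all negligible
        tail_run = 0
        for c in small[::-1]:
            if not c:
                break
            tail_run += 1
        small_run = small_run + tail_run if tail_run == batch else tail_run
        if small_run >= 8:
            break
    return 0.5 + total / np.pi


def _two_weight_sf(x: float, w1: float, w2: float) -> float:
    """Closed-form density of w1*chi2(1) + w2*chi2(1) integrated numerically.

    f(q) = i0e(b q) * exp(-q / (2 max(w))) / (2 sqrt(w1 w2)),
    b = |w1 - w2| / (4 w1 w2); smooth and positive, so adaptive quadrature
    on [x, inf) is stable at any tail depth representable in float64.
    """
    b = abs(w1 - w2) / (4.0 * w1 * w2)
    c = 1.0 / (2.0 * max(w1, w2))
    norm = 1.0 / (2.0 * np.sqrt(w1 * w2))

    def pdf(q):
        return norm * special.i0e(b * q) * np.exp(-c * q)

    val, _ = integrate.quad(pdf, x, np.inf, limit=200)
    return val


class WeightedChi2:
    """Null distribution of Q = sum_j w_j chi2(1) for fixed positive weights."""

    def __init__(self, weights, grid_points: int = 200):
        w = np.asarray(weights, dtype=float).ravel()
        if w.size == 0 or np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be a non-empty array of finite non-negative values")
        total = w.sum()
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        w = w[w > _WEIGHT_DROP * total]
        self.weights = np.sort(w)[::-1]
        self._mean = self.weights.sum()
        self._var = 2.0 * np.sum(self.weights ** 2)
        self._equal = np.allclose(self.weights, self.weights[0], rtol=1e-12)
        self._grid_points = grid_points
        self._interp = None
        self._x_hi = None

    # -- exact-ish scalar evaluations ------------------------------------

    def _saddlepoint_sf(self, x: float) -> float:
        """Lugannani-Rice tail approximation; used beyond the grid."""
        w = self.weights
        if x <= self._mean:
            return 1.0  # only called in the far right tail
        hi = 1.0 / (2.0 * w[0])

        def kprime_minus_x(t):
            return np.sum(w / (1.0 - 2.0 * t * w)) - x

        t = brentq(kprime_minus_x, 0.0, hi * (1.0 - 1e-12), xtol=1e-14)
        r = 1.0 - 2.0 * t * w
        K = -0.5 * np.sum(np.log(r))
        K2 = 2.0 * np.sum(w ** 2 / r ** 2)
        wstat = np.sqrt(max(2.0 * (t * x - K), 0.0))
        v = t * np.sqrt(K2)
        base = float(special.ndtr(-wstat))
        # near the mean both w and v vanish and the expansion is singular;
        # the normal term alone is adequate there (only the far tail matters)
        if wstat < 0.05 or v < 0.05:
            return base
        phi = np.exp(-0.5 * wstat * wstat) / np.sqrt(2 * np.pi)
        first = phi * (1.0 / v - 1.0 / wstat)
        # Daniels' second-order correction (standardised cumulants at t)
        k3 = 8.0 * np.sum(w ** 3 / r ** 3) / K2 ** 1.5
        k4 = 48.0 * np.sum(w ** 4 / r ** 4) / K2 ** 2
        second = phi * ((k4 / 8.0 - 5.0 * k3 ** 2 / 24.0) / v
                        - 1.0 / v ** 3 - k3 / (2.0 * v ** 2) + 1.0 / wstat ** 3)
        if abs(second) > 0.5 * abs(base + first):
            second = 0.0  # outside the expansion's trust region
        return float(min(max(base + first + second, 0.0), 1.0))

    def sf_exact(self, x: float) -> float:
        """High-accuracy survival function at a single point."""
        x = float(x)
        if x <= 0.0:
            return 1.0
        w = self.weights
        m = w.size
        if m == 1 or self._equal:
            return float(chi2.sf(x / w[0], df=m))
        # deep tail: the inversion integral is tolerance-limited there, the
        # second-order saddlepoint holds ~0.7% relative accuracy
        sp = self._saddlepoint_sf(x)
        if m > 2 and sp < 1e-10:
            return sp
        if m == 2:
            return _two_weight_sf(x, w[0], w[1])
        val = _imhof_sf(x, w, abs_tol=max(1e-15, min(1e-10, 1e-8 * sp)))
        if not np.isfinite(val) or val <= 0.0 or val > 1.0:
            return min(max(sp, 0.0), 1.0)
        return min(val, 1.0)

    # -- vectorised path via monotone grid interpolation ------------------

    def _build_grid(self):
        w = self.weights
        # right edge: sf ~ 1e-13 by saddlepoint bisection
        lo, hi = self._mean, self._mean + 40.0 * np.sqrt(self._var) + 60.0 * w[0]
        while self._saddlepoint_sf(hi) > 1e-13:
            hi *= 2.0
        x_hi = brentq(lambda x: np.log(max(self._saddlepoint_sf(x), 1e-300)) + 13 * np.log(10),
                      lo, hi, xtol=1e-6 * hi)
        # dense near zero (sf ~ 1), stretched into the tail
        n = self._grid_points
        frac = np.sin(np.linspace(0.0, np.pi / 2, n)) ** 2  # clustered at both ends
        xs = np.unique(np.concatenate([[0.0], x_hi * frac, [x_hi]]))
        log_sf = np.empty_like(xs)
        log_sf[0] = 0.0
        for i, x in enumerate(xs[1:], start=1):
            v = self.sf_exact(float(x))
            log_sf[i] = np.log(max(v, 1e-300))
        # enforce strict monotonicity for the pchip fit
        log_sf = np.minimum.accumulate(log_sf)
        for i in range(1, log_sf.size):
            if log_sf[i] >= log_sf[i - 1]:
                log_sf[i] = log_sf[i - 1] - 1e-12
        self._interp = PchipInterpolator(xs, log_sf, extrapolate=False)
        self._x_hi = x_hi

    def sf(self, x):
        """Survival function, vectorised (interpolated to ~1e-6 relative)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if self.weights.size == 1 or self._equal:
            out = chi2.sf(x / self.weights[0], df=self.weights.size)
            return float(out[0]) if scalar else out
        if self._interp is None:
            self._build_grid()
        out = np.ones_like(x)
        inside = (x > 0) & (x <= self._x_hi)
        out[inside] = np.exp(self._interp(x[inside]))
        beyond = x > self._x_hi
        if np.any(beyond):
            out[beyond] = [self._saddlepoint_sf(float(v)) for v in x[beyond]]
        return float(out[0]) if scalar else out
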