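"""Sine circle map: winding numbers, mode-locking plateaus, Devil's staircase.

The map is ``theta[n+1] = theta[n] + omega + (k / 2*pi) * sin(2*pi*theta[n])``,
iterated on the real line (the lift, no reduction mod 1). ``omega`` is the
bare winding number; the dressed winding number ``w`` is the mean phase
advance per step after a transient. At the critical coupling ``k = 1`` the
plateaus of ``w(omega)`` at rational values cover the whole interval and
form a Devil's staircase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import pearsonr

from tonerec.curves import StaircaseCurve

__all__ = [
    "CircleMapParams",
    "WindingResult",
    "StaircaseComparison",
    "iterate_map",
    "winding_number",
    "devils_staircase",
    "plateau_width",
    "compare_staircases",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class CircleMapParams:
    omega: float
    k: float = 1.0
    theta0: float = 0.2
    n_transient: int = 1000
    n_iter: int = 10000

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("coupling strength k must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.n_transient < 0:
            raise ValueError("n_transient must be >= 0")


@dataclass(frozen=True)
class WindingResult:
    w: float
    converged: bool
    residual: float


def iterate_map(params: CircleMapParams) -> np.ndarray:
    """Phase trajectory on the lift, ``n_transient + n_iter + 1`` values."""
    n_total = params.n_transient + params.n_iter
    theta = np.empty(n_total + 1)
    theta[0] = params.theta0
    t = params.theta0
    omega = params.omega
    coupling = params.k / TWO_PI
    for j in range(n_total):
        t = t + omega + coupling * math.sin(TWO_PI * t)
        theta[j + 1] = t
    return theta


def winding_number(params: CircleMapParams) -> WindingResult:
    """Dressed winding number: mean phase advance per step after the transient.

    The residual compares the estimate over the full counted stretch with
    the estimate over its second half; on a mode-locked plateau it decays
    to the rounding level.
    """
    theta = iterate_map(params)
    t0 = params.n_transient
    w = (theta[-1] - theta[t0]) / params.n_iter
    mid = t0 + params.n_iter // 2
    w_half = (theta[-1] - theta[mid]) / (len(theta) - 1 - mid)
    residual = abs(w - w_half)
    return WindingResult(w=float(w), converged=residual < 1e-6, residual=float(residual))


def devils_staircase(
    k: float,
    omega_grid: np.ndarray,
    theta0: float = 0.2,
    n_transient: int = 1000,
    n_iter: int = 10000,
) -> StaircaseCurve:
    """Dressed winding number over an ascending grid of bare winding numbers.

    All grid points are iterated simultaneously (the map is elementwise),
    so the cost is ``O(grid * iterations)`` vectorized.
    """
    omega = np.asarray(omega_grid, dtype=float)
    if omega.ndim != 1 or len(omega) < 2:
        raise ValueError("omega_grid must be a 1-D array with >= 2 points")
    if np.any(np.diff(omega) <= 0):
        raise ValueError("omega_grid must be strictly ascending")
    coupling = k / TWO_PI
    theta = np.full_like(omega, theta0)
    for _ in range(n_transient):
        theta = theta + omega + coupling * np.sin(TWO_PI * theta)
    start = theta.copy()
    for _ in range(n_iter):
        theta = theta + omega + coupling * np.sin(TWO_PI * theta)
    w = (theta - start) / n_iter
    return StaircaseCurve(omega, w, x_label="omega", y_label="w")


def _is_locked(omega: float, p: int, q: int, k: float, tol: float,
               theta0: float = 0.2, max_transient: int = 12000,
               block: int = 3000) -> bool:
    """Locked onto p/q iff the q-step phase advance settles to exactly p.

    The transient is adaptive: the residual is checked after each block of
    iterations, so deep inside a plateau (fast exponential convergence) the
    test exits early while quasiperiodic points run to ``max_transient``.
    """
    t = theta0
    coupling = k / TWO_PI
    done = 0
    while done < max_transient:
        for _ in range(block):
            t = t + omega + coupling * math.sin(TWO_PI * t)
        done += block
        start = t
        for _ in range(q):
            t = t + omega + coupling * math.sin(TWO_PI * t)
        if abs(t - start - p) < tol:
            return True
    return False


def _classify(omega: float, p: int, q: int, k: float, tol: float,
              theta0: float = 0.2, n_estimate: int = 20000) -> int:
    """-1 / 0 / +1: dressed winding below, locked onto, or above ``p/q``."""
    if _is_locked(omega, p, q, k, tol, theta0=theta0):
        return 0
    coupling = k / TWO_PI
    t = theta0
    for _ in range(3000):
        t = t + omega + coupling * math.sin(TWO_PI * t)
    start = t
    for _ in range(n_estimate):
        t = t + omega + coupling * math.sin(TWO_PI * t)
    w_est = (t - start) / n_estimate
    return -1 if w_est < p / q else 1


def plateau_width(p: int, q: int, k: float, tol: float = 1e-6) -> float:
    """Width of the bare-winding interval locked onto ``w = p/q``.

    Because ``w(omega)`` is non-decreasing, the plateau is the boundary
    layer between ``{w < p/q}`` and ``{w > p/q}``; each edge is found by
    global bisection over [0, 1] on a three-way classifier (below / locked /
    above), with the locked state decided by the q-step phase-advance test
    of :func:`_is_locked`. A zero-measure crossing (e.g. any rational at
    ``k = 0``) collapses both edges to the same point and the width is ~0.
    """
    if q < 1 or p < 0:
        raise ValueError("need q >= 1 and p >= 0")
    if math.gcd(p, q) != 1:
        raise ValueError(f"{p}/{q} is not a reduced fraction")
    if not 0 <= p / q <= 1:
        raise ValueError("p/q must lie in [0, 1]")

    def classify(om: float) -> int:
        return _classify(om, p, q, k, tol)

    n_halvings = 45

    # left edge: smallest omega with classify >= 0
    lo, hi = 0.0, 1.0
    if classify(lo) >= 0:
        left = lo
    else:
        for _ in range(n_halvings):
            mid = 0.5 * (lo + hi)
            if classify(mid) >= 0:
                hi = mid
            else:
                lo = mid
        left = hi
    # right edge: largest omega with classify <= 0
    lo, hi = 0.0, 1.0
    if classify(hi) <= 0:
        right = hi
    else:
        for _ in range(n_halvings):
            mid = 0.5 * (lo + hi)
            if classify(mid) <= 0:
                lo = mid
            else:
                hi = mid
        right = lo
    return max(right - left, 0.0)


@dataclass(frozen=True)
class StaircaseComparison:
    sup_norm: float
    pearson_r: float
    pearson_r_swapped: float
    n_grid: int


def compare_staircases(
    empirical: StaircaseCurve,
    theoretical: StaircaseCurve,
    n_grid: int = 512,
) -> StaircaseComparison:
    """Similarity of two staircases after normalizing both to the unit square.

    Both curves are min-max normalized and resampled onto a common uniform
    grid; the report carries the sup-norm difference and the Pearson
    correlation of the resampled ordinates. Because the natural orientation
    of the empirical curve is ambiguous (either axis can play the control
    role), the correlation with the empirical axes swapped is reported too.
    """
    a = empirical.normalized()
    b = theoretical.normalized()
    grid = np.linspace(0.0, 1.0, n_grid)
    ya = a.resample(grid)
    yb = b.resample(grid)
    sup = float(np.max(np.abs(ya - yb)))
    r = float(pearsonr(ya, yb).statistic)
    swapped = StaircaseCurve(np.sort(a.y), a.x[np.argsort(a.y, kind="stable")])
    ys = swapped.resample(grid)
    r_swapped = float(pearsonr(ys, yb).statistic)
    return StaircaseComparison(
        sup_norm=sup, pearson_r=r, pearson_r_swapped=r_swapped, n_grid=n_grid
    )


def mirror_params(params: CircleMapParams, omega: float) -> CircleMapParams:
    """Convenience: same map parameters at a different bare winding number."""
    return replace(params, omega=omega)
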