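"""From-scratch recurrence quantification.

Delay embedding, Euclidean distance matrix, radius selection, recurrence
plot / percent recurrence, and lag selection by the first minimum of the
average mutual information.

Recurrence of a pair of epochs is defined by strict inequality
``distance < radius``; the denominator of percent recurrence is the number
of distinct off-diagonal epoch pairs ``N_e * (N_e - 1) / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "EmbeddingMatrix",
    "DistanceMatrix",
    "RecurrenceConfig",
    "RecurrenceResult",
    "AMIResult",
    "RADIUS_POLICIES",
    "embed",
    "pairwise_distances",
    "select_radius",
    "recurrence",
    "ami_first_minimum",
]

RADIUS_POLICIES = (
    "fraction_of_mean_distance",
    "gaussian_percentile",
    "empirical_percentile",
    "absolute",
)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Delay-embedded trajectory; row ``i`` is ``(x[i], x[i+L], ..., x[i+(m-1)L])``."""

    rows: np.ndarray
    m: int
    L: int
    source_length: int

    @property
    def n_epochs(self) -> int:
        return self.rows.shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of Euclidean distances between embedded epochs."""

    values: np.ndarray
    metric: str = "euclidean"

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """The strictly-below-diagonal entries, one per unordered pair."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class RecurrenceConfig:
    m: int = 5
    L: int = 3
    radius_policy: str = "fraction_of_mean_distance"
    radius_parameter: float = 0.1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.L < 1:
            raise ValueError("lag L must be >= 1")
        if self.radius_policy not in RADIUS_POLICIES:
            raise ValueError(
                f"unknown radius policy {self.radius_policy!r}; "
                f"choose from {RADIUS_POLICIES}"
            )
        if self.radius_parameter <= 0 and self.radius_policy != "empirical_percentile":
            raise ValueError("radius_parameter must be positive")


@dataclass(frozen=True)
class RecurrenceResult:
    radius: float
    recurrence_count: int
    pair_count: int
    recurrence_plot: np.ndarray

    @property
    def recurrence_rate(self) -> float:
        return self.recurrence_count / self.pair_count

    @property
    def percent_recurrence(self) -> float:
        return 100.0 * self.recurrence_count / self.pair_count


@dataclass(frozen=True)
class AMIResult:
    lag: int
    no_minimum: bool
    mi_values: np.ndarray  # mi_values[k] = I(x_t; x_{t+k}), k = 0..max_lag


def embed(series: Sequence[float], m: int, L: int) -> EmbeddingMatrix:
    """Delay-embed a scalar series into ``N - (m-1)*L`` epochs of dimension ``m``."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if m < 1 or L < 1:
        raise ValueError("m and L must be >= 1")
    n = len(x)
    required = (m - 1) * L + 1
    if n < required:
        raise ValueError(
            f"series of length {n} too short for m={m}, L={L}: "
            f"needs at least {required} samples"
        )
    span = (m - 1) * L + 1
    rows = np.lib.stride_tricks.sliding_window_view(x, span)[:, ::L].copy()
    return EmbeddingMatrix(rows=rows, m=m, L=L, source_length=n)


def pairwise_distances(embedding: EmbeddingMatrix) -> DistanceMatrix:
    """Euclidean distances between all epoch pairs."""
    if embedding.n_epochs < 2:
        raise ValueError("need at least 2 epochs to form a distance matrix")
    return DistanceMatrix(squareform(pdist(embedding.rows, metric="euclidean")))


def select_radius(
    distances: DistanceMatrix | np.ndarray, policy: str, parameter: float
) -> float:
    """Compute a recurrence radius from the off-diagonal distance distribution.

    Policies:

    ``fraction_of_mean_distance``
        ``parameter * mean(d)`` — e.g. 0.1 for the common 10%-of-mean rule.
    ``gaussian_percentile``
        ``mean(d) - z(parameter) * sd(d)`` with a one-sided normal quantile
        (``parameter = 0.05`` keeps roughly the smallest 5% of distances
        under a Gaussian model); the SD uses divisor ``n`` (population).
    ``empirical_percentile``
        the ``parameter``-quantile (0..1, linear interpolation) of the
        distances themselves.
    ``absolute``
        ``parameter`` as-is.
    """
    if isinstance(distances, DistanceMatrix):
        d = distances.condensed()
    else:
        d = np.asarray(distances, dtype=float)
        if d.ndim == 2:
            d = squareform(d, checks=False)
    if policy == "fraction_of_mean_distance":
        if parameter <= 0:
            raise ValueError("fraction must be positive")
        return float(parameter * d.mean())
    if policy == "gaussian_percentile":
        if not 0 < parameter < 1:
            raise ValueError("gaussian percentile must be in (0, 1)")
        z = norm.ppf(1.0 - parameter)
        return float(d.mean() - z * d.std())
    if policy == "empirical_percentile":
        if not 0 <= parameter <= 1:
            raise ValueError("empirical percentile must be in [0, 1]")
        return float(np.quantile(d, parameter))
    if policy == "absolute":
        if parameter <= 0:
            raise ValueError("absolute radius must be positive")
        return float(parameter)
    raise ValueError(f"unknown radius policy {policy!r}; choose from {RADIUS_POLICIES}")


def recurrence(distances: DistanceMatrix, radius: float) -> RecurrenceResult:
    """Threshold the distance matrix: pair (i, j) is recurrent iff d(i,j) < radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    dm = distances.values
    n = dm.shape[0]
    plot = (dm < radius).astype(np.int8)
    np.fill_diagonal(plot, 0)
    count = int(plot.sum()) // 2
    pair_count = n * (n - 1) // 2
    return RecurrenceResult(
        radius=float(radius),
        recurrence_count=count,
        pair_count=pair_count,
        recurrence_plot=plot,
    )


def _histogram_mi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information (nats) from an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz])))


def ami_first_minimum(
    series: Sequence[float],
    max_lag: int,
    n_bins: int = 16,
    flat_tolerance: float = 0.05,
) -> AMIResult:
    """First local minimum of the average mutual information over lags.

    Returns the smallest lag ``1 <= l < max_lag`` where the histogram MI is a
    strict local minimum against its neighbours (lag 0 acts as the left
    neighbour of lag 1). If no minimum exists, or the MI curve is flat to
    within ``flat_tolerance`` nats (e.g. white noise), ``lag = max_lag`` is
    returned with ``no_minimum`` set.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    if np.ptp(x) == 0:
        raise ValueError("mutual information is undefined for a constant series")
    if n < n_bins * n_bins:
        warnings.warn(
            f"series length {n} below bins^2 = {n_bins**2}: "
            "MI estimates may be unreliable",
            stacklevel=2,
        )
    mi = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        if lag == 0:
            mi[lag] = _histogram_mi(x, x, n_bins)
        else:
            mi[lag] = _histogram_mi(x[:-lag], x[lag:], n_bins)
    flat = np.ptp(mi[1:]) < flat_tolerance
    first_min: Optional[int] = None
    for lag in range(1, max_lag):
        if mi[lag] < mi[lag - 1] and mi[lag] < mi[lag + 1]:
            first_min = lag
            break
    if flat or first_min is None:
        return AMIResult(lag=max_lag, no_minimum=True, mi_values=mi)
    return AMIResult(lag=first_min, no_minimum=False, mi_values=mi)
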