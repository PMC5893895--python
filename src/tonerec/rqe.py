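"""Sliding-window recurrence scan (recurrence quantification of epochs).

A fixed-length window slides along the glissando mixture in constant
shifts; each window is delay-embedded and reduced to its percent
recurrence, which is recorded against the mean interval ratio of the
window's samples. The result is a profile of recurrence versus interval
ratio covering the whole sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from tonerec.rqa import RADIUS_POLICIES, embed, select_radius
from tonerec.synthesis import Signal

__all__ = ["RQEConfig", "RQEProfile", "rqe_scan", "window_ratio"]


@dataclass(frozen=True)
class RQEConfig:
    """Parameters of the sliding-window scan.

    Defaults follow the reference analysis: 480-sample windows shifted by
    48 samples, embedding dimension 5 with lag 3, and a per-window radius of
    10% of the window's mean pairwise distance.
    """

    window_length: int = 480
    shift: int = 48
    m: int = 5
    L: int = 3
    radius_policy: str = "fraction_of_mean_distance"
    radius_parameter: float = 0.1
    radius_scope: str = "per_window"  # or "global"

    def __post_init__(self) -> None:
        if self.window_length < (self.m - 1) * self.L + 2:
            raise ValueError(
                f"window_length {self.window_length} too short for "
                f"m={self.m}, L={self.L}: needs at least {(self.m - 1) * self.L + 2}"
            )
        if not 1 <= self.shift <= self.window_length:
            raise ValueError("shift must be in [1, window_length]")
        if self.radius_policy not in RADIUS_POLICIES:
            raise ValueError(f"unknown radius policy {self.radius_policy!r}")
        if self.radius_scope not in ("per_window", "global"):
            raise ValueError("radius_scope must be 'per_window' or 'global'")

    def window_starts(self, n_samples: int) -> np.ndarray:
        if n_samples < self.window_length:
            raise ValueError(
                f"signal of length {n_samples} shorter than window "
                f"({self.window_length})"
            )
        last = n_samples - self.window_length
        return np.arange(0, last + 1, self.shift)


@dataclass
class RQEProfile:
    """Ordered (window start, interval ratio, percent recurrence) records."""

    window_start: np.ndarray
    ratio: np.ndarray
    percent_recurrence: np.ndarray
    config: RQEConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.window_start = np.asarray(self.window_start, dtype=int)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.percent_recurrence = np.asarray(self.percent_recurrence, dtype=float)
        if not (len(self.window_start) == len(self.ratio) == len(self.percent_recurrence)):
            raise ValueError("profile columns must have equal length")

    def __len__(self) -> int:
        return len(self.ratio)

    def __iter__(self) -> Iterator[tuple[int, float, float]]:
        return iter(zip(self.window_start, self.ratio, self.percent_recurrence))

    def restrict_ratio(self, lo: float, hi: float) -> "RQEProfile":
        """Sub-profile with interval ratio in [lo, hi] (e.g. the octave span)."""
        mask = (self.ratio >= lo) & (self.ratio <= hi)
        if not mask.any():
            raise ValueError(f"no windows with ratio in [{lo}, {hi}]")
        return RQEProfile(
            self.window_start[mask],
            self.ratio[mask],
            self.percent_recurrence[mask],
            self.config,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_start,
                "ratio": self.ratio,
                "percent_recurrence": self.percent_recurrence,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RQEProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            window_start=df["window_start"].to_numpy(),
            ratio=df["ratio"].to_numpy(),
            percent_recurrence=df["percent_recurrence"].to_numpy(),
        )


def window_ratio(signal: Signal, window_start: int, window_length: int) -> float:
    """Mean interval ratio over one window's samples."""
    if signal.ratio_trajectory is None:
        raise ValueError("signal carries no ratio_trajectory")
    if window_start < 0 or window_start + window_length > len(signal):
        raise ValueError(
            f"window [{window_start}, {window_start + window_length}) out of range "
            f"for signal of length {len(signal)}"
        )
    return float(signal.ratio_trajectory[window_start : window_start + window_length].mean())


def _window_distances(x: np.ndarray, config: RQEConfig) -> np.ndarray:
    rows = embed(x, config.m, config.L).rows
    return pdist(rows, metric="euclidean")


def _global_radius(x: np.ndarray, starts: np.ndarray, config: RQEConfig) -> float:
    """One radius for every window, from the pooled distance distribution.

    Mean/SD-based policies stream the pooled moments window by window;
    the empirical percentile uses a deterministic 1-in-16 subsample of each
    window's distances to bound memory.
    """
    if config.radius_policy == "absolute":
        return config.radius_parameter
    if config.radius_policy == "empirical_percentile":
        sub = [
            _window_distances(x[s : s + config.window_length], config)[::16]
            for s in starts
        ]
        return select_radius(
            np.concatenate(sub), config.radius_policy, config.radius_parameter
        )
    total = 0
    s1 = 0.0
    s2 = 0.0
    for s in starts:
        d = _window_distances(x[s : s + config.window_length], config)
        total += len(d)
        s1 += d.sum()
        s2 += np.square(d).sum()
    mean = s1 / total
    if config.radius_policy == "fraction_of_mean_distance":
        return float(config.radius_parameter * mean)
    # gaussian_percentile
    from scipy.stats import norm

    sd = np.sqrt(max(s2 / total - mean * mean, 0.0))
    return float(mean - norm.ppf(1.0 - config.radius_parameter) * sd)


def rqe_scan(signal: Signal, config: RQEConfig | None = None) -> RQEProfile:
    """Scan the signal and return percent recurrence per window.

    With ``radius_scope='per_window'`` each window's radius is derived from
    its own distance distribution; with ``'global'`` a single radius is
    derived from the pooled per-window distance means (or, for the
    ``absolute`` policy, used directly) and applied everywhere.
    """
    if config is None:
        config = RQEConfig()
    if signal.ratio_trajectory is None:
        raise ValueError("rqe_scan requires a signal with a ratio_trajectory")
    x = signal.samples
    starts = config.window_starts(len(x))

    global_radius: float | None = None
    if config.radius_scope == "global":
        global_radius = _global_radius(x, starts, config)

    ratios = np.empty(len(starts))
    percents = np.empty(len(starts))
    for i, s in enumerate(starts):
        d = _window_distances(x[s : s + config.window_length], config)
        if global_radius is None:
            radius = select_radius(d, config.radius_policy, config.radius_parameter)
        else:
            radius = global_radius
        percents[i] = 100.0 * np.count_nonzero(d < radius) / len(d)
        ratios[i] = window_ratio(signal, int(s), config.window_length)
    return RQEProfile(
        window_start=starts, ratio=ratios, percent_recurrence=percents, config=config
    )
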