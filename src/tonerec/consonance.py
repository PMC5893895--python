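"""Consonance metrics over a recurrence profile.

Peak detection on the recurrence-versus-ratio profile, matching of peak
positions to small-integer frequency ratios (just intonation), ranking of
the matched intervals by recurrence, the two-term simplicity index
``(m + n) / (m * n)`` of a reduced ratio ``m/n``, and the cumulative
recurrence staircase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import peak_prominences
from scipy.stats import pearsonr, spearmanr

from tonerec.curves import StaircaseCurve
from tonerec.rqe import RQEProfile

__all__ = [
    "RationalInterval",
    "Peak",
    "PeakSet",
    "RankingReport",
    "CorrelationReport",
    "INTERVAL_CATALOG",
    "REFERENCE_CONSONANCE_ORDER",
    "detect_peaks",
    "match_rational",
    "frova_index",
    "consonance_ranking",
    "recurrence_frova_correlation",
    "cumulative_recurrence",
]


@dataclass(frozen=True)
class RationalInterval:
    """A musical interval as a reduced fraction ``numerator/denominator``."""

    numerator: int
    denominator: int
    name: str = ""
    label: str = ""
    caveat: bool = False  # position ambiguous in the source catalog

    def __post_init__(self) -> None:
        if self.numerator < 1 or self.denominator < 1:
            raise ValueError("interval terms must be positive integers")
        if math.gcd(self.numerator, self.denominator) != 1:
            raise ValueError(
                f"{self.numerator}/{self.denominator} is not in lowest terms"
            )

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def _ri(num: int, den: int, name: str = "", label: str = "", caveat: bool = False):
    return RationalInterval(num, den, name, label, caveat)


#: Just-intonation catalog, in decreasing order of recurrence in the
#: reference analysis. The 15/8 entry is flagged: the source catalog lists
#: the same fraction at two inconsistent positions.
INTERVAL_CATALOG: tuple[RationalInterval, ...] = (
    _ri(1, 1, "Unison", "U"),
    _ri(2, 1, "Octave", "P8"),
    _ri(3, 2, "Perfect fifth", "P5"),
    _ri(4, 3, "Perfect fourth", "P4"),
    _ri(5, 3, "Major sixth", "M6"),
    _ri(5, 4, "Major third", "M3"),
    _ri(7, 4, "Harmonic seventh", "H7"),
    _ri(6, 5, "Minor third", "m3"),
    _ri(7, 5, "Septimal"),
    _ri(8, 5, "Minor sixth", "m6"),
    _ri(9, 5, "Just minor seventh", "m7"),
    _ri(7, 6, "Septimal minor third"),
    _ri(9, 7, "Septimal major third"),
    _ri(11, 6, "Undecimal neutral seventh"),
    _ri(8, 7, "Septimal whole tone"),
    _ri(10, 7, "Euler's tritone"),
    _ri(9, 8, "Major whole tone", "Mt"),
    _ri(12, 7, "Septimal major sixth"),
    _ri(11, 7, "Undecimal augmented fifth"),
    _ri(10, 9, "Minor whole tone", "mt"),
    _ri(15, 8, "Classic major seventh", "M7", caveat=True),
    _ri(11, 9, "Undecimal neutral third"),
    _ri(11, 10, "4/5 tone"),
    _ri(11, 8, "Undecimal semi-augmented fourth"),
    _ri(13, 10, "Tridecimal semi-diminished fourth"),
    _ri(13, 8, "Tridecimal neutral sixth"),
    _ri(12, 11, "3/4 tone"),
    _ri(17, 9, "Septendecimal minor third"),
    _ri(13, 11, "Tridecimal minor third"),
    _ri(13, 9, "Tridecimal diminished fifth", "D5"),
)

#: The ten named intervals in decreasing order of consonance.
REFERENCE_CONSONANCE_ORDER: tuple[str, ...] = (
    "U", "P8", "P5", "P4", "M6", "M3", "m3", "m6", "m7", "M7",
)

_CATALOG_BY_FRACTION = {
    (iv.numerator, iv.denominator): iv for iv in INTERVAL_CATALOG
}


@dataclass(frozen=True)
class Peak:
    ratio: float
    percent_recurrence: float
    prominence: float
    matched: Optional[RationalInterval] = None


@dataclass
class PeakSet:
    """Profile peaks sorted by descending recurrence."""

    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def matched_only(self) -> "PeakSet":
        return PeakSet([p for p in self.peaks if p.matched is not None])

    def by_label(self) -> dict[str, Peak]:
        """Best (highest-recurrence) peak per matched interval label."""
        out: dict[str, Peak] = {}
        for p in self.peaks:
            if p.matched is not None and p.matched.label:
                out.setdefault(p.matched.label, p)
        return out


@dataclass(frozen=True)
class RankingReport:
    labels: tuple[str, ...]
    spearman_rho: float


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    slope: float
    intercept: float
    n: int
    underdetermined: bool


def match_rational(
    ratio: float, max_denominator: int = 11
) -> RationalInterval:
    """Best rational approximation ``m/n`` with ``n <= max_denominator``.

    Minimizes ``|ratio - m/n|`` over reduced fractions; exact ties resolve
    to the smaller denominator. Known catalog intervals come back with
    their names and labels.
    """
    if max_denominator < 1:
        raise ValueError("max_denominator must be >= 1")
    best: tuple[float, int, int] | None = None
    for den in range(1, max_denominator + 1):
        num = max(1, round(ratio * den))
        for cand in (num - 1, num, num + 1):
            if cand < 1:
                continue
            g = math.gcd(cand, den)
            m, n = cand // g, den // g
            err = abs(ratio - m / n)
            if best is None or err < best[0] - 1e-15:
                best = (err, m, n)
    assert best is not None
    _, m, n = best
    known = _CATALOG_BY_FRACTION.get((m, n))
    if known is not None:
        return known
    return RationalInterval(m, n)


def frova_index(interval: RationalInterval) -> float:
    """Simplicity index ``(m + n) / (m * n)`` of a reduced interval ``m/n``."""
    return (interval.numerator + interval.denominator) / (
        interval.numerator * interval.denominator
    )


def _plateau_local_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima; a flat run counts once, at its left edge."""
    n = len(y)
    maxima: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # run [i, j] of equal values; interior peak iff higher than both sides
        if y[i] > y[i - 1] and j + 1 < n and y[i] > y[j + 1]:
            maxima.append(i)
        i = j + 1
    return maxima


def detect_peaks(
    profile: RQEProfile,
    min_prominence: float = 0.2,
    min_separation: float = 0.01,
    max_denominator: int = 11,
    match_tolerance: float = 0.005,
) -> PeakSet:
    """Local maxima of the recurrence profile, matched to rational intervals.

    Peaks are strict interior maxima (flat runs collapse to their lower
    ratio), filtered by topographic prominence (percent-recurrence units)
    and by minimum separation on the ratio axis; when two candidates are
    closer than ``min_separation`` the higher one wins. A peak is matched to
    a rational only if the best ``m/n`` lies within ``match_tolerance`` of
    the peak ratio.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    order = np.argsort(profile.ratio, kind="stable")
    ratio = profile.ratio[order]
    percent = profile.percent_recurrence[order]
    idx = _plateau_local_maxima(percent)
    if not idx:
        return PeakSet([])
    prominences = peak_prominences(percent, idx)[0]
    candidates = [
        (percent[i], ratio[i], prominences[k])
        for k, i in enumerate(idx)
        if prominences[k] >= min_prominence
    ]
    # greedy separation filter: strongest first, ties toward lower ratio
    candidates.sort(key=lambda c: (-c[0], c[1]))
    accepted: list[tuple[float, float, float]] = []
    for cand in candidates:
        if all(abs(cand[1] - a[1]) >= min_separation for a in accepted):
            accepted.append(cand)
    peaks = []
    for pct, rho, prom in accepted:
        matched = match_rational(rho, max_denominator)
        if abs(matched.ratio - rho) > match_tolerance:
            matched = None
        peaks.append(Peak(float(rho), float(pct), float(prom), matched))
    peaks.sort(key=lambda p: (-p.percent_recurrence, p.ratio))
    return PeakSet(peaks)


def consonance_ranking(
    peaks: PeakSet,
    reference: Sequence[str] = REFERENCE_CONSONANCE_ORDER,
) -> RankingReport:
    """Order matched interval labels by recurrence; Spearman rho vs reference.

    rho is computed between the reference consonance rank and the
    recurrence-descending rank of the labels present in both; +1 means the
    recurrence ordering reproduces the reference consonance ordering.
    """
    by_label = peaks.by_label()
    present = [lab for lab in reference if lab in by_label]
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 matched reference intervals, got {len(present)}"
        )
    ordered = sorted(present, key=lambda lab: -by_label[lab].percent_recurrence)
    ref_rank = [reference.index(lab) for lab in ordered]
    rho = spearmanr(ref_rank, np.arange(len(ordered))).statistic
    return RankingReport(labels=tuple(ordered), spearman_rho=float(rho))


def recurrence_frova_correlation(
    peaks: PeakSet,
    labels: Sequence[str] | None = None,
) -> CorrelationReport:
    """Pearson correlation (and OLS line) of peak recurrence vs simplicity index.

    ``labels`` restricts the computation to specific matched interval labels
    (e.g. the ten reference consonances); by default every matched peak
    participates, one per interval.
    """
    by_label = peaks.by_label()
    if labels is not None:
        selected = [by_label[lab] for lab in labels if lab in by_label]
    else:
        seen: dict[str, Peak] = {}
        for p in peaks.matched_only():
            seen.setdefault(str(p.matched), p)
        selected = list(seen.values())
    if len(selected) < 2:
        raise ValueError(f"need at least 2 matched intervals, got {len(selected)}")
    x = np.array([frova_index(p.matched) for p in selected])
    y = np.array([p.percent_recurrence for p in selected])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    r = pearsonr(x, y).statistic
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationReport(
        pearson_r=float(r),
        slope=float(slope),
        intercept=float(intercept),
        n=len(selected),
        underdetermined=len(selected) < 3,
    )


def cumulative_recurrence(profile: RQEProfile) -> StaircaseCurve:
    """Running sum of percent recurrence along ascending ratio, scaled to [0, 1]."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    order = np.argsort(profile.ratio, kind="stable")
    ratio = profile.ratio[order]
    percent = profile.percent_recurrence[order]
    total = percent.sum()
    if total <= 0:
        raise ValueError("profile has no recurrence mass")
    return StaircaseCurve(
        ratio,
        np.cumsum(percent) / total,
        x_label="ratio",
        y_label="cumulative_recurrence",
    )
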