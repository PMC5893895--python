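"""First- and second-order beat rates of two-tone mixtures.

First-order beats are the slow amplitude-envelope oscillation of two
near-equal frequencies; their rate is counted from the maxima of the
low-passed analytic-signal envelope. Second-order beats leave the envelope
flat but make the waveform's vibration pattern drift; their rate is the
reciprocal of the smallest lag at which a short probe window of the
waveform maximally re-correlates with the delayed signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, hilbert

from tonerec.synthesis import Signal

__all__ = ["BeatReport", "envelope_beat_rate", "pattern_beat_rate", "PatternRateError"]


class PatternRateError(RuntimeError):
    """No self-similarity maximum above the correlation threshold."""

    def __init__(self, best_correlation: float):
        self.best_correlation = best_correlation
        super().__init__(
            "no self-similarity maximum above threshold; "
            f"best correlation found: {best_correlation:.6f}"
        )


@dataclass(frozen=True)
class BeatReport:
    first_order_rate: Optional[float]
    pattern_rate: Optional[float]
    flat_envelope: bool
    tuned: bool
    method: str = "analytic-envelope + probe-correlation"


def _slow_envelope(signal: Signal, cutoff_hz: float) -> np.ndarray:
    env = np.abs(hilbert(signal.samples))
    nyq = signal.sample_rate / 2.0
    b, a = butter(4, cutoff_hz / nyq, btype="low")
    return filtfilt(b, a, env)


def envelope_beat_rate(
    signal: Signal,
    cutoff_hz: float = 30.0,
    min_depth: float = 0.1,
    edge_fraction: float = 0.05,
) -> Optional[float]:
    """Amplitude-envelope beat rate in Hz, or ``None`` for a flat envelope.

    The magnitude of the analytic signal is low-passed at ``cutoff_hz`` to
    keep only slow amplitude modulation; if its modulation depth
    ``(max - min)/mean`` over the interior (edges trimmed) is below
    ``min_depth`` there is no first-order beating. Otherwise the envelope
    maxima are counted and converted to a per-second rate, rounded to
    0.1 Hz.
    """
    if len(signal) < 16:
        raise ValueError("signal too short for envelope analysis")
    env = _slow_envelope(signal, cutoff_hz)
    trim = int(len(env) * edge_fraction)
    interior = env[trim : len(env) - trim] if trim > 0 else env
    mean = interior.mean()
    if mean <= 0 or (interior.max() - interior.min()) / mean < min_depth:
        return None
    span = interior.max() - interior.min()
    peaks, _ = find_peaks(interior, prominence=0.25 * span)
    if len(peaks) < 2:
        return None
    # rate from mean peak spacing: immune to partial periods at the edges
    spacing = (peaks[-1] - peaks[0]) / (len(peaks) - 1)
    return round(signal.sample_rate / spacing, 1)


def _normalized_correlation(probe: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Cosine similarity of a mean-removed probe against stacked windows."""
    p = probe - probe.mean()
    w = windows - windows.mean(axis=1, keepdims=True)
    num = w @ p
    den = np.linalg.norm(p) * np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / den
    return np.nan_to_num(c, nan=-1.0)


def pattern_beat_rate(
    signal: Signal,
    probe_length: Optional[int] = None,
    search_range: tuple[float, float] = (0.05, 1.5),
    threshold: float = 0.99,
    cluster_gap: float = 0.0125,
    f_ref: float = 400.0,
) -> tuple[float, bool]:
    """Vibration-pattern recurrence rate in Hz and a ``tuned`` flag.

    A probe window (default: two periods of ``f_ref``) taken at the start of
    the signal is correlated against every lag. If the waveform is exactly
    periodic at a lag shorter than the search range (correlation ~1), the
    interval is perfectly tuned and the reciprocal waveform period is
    returned with ``tuned=True``. Otherwise the lags whose correlation
    exceeds ``threshold`` are grouped into clusters (gaps larger than
    ``cluster_gap`` seconds split clusters); the best-correlated lag of the
    earliest cluster is the pattern recurrence time, and its reciprocal is
    the second-order beat rate, rounded to 0.1 Hz.
    """
    sr = signal.sample_rate
    if probe_length is None:
        probe_length = int(round(2.0 * sr / f_ref))
    x = signal.samples
    lo = int(round(search_range[0] * sr))
    hi = int(round(search_range[1] * sr))
    if len(x) < hi + probe_length:
        raise ValueError(
            f"signal too short: need {hi + probe_length} samples for a "
            f"{search_range[1]} s search, got {len(x)}"
        )
    probe = x[:probe_length]
    windows = np.lib.stride_tricks.sliding_window_view(x, probe_length)
    c = _normalized_correlation(probe, windows)

    # exactly periodic below the search floor -> perfectly tuned interval
    if lo > 1:
        short = c[1:lo]
        exact = np.nonzero(short > 1.0 - 1e-7)[0]
        if exact.size:
            lag = int(exact[0]) + 1
            return round(sr / lag, 1), True

    band = c[lo : hi + 1]
    above = np.nonzero(band >= threshold)[0]
    if above.size == 0:
        raise PatternRateError(float(band.max()))
    gap = int(round(cluster_gap * sr))
    cluster_end = above[-1]
    for prev, cur in zip(above, above[1:]):
        if cur - prev > gap:
            cluster_end = prev
            break
    segment = band[above[0] : cluster_end + 1]
    lag = lo + int(above[0]) + int(np.argmax(segment))
    return round(sr / lag, 1), False
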