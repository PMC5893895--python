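"""Stimulus synthesis and signal I/O.

All stimuli used by the analysis are generated here: fixed pure tones,
mistuned two-tone intervals (a small-integer ratio offset by a few hertz)
and a linear glissando mixed with a fixed reference tone. Signals are plain
sampled waveforms; the glissando mixture additionally carries a per-sample
interval-ratio trajectory used by the sliding-window recurrence scan.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ToneSpec",
    "MistunedIntervalSpec",
    "GlissandoSpec",
    "Signal",
    "SignalIOError",
    "synth_pure_tone",
    "mix_to_mono",
    "synth_mistuned_interval",
    "synth_glissando_mix",
    "read_signal",
    "write_signal",
]


class SignalIOError(ValueError):
    """Raised for malformed signal files."""


def _n_samples(duration: float, sample_rate: float) -> int:
    return int(round(duration * sample_rate))


@dataclass(frozen=True)
class ToneSpec:
    """A single sinusoid: ``amplitude * sin(2*pi*frequency*t + phase)``."""

    frequency: float
    duration: float
    sample_rate: float
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.frequency < 0:
            raise ValueError(f"frequency must be non-negative, got {self.frequency}")
        if self.frequency >= self.sample_rate / 2:
            raise ValueError(
                f"frequency {self.frequency} Hz violates the Nyquist limit "
                f"({self.sample_rate / 2} Hz at {self.sample_rate} samples/s)"
            )


@dataclass(frozen=True)
class MistunedIntervalSpec:
    """Two tones at ``f1`` and ``(num/den)*f1 + epsilon``, mixed to mono.

    ``epsilon = 0`` gives the perfectly tuned interval with a static
    vibration pattern; a small nonzero ``epsilon`` makes the pattern drift.
    """

    base_frequency: float
    ratio_numerator: int
    ratio_denominator: int
    epsilon: float
    duration: float
    sample_rate: float

    def __post_init__(self) -> None:
        if self.ratio_numerator < 1 or self.ratio_denominator < 1:
            raise ValueError("interval ratio must be a positive fraction")
        # tone specs re-check Nyquist for both component frequencies
        ToneSpec(self.base_frequency, self.duration, self.sample_rate)
        ToneSpec(self.second_frequency, self.duration, self.sample_rate)

    @property
    def second_frequency(self) -> float:
        return (self.ratio_numerator / self.ratio_denominator) * self.base_frequency + self.epsilon


@dataclass(frozen=True)
class GlissandoSpec:
    """A linear frequency sweep mixed with a fixed tone.

    Defaults reproduce the reference stimulus: a 360 -> 840 Hz sweep against
    a fixed 400 Hz tone, 6 s at 8000 samples/s, so the mixture traverses
    every interval ratio from 0.9 to 2.1.
    """

    f_start: float = 360.0
    f_end: float = 840.0
    fixed_frequency: float = 400.0
    duration: float = 6.0
    sample_rate: float = 8000.0

    def __post_init__(self) -> None:
        if self.f_start > self.f_end:
            raise ValueError("f_start must not exceed f_end")
        if self.fixed_frequency <= 0:
            raise ValueError("fixed_frequency must be positive")
        ToneSpec(self.f_end, self.duration, self.sample_rate)
        ToneSpec(self.fixed_frequency, self.duration, self.sample_rate)


@dataclass
class Signal:
    """A uniformly sampled mono waveform.

    ``ratio_trajectory``, when present, gives the instantaneous interval
    ratio (sweep frequency / fixed frequency) for every sample.
    """

    samples: np.ndarray
    sample_rate: float
    ratio_trajectory: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.ratio_trajectory is not None:
            self.ratio_trajectory = np.asarray(self.ratio_trajectory, dtype=float)
            if self.ratio_trajectory.shape != self.samples.shape:
                raise ValueError(
                    "ratio_trajectory must have the same length as samples "
                    f"({len(self.ratio_trajectory)} != {len(self.samples)})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def synth_pure_tone(spec: ToneSpec) -> Signal:
    """Synthesize a pure sinusoid; sample ``n`` is taken at ``t = n/rate``."""
    n = np.arange(_n_samples(spec.duration, spec.sample_rate))
    samples = spec.amplitude * np.sin(
        2.0 * np.pi * spec.frequency * n / spec.sample_rate + spec.phase
    )
    return Signal(samples, spec.sample_rate)


def mix_to_mono(left: Signal, right: Signal) -> Signal:
    """Average two equal-length channels into one (stereo -> mono)."""
    if len(left) != len(right):
        raise ValueError(f"channel length mismatch: {len(left)} != {len(right)}")
    if left.sample_rate != right.sample_rate:
        raise ValueError(
            f"sample rate mismatch: {left.sample_rate} != {right.sample_rate}"
        )
    trajectory = left.ratio_trajectory
    if trajectory is None:
        trajectory = right.ratio_trajectory
    return Signal(0.5 * (left.samples + right.samples), left.sample_rate, trajectory)


def synth_mistuned_interval(spec: MistunedIntervalSpec) -> Signal:
    """Mono mixture of the base tone and its (possibly mistuned) interval."""
    base = synth_pure_tone(
        ToneSpec(spec.base_frequency, spec.duration, spec.sample_rate)
    )
    upper = synth_pure_tone(
        ToneSpec(spec.second_frequency, spec.duration, spec.sample_rate)
    )
    return mix_to_mono(base, upper)


def synth_glissando_mix(spec: GlissandoSpec) -> Signal:
    """Mono mixture of a linear chirp and a fixed tone, with ratio trajectory.

    The chirp phase is the integral of the linear frequency law,
    ``2*pi*(f_start*t + (f_end - f_start)*t^2 / (2*duration))``, so the sweep
    is free of phase discontinuities. The trajectory interpolates linearly
    from ``f_start/fixed`` at the first sample to ``f_end/fixed`` at the last.
    """
    n_total = _n_samples(spec.duration, spec.sample_rate)
    t = np.arange(n_total) / spec.sample_rate
    sweep_rate = (spec.f_end - spec.f_start) / spec.duration
    chirp_phase = 2.0 * np.pi * (spec.f_start * t + 0.5 * sweep_rate * t * t)
    chirp = Signal(np.sin(chirp_phase), spec.sample_rate)
    fixed = synth_pure_tone(
        ToneSpec(spec.fixed_frequency, spec.duration, spec.sample_rate)
    )
    mixed = mix_to_mono(chirp, fixed)
    f_inst = spec.f_start + (spec.f_end - spec.f_start) * np.arange(n_total) / (n_total - 1)
    mixed.ratio_trajectory = f_inst / spec.fixed_frequency
    return mixed


# ---------------------------------------------------------------------------
# I/O: plain-text (one sample per line) and 16-bit PCM WAV.
# ---------------------------------------------------------------------------

_TEXT_RATE_PREFIX = "# rate="


def write_signal(signal: Signal, path: str | Path, format: str = "text") -> None:
    """Write a signal as plain text (``format='text'``) or 16-bit PCM WAV.

    Text files carry a ``# rate=<Hz>`` header followed by one decimal sample
    per line. WAV samples are scaled by 32767 and clipped to the int16 range.
    """
    path = Path(path)
    if format == "text":
        with open(path, "w") as fh:
            fh.write(f"{_TEXT_RATE_PREFIX}{float(signal.sample_rate)!r}\n")
            for x in signal.samples:
                fh.write(f"{float(x)!r}\n")
    elif format == "wav":
        scaled = np.clip(np.round(signal.samples * 32767.0), -32768, 32767)
        with wave.open(str(path), "wb") as wf:
            wf.setnchannels(1)
            wf.setsampwidth(2)
            wf.setframerate(int(round(signal.sample_rate)))
            wf.writeframes(scaled.astype("<i2").tobytes())
    else:
        raise ValueError(f"unknown format {format!r}; use 'text' or 'wav'")


def read_signal(path: str | Path, format: str = "text") -> Signal:
    """Read a signal written by :func:`write_signal`.

    Text round-trips are exact; WAV round-trips are exact up to the 16-bit
    quantization step. Malformed text raises :class:`SignalIOError` naming
    the offending line.
    """
    path = Path(path)
    if format == "text":
        sample_rate = 1.0
        values: list[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(_TEXT_RATE_PREFIX):
                    try:
                        sample_rate = float(line[len(_TEXT_RATE_PREFIX):])
                    except ValueError:
                        raise SignalIOError(
                            f"{path}: line {lineno}: bad rate header {line!r}"
                        ) from None
                    continue
                if line.startswith("#"):
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    raise SignalIOError(
                        f"{path}: line {lineno}: not a number: {line!r}"
                    ) from None
        if not values:
            raise SignalIOError(f"{path}: no samples found")
        return Signal(np.array(values), sample_rate)
    elif format == "wav":
        with wave.open(str(path), "rb") as wf:
            if wf.getsampwidth() != 2:
                raise SignalIOError(f"{path}: only 16-bit PCM WAV is supported")
            n_frames = wf.getnframes()
            if n_frames == 0:
                raise SignalIOError(f"{path}: no samples found")
            raw = wf.readframes(n_frames)
            rate = float(wf.getframerate())
            data = np.frombuffer(raw, dtype="<i2").astype(float)
            if wf.getnchannels() > 1:
                data = data.reshape(-1, wf.getnchannels()).mean(axis=1)
        return Signal(data / 32767.0, rate)
    else:
        raise ValueError(f"unknown format {format!r}; use 'text' or 'wav'")
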