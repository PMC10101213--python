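"""Raw sEMG to normalized amplitude envelopes and condition data matrices.

The fixed processing chain is: band-pass denoising (40-350 Hz), full-wave
rectification, low-pass envelope extraction (10 Hz), amplitude normalization
of each muscle to its median per-cycle peak, and assembly of a
samples-by-muscles matrix for one of the six analysis conditions (whole
cycles, upward phases only, or downward phases only, over either all cycles
of the 30-s recording or its first five cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import DegenerateChannelError, NyquistError
from .segmentation import CycleEvents

__all__ = [
    "CONDITIONS",
    "EnvelopeMatrix",
    "bandpass_filter",
    "compute_envelope",
    "normalize_envelope",
    "build_condition_matrix",
]

#: The six analysis conditions: full 30-s recording and its 5-cycle slice,
#: each as whole cycles, upward phases only, or downward phases only.
CONDITIONS = ("30s", "30upward", "30downward", "5tsts", "5upward", "5downward")

_N_SHORT_CYCLES = 5  # the "5 times sit-to-stand" slice length, in cycles


@dataclass
class EnvelopeMatrix:
    """Nonnegative samples-by-muscles envelope matrix for one condition.

    ``cycle_bounds`` lists the half-open row ranges of ``M`` occupied by each
    concatenated segment (a whole cycle or a single phase); the ranges are
    disjoint, ordered, and tile ``[0, n_samples)``.
    """

    M: np.ndarray
    cycle_bounds: tuple[tuple[int, int], ...]
    condition: str
    muscle_labels: tuple[str, ...]
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise ValueError("M must be 2-D (samples x muscles)")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M contains non-finite values")
        if np.any(self.M < 0):
            raise ValueError("M must be nonnegative")
        if self.M.shape[1] != len(self.muscle_labels):
            raise ValueError("column count must match the number of muscle labels")
        self.cycle_bounds = tuple((int(a), int(b)) for a, b in self.cycle_bounds)
        cursor = 0
        for a, b in self.cycle_bounds:
            if a != cursor or b <= a:
                raise ValueError("cycle_bounds must be ordered, disjoint and tile the rows")
            cursor = b
        if cursor != self.M.shape[0]:
            raise ValueError("cycle_bounds do not cover all rows of M")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")

    @property
    def n_samples(self) -> int:
        return self.M.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.M.shape[1]


def _check_band(fs: float, *edges: float) -> None:
    if fs <= 0:
        raise ValueError("fs must be positive")
    for f in edges:
        if f <= 0:
            raise ValueError("corner frequencies must be positive")
        if f >= fs / 2:
            raise NyquistError(f"corner frequency {f} Hz is at or above Nyquist ({fs / 2} Hz)")


def bandpass_filter(
    raw: np.ndarray,
    fs: float,
    low: float = 40.0,
    high: float = 350.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Band-pass denoise raw sEMG (default 40-350 Hz, 4th-order Butterworth).

    Filtering is applied along the last axis.  With ``zero_phase`` the filter
    runs forward and backward (no phase lag; effective attenuation doubles);
    the stated order refers to the designed filter.
    """
    _check_band(fs, low, high)
    if not low < high:
        raise ValueError("low must be below high")
    raw = np.asarray(raw, dtype=float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, raw, axis=-1)
    return signal.sosfilt(sos, raw, axis=-1)


def compute_envelope(
    filtered: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Amplitude envelope via full-wave rectification and low-pass filtering.

    Small negative values produced by the low-pass are clipped to zero so the
    result is a valid nonnegative input for factorization.
    """
    _check_band(fs, cutoff)
    rectified = np.abs(np.asarray(filtered, dtype=float))
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    if zero_phase:
        env = signal.sosfiltfilt(sos, rectified, axis=-1)
    else:
        env = signal.sosfilt(sos, rectified, axis=-1)
    return np.clip(env, 0.0, None)


def normalize_envelope(envelope: np.ndarray, events: CycleEvents) -> np.ndarray:
    """Normalize each muscle's envelope to its median per-cycle peak.

    For every muscle the peak value within each cycle is collected and the
    envelope is divided by the median of those peaks, so that after
    normalization the median per-cycle peak equals one for every muscle.
    """
    env = np.asarray(envelope, dtype=float)
    if env.ndim != 2:
        raise ValueError("envelope must be channels x samples")
    if events.n_cycles < 1:
        raise ValueError("at least one complete cycle is required")
    peaks = np.empty((env.shape[0], events.n_cycles))
    for j, (start, end) in enumerate(events.whole_segments()):
        if end > env.shape[1]:
            raise ValueError("events extend beyond the envelope")
        peaks[:, j] = env[:, start:end].max(axis=1)
    divisors = np.median(peaks, axis=1)
    bad = np.flatnonzero(divisors == 0)
    if bad.size:
        raise DegenerateChannelError(
            f"median per-cycle peak is zero for channel(s) {bad.tolist()}"
        )
    return env / divisors[:, None]


def _condition_segments(events: CycleEvents, condition: str) -> list[tuple[int, int]]:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    short = condition.startswith("5")
    cycles = events.cycles
    if short:
        if events.n_cycles < _N_SHORT_CYCLES:
            raise ValueError(
                f"condition {condition!r} requires at least {_N_SHORT_CYCLES} cycles, "
                f"got {events.n_cycles}"
            )
        cycles = cycles[:_N_SHORT_CYCLES]
    if condition.endswith("upward"):
        return [(s, t) for s, t, _ in cycles]
    if condition.endswith("downward"):
        return [(t, e) for _, t, e in cycles]
    return [(s, e) for s, _, e in cycles]


def build_condition_matrix(
    normalized: np.ndarray,
    events: CycleEvents,
    condition: str,
    muscle_labels: tuple[str, ...] | list[str] | None = None,
    fs: float | None = None,
) -> EnvelopeMatrix:
    """Concatenate the requested segments into a samples-by-muscles matrix.

    Each column of the result is the temporal concatenation of one muscle's
    normalized envelope over the requested segments (whole cycles, upward
    phases only, or downward phases only; the 5-cycle conditions use the
    first five cycles).
    """
    env = np.asarray(normalized, dtype=float)
    if env.ndim != 2:
        raise ValueError("normalized envelope must be channels x samples")
    segments = _condition_segments(events, condition)
    pieces = []
    bounds = []
    cursor = 0
    for start, end in segments:
        if end > env.shape[1]:
            raise ValueError("events extend beyond the envelope")
        pieces.append(env[:, start:end].T)
        bounds.append((cursor, cursor + (end - start)))
        cursor += end - start
    M = np.vstack(pieces)
    if muscle_labels is None:
        muscle_labels = tuple(f"ch{i}" for i in range(env.shape[0]))
    return EnvelopeMatrix(
        M=np.clip(M, 0.0, None),
        cycle_bounds=tuple(bounds),
        condition=condition,
        muscle_labels=tuple(muscle_labels),
        fs=events.fs if fs is None else fs,
    )
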