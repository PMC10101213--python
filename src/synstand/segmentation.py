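"""Sit-to-stand cycle and phase-transition detection from a sacrum marker trace.

A complete cycle runs from the start of one sit-to-stand movement to the
start of the following one and splits into an *upward* (sit-to-stand) and a
*downward* (stand-to-sit) phase.  The split point is the instant at which the
antero-posterior velocity of the sacrum marker changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import NoCyclesError, NyquistError

__all__ = ["CycleEvents", "detect_events"]


@dataclass(frozen=True)
class CycleEvents:
    """Per-cycle (start, transition, end) sample indices at a common rate.

    Indices are 0-based and half-open: cycle ``i`` covers samples
    ``[start_i, end_i)`` with the upward phase ``[start_i, transition_i)``
    and the downward phase ``[transition_i, end_i)``.
    """

    cycles: tuple[tuple[int, int, int], ...]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        prev_end = None
        for start, transition, end in self.cycles:
            if not (0 <= start < transition < end):
                raise ValueError(
                    f"cycle indices must satisfy 0 <= start < transition < end, "
                    f"got ({start}, {transition}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError("cycles must be ordered and non-overlapping")
            prev_end = end

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_samples(self) -> int:
        """Total number of samples spanned, assuming cycles tile the trace."""
        return self.cycles[-1][2] if self.cycles else 0

    def upward_segments(self) -> list[tuple[int, int]]:
        return [(s, t) for s, t, _ in self.cycles]

    def downward_segments(self) -> list[tuple[int, int]]:
        return [(t, e) for _, t, e in self.cycles]

    def whole_segments(self) -> list[tuple[int, int]]:
        return [(s, e) for s, _, e in self.cycles]


def _smooth_position(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff >= fs / 2:
        # Short or slow marker streams: skip smoothing rather than error out;
        # the debounce rule below still rejects jitter-induced crossings.
        return x
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_events(
    sacrum_ap: np.ndarray,
    fs_marker: float,
    fs_emg: float,
    min_phase_duration: float = 0.3,
    smoothing_cutoff: float = 5.0,
    upward_sign: int | None = None,
) -> CycleEvents:
    """Identify cycle starts and upward-to-downward transitions.

    The position trace is low-pass smoothed, differentiated with central
    differences, and scanned for velocity sign changes.  Alternating sign
    changes define the phase-transition (upward to downward) and cycle-start
    events; crossings closer than ``min_phase_duration`` to the previous
    accepted one are treated as jitter and discarded.  Indices are rescaled
    from the marker rate to the EMG rate.

    Parameters
    ----------
    sacrum_ap:
        Antero-posterior sacrum position, one sample per marker frame.
    fs_marker, fs_emg:
        Sampling rates of the marker trace and of the EMG, in Hz.
    min_phase_duration:
        Minimum admissible duration of a single phase, in seconds.
    smoothing_cutoff:
        Corner frequency of the position pre-smoothing low-pass, in Hz.
    upward_sign:
        Sign (+1/-1) of the antero-posterior velocity during the upward
        phase.  By default it is calibrated from the first large velocity
        excursion of the trace.
    """
    x = np.asarray(sacrum_ap, dtype=float).ravel()
    if fs_marker <= 0 or fs_emg <= 0:
        raise ValueError("sampling rates must be positive")
    if x.size < 4:
        raise NoCyclesError("marker trace too short")
    if not np.all(np.isfinite(x)):
        raise ValueError("marker trace contains non-finite values")

    xs = _smooth_position(x, fs_marker, smoothing_cutoff)
    v = np.gradient(xs) * fs_marker
    vmax = np.max(np.abs(v))
    if vmax == 0:
        raise NoCyclesError("marker trace is constant; no movement detected")

    # Propagate the sign through exact zeros so a zero sample does not
    # produce two spurious crossings.
    s = np.sign(v).astype(int)
    nonzero = np.flatnonzero(s)
    if nonzero.size == 0:
        raise NoCyclesError("velocity is identically zero")
    first_sign = s[nonzero[0]]
    s[: nonzero[0]] = first_sign
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]

    crossings = np.flatnonzero(np.diff(s) != 0) + 1
    if crossings.size == 0:
        raise NoCyclesError("no change in antero-posterior velocity direction")

    # Debounce: enforce the minimum phase duration between kept crossings.
    min_gap = int(round(min_phase_duration * fs_marker))
    kept: list[int] = []
    for c in crossings:
        if kept and c - kept[-1] < min_gap:
            continue
        kept.append(int(c))
    if not kept:
        raise NoCyclesError("all velocity sign changes rejected by debouncing")

    if upward_sign is None:
        big = np.flatnonzero(np.abs(v) >= 0.5 * vmax)
        upward_sign = int(np.sign(v[big[0]]))
    if upward_sign not in (-1, 1):
        raise ValueError("upward_sign must be +1 or -1")

    starts: list[int] = []   # crossings into the upward direction
    transitions: list[int] = []  # crossings into the downward direction
    for c in kept:
        if s[c] == upward_sign:
            starts.append(c)
        else:
            transitions.append(c)

    if not transitions:
        raise NoCyclesError("no upward-to-downward transition found")

    # The first movement onset generates no sign change when the trace
    # starts from rest: infer it as the last near-zero-velocity sample
    # preceding the first large upward excursion.
    if not starts or starts[0] > transitions[0]:
        surge = np.flatnonzero(
            (s[: transitions[0]] == upward_sign)
            & (np.abs(v[: transitions[0]]) >= 0.5 * vmax)
        )
        anchor = int(surge[0]) if surge.size else transitions[0]
        quiet = np.flatnonzero(np.abs(v[:anchor]) < 0.1 * vmax)
        onset = int(quiet[-1]) if quiet.size else 0
        starts.insert(0, onset)

    # Pair starts with the first transition that follows each of them.
    cycles_marker: list[tuple[int, int, int]] = []
    t_arr = np.asarray(transitions)
    for i, st in enumerate(starts):
        after = t_arr[t_arr > st]
        if after.size == 0:
            break  # incomplete final cycle: upward started, never came down
        tr = int(after[0])
        end = starts[i + 1] if i + 1 < len(starts) else x.size
        if end <= tr:
            continue
        cycles_marker.append((st, tr, int(end)))

    if not cycles_marker:
        raise NoCyclesError("no complete sit-to-stand cycle identified")

    scale = fs_emg / fs_marker
    cycles = tuple(
        (int(round(st * scale)), int(round(tr * scale)), int(round(en * scale)))
        for st, tr, en in cycles_marker
    )
    return CycleEvents(cycles=cycles, fs=fs_emg)
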