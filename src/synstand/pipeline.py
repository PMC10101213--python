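"""End-to-end convenience wrappers: raw trial to envelope matrix to AIC curve."""

from __future__ import annotations

import numpy as np

from .factorization import AicCurve, select_nsyn
from .preprocessing import (
    EnvelopeMatrix,
    bandpass_filter,
    build_condition_matrix,
    compute_envelope,
    normalize_envelope,
)
from .segmentation import CycleEvents, detect_events
from .synthetic import EmgTrial

__all__ = ["preprocess_trial", "extract_synergies"]


def preprocess_trial(
    trial: EmgTrial,
    condition: str = "30s",
    events: CycleEvents | None = None,
    low: float = 40.0,
    high: float = 350.0,
    envelope_cutoff: float = 10.0,
) -> EnvelopeMatrix:
    """Run the full preprocessing chain on one trial.

    Band-pass, rectify, low-pass, normalize to the median per-cycle peak,
    then assemble the samples-by-muscles matrix for the requested condition.
    Events are detected from the sacrum trace unless supplied.
    """
    if events is None:
        events = detect_events(trial.sacrum_ap, trial.fs_marker, trial.fs_emg)
    n = trial.emg.shape[1]
    cycles = tuple(
        (s, min(t, n - 1), min(e, n)) for s, t, e in events.cycles if s < n - 1
    )
    events = CycleEvents(cycles=cycles, fs=events.fs)
    filtered = bandpass_filter(trial.emg, trial.fs_emg, low=low, high=high)
    envelope = compute_envelope(filtered, trial.fs_emg, cutoff=envelope_cutoff)
    normalized = normalize_envelope(envelope, events)
    return build_condition_matrix(
        normalized, events, condition, muscle_labels=trial.muscle_labels,
        fs=trial.fs_emg,
    )


def extract_synergies(
    trial: EmgTrial,
    condition: str = "30s",
    k_range=None,
    seed: int = 0,
    **select_kwargs,
) -> tuple[EnvelopeMatrix, AicCurve]:
    """Preprocess one trial and select the synergy model order by AIC."""
    matrix = preprocess_trial(trial, condition=condition)
    curve = select_nsyn(matrix, k_range=k_range, seed=seed, **select_kwargs)
    return matrix, curve
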