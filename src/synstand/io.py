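"""Delimited-text and JSON persistence for trials, envelopes and results.

Everything is stored as plain text: EMG and marker traces as CSV (one column
per channel, one row per sample), events as TSV in seconds, matrices as CSV,
and the bookkeeping (sampling rates, muscle order, condition, ground truth,
configuration echo) as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .factorization import AicCurve, SynergyModel
from .preprocessing import EnvelopeMatrix
from .segmentation import CycleEvents
from .synthetic import EmgTrial, GroundTruth, TrialConfig

__all__ = [
    "write_trial", "read_trial",
    "write_events", "read_events",
    "write_envelope_matrix", "read_envelope_matrix",
    "write_synergy_model", "write_aic_curve",
]


def write_trial(trial: EmgTrial, outdir, stem: str = "trial",
                config: TrialConfig | None = None) -> Path:
    """Write a trial as <stem>_emg.csv, <stem>_marker.csv and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emg = pd.DataFrame(trial.emg.T, columns=list(trial.muscle_labels))
    emg.to_csv(outdir / f"{stem}_emg.csv", index=False, float_format="%.6g")
    pd.DataFrame({"sacrum_ap": trial.sacrum_ap}).to_csv(
        outdir / f"{stem}_marker.csv", index=False, float_format="%.6g"
    )
    meta = {
        "fs_emg": trial.fs_emg,
        "fs_marker": trial.fs_marker,
        "muscle_labels": list(trial.muscle_labels),
    }
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    if trial.ground_truth is not None:
        gt = trial.ground_truth
        meta["ground_truth"] = {
            "W": gt.W.tolist(),
            "events": [list(c) for c in gt.events.cycles],
        }
        pd.DataFrame(gt.activations.T).to_csv(
            outdir / f"{stem}_activations.csv", index=False, float_format="%.6g"
        )
        pd.DataFrame(gt.envelope.T, columns=list(trial.muscle_labels)).to_csv(
            outdir / f"{stem}_envelope.csv", index=False, float_format="%.6g"
        )
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return outdir


def read_trial(indir, stem: str = "trial") -> EmgTrial:
    indir = Path(indir)
    with open(indir / f"{stem}.json") as fh:
        meta = json.load(fh)
    emg = pd.read_csv(indir / f"{stem}_emg.csv")
    marker = pd.read_csv(indir / f"{stem}_marker.csv")
    truth = None
    if "ground_truth" in meta:
        gt = meta["ground_truth"]
        events = CycleEvents(
            cycles=tuple(tuple(c) for c in gt["events"]), fs=meta["fs_emg"]
        )
        activations = pd.read_csv(indir / f"{stem}_activations.csv").to_numpy().T
        envelope = pd.read_csv(indir / f"{stem}_envelope.csv").to_numpy().T
        truth = GroundTruth(
            W=np.asarray(gt["W"]), activations=activations,
            events=events, envelope=envelope,
        )
    return EmgTrial(
        emg=emg.to_numpy().T,
        sacrum_ap=marker["sacrum_ap"].to_numpy(),
        fs_emg=meta["fs_emg"],
        fs_marker=meta["fs_marker"],
        muscle_labels=tuple(meta["muscle_labels"]),
        ground_truth=truth,
    )


def write_events(events: CycleEvents, path) -> Path:
    path = Path(path)
    rows = [
        {"cycle": i, "start_s": s / events.fs, "transition_s": t / events.fs,
         "end_s": e / events.fs}
        for i, (s, t, e) in enumerate(events.cycles)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_events(path, fs: float) -> CycleEvents:
    df = pd.read_csv(path, sep="\t")
    cycles = tuple(
        (int(round(r.start_s * fs)), int(round(r.transition_s * fs)),
         int(round(r.end_s * fs)))
        for r in df.itertuples()
    )
    return CycleEvents(cycles=cycles, fs=fs)


def write_envelope_matrix(matrix: EnvelopeMatrix, outdir, stem: str = "envelope") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(matrix.M, columns=list(matrix.muscle_labels)).to_csv(
        outdir / f"{stem}.csv", index=False, float_format="%.8g"
    )
    meta = {
        "condition": matrix.condition,
        "cycle_bounds": [list(b) for b in matrix.cycle_bounds],
        "muscle_labels": list(matrix.muscle_labels),
        "fs": matrix.fs,
    }
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return outdir


def read_envelope_matrix(indir, stem: str = "envelope") -> EnvelopeMatrix:
    indir = Path(indir)
    with open(indir / f"{stem}.json") as fh:
        meta = json.load(fh)
    M = pd.read_csv(indir / f"{stem}.csv").to_numpy()
    return EnvelopeMatrix(
        M=M,
        cycle_bounds=tuple(tuple(b) for b in meta["cycle_bounds"]),
        condition=meta["condition"],
        muscle_labels=tuple(meta["muscle_labels"]),
        fs=meta["fs"],
    )


def write_synergy_model(model: SynergyModel, outdir, stem: str = "model",
                        muscle_labels=None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = list(muscle_labels) if muscle_labels is not None else None
    pd.DataFrame(model.W, index=cols).to_csv(
        outdir / f"{stem}_W.csv", float_format="%.8g",
        index=muscle_labels is not None, header=False if cols is None else True,
    )
    pd.DataFrame(model.C).to_csv(outdir / f"{stem}_C.csv", index=False,
                                 float_format="%.8g")
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump({"k": model.k, "r2": model.r2, "sse": model.sse,
                   "seed": model.seed}, fh, indent=1)
    return outdir


def write_aic_curve(curve: AicCurve, outdir, stem: str = "aic") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"k": curve.k_values, "aic": curve.aic_values,
         "residual": curve.residual_per_k, "dof": curve.dof_per_k}
    ).to_csv(outdir / f"{stem}.csv", index=False)
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump({"selected_k": curve.selected_k,
                   "k_values": list(curve.k_values)}, fh, indent=1)
    return outdir
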