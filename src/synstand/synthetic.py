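"""Synthetic sit-to-stand sEMG trials with known synergy structure.

Generates multi-channel surface EMG whose amplitude structure follows the
synchronous muscle-synergy model: a small set of fixed nonnegative muscle
weighting vectors (the spatial synergies W) recruited by smooth, phase-locked
activation bursts across repeated sit-to-stand-to-sit cycles.  Raw signals
are produced by modulating band-limited stochastic carriers with the true
envelopes, then adding baseline noise, signal-dependent noise, and (optional)
broadband movement artifacts on the posterior-chain channels that contact
the chair.  A quasi-periodic sacrum antero-posterior trace with analytically
known velocity zero-crossings accompanies each trial for segmentation.

All randomness in a trial flows from a single integer seed through a fixed
splitting scheme (one independent stream per noise source), so trials are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .segmentation import CycleEvents

__all__ = [
    "MUSCLES",
    "GroundTruthSynergies",
    "TrialConfig",
    "GroundTruth",
    "EmgTrial",
    "make_ground_truth_synergies",
    "make_activations",
    "synthesize_trial",
    "normalized_true_synergies",
]

#: Right-leg muscle set, in recording order: soleus, gastrocnemius medialis,
#: peroneus longus, tibialis anterior, vastus lateralis, rectus femoris,
#: biceps femoris, gluteus maximus.
MUSCLES = ("SOL", "GMED", "PER", "TA", "VL", "RF", "BF", "GLU")

# Template weights for the three functional groups seen in sit-to-stand:
# knee extensors (with minor knee-flexor/hip-extensor contribution),
# plantar flexors with hip extensors, and muscles acting on ankle and hip.
_TEMPLATES = {
    # SOL   GMED  PER   TA    VL    RF    BF    GLU
    0: (0.05, 0.05, 0.05, 0.05, 0.90, 0.75, 0.15, 0.20),  # knee extensors
    1: (0.90, 0.80, 0.55, 0.05, 0.05, 0.05, 0.10, 0.30),  # plantar flexors
    2: (0.15, 0.10, 0.30, 0.90, 0.05, 0.05, 0.20, 0.35),  # ankle/hip (TA-led)
}

# Phase preference of each template's activation burst within a cycle.
_TEMPLATE_PHASE = {0: "upward", 1: "downward", 2: "transition"}


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one noise source of one trial."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class GroundTruthSynergies:
    """True spatial synergies: nonnegative muscles-by-k matrix, unit-norm columns."""

    W: np.ndarray
    muscle_labels: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != len(self.muscle_labels):
            raise ValueError("W must be muscles x k")
        if np.any(W < 0):
            raise ValueError("synergy weights must be nonnegative")
        norms = np.linalg.norm(W, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("synergy columns must have unit Euclidean norm")

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrialConfig:
    """Generator settings for one synthetic sit-to-stand trial.

    Defaults describe a 30-second recording: 15 cycles of about 2 s each
    (10% duration jitter), the upward phase taking 45% of the cycle, EMG at
    1 kHz and the marker at 100 Hz.  Signal-dependent noise has standard
    deviation ``sdn_coefficient`` times the true envelope; baseline noise is
    white with standard deviation ``baseline_noise_sd`` in normalized
    envelope units (cycle peaks are of order one).  Movement artifacts, when
    enabled, hit the channels in ``artifact_channels`` with broadband bursts
    scaled to ``artifact_amplitude`` times the clean channel RMS.
    """

    n_cycles: int = 15
    cycle_duration_mean: float = 2.0
    cycle_duration_cv: float = 0.1
    upward_fraction: float = 0.45
    fs_emg: float = 1000.0
    fs_marker: float = 100.0
    sdn_coefficient: float = 0.2
    baseline_noise_sd: float = 0.02
    artifact_channels: tuple[str, ...] = ("BF", "GLU")
    artifact_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if min(self.cycle_duration_mean, self.fs_emg, self.fs_marker) <= 0:
            raise ValueError("durations and sampling rates must be positive")
        if not 0 < self.upward_fraction < 1:
            raise ValueError("upward_fraction must lie in (0, 1)")
        if self.cycle_duration_cv < 0 or self.sdn_coefficient < 0:
            raise ValueError("cycle_duration_cv and sdn_coefficient must be >= 0")
        if self.baseline_noise_sd < 0 or self.artifact_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    W: np.ndarray                 # muscles x k, unit-norm columns
    activations: np.ndarray       # k x samples, nonnegative
    events: CycleEvents           # true cycle/phase boundaries (EMG rate)
    envelope: np.ndarray          # muscles x samples true envelope


@dataclass(frozen=True)
class EmgTrial:
    """One synthetic trial: raw EMG, sacrum trace, rates, labels, truth."""

    emg: np.ndarray
    sacrum_ap: np.ndarray
    fs_emg: float
    fs_marker: float
    muscle_labels: tuple[str, ...]
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        emg = np.asarray(self.emg, dtype=float)
        object.__setattr__(self, "emg", emg)
        object.__setattr__(self, "sacrum_ap", np.asarray(self.sacrum_ap, dtype=float))
        if emg.ndim != 2 or emg.shape[0] != len(self.muscle_labels):
            raise ValueError("emg must have one row per muscle label")
        if not np.all(np.isfinite(emg)):
            raise ValueError("emg contains non-finite values")


def make_ground_truth_synergies(k_true: int = 3, seed: int = 0) -> GroundTruthSynergies:
    """Build a ground-truth synergy set with the sit-to-stand functional groups.

    For ``k_true <= 3`` the columns are seeded from the three functional-group
    templates (knee extensors, plantar flexors, ankle/hip) with mild
    seed-dependent weight jitter that preserves each column's dominant
    muscles; extra columns beyond three are random nonnegative patterns.
    """
    if not 1 <= k_true <= len(MUSCLES):
        raise ValueError(f"k_true must be in [1, {len(MUSCLES)}], got {k_true}")
    rng = _rng(seed, 0)
    cols = []
    for i in range(k_true):
        if i in _TEMPLATES:
            base = np.array(_TEMPLATES[i], dtype=float)
            col = base * (1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=base.size))
            col += 0.02 * rng.uniform(0.0, 1.0, size=base.size)
        else:
            col = rng.uniform(0.0, 1.0, size=len(MUSCLES)) ** 2 + 0.02
        cols.append(np.clip(col, 0.0, None))
    W = np.column_stack(cols)
    W /= np.linalg.norm(W, axis=0)
    return GroundTruthSynergies(W=W)


def _cycle_layout(cfg: TrialConfig, rng: np.random.Generator) -> CycleEvents:
    durations = cfg.cycle_duration_mean * (
        1.0 + cfg.cycle_duration_cv * rng.standard_normal(cfg.n_cycles)
    )
    durations = np.clip(durations, 0.3 * cfg.cycle_duration_mean, None)
    cycles = []
    cursor = 0
    for dur in durations:
        n = max(int(round(dur * cfg.fs_emg)), 4)
        n_up = int(round(cfg.upward_fraction * n))
        n_up = min(max(n_up, 1), n - 1)
        cycles.append((cursor, cursor + n_up, cursor + n))
        cursor += n
    return CycleEvents(cycles=tuple(cycles), fs=cfg.fs_emg)


def make_activations(
    cfg: TrialConfig, k_true: int, seed: int | None = None
) -> tuple[np.ndarray, CycleEvents]:
    """Generate k phase-locked nonnegative activation profiles and the events.

    Each synergy fires one smooth Gaussian burst per cycle, centered in its
    preferred window (upward phase, downward phase, or around the phase
    transition, cycling through those assignments for k > 3) with per-cycle
    amplitude and timing jitter.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if seed is None:
        seed = cfg.seed
    layout_rng = _rng(seed, 1)
    burst_rng = _rng(seed, 2)
    events = _cycle_layout(cfg, layout_rng)
    n_samples = events.n_samples
    t = np.arange(n_samples)
    activations = np.zeros((k_true, n_samples))
    for i in range(k_true):
        phase = _TEMPLATE_PHASE[i % 3]
        for start, transition, end in events.cycles:
            if phase == "upward":
                lo, hi = start, transition
            elif phase == "downward":
                lo, hi = transition, end
            else:  # straddles the transition
                half = min(transition - start, end - transition)
                lo, hi = transition - half, transition + half
            span = hi - lo
            center = lo + 0.5 * span + 0.05 * span * burst_rng.standard_normal()
            width = 0.18 * span
            amp = 1.0 + 0.15 * burst_rng.standard_normal()
            amp = max(amp, 0.2)
            seg = slice(start, end)
            activations[i, seg] += amp * np.exp(
                -0.5 * ((t[seg] - center) / max(width, 1.0)) ** 2
            )
    return activations, events


def normalized_true_synergies(trial: EmgTrial) -> np.ndarray:
    """Ground-truth synergies expressed in the pipeline's normalized units.

    The preprocessing chain divides each muscle's envelope by its median
    per-cycle peak, which rescales the rows of the effective mixing matrix;
    recovered synergies therefore live in that rescaled space.  This returns
    the true W with the same per-muscle rescaling applied (computed from the
    noise-free true envelope) and columns re-normalized, i.e. what a perfect
    extraction from normalized envelopes would yield.
    """
    if trial.ground_truth is None:
        raise ValueError("trial carries no ground truth")
    gt = trial.ground_truth
    peaks = np.column_stack(
        [gt.envelope[:, s:e].max(axis=1) for s, e in gt.events.whole_segments()]
    )
    divisors = np.median(peaks, axis=1)
    if np.any(divisors <= 0):
        raise ValueError("a muscle has zero true envelope peak")
    Wn = gt.W / divisors[:, None]
    return Wn / np.linalg.norm(Wn, axis=0)


def _marker_trace(events: CycleEvents, cfg: TrialConfig) -> np.ndarray:
    """Raised-cosine sacrum displacement whose velocity flips sign exactly
    at the phase transitions: forward excursion during the upward phase,
    return during the downward phase."""
    n_marker = int(round(events.n_samples * cfg.fs_marker / cfg.fs_emg))
    ratio = cfg.fs_marker / cfg.fs_emg
    x = np.zeros(n_marker)
    for start, transition, end in events.cycles:
        s, tr, e = (int(round(v * ratio)) for v in (start, transition, end))
        e = min(e, n_marker)
        tr = min(tr, e - 1)
        if tr > s:
            u = np.arange(s, tr) - s
            x[s:tr] = 0.5 * (1.0 - np.cos(np.pi * u / (tr - s)))
        if e > tr:
            d = np.arange(tr, e) - tr
            x[tr:e] = 0.5 * (1.0 + np.cos(np.pi * d / (e - tr)))
    return x


def _bandlimited_carrier(
    rng: np.random.Generator, shape: tuple[int, int], fs: float,
    low: float = 20.0, high: float = 450.0,
) -> np.ndarray:
    """Zero-mean band-limited noise carrier, scaled so E|carrier| = 1.

    The unit mean absolute value makes rectification + low-pass of
    (envelope x carrier) recover the envelope with approximately unit gain.
    """
    high = min(high, 0.49 * fs)
    noise = rng.standard_normal(shape)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, noise, axis=-1)
    mean_abs = np.mean(np.abs(carrier), axis=-1, keepdims=True)
    return carrier / mean_abs


def _artifact_bursts(
    rng: np.random.Generator, events: CycleEvents, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-RMS broadband artifact: random-onset bursts of low-pass-heavy
    noise, so a 40 Hz high-pass attenuates it only partially."""
    wave = np.zeros(n_samples)
    sos = signal.butter(2, 120.0, btype="lowpass", fs=fs, output="sos")
    for start, _, end in events.cycles:
        if rng.uniform() > 0.7:
            continue
        dur = int(rng.uniform(0.15, 0.5) * fs)
        dur = min(dur, end - start)
        onset = start + int(rng.uniform(0, max(end - start - dur, 1)))
        burst = signal.sosfiltfilt(sos, rng.standard_normal(dur))
        burst *= signal.windows.tukey(dur, alpha=0.25)
        wave[onset:onset + dur] += burst
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave /= rms
    return wave


def synthesize_trial(W_true: GroundTruthSynergies, cfg: TrialConfig) -> EmgTrial:
    """Render a raw sEMG trial plus sacrum trace from true synergies.

    Per channel the raw signal is (true envelope) x (band-limited carrier)
    plus white baseline noise and signal-dependent noise whose standard
    deviation is ``sdn_coefficient`` times the true envelope.  Channels in
    ``cfg.artifact_channels`` additionally receive broadband movement-artifact
    bursts scaled to ``cfg.artifact_amplitude`` times the clean channel RMS.
    """
    unknown = set(cfg.artifact_channels) - set(W_true.muscle_labels)
    if unknown:
        raise ValueError(f"artifact_channels not in muscle_labels: {sorted(unknown)}")

    activations, events = make_activations(cfg, W_true.k, seed=cfg.seed)
    envelope = W_true.W @ activations  # muscles x samples
    n_ch, n_samples = envelope.shape

    carrier = _bandlimited_carrier(_rng(cfg.seed, 3), (n_ch, n_samples), cfg.fs_emg)
    emg = envelope * carrier
    if cfg.baseline_noise_sd > 0:
        emg = emg + cfg.baseline_noise_sd * _rng(cfg.seed, 4).standard_normal(emg.shape)
    if cfg.sdn_coefficient > 0:
        emg = emg + cfg.sdn_coefficient * envelope * _rng(cfg.seed, 5).standard_normal(
            emg.shape
        )

    if cfg.artifact_amplitude > 0:
        art_rng = _rng(cfg.seed, 6)
        for ch in cfg.artifact_channels:
            idx = W_true.muscle_labels.index(ch)
            clean_rms = np.sqrt(np.mean(emg[idx] ** 2))
            wave = _artifact_bursts(art_rng, events, n_samples, cfg.fs_emg)
            emg[idx] = emg[idx] + cfg.artifact_amplitude * clean_rms * wave

    sacrum = _marker_trace(events, cfg)
    truth = GroundTruth(
        W=W_true.W.copy(), activations=activations, events=events, envelope=envelope
    )
    return EmgTrial(
        emg=emg,
        sacrum_ap=sacrum,
        fs_emg=cfg.fs_emg,
        fs_marker=cfg.fs_marker,
        muscle_labels=W_true.muscle_labels,
        ground_truth=truth,
    )
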