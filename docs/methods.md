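# Methods

## Model

The synchronous muscle-synergy model factorizes a nonnegative envelope
matrix M (N_s samples × N_m muscles) as M ≈ C·Wᵀ, where the k columns of W
(N_m × k, unit Euclidean norm) are fixed spatial synergies and the columns
of C (N_s × k) their nonnegative temporal activations. The assumptions are
the standard ones of the model: synergies are constant within a trial,
activations are nonnegative, and everything the model should explain lives
in the amplitude envelope (40–350 Hz band-passed, rectified, 10 Hz
low-passed, per-muscle normalized sEMG).

## Processing chain and its parameters

| stage | parameter | default | why |
|---|---|---|---|
| band-pass | 40–350 Hz, 4th-order Butterworth | fixed | standard sEMG denoising band; 40 Hz floor also attenuates motion artifact |
| envelope | 10 Hz low-pass, 4th order | fixed | retains burst dynamics of a ~2 s movement cycle |
| zero-phase filtering | on (`zero_phase=False` available) | on | no group delay, so envelope bursts stay aligned with kinematic events; the stated order is the designed filter's (attenuation doubles) |
| normalization | median per-cycle peak, per muscle | — | robust to a single outlier cycle; median peak of 1 afterwards |
| segmentation smoothing | 5 Hz low-pass on position, central differences | 5 Hz | suppress marker jitter before sign-change detection |
| debounce | `min_phase_duration` 0.3 s | 0.3 s | phases shorter than this are physiologically implausible and treated as jitter |
| NMF | 10 restarts, ≤ 2000 iterations | — | multi-restart multiplicative updates; see below |
| AIC noise | `sdn_coefficient` 0.2, smoothing 2 Hz | 0.2 | signal-dependent noise SD as a fraction of the envelope; 0.2 matches the demodulation noise a rectify+low-pass estimator leaves on a band-limited carrier |
| wavelet DoF | sym4, maximum useful level, universal threshold | — | see below |
| surrogates | 50 shuffles, 95th percentile | — | within-column permutation; linear-interpolation percentile |

Indexing is 0-based and half-open everywhere: cycle i covers samples
`[start, end)`, upward phase `[start, transition)`. Envelopes are not
time-normalized or resampled across cycles; segments are concatenated at
native length and rate.

## Model-order criterion

For each candidate order k the criterion is

    AIC(k) = Σ_{i,j} (M_{ij} − M̂_{ij})² / (σ²_M + σ²_SDN;ij)
             + 2·k·N_m
             + 2·Σ_{i=1..k} N_DoF(c_i)

- **σ²_M** defaults to the mean squared residual of an NMF at full order
  k = N_m (the variance no admissible synergy model explains), with a tiny
  relative floor (10⁻¹² of the mean squared envelope) so that exactly
  low-rank, noise-free input cannot collapse the weight to numerical dust.
  A fixed value can be supplied instead.
- **σ²_SDN** is (`sdn_coefficient` × M̃)², M̃ a 2 Hz zero-phase low-pass of
  each envelope column. Using a smoothed copy — never the reconstruction —
  keeps the weighting independent of the candidate model being scored, and
  avoids tying the error weight to the estimate itself.
- **N_DoF(c)** is the number of wavelet coefficients of the activation
  profile c whose magnitude exceeds the universal threshold σ̂·√(2 ln L),
  with σ̂ the median-rule (MAD/0.6745) estimate from the finest-detail
  coefficients. The decomposition uses sym4, periodized, at the maximum
  useful level, and counts detail and coarse approximation coefficients
  alike. On a 1 kHz envelope the raw sample count wildly overstates the
  information content; this term charges each activation profile for its
  *effective* complexity. By construction the universal threshold leaves
  essentially no significant coefficients on pure zero-mean white noise —
  the mechanism that penalizes over-factorization is that activation
  profiles tracking *signal-dependent* noise are amplitude-modulated, hence
  heavy-tailed in wavelet space, and rack up large DoF counts.

Selection is the global AIC minimum over k = 1..N_m, ties broken toward the
smaller order.

### Numerical choices in the NMF

Frobenius-norm Lee–Seung multiplicative updates (objective provably
non-increasing per iteration; asserted in the test suite). Ten random
nonnegative initializations are run for a 50-iteration exploration phase and
the best (lowest residual) is polished to convergence — "best of n restarts"
in two phases. Convergence is declared when the objective decrease between
checks (every 10 iterations) falls below `tol` (10⁻⁶) × ‖M‖²_F; normalizing
to the data energy rather than the current objective keeps the rule
meaningful at k = N_m, where the residual itself approaches zero. A 10⁻¹²
additive constant guards the update denominators. After convergence W
columns are scaled to unit norm with the scale pushed into C.

### Cross-validation

Fixed-W activations are re-fit by exact nonnegative least squares: all 2^k
candidate active sets are solved simultaneously for every sample row and the
KKT-optimal one picked per row (scipy's NNLS is the per-row fallback and the
test oracle). R² = 1 − SSE/SST with SST about the grand mean of the target
matrix (uncentered variant available). Surrogate W matrices permute entries
within each column — preserving each synergy's weight distribution while
destroying its muscle assignment; whole-matrix shuffling is available via
`scheme=`. Thresholds are computed per (W-source, target) pairing.

## What the generator emulates — and what it does not

Each trial is built from k_true unit-norm synergy templates (for k = 3: knee
extensors VL/RF with minor BF/GLU; plantar flexors SOL/GMED/PER with GLU;
TA with ankle/hip support) jittered ±10% per seed. Activations are one
Gaussian burst per synergy per cycle, phase-locked (upward / downward /
transition-straddling) with 5% timing and 15% amplitude jitter. Defaults:
15 cycles of 2.0 s mean duration (CV 0.1) ≈ a 30-s recording, upward
fraction 0.45, EMG 1 kHz, marker 100 Hz. Raw EMG is the true envelope ×
a 20–450 Hz Gaussian carrier scaled to E|carrier| = 1 (so rectify+low-pass
demodulates with unit gain), plus white baseline noise (SD 0.02 envelope
units) and signal-dependent noise (SD = 0.2 × envelope). Artifacts, when
enabled, are 0.15–0.5 s bursts of 120 Hz low-passed (order 2, hence
broadband-skirted) noise on BF/GLU in ~70% of cycles, scaled to a multiple
of the clean channel RMS — deliberately only partially removed by the 40 Hz
high-pass edge, like chair-contact artifacts. The sacrum trace is a
raised-cosine excursion per phase, so velocity zero-crossings sit exactly at
the phase boundaries. All randomness derives from one integer seed through
fixed SeedSequence streams (one per noise source), making trials
bit-reproducible.

Not emulated: motor-unit physiology, electrode crosstalk, fatigue and
accommodation drift across cycles, inter-subject variability in template
structure, and force-plate/kinematic detail beyond the single marker trace.
Passing recovery tests therefore shows the pipeline is correct and
well-conditioned *under the synchronous synergy model with realistic noise*,
not that real recordings satisfy that model.

A subtlety worth knowing when comparing recovered synergies to ground
truth: per-muscle amplitude normalization rescales each row of the effective
mixing matrix, so extracted W lives in normalized-envelope units.
`normalized_true_synergies()` returns the ground truth in the same units
(typical matched cosine ≈ 0.99 at moderate noise; comparing against raw
W_true instead biases the similarity down to ≈ 0.90 by construction).

## Degenerate inputs and edge rules

- A muscle whose median per-cycle peak is zero raises a degenerate-channel
  error naming the channel.
- A monotone (or constant) marker trace raises a no-cycles error; the first
  movement onset, which produces no velocity sign change when the trace
  starts from rest, is inferred as the last near-zero-velocity sample before
  the first large upward excursion.
- Activation profiles shorter than the wavelet filter support are rejected;
  an all-zero profile has 0 DoF.
- σ²_M + σ²_SDN must be positive everywhere, else a zero-variance error.
- Sparsity counts entries *strictly* below the vector mean (a constant
  vector has sparsity 0); ties at the mean count as not-below.
- transform(X) = ln(1 − X) requires X < 1.

## Problem sizes used in the shipped studies

The recovery studies run 20 trials × 15 cycles at 1 kHz (envelope matrices
≈ 30 000 × 8), candidate orders 1..8, 50 surrogates per threshold — a few
minutes on one CPU. Unit tests use 5–6-cycle trials; order-selection
assertions use full-length trials because short signals genuinely blur the
criterion (selection variance rises, mirroring the behaviour of short
clinical tests).

## Known limitations

- The signal-dependent variance model is quadratic in the smoothed envelope
  with a single global coefficient; no per-muscle coefficients.
- The N_syn-specific pooling averages R² per (k_W, k_data) cell without
  weighting by trial length.
- Order selection on very short segments (e.g. 5 downward phases alone) is
  noticeably less stable — an inherent property of the criterion on little
  data, not a numerical defect.
- The three-way mixed ANOVA itself is out of scope: the stats module exports
  tidy transformed tables for statsmodels/R.
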