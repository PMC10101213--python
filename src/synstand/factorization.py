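"""Synergy extraction by NMF and model-order selection with a modified AIC.

The envelope matrix M (samples x muscles) is factorized as M ~ C @ W.T with
nonnegative activations C and unit-norm spatial synergies W, using Frobenius
multiplicative updates.  The number of synergies is selected by minimizing

    AIC(k) = sum_{i,j} (M_ij - Mhat_ij)^2 / (sigma2_M + sigma2_SDN_ij)
             + 2 k N_m + 2 sum_i N_DoF(c_i)

where the residual is weighted by a constant noise variance plus an additive
signal-dependent term (standard deviation proportional to a smoothed copy of
the data, reflecting the mean-variance relationship of motor output), and the
effective degrees of freedom of each temporal activation profile c_i are
estimated as the number of its wavelet coefficients exceeding the universal
threshold.  The DoF term is what keeps the criterion honest on highly
oversampled envelopes: activation profiles that merely track noise require
many significant coefficients and are penalized accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .exceptions import ZeroVarianceError
from .preprocessing import EnvelopeMatrix

__all__ = [
    "SynergyModel",
    "NoiseModel",
    "AicCurve",
    "nmf",
    "estimate_noise",
    "wavelet_dof",
    "compute_aic",
    "aic_terms",
    "select_nsyn",
]

_EPS = 1e-12


def _data_matrix(M) -> np.ndarray:
    X = M.M if isinstance(M, EnvelopeMatrix) else np.asarray(M, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x muscles matrix")
    if np.any(X < 0):
        raise ValueError("data must be nonnegative")
    return X


@dataclass(frozen=True)
class SynergyModel:
    """One NMF solution: W (muscles x k, unit-norm columns), C (samples x k)."""

    W: np.ndarray
    C: np.ndarray
    k: int
    r2: float
    sse: float
    objective_history: np.ndarray | None = None
    seed: int | None = None

    @property
    def reconstruction(self) -> np.ndarray:
        return self.C @ self.W.T


@dataclass(frozen=True)
class NoiseModel:
    """Noise variances entering the AIC residual weighting.

    ``sigma2_M`` is a constant variance floor (by default the mean squared
    residual of the NMF at k = N_m); ``sigma2_SDN`` is the elementwise
    signal-dependent variance (coefficient times a low-pass-smoothed copy of
    the data, squared).  The smoothed copy - never the reconstruction - is
    used so the weighting does not depend on the model being scored.
    """

    sigma2_M: float
    sigma2_SDN: np.ndarray
    sdn_coefficient: float
    smoothing_cutoff: float

    def __post_init__(self) -> None:
        if self.sigma2_M < 0 or np.any(self.sigma2_SDN < 0):
            raise ValueError("variances must be nonnegative")


@dataclass(frozen=True)
class AicCurve:
    """AIC(k) over a candidate range with the selected order (argmin,
    ties broken toward the smallest k)."""

    k_values: tuple[int, ...]
    aic_values: np.ndarray
    selected_k: int
    dof_per_k: tuple[int, ...]
    residual_per_k: np.ndarray
    models: dict | None = None

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.aic_values):
            raise ValueError("k_values and aic_values must align")
        if self.selected_k not in self.k_values:
            raise ValueError("selected_k must be one of k_values")


def _mu_run(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    track: bool,
    C0: np.ndarray | None = None,
    H0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One multiplicative-update run; returns C, H, final SSE, history."""
    n_s, n_m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    C = rng.uniform(0.1, 1.0, size=(n_s, k)) * scale if C0 is None else C0.copy()
    H = rng.uniform(0.1, 1.0, size=(k, n_m)) * scale if H0 is None else H0.copy()
    norm_x2 = float(np.einsum("ij,ij->", X, X))

    def sse(C, H, XHt, HHt):
        # ||X - C H||^2 expanded; XHt and HHt are reused from the C update.
        return float(
            norm_x2
            - 2.0 * np.einsum("ij,ij->", C, XHt)
            + np.einsum("ij,ij->", C @ HHt, C)
        )

    prev = sse(C, H, X @ H.T, H @ H.T)
    ref = max(norm_x2, _EPS)  # convergence scale: the data energy
    history = [prev] if track else []
    check_every = 1 if track else 10
    for it in range(1, max_iter + 1):
        # H update (Lee-Seung, Frobenius norm)
        CtX = C.T @ X
        CtC = C.T @ C
        H *= CtX / (CtC @ H + _EPS)
        # C update
        XHt = X @ H.T
        HHt = H @ H.T
        C *= XHt / (C @ HHt + _EPS)
        if track or it % check_every == 0 or it == max_iter:
            cur = sse(C, H, XHt, HHt)
            if track:
                history.append(cur)
            # Converged when the decrease since the previous check is a
            # negligible fraction of the data energy ||X||^2.
            if prev - cur <= tol * ref:
                prev = cur
                break
            prev = cur
    return C, H, prev, history


def nmf(
    M,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    track_objective: bool = False,
) -> SynergyModel:
    """Nonnegative factorization M ~ C @ W.T by multiplicative updates.

    Runs ``n_restarts`` random nonnegative initializations for a short
    exploration phase, then polishes the best one (lowest residual) to the
    full tolerance.  The Frobenius objective is non-increasing across
    iterations by construction of the updates.  Synergy columns of W are
    normalized to unit Euclidean norm afterwards, with the scale pushed into C.
    """
    X = _data_matrix(M)
    n_s, n_m = X.shape
    if not 1 <= k <= n_m:
        raise ValueError(f"k must be in [1, {n_m}], got {k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    root = np.random.SeedSequence([int(seed), 7])
    streams = [np.random.default_rng(s) for s in root.spawn(n_restarts)]

    explore_iter = min(max_iter, 50)
    best = None
    for rng in streams:
        C, H, val, hist = _mu_run(X, k, rng, explore_iter, tol * 100, track_objective)
        if best is None or val < best[2]:
            best = (C, H, val, hist)
    C, H, val, hist = best
    C, H, val, hist2 = _mu_run(
        X, k, streams[0], max_iter, tol, track_objective, C0=C, H0=H
    )
    if track_objective:
        hist = hist + hist2[1:]

    W = H.T.copy()
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W /= norms
    C = C * norms
    sst = float(np.sum((X - X.mean()) ** 2))
    r2 = 1.0 - val / sst if sst > 0 else 1.0
    return SynergyModel(
        W=W,
        C=C,
        k=k,
        r2=r2,
        sse=val,
        objective_history=np.asarray(hist) if track_objective else None,
        seed=seed,
    )


def estimate_noise(
    M,
    sdn_coefficient: float = 0.2,
    smoothing_cutoff: float = 2.0,
    fs_env: float = 1000.0,
    sigma2_m: float | None = None,
    seed: int = 0,
) -> NoiseModel:
    """Build the noise model weighting the AIC residual.

    ``sigma2_SDN[i, j] = (sdn_coefficient * Msmooth[i, j])**2`` where
    ``Msmooth`` is each muscle column low-pass filtered at
    ``smoothing_cutoff`` (zero phase).  When ``sigma2_m`` is not given, it is
    estimated as the mean squared residual of an NMF at full order k = N_m,
    i.e. the part of the data no synergy model of admissible order explains.
    """
    X = _data_matrix(M)
    n_s, n_m = X.shape
    if sdn_coefficient < 0:
        raise ValueError("sdn_coefficient must be >= 0")
    if sdn_coefficient == 0:
        sigma2_sdn = np.zeros_like(X)
    else:
        if smoothing_cutoff <= 0 or smoothing_cutoff >= fs_env / 2:
            raise ValueError("smoothing_cutoff must lie in (0, fs_env / 2)")
        sos = signal.butter(2, smoothing_cutoff, btype="lowpass", fs=fs_env, output="sos")
        smooth = np.clip(signal.sosfiltfilt(sos, X, axis=0), 0.0, None)
        sigma2_sdn = (sdn_coefficient * smooth) ** 2
    if sigma2_m is None:
        full = nmf(X, k=n_m, seed=seed, n_restarts=3, max_iter=500)
        # Tiny relative floor so exactly-low-rank (noise-free) data cannot
        # collapse the variance to numerical-convergence dust.
        sigma2_m = max(full.sse / X.size, 1e-12 * float(np.mean(X**2)))
    return NoiseModel(
        sigma2_M=float(sigma2_m),
        sigma2_SDN=sigma2_sdn,
        sdn_coefficient=sdn_coefficient,
        smoothing_cutoff=smoothing_cutoff,
    )


def wavelet_dof(
    activation: np.ndarray,
    wavelet: str = "sym4",
    level: int | None = None,
) -> int:
    """Effective degrees of freedom of a temporal activation profile.

    The profile is decomposed with a multi-level DWT (periodized, so the
    coefficient count equals the profile length); the noise standard
    deviation is estimated from the finest-detail coefficients by the median
    rule (MAD / 0.6745) and the DoF is the number of coefficients - details
    and coarse approximation alike - whose magnitude exceeds the universal
    threshold sigma * sqrt(2 ln L).
    """
    x = np.asarray(activation, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("activation profile must have at least 2 samples")
    if not np.any(x):
        return 0
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(x.size, wav.dec_len)
    if max_level < 1:
        raise ValueError(
            f"profile of length {x.size} is shorter than the {wavelet} filter support"
        )
    lvl = max_level if level is None else min(int(level), max_level)
    if lvl < 1:
        raise ValueError("level must be >= 1")
    coeffs = pywt.wavedec(x, wav, level=lvl, mode="periodization")
    allc = np.concatenate([np.abs(c) for c in coeffs])
    finest = np.abs(coeffs[-1])
    sigma = np.median(finest) / 0.6745
    sigma = max(sigma, 1e-12 * allc.max())
    threshold = sigma * np.sqrt(2.0 * np.log(x.size))
    dof = int(np.count_nonzero(allc > threshold))
    return min(dof, x.size)


@dataclass(frozen=True)
class AicTerms:
    """The three AIC addends, kept separate for inspection."""

    residual: float
    order_penalty: float
    dof_penalty: float
    dof_total: int

    @property
    def total(self) -> float:
        return self.residual + self.order_penalty + self.dof_penalty


def aic_terms(
    M,
    model: SynergyModel,
    noise: NoiseModel,
    wavelet: str = "sym4",
    level: int | None = None,
    dof_total: int | None = None,
) -> AicTerms:
    """Evaluate the three addends of the modified AIC for one fitted model."""
    X = _data_matrix(M)
    n_s, n_m = X.shape
    if model.W.shape[0] != n_m or model.C.shape[0] != n_s:
        raise ValueError("model shapes do not match the data")
    denom = noise.sigma2_M + noise.sigma2_SDN
    if np.isscalar(denom) or denom.ndim == 0:
        denom = np.full_like(X, float(denom))
    if denom.shape != X.shape:
        raise ValueError("sigma2_SDN shape does not match the data")
    if np.any(denom <= 0):
        raise ZeroVarianceError("sigma2_M + sigma2_SDN must be positive everywhere")
    resid = X - model.reconstruction
    residual = float(np.sum(resid**2 / denom))
    if dof_total is None:
        dof_total = sum(
            wavelet_dof(model.C[:, i], wavelet=wavelet, level=level)
            for i in range(model.k)
        )
    return AicTerms(
        residual=residual,
        order_penalty=2.0 * model.k * n_m,
        dof_penalty=2.0 * dof_total,
        dof_total=int(dof_total),
    )


def compute_aic(
    M,
    model: SynergyModel,
    noise: NoiseModel,
    wavelet: str = "sym4",
    level: int | None = None,
    dof_total: int | None = None,
) -> float:
    """Modified AIC of one fitted synergy model (lower is better)."""
    return aic_terms(M, model, noise, wavelet=wavelet, level=level,
                     dof_total=dof_total).total


def select_nsyn(
    M,
    k_range: tuple[int, ...] | range | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    sdn_coefficient: float = 0.2,
    smoothing_cutoff: float = 2.0,
    fs_env: float | None = None,
    sigma2_m: float | None = None,
    wavelet: str = "sym4",
    level: int | None = None,
    keep_models: bool = True,
) -> AicCurve:
    """Fit NMF over candidate orders and select the AIC minimum.

    The noise model is estimated once from the data (independently of any
    candidate fit); each candidate order is then scored with the modified
    AIC and the global minimum selected, with ties broken toward the
    smallest order.
    """
    X = _data_matrix(M)
    n_m = X.shape[1]
    if k_range is None:
        k_range = range(1, n_m + 1)
    k_values = tuple(int(k) for k in k_range)
    if not k_values or any(not 1 <= k <= n_m for k in k_values):
        raise ValueError(f"candidate orders must lie in [1, {n_m}]")
    if fs_env is None:
        fs_env = M.fs if isinstance(M, EnvelopeMatrix) else 1000.0

    noise = estimate_noise(
        X,
        sdn_coefficient=sdn_coefficient,
        smoothing_cutoff=smoothing_cutoff,
        fs_env=fs_env,
        sigma2_m=sigma2_m,
        seed=seed,
    )
    aics = []
    dofs = []
    residuals = []
    models = {} if keep_models else None
    for k in k_values:
        model = nmf(X, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol)
        terms = aic_terms(X, model, noise, wavelet=wavelet, level=level)
        aics.append(terms.total)
        dofs.append(terms.dof_total)
        residuals.append(terms.residual)
        if keep_models:
            models[k] = model
    aic_values = np.asarray(aics)
    selected = k_values[int(np.argmin(aic_values))]  # argmin takes the first
    return AicCurve(
        k_values=k_values,
        aic_values=aic_values,
        selected_k=selected,
        dof_per_k=tuple(dofs),
        residual_per_k=np.asarray(residuals),
        models=models,
    )
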