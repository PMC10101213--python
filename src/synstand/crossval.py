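"""Cross-validation of synergy sets against a shuffled-surrogate null.

A set of spatial synergies W extracted from one condition is scored on how
well it reconstructs the envelope data of another: activations are re-fit by
nonnegative least squares with W held fixed, and the reconstruction R^2 is
compared with the 95th percentile of R^2 obtained from randomly shuffled
copies of W (chance level).  Two modalities are provided: *trial-specific*
(per subject, all six condition pairings) and *N_syn-specific* (all W sets
pooled across subjects/trials, aggregated by the model orders of the
reconstructing set and of the target data).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls as _scipy_nnls

from .factorization import SynergyModel
from .preprocessing import CONDITIONS, EnvelopeMatrix

__all__ = [
    "CrossValResult",
    "order_synergies",
    "match_synergies",
    "nnls_matrix",
    "reconstruct_fixed_w",
    "surrogate_threshold",
    "trial_specific",
    "nsyn_specific",
]


@dataclass(frozen=True)
class CrossValResult:
    """Cross-reconstruction R^2 with matching surrogate thresholds.

    In trial-specific mode both frames are 6x6 (rows: condition providing W,
    columns: reconstructed condition); in N_syn-specific mode cells are
    indexed by (k of the reconstructing W, k of the target data) and hold
    means over all pooled pairings, with the tidy per-pairing records kept
    alongside.
    """

    mode: str
    r2: pd.DataFrame
    surrogate_threshold: pd.DataFrame
    n_surrogates: int
    seed: int
    records: pd.DataFrame | None = None


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    return An.T @ Bn


def match_synergies(W: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one column matching by total cosine similarity.

    Returns ``(ref_idx, w_idx, sims)``: matched column pairs (Hungarian
    assignment on the pairwise cosine matrix, min(k_ref, k) pairs) and their
    cosine similarities.
    """
    if W.shape[0] != reference.shape[0]:
        raise ValueError("muscle counts differ between W and reference")
    cos = _cosine_matrix(reference, W)
    ref_idx, w_idx = linear_sum_assignment(-cos)
    return ref_idx, w_idx, cos[ref_idx, w_idx]


def order_synergies(
    W_set: Sequence[np.ndarray], reference: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Reorder each W in a set so matched columns align with the reference.

    Columns are permuted so that column ``i`` of the result best matches
    column ``i`` of the reference; unmatched extra columns (k > k_ref) are
    appended after the matched ones.  Returns the permuted set and the
    per-matrix cosine similarities of the matched columns (in reference
    order).
    """
    ordered = []
    scores = []
    for W in W_set:
        ref_idx, w_idx, sims = match_synergies(W, reference)
        order = np.argsort(ref_idx)
        matched = w_idx[order]
        rest = [j for j in range(W.shape[1]) if j not in set(matched.tolist())]
        ordered.append(W[:, list(matched) + rest])
        scores.append(sims[order])
    return ordered, scores


def nnls_matrix(W: np.ndarray, X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Solve min ||X - C @ W.T||_F^2 with C >= 0, row by row, exactly.

    Every row of X shares the same design W (muscles x k), so for small k
    all 2^k candidate active sets are solved simultaneously for all rows and
    the KKT-optimal one selected per row; rows that no candidate satisfies
    (numerically degenerate W) fall back to scipy's NNLS.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    n_s, n_m = X.shape
    if W.shape[0] != n_m:
        raise ValueError("W rows must match the muscle dimension of the data")
    k = W.shape[1]
    if k > 12:
        return np.vstack([_scipy_nnls(W, x)[0] for x in X])

    G = W.T @ W                      # k x k
    B = X @ W                        # n_s x k,   B[s] = W.T @ x_s
    scale = max(np.abs(B).max(), 1.0)
    atol = tol * scale

    C = np.zeros((n_s, k))
    solved = np.zeros(n_s, dtype=bool)
    # Empty support: optimal iff the gradient at zero is nonnegative,
    # i.e. W.T @ x <= 0 for the row.
    solved |= np.all(B <= atol, axis=1)

    for size in range(1, k + 1):
        if solved.all():
            break
        for S in combinations(range(k), size):
            idx = list(S)
            GS = G[np.ix_(idx, idx)]
            try:
                coef = np.linalg.solve(GS, B[:, idx].T).T  # n_s x |S|
            except np.linalg.LinAlgError:
                continue
            feasible = np.all(coef >= -atol, axis=1)
            # KKT: gradient on the inactive set must be nonnegative.
            comp = [j for j in range(k) if j not in S]
            if comp:
                grad = coef @ G[np.ix_(idx, comp)] - B[:, comp]
                optimal = np.all(grad >= -atol, axis=1)
            else:
                optimal = np.ones(n_s, dtype=bool)
            take = feasible & optimal & ~solved
            if np.any(take):
                sub = np.zeros((int(take.sum()), k))
                sub[:, idx] = np.clip(coef[take], 0.0, None)
                C[take] = sub
                solved[take] = True
        if solved.all():
            break

    for s in np.flatnonzero(~solved):
        C[s] = _scipy_nnls(W, X[s])[0]
    return C


def _r2(X: np.ndarray, Xhat: np.ndarray, centered: bool = True) -> float:
    sse = float(np.sum((X - Xhat) ** 2))
    ref = X.mean() if centered else 0.0
    sst = float(np.sum((X - ref) ** 2))
    return 1.0 - sse / sst if sst > 0 else 1.0


def reconstruct_fixed_w(
    M, W: np.ndarray, centered: bool = True
) -> tuple[np.ndarray, float]:
    """Re-fit nonnegative activations for fixed synergies W and score R^2.

    R^2 = 1 - SSE/SST with SST the total sum of squares about the grand mean
    (set ``centered=False`` for the uncentered variant).
    """
    X = M.M if isinstance(M, EnvelopeMatrix) else np.asarray(M, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    C = nnls_matrix(W, X)
    return C, _r2(X, C @ W.T, centered=centered)


def _shuffle_w(W: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    if scheme == "within_column":
        out = np.empty_like(W)
        for j in range(W.shape[1]):
            out[:, j] = rng.permutation(W[:, j])
        return out
    if scheme == "whole_matrix":
        flat = rng.permutation(W.ravel())
        return flat.reshape(W.shape)
    raise ValueError(f"unknown shuffle scheme {scheme!r}")


def surrogate_threshold(
    M,
    W: np.ndarray,
    n_surrogates: int = 50,
    percentile: float = 95.0,
    seed: int = 0,
    scheme: str = "within_column",
    centered: bool = True,
) -> float:
    """Chance-level R^2: 95th percentile over shuffled copies of W.

    Each surrogate permutes the entries within every column of W
    independently (preserving each synergy's weight distribution while
    destroying the muscle assignment), reconstructs the data, and records
    R^2; the percentile uses the linear-interpolation convention.
    """
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    r2s = np.empty(n_surrogates)
    for i in range(n_surrogates):
        Ws = _shuffle_w(np.asarray(W, dtype=float), rng, scheme)
        _, r2s[i] = reconstruct_fixed_w(M, Ws, centered=centered)
    return float(np.percentile(r2s, percentile))


def trial_specific(
    models: Mapping[str, SynergyModel],
    data: Mapping[str, EnvelopeMatrix],
    n_surrogates: int = 50,
    seed: int = 0,
    scheme: str = "within_column",
) -> CrossValResult:
    """Per-subject 6x6 cross-reconstruction: every condition's W against
    every condition's data, each pairing with its own surrogate threshold."""
    missing = [c for c in CONDITIONS if c not in models or c not in data]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    r2 = pd.DataFrame(index=list(CONDITIONS), columns=list(CONDITIONS), dtype=float)
    thr = r2.copy()
    for src in CONDITIONS:
        W = models[src].W
        for tgt in CONDITIONS:
            _, val = reconstruct_fixed_w(data[tgt], W)
            r2.loc[src, tgt] = val
            thr.loc[src, tgt] = surrogate_threshold(
                data[tgt], W, n_surrogates=n_surrogates, seed=seed, scheme=scheme
            )
    r2.index.name = thr.index.name = "w_source"
    r2.columns.name = thr.columns.name = "target"
    return CrossValResult(
        mode="trial", r2=r2, surrogate_threshold=thr,
        n_surrogates=n_surrogates, seed=seed,
    )


def nsyn_specific(
    models: Sequence[SynergyModel],
    data: Sequence[tuple[EnvelopeMatrix, int]],
    n_surrogates: int = 50,
    seed: int = 0,
    scheme: str = "within_column",
) -> CrossValResult:
    """Pooled cross-reconstruction aggregated by model order.

    ``data`` pairs each target envelope matrix with its own selected order.
    Every pooled W set reconstructs every target; R^2 values (and surrogate
    thresholds) are averaged into cells indexed by (k of the reconstructing
    W, k of the target data).
    """
    if not models or not data:
        raise ValueError("pooled models and data must be nonempty")
    rows = []
    for mi, model in enumerate(models):
        for di, (matrix, k_data) in enumerate(data):
            _, val = reconstruct_fixed_w(matrix, model.W)
            t = surrogate_threshold(
                matrix, model.W, n_surrogates=n_surrogates, seed=seed, scheme=scheme
            )
            rows.append(
                {"model": mi, "target": di, "k_w": model.k, "k_data": int(k_data),
                 "r2": val, "threshold": t}
            )
    records = pd.DataFrame(rows)
    r2 = records.pivot_table(index="k_w", columns="k_data", values="r2", aggfunc="mean")
    thr = records.pivot_table(
        index="k_w", columns="k_data", values="threshold", aggfunc="mean"
    )
    return CrossValResult(
        mode="nsyn", r2=r2, surrogate_threshold=thr,
        n_surrogates=n_surrogates, seed=seed, records=records,
    )
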