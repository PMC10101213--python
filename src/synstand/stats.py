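"""Descriptive statistics and analysis-ready exports.

Covers the two bespoke quantities of the analysis - the sparsity of spatial
synergy vectors and the variance-stabilizing log transform of reconstruction
R^2 values - and exports tidy long-format tables keyed by the experimental
factors (phase x length x subject) so that any off-the-shelf linear-model or
ANOVA routine can consume them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .crossval import CrossValResult
from .preprocessing import CONDITIONS

__all__ = ["SparsityReport", "sparsity", "transform_r2", "inverse_transform_r2",
           "condition_factors", "export_anova_table"]


@dataclass(frozen=True)
class SparsityReport:
    """Per-synergy sparsity (fraction of weights strictly below the vector
    mean) and the across-synergy mean, for a model of order k."""

    per_synergy: np.ndarray
    mean: float
    k: int


def sparsity(W: np.ndarray) -> SparsityReport:
    """Sparsity of each synergy vector: fraction of entries strictly below
    that vector's mean (ties at the mean count as not below).

    Invariant to positive rescaling of each column; rises when additional,
    single-muscle-dominated modules (e.g. artifact-driven ones) appear.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("W must be nonempty")
    if W.ndim == 1:
        W = W[:, None]
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    fractions = (W < W.mean(axis=0, keepdims=True)).mean(axis=0)
    return SparsityReport(
        per_synergy=fractions, mean=float(fractions.mean()), k=W.shape[1]
    )


def transform_r2(X):
    """Variance-stabilizing transform X' = ln(1 - X) for R^2-type values.

    Maps X in (-inf, 1) onto the real line (strictly decreasing); values at
    or above 1 are outside the domain.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X >= 1.0):
        raise ValueError("transform_r2 requires X < 1")
    out = np.log1p(-X)
    return float(out) if out.ndim == 0 else out


def inverse_transform_r2(Xp):
    """Inverse of :func:`transform_r2`: X = 1 - exp(X')."""
    Xp = np.asarray(Xp, dtype=float)
    out = 1.0 - np.exp(Xp)
    return float(out) if out.ndim == 0 else out


def condition_factors(condition: str) -> tuple[str, str]:
    """Decompose a condition label into its (phase, length) factors."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    length = "30s" if condition.startswith("30") else "5tsts"
    if condition.endswith("upward"):
        phase = "upward"
    elif condition.endswith("downward"):
        phase = "downward"
    else:
        phase = "whole"
    return phase, length


def export_anova_table(results: Mapping[str, CrossValResult]) -> pd.DataFrame:
    """Flatten trial-specific cross-validation results into a tidy table.

    One row per (subject, W-source condition): the subject identifier, the
    phase and length factors of the condition that provided the synergy set,
    the mean cross-reconstruction R^2 of that set over all six targets, and
    its ln(1 - R^2) transform.  Ready for a three-way mixed ANOVA with the
    subject as a random factor in any standard statistics package.
    """
    if not results:
        raise ValueError("results must be nonempty")
    rows = []
    for subject, res in results.items():
        if res.mode != "trial":
            raise ValueError("export_anova_table expects trial-specific results")
        for cond in CONDITIONS:
            phase, length = condition_factors(cond)
            value = float(res.r2.loc[cond].mean())
            rows.append(
                {"subject": subject, "phase": phase, "length": length,
                 "r2": value, "log_residual": transform_r2(value)}
            )
    return pd.DataFrame(rows)
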