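"""Paired-comparison statistics used to score each measure.

For every simulated experiment the two conditions are compared per measure
with a two-sided paired t test; the per-experiment effect size is
``d_z = t / sqrt(n)``.  Differences are taken as condition 1 minus
condition 2 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import UndefinedCorrelationError

__all__ = [
    "PairedResult",
    "DegenerateTestError",
    "UndefinedCorrelationError",
    "paired_t",
    "percent_significant",
    "condition_correlation",
    "partial_eta_squared",
]


class DegenerateTestError(ValueError):
    """The paired differences have zero variance; t is undefined."""


@dataclass(frozen=True)
class PairedResult:
    """Two-sided paired t test with its per-experiment effect size d_z."""

    t: float
    df: int
    p: float
    dz: float


def paired_t(x1: Sequence[float], x2: Sequence[float]) -> PairedResult:
    """Two-sided paired t test on ``x1 - x2``; ``dz = t / sqrt(n)``."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-d arrays of equal length")
    n = x1.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = x1 - x2
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    res = stats.ttest_rel(x1, x2, alternative="two-sided")
    t = float(res.statistic)
    return PairedResult(t=t, df=n - 1, p=float(res.pvalue), dz=t / math.sqrt(n))


def percent_significant(pvalues: Sequence[float], alpha: float = 0.05) -> float:
    """Percentage of p-values below ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("pvalues must be nonempty")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return 100.0 * float(np.mean(p < alpha))


def condition_correlation(scored_cells: pd.DataFrame, column: str) -> float:
    """Pearson correlation across participants between the two conditions.

    ``scored_cells`` must contain ``participant``, ``condition`` and the
    named measure column, with both conditions present for every participant.
    """
    wide = scored_cells.pivot(index="participant", columns="condition", values=column)
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("every participant must appear in exactly two conditions")
    a = wide.iloc[:, 0].to_numpy(dtype=float)
    b = wide.iloc[:, 1].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError(
            f"correlation of {column!r} undefined: a condition's values are constant"
        )
    return float(np.corrcoef(a, b)[0, 1])


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be >= 0")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_error)
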