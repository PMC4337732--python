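"""Shared group-statistics machinery.

Correlations are Fisher z-transformed before group t-tests; two-tailed
one-sample and paired t-tests feed Benjamini-Hochberg FDR correction
applied within each experimental condition separately.  A Spearman
rank-correlation control relates per-subject head-motion summaries to
radial-distance slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .core_data import ValidationError


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, float)
    if (np.abs(r) >= 1).any():
        raise ValidationError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def fisher_z_inverse(z):
    return np.tanh(np.asarray(z, float))


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    n: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValidationError("adjusted p must be >= raw p")


def group_ttest(values, values_b=None, mode: str = "one_sample") -> GroupTestResult:
    """Two-tailed t-test across subjects.

    ``one_sample`` tests the mean of ``values`` against zero;
    ``paired`` tests the mean difference ``values - values_b``.
    """
    values = np.asarray(values, float)
    if mode == "paired":
        if values_b is None:
            raise ValidationError("paired test needs two samples")
        values = values - np.asarray(values_b, float)
    elif mode != "one_sample":
        raise ValidationError(f"unknown mode {mode!r}")
    n = len(values)
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    if values.std(ddof=1) == 0:
        raise ValidationError("zero variance sample")
    t, p = sp_stats.ttest_1samp(values, 0.0)
    return GroupTestResult(statistic=float(t), df=n - 1, p_value=float(p), n=n)


def fdr_bh(pvals, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, within condition groups.

    ``groups`` assigns each p-value to a condition; correction is applied
    separately per group.  Adjusted p-values are monotone in the raw ones
    within each group.
    """
    pvals = np.asarray(pvals, float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.empty_like(pvals)
    if groups is None:
        groups = np.zeros(len(pvals), dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = groups == g
        out[m] = multipletests(pvals[m], method="fdr_bh")[1]
    return out


def total_movement(motion: np.ndarray) -> np.ndarray:
    """Per-parameter total movement: sum of |frame-to-frame differences|.

    ``motion`` is (6, T); returns 6 values.
    """
    return np.abs(np.diff(np.asarray(motion, float), axis=-1)).sum(axis=-1)


def motion_slope_control(
    motion_summaries: np.ndarray, slopes: np.ndarray
) -> list[GroupTestResult]:
    """Spearman rank correlation of subject motion against radial slopes.

    ``motion_summaries`` is (n_subjects, 6) of per-parameter total
    movement; ``slopes`` the per-subject mean radial-distance slope.
    Returns one result per motion parameter (statistic = Spearman rho,
    ties handled by average ranks).
    """
    motion_summaries = np.atleast_2d(np.asarray(motion_summaries, float))
    slopes = np.asarray(slopes, float)
    n = len(slopes)
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    results = []
    for k in range(motion_summaries.shape[1]):
        rho, p = sp_stats.spearmanr(motion_summaries[:, k], slopes)
        results.append(
            GroupTestResult(statistic=float(rho), df=n - 2, p_value=float(p), n=n)
        )
    return results
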