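"""Linear topographic connectivity model and residual analyses.

The observed 36 x 36 bin correlation matrix C is modeled as

    C = A + b1*NSE + b2*RF + b3*Ecc + b4*Pol + eps

fit by ordinary least squares over vectorized cells (cells missing in the
data or any predictor are dropped pairwise from all terms).  Residual
analysis first removes topographically local connectivity (NSE + RF, or a
homotopic/Cholesky variant) and then correlates the residuals with each
widespread predictor separately — attributing all shared local/widespread
variance to the local model.  Intra- and inter-hemisphere matrices are
fitted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import BinCorrelationMatrix, NodeTable, ValidationError
from .topo_predictors import PredictorMatrix


@dataclass
class RegressionFit:
    """OLS fit of the topographic connectivity model for one area pair."""

    constant: float
    coefficients: dict  # predictor kind -> beta
    residuals: np.ndarray  # same shape as C, NaN on dropped cells
    r_squared: float
    n_cells: int
    condition_number: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r_squared) and not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError("R^2 out of [0, 1]")


def _as_values(m) -> np.ndarray:
    if isinstance(m, (BinCorrelationMatrix, PredictorMatrix)):
        return np.asarray(m.values, float)
    return np.asarray(m, float)


def _kind_of(m, default: str) -> str:
    if isinstance(m, PredictorMatrix):
        return m.kind
    return default


def fit_topographic_model(
    C,
    predictors: list,
    check_collinearity: bool = True,
    standardize: bool = False,
) -> RegressionFit:
    """OLS of vectorized correlation cells on predictors plus an intercept.

    ``predictors`` is a list of :class:`PredictorMatrix` (or bare arrays).
    Exactly collinear predictors raise an error naming the pair; condition
    number > 1e6 warns.  ``standardize`` optionally z-scores C and the
    predictors over the retained cells before fitting (the intercept
    absorbs offsets either way; off by default).
    """
    c_vals = _as_values(C)
    kinds = [_kind_of(p, f"P{i + 1}") for i, p in enumerate(predictors)]
    p_vals = [_as_values(p) for p in predictors]
    for p in p_vals:
        if p.shape != c_vals.shape:
            raise ValidationError(
                f"predictor shape {p.shape} does not match data shape {c_vals.shape}"
            )
    ok = np.isfinite(c_vals)
    for p in p_vals:
        ok &= np.isfinite(p)
    y = c_vals[ok]
    X = np.column_stack([p[ok] for p in p_vals])
    if standardize:
        y = (y - y.mean()) / y.std()
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    design = np.column_stack([np.ones(len(y)), X])

    if check_collinearity and X.shape[1] >= 2:
        Xc = X - X.mean(axis=0)
        norms = np.linalg.norm(Xc, axis=0)
        norms[norms == 0] = 1.0
        corr = (Xc / norms).T @ (Xc / norms)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) > 1 - 1e-10:
            raise ValidationError(
                f"predictors {kinds[i]!r} and {kinds[j]!r} are exactly collinear"
            )
    cond = float(np.linalg.cond(design))
    if cond > 1e6:
        warnings.warn(f"ill-conditioned design (condition number {cond:.3g})")

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    resid_mat = np.full_like(c_vals, np.nan)
    resid_mat[ok] = resid
    return RegressionFit(
        constant=float(coef[0]),
        coefficients=dict(zip(kinds, coef[1:].tolist())),
        residuals=resid_mat,
        r_squared=float(r2) if np.isfinite(r2) else np.nan,
        n_cells=int(ok.sum()),
        condition_number=cond,
    )


def residual_widespread_correlation(
    C,
    local: list,
    widespread,
) -> float:
    """Correlate residuals after removing local connectivity with a widespread predictor.

    Fits C on the local predictors (attributing all shared variance to
    them), then returns the Pearson r between the vectorized residuals and
    the widespread predictor over the jointly valid cells.  Returns NaN
    for constant residuals.
    """
    w_vals = _as_values(widespread)
    fit = fit_topographic_model(C, local, check_collinearity=False)
    ok = np.isfinite(fit.residuals) & np.isfinite(w_vals)
    r_vec = fit.residuals[ok]
    w_vec = w_vals[ok]
    c_scale = np.nanstd(_as_values(C)[ok])
    if (
        r_vec.size < 3
        or r_vec.std() <= 1e-10 * (c_scale + 1.0)  # residuals numerically constant
        or w_vec.std() == 0
    ):
        return np.nan
    return float(np.corrcoef(r_vec, w_vec)[0, 1])


@dataclass
class VarianceComparison:
    r2_nse: float
    r2_nse_rf: float
    r2_full: float
    rf_increment: float  # R^2 gain of RF over NSE-only
    widespread_increment: float  # R^2 gain of {Ecc, Pol} over {NSE, RF}
    ratio_local_to_widespread: float


def variance_comparison(C, nse, rf, ecc, pol) -> VarianceComparison:
    """Incremental variance explained by nested predictor sets.

    Compares the local overlapping-RF contribution (after the noise model)
    with the widespread eccentricity/polar-angle contribution (after the
    full local model).  Increments are non-negative by construction of
    nested OLS.
    """
    f1 = fit_topographic_model(C, [nse], check_collinearity=False)
    f2 = fit_topographic_model(C, [nse, rf], check_collinearity=False)
    f3 = fit_topographic_model(C, [nse, rf, ecc, pol], check_collinearity=False)
    rf_inc = max(f2.r_squared - f1.r_squared, 0.0)
    ws_inc = max(f3.r_squared - f2.r_squared, 0.0)
    ratio = rf_inc / ws_inc if ws_inc > 0 else np.inf
    return VarianceComparison(
        r2_nse=f1.r_squared,
        r2_nse_rf=f2.r_squared,
        r2_full=f3.r_squared,
        rf_increment=rf_inc,
        widespread_increment=ws_inc,
        ratio_local_to_widespread=ratio,
    )


def equalize_bin_nodes(
    nodes: NodeTable,
    labels: np.ndarray,
    n: int,
    policy: str = "include",
    seed: int = 0,
) -> np.ndarray:
    """Subsample bins to a fixed node count (bin-size equalization control).

    Bins with more than ``n`` members are subsampled without replacement
    to exactly ``n``; bins with fewer are kept as-is under
    ``policy="include"`` or dropped entirely under ``policy="exclude"``.
    Returns a copy of ``labels`` with removed nodes set to 0.
    """
    if policy not in ("include", "exclude"):
        raise ValidationError(f"unknown policy {policy!r}")
    labels = np.asarray(labels).copy()
    rng = np.random.default_rng(seed)
    for b in np.unique(labels):
        if b == 0:
            continue
        idx = np.flatnonzero(labels == b)
        if idx.size > n:
            drop = rng.choice(idx, size=idx.size - n, replace=False)
            labels[drop] = 0
        elif idx.size < n and policy == "exclude":
            labels[idx] = 0
    return labels
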