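"""Post-acquisition timeseries cleaning chain.

Stage order: drop initial volumes, despike, detrend + band-pass, nuisance
regression.  Despiking clips samples beyond mean +/- k SD per node (k
defaults to 2.5).  The temporal filter retains 0.01-0.1 Hz via a zero-phase
2nd-order Butterworth applied forward-backward after removing linear and
quadratic trends by least squares.  Nuisance regression removes, per node,
the OLS projection onto the motion parameters, their temporal derivatives,
and white-matter/ventricle traces.  Global mean signal removal is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .core_data import RunTimeseries


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    despike_sd: float = 2.5
    band: tuple[float, float] = (0.01, 0.1)
    detrend_order: int = 2
    #: seconds of initial data dropped, keyed by condition
    drop_initial_s: dict = field(
        default_factory=lambda: {"rest_fix": 21.6, "rest_closed": 21.6, "movie": 19.5}
    )
    regress_motion: bool = True
    regress_wm: bool = True
    regress_csf: bool = True
    gms_removal: bool = False
    enable_despike: bool = True
    enable_filter: bool = True
    enable_nuisance: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise PreprocessError("band low must be >= 0 and < band high")
        if any(v < 0 for v in self.drop_initial_s.values()):
            raise PreprocessError("drop_initial_s must be non-negative")


def despike(ts: RunTimeseries, k: float = 2.5) -> RunTimeseries:
    """Clip samples beyond mean +/- k*SD of each node's series.

    Mean and SD are computed per node over the whole run before clipping;
    constant series pass through unchanged (SD = 0 means no finite bound).
    """
    if ts.n_timepoints < 3:
        raise PreprocessError("despike needs at least 3 timepoints")
    if not np.isfinite(k):
        return ts.copy_with(ts.matrix.copy())
    m = ts.matrix.mean(axis=1, keepdims=True)
    sd = ts.matrix.std(axis=1, keepdims=True)
    lo = np.where(sd > 0, m - k * sd, -np.inf)
    hi = np.where(sd > 0, m + k * sd, np.inf)
    return ts.copy_with(np.clip(ts.matrix, lo, hi))


def polynomial_detrend(x: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial trend (per row) up to ``order``."""
    T = x.shape[1]
    t = np.linspace(-1.0, 1.0, T)
    basis = np.vander(t, order + 1, increasing=True)  # 1, t, t^2, ...
    coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
    return x - (basis @ coef).T


def filter_detrend(
    ts: RunTimeseries,
    band: tuple[float, float] = (0.01, 0.1),
    order: int = 2,
) -> RunTimeseries:
    """Least-squares polynomial detrend then zero-phase band-pass.

    ``order`` is the polynomial detrend order (2 = linear + quadratic).
    The band-pass is a 2nd-order Butterworth run forward and backward
    (``filtfilt``) so correlations are not distorted by filter lag.
    """
    lo, hi = band
    nyquist = 0.5 / ts.tr
    if hi >= nyquist:
        raise PreprocessError(
            f"band high {hi} Hz >= Nyquist {nyquist:.4f} Hz at TR {ts.tr} s"
        )
    x = polynomial_detrend(ts.matrix, order)
    sos = sp_signal.butter(2, [lo, hi], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    padlen = min(3 * 10, ts.n_timepoints - 1)
    y = sp_signal.sosfiltfilt(sos, x, axis=1, padlen=padlen)
    return ts.copy_with(y)


def nuisance_regress(ts: RunTimeseries, regressors: np.ndarray) -> RunTimeseries:
    """Per-node OLS residuals against [1, regressors].

    ``regressors`` is (n_regressors x T).  Residuals are orthogonal to
    every regressor.  Constant (zero-variance) regressors are dropped;
    exactly collinear regressors raise an error naming the pair.
    """
    R = np.atleast_2d(np.asarray(regressors, float))
    if R.shape[1] != ts.n_timepoints:
        raise PreprocessError(
            f"regressors have {R.shape[1]} timepoints, run has {ts.n_timepoints}"
        )
    keep = np.flatnonzero(R.std(axis=1) > 0)
    R = R[keep]
    design = np.column_stack([np.ones(ts.n_timepoints), R.T])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # locate a collinear pair for the error message
        Rc = R - R.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Rc, axis=1)
        C = (Rc / norms[:, None]) @ (Rc / norms[:, None]).T
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        raise PreprocessError(
            f"rank-deficient nuisance set: regressors {keep[i]} and {keep[j]} "
            f"are collinear (|r| = {abs(C[i, j]):.6f})"
        )
    coef, *_ = np.linalg.lstsq(design, ts.matrix.T, rcond=None)
    resid = ts.matrix - (design @ coef).T
    return ts.copy_with(resid)


def drop_initial_volumes(ts: RunTimeseries, drop_s: float) -> RunTimeseries:
    n_drop = int(np.floor(drop_s / ts.tr))
    if n_drop >= ts.n_timepoints - 1:
        raise PreprocessError("initial drop would leave fewer than 2 timepoints")
    return ts.copy_with(ts.matrix[:, n_drop:])


def preprocess_run(
    ts: RunTimeseries,
    nuisance: np.ndarray | dict | None = None,
    config: PreprocessConfig | None = None,
) -> RunTimeseries:
    """Full cleaning chain for one run.

    Drops ``floor(drop_initial_s / tr)`` initial volumes, then despike,
    detrend + band-pass, and nuisance regression, in that order.
    ``nuisance`` may be the dict returned by
    :func:`retinocorr.synthetic_data.simulate_nuisance` or a ready
    (n_regressors x T) matrix aligned with the *undropped* run.
    """
    if config is None:
        config = PreprocessConfig()
    drop_s = config.drop_initial_s.get(ts.condition, 0.0)
    n_drop = int(np.floor(drop_s / ts.tr))
    out = drop_initial_volumes(ts, drop_s)

    R = None
    if nuisance is not None and config.enable_nuisance:
        if isinstance(nuisance, dict):
            parts = []
            if config.regress_motion:
                parts += [nuisance["motion"], nuisance["motion_deriv"]]
            if config.regress_wm:
                parts.append(np.atleast_2d(nuisance["wm"]))
            if config.regress_csf:
                parts.append(np.atleast_2d(nuisance["csf"]))
            if parts:
                R = np.vstack(parts)
        else:
            R = np.atleast_2d(np.asarray(nuisance, float))
        if R is not None:
            if R.shape[1] == ts.n_timepoints:
                R = R[:, n_drop:]
            elif R.shape[1] != out.n_timepoints:
                raise PreprocessError(
                    f"nuisance length {R.shape[1]} matches neither raw "
                    f"({ts.n_timepoints}) nor trimmed ({out.n_timepoints}) run"
                )
            if not (R.std(axis=1) > 0).any():
                R = None

    if config.enable_despike:
        out = despike(out, config.despike_sd)
    if config.enable_filter:
        out = filter_detrend(out, config.band, config.detrend_order)
    if R is not None:
        if config.gms_removal:
            R = np.vstack([R, out.matrix.mean(axis=0)])
        out = nuisance_regress(out, R)
    elif config.gms_removal and config.enable_nuisance:
        out = nuisance_regress(out, out.matrix.mean(axis=0, keepdims=True))
    return out
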