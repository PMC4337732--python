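"""Eccentricity binning, radial/angular distance profiles, and slope tests.

Nodes are partitioned into 12 eccentricity bins spanning 0.50-12.50 deg
whose boundaries follow the log-scaled cortical magnification of early
visual cortex.  The mean timeseries of each bin is correlated with every
bin of a second region, correlation matrices are averaged over runs, and
correlations are grouped by ranked radial distance (|bin rank difference|,
0 = iso-eccentricity, 11 = foveal vs peripheral-most).  Group significance
of the linear slope of mean correlation against radial distance is
assessed with a label-shuffling permutation test in which the same shuffle
of distance labels is applied to every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import warnings

from .core_data import BinCorrelationMatrix, NodeTable, RunTimeseries, ValidationError


def average_over_runs(stack: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean over per-run matrices; all-missing cells stay NaN."""
    if len(stack) == 1:
        return stack[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack(stack), axis=0)

#: log-scaled eccentricity bin boundaries (degrees); 12 bins
ECC_BIN_BOUNDARIES = (
    0.50, 0.84, 1.24, 1.71, 2.27, 2.93, 3.71, 4.63, 5.73, 7.02, 8.55, 10.36, 12.50,
)


@dataclass
class EccBinning:
    """12-bin eccentricity partition of [0.50, 12.50] deg."""

    boundaries: tuple[float, ...] = ECC_BIN_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if not (np.diff(b) > 0).all():
            raise ValidationError("bin boundaries must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, ecc: np.ndarray) -> np.ndarray:
        """Bin labels 1..n_bins; 0 for nodes outside the analyzed range.

        Intervals are half-open [b_i, b_{i+1}) with the final bin closed so
        the boundary list exactly covers [0.50, 12.50].
        """
        ecc = np.asarray(ecc, float)
        b = np.asarray(self.boundaries, float)
        labels = np.searchsorted(b, ecc, side="right")  # 1..n+1 inside
        labels[ecc == b[-1]] = self.n_bins  # closed last bin
        labels[(ecc < b[0]) | (ecc > b[-1])] = 0
        return labels


def assign_ecc_bins(nodes: NodeTable, binning: EccBinning | None = None) -> np.ndarray:
    """Per-node eccentricity bin label (1..12; 0 = outside [0.50, 12.50])."""
    if binning is None:
        binning = EccBinning()
    return binning.assign(nodes.df["eccentricity_deg"].to_numpy(float))


def bin_mean_timeseries(
    ts: RunTimeseries,
    labels: np.ndarray,
    group_mask: np.ndarray,
    n_bins: int,
) -> np.ndarray:
    """Per-bin mean timeseries over the selected nodes.

    Returns an (n_bins x T) array with NaN rows for empty bins; missing
    bins propagate as missing matrix cells downstream.
    """
    labels = np.asarray(labels)
    out = np.full((n_bins, ts.n_timepoints), np.nan)
    for b in range(1, n_bins + 1):
        idx = np.flatnonzero(group_mask & (labels == b))
        if idx.size:
            out[b - 1] = ts.matrix[idx].mean(axis=0)
    return out


def _corr_between(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between rows of A and rows of B; NaN for invalid rows."""
    A = np.where(np.isfinite(A), A, np.nan)
    B = np.where(np.isfinite(B), B, np.nan)
    mu_a = np.nansum(A, axis=1, keepdims=True) / np.maximum(
        np.isfinite(A).sum(axis=1, keepdims=True), 1
    )
    mu_b = np.nansum(B, axis=1, keepdims=True) / np.maximum(
        np.isfinite(B).sum(axis=1, keepdims=True), 1
    )
    A = A - mu_a
    B = B - mu_b
    sa = np.sqrt(np.nansum(A * A, axis=1))
    sb = np.sqrt(np.nansum(B * B, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (np.nan_to_num(A) @ np.nan_to_num(B).T) / np.outer(sa, sb)
    bad_a = ~np.isfinite(A).all(axis=1) | (sa == 0)
    bad_b = ~np.isfinite(B).all(axis=1) | (sb == 0)
    r[bad_a, :] = np.nan
    r[:, bad_b] = np.nan
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class RegionSelection:
    """An (area, hemisphere, quadrant) node selection."""

    area: str
    hemisphere: str
    quadrant: str | None = None

    def mask(self, nodes: NodeTable) -> np.ndarray:
        return nodes.select(
            area=self.area, hemisphere=self.hemisphere, quadrant=self.quadrant
        )


def bin_correlation_matrix(
    runs: list[RunTimeseries],
    nodes: NodeTable,
    region_a: RegionSelection,
    region_b: RegionSelection,
    binning: EccBinning | None = None,
    labels: np.ndarray | None = None,
) -> BinCorrelationMatrix:
    """Run-averaged Pearson correlations between all eccentricity-bin pairs.

    Matrices are computed per run and averaged element-wise on r (not
    Fisher-averaged); Fisher transformation is reserved for group
    statistics.
    """
    if not runs:
        raise ValidationError("need at least one run")
    if binning is None:
        binning = EccBinning()
    if labels is None:
        labels = assign_ecc_bins(nodes, binning)
    mask_a = region_a.mask(nodes)
    mask_b = region_b.mask(nodes)
    acc = []
    for run in runs:
        A = bin_mean_timeseries(run, labels, mask_a, binning.n_bins)
        B = bin_mean_timeseries(run, labels, mask_b, binning.n_bins)
        acc.append(_corr_between(A, B))
    values = average_over_runs(acc)
    return BinCorrelationMatrix(
        values=values,
        area_a=region_a.area,
        area_b=region_b.area,
        hemi_a=region_a.hemisphere,
        hemi_b=region_b.hemisphere,
        quadrant_a=region_a.quadrant,
        quadrant_b=region_b.quadrant,
        bin_grid="ecc12",
        n_runs_averaged=len(runs),
    )


def interrun_correlation_matrix(
    run_a: RunTimeseries,
    run_b: RunTimeseries,
    nodes: NodeTable,
    region_a: RegionSelection,
    region_b: RegionSelection,
    binning: EccBinning | None = None,
) -> BinCorrelationMatrix:
    """Correlations between bin series of one run and bin series of another.

    Intrinsic dynamics and non-neuronal artifacts cannot correlate across
    runs, so only stimulus-locked (movie) signal survives here.  Runs are
    truncated to the shorter length.
    """
    if binning is None:
        binning = EccBinning()
    labels = assign_ecc_bins(nodes, binning)
    T = min(run_a.n_timepoints, run_b.n_timepoints)
    A = bin_mean_timeseries(run_a.copy_with(run_a.matrix[:, :T]), labels,
                            region_a.mask(nodes), binning.n_bins)
    B = bin_mean_timeseries(run_b.copy_with(run_b.matrix[:, :T]), labels,
                            region_b.mask(nodes), binning.n_bins)
    return BinCorrelationMatrix(
        values=_corr_between(A, B),
        area_a=region_a.area,
        area_b=region_b.area,
        hemi_a=region_a.hemisphere,
        hemi_b=region_b.hemisphere,
        quadrant_a=region_a.quadrant,
        quadrant_b=region_b.quadrant,
        bin_grid="ecc12",
        n_runs_averaged=1,
    )


def radial_distance_matrix(n_bins: int = 12) -> np.ndarray:
    """Ranked radial distance |i - j| between bin indices (max n_bins - 1)."""
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    idx = np.arange(n_bins)
    return np.abs(idx[:, None] - idx[None, :])


@dataclass
class RadialProfile:
    """Mean correlation per ranked radial distance plus its linear slope.

    ``normalized`` is d_X = 1 - (r_0 - r_X): 1 at distance 0, smaller when
    correlations fall off with distance; subtraction preserves the slope.
    """

    mean_r: np.ndarray  # length n_bins; NaN where a distance level is missing
    slope: float
    intercept: float
    distances: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.distances is None:
            self.distances = np.arange(len(self.mean_r))

    @property
    def normalized(self) -> np.ndarray:
        return 1.0 - (self.mean_r[0] - self.mean_r)


def radial_profile(
    matrix: BinCorrelationMatrix | np.ndarray,
    self_pair: bool | None = None,
) -> RadialProfile:
    """Group matrix cells by ranked radial distance; average; fit a line.

    For self-pairs the identical-series diagonal (distance 0) is excluded
    from both the grouping and the slope fit.  Distance levels with no
    valid cells are excluded from the fit.
    """
    if isinstance(matrix, BinCorrelationMatrix):
        values = matrix.values
        if self_pair is None:
            self_pair = matrix.is_self_pair
    else:
        values = np.asarray(matrix, float)
        self_pair = bool(self_pair)
    n = values.shape[0]
    if values.shape[0] != values.shape[1]:
        raise ValidationError("radial profile requires a square bin matrix")
    D = radial_distance_matrix(n)
    vals = values.copy()
    if self_pair:
        np.fill_diagonal(vals, np.nan)
    mean_r = np.full(n, np.nan)
    for d in range(n):
        cells = vals[D == d]
        if np.isfinite(cells).any():
            mean_r[d] = np.nanmean(cells)
    fit_d = np.arange(n)
    ok = np.isfinite(mean_r)
    if self_pair:
        ok &= fit_d != 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(fit_d[ok], mean_r[ok], 1)
    else:
        slope, intercept = np.nan, np.nan
    return RadialProfile(mean_r=mean_r, slope=float(slope), intercept=float(intercept))


def _slopes_for_profiles(profiles: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Per-subject OLS slope of profile values (re-ordered) against distance.

    ``profiles`` is (n_subjects x n_distances) with NaN for missing levels;
    ``order`` permutes the distance labels (identical for all subjects).
    """
    S, n = profiles.shape
    d = np.arange(n, dtype=float)
    x = profiles[:, order]
    slopes = np.empty(S)
    for s in range(S):
        ok = np.isfinite(x[s])
        dd = d[ok]
        xx = x[s, ok]
        dd_c = dd - dd.mean()
        slopes[s] = (dd_c @ xx) / (dd_c @ dd_c)
    return slopes


@dataclass
class PermutationResult:
    observed_mean_slope: float
    null_slopes: np.ndarray
    q_low: float
    q_high: float
    p_two_tailed: float

    @property
    def significant(self) -> bool:
        return (
            self.observed_mean_slope < self.q_low
            or self.observed_mean_slope > self.q_high
        )


def permutation_test_slope(
    subject_profiles: np.ndarray,
    n_iter: int = 10_000,
    seed: int = 0,
    exclude_zero: bool = False,
) -> PermutationResult:
    """Label-shuffling permutation test of the group-mean radial slope.

    ``subject_profiles`` is (n_subjects x n_distances) of mean correlations
    per ranked distance.  Each iteration applies one shared shuffle of the
    distance labels to all subjects, refits per-subject slopes, and records
    the mean.  Returns the 2.5%/97.5% quantiles of the null and a
    two-tailed p-value for the observed mean slope.  ``exclude_zero``
    drops the distance-0 level (identical-series diagonal of self-pairs).
    """
    profiles = np.asarray(subject_profiles, float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValidationError("need profiles for at least 2 subjects")
    if n_iter < 100:
        import warnings

        warnings.warn("n_iter < 100 gives unstable permutation quantiles")
    if exclude_zero:
        profiles = profiles[:, 1:]
    n = profiles.shape[1]
    rng = np.random.default_rng(seed)
    observed = float(np.mean(_slopes_for_profiles(profiles, np.arange(n))))
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = np.mean(_slopes_for_profiles(profiles, rng.permutation(n)))
    q_low, q_high = np.quantile(null, [0.025, 0.975])
    p = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_iter)
    return PermutationResult(
        observed_mean_slope=observed,
        null_slopes=null,
        q_low=float(q_low),
        q_high=float(q_high),
        p_two_tailed=float(p),
    )


def meridian_keep_mask(nodes: NodeTable, mode: str) -> np.ndarray:
    """Boolean mask of nodes kept by :func:`remove_meridian_nodes`.

    Use it to subset run matrices consistently with the trimmed table.
    """
    theta = nodes.df["polar_angle_deg"].to_numpy(float)
    if mode == "horizontal60":
        return np.abs(theta) >= 30.0
    if mode == "vertical90":
        return np.abs(theta) <= 45.0
    raise ValidationError(f"unknown meridian-removal mode {mode!r}")


def remove_meridian_nodes(nodes: NodeTable, mode: str) -> NodeTable:
    """Drop nodes in a polar-angle wedge around a meridian.

    ``horizontal60`` removes the 60 deg wedge centered on the horizontal
    meridian (|theta| < 30); ``vertical90`` removes 90 deg centered on each
    vertical meridian (|theta| > 45).  Boundary nodes at exactly 30/45 deg
    are kept (strict-inequality removal).
    """
    return nodes.subset(meridian_keep_mask(nodes, mode))


def angular_bin_labels(nodes: NodeTable, n_angle_bins: int = 12,
                       mirror: str = "none") -> np.ndarray:
    """Equal polar-angle bins over the hemifield's 180 deg (1..n; 15 deg each).

    ``mirror="horizontal"`` reflects angles across the horizontal meridian
    (theta -> -theta) before binning; ``mirror="vertical"`` is a no-op on
    the signed hemifield angle because reflection about the vertical
    meridian maps (e, theta) in one hemifield onto (e, theta) in the other.
    """
    theta = nodes.df["polar_angle_deg"].to_numpy(float).copy()
    if mirror == "horizontal":
        theta = -theta
    elif mirror not in ("none", "vertical"):
        raise ValidationError(f"unknown mirror mode {mirror!r}")
    edges = np.linspace(-90.0, 90.0, n_angle_bins + 1)
    labels = np.searchsorted(edges, theta, side="right")
    labels[theta == 90.0] = n_angle_bins
    return np.clip(labels, 1, n_angle_bins)


def angular_profile(
    runs: list[RunTimeseries],
    nodes: NodeTable,
    region_a: RegionSelection,
    region_b: RegionSelection,
    n_angle_bins: int = 12,
    mirror: str = "none",
) -> RadialProfile:
    """Mean correlation per angular-bin distance, with linear slope.

    Bins span the hemifield (15 deg each with the default 12).  Within one
    hemifield the angular distance is |i - j| of bin indices.  Across
    hemifields with ``mirror="none"`` the distance runs through the nearer
    vertical meridian (so same-|theta| bins in opposite hemifields sit at a
    nonzero distance); with ``mirror="vertical"`` one region's angles are
    reflected onto the other hemifield first, making mirror-symmetric bins
    distance 0.
    """
    labels_a = angular_bin_labels(nodes, n_angle_bins, "none")
    labels_b = angular_bin_labels(nodes, n_angle_bins, mirror)
    mask_a = region_a.mask(nodes)
    mask_b = region_b.mask(nodes)
    cross_hemi = region_a.hemisphere != region_b.hemisphere

    acc = []
    for run in runs:
        A = bin_mean_timeseries(run, labels_a, mask_a, n_angle_bins)
        B = bin_mean_timeseries(run, labels_b, mask_b, n_angle_bins)
        acc.append(_corr_between(A, B))
    values = average_over_runs(acc)

    i = np.arange(n_angle_bins)
    if cross_hemi and mirror == "none":
        # path through the nearer vertical meridian, in bin steps; bins
        # adjacent to a vertical meridian in both hemifields are 1 apart
        up = (n_angle_bins - 1 - i[:, None]) + (n_angle_bins - 1 - i[None, :]) + 1
        low = i[:, None] + i[None, :] + 1
        D = np.minimum(up, low)
    else:
        D = np.abs(i[:, None] - i[None, :])
    self_pair = (
        region_a.area == region_b.area
        and region_a.hemisphere == region_b.hemisphere
        and region_a.quadrant == region_b.quadrant
        and mirror == "none"
    )
    vals = values.copy()
    if self_pair:
        np.fill_diagonal(vals, np.nan)
    max_d = int(D.max())
    mean_r = np.full(max_d + 1, np.nan)
    for d in range(max_d + 1):
        cells = vals[D == d]
        if cells.size and np.isfinite(cells).any():
            mean_r[d] = np.nanmean(cells)
    dist = np.arange(max_d + 1, dtype=float)
    ok = np.isfinite(mean_r)
    if self_pair:
        ok &= dist != 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(dist[ok], mean_r[ok], 1)
    else:
        slope, intercept = np.nan, np.nan
    return RadialProfile(
        mean_r=mean_r, slope=float(slope), intercept=float(intercept), distances=dist
    )


def zscore_matrix(matrix: BinCorrelationMatrix) -> np.ndarray:
    """Z-score the matrix cells (display only; never used for statistics)."""
    vals = matrix.values
    finite = vals[np.isfinite(vals)]
    if finite.size < 2 or finite.std() == 0:
        raise ValidationError("cannot z-score a constant matrix")
    return (vals - finite.mean()) / finite.std()
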