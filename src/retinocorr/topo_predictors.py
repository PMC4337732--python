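"""Connectivity predictor matrices on the 36-bin topographic grid.

Each visual hemifield map is divided into six eccentricity divisions
(E1-E6), each containing six polar-angle divisions (A1-A6) — 36 bins that
tile [0.5, 12.5] deg x [-90, +90] deg.  Four connectivity sources are
modeled as 36 x 36 predictor matrices:

* **NSE** — instrumental "noise": correlations of spatially smoothed random
  timeseries passed through the full preprocessing and binning pipeline;
* **RF** — overlap of bin-averaged population receptive fields (2-D
  Gaussians with a per-area linear size law);
* **Ecc** — a 0-1 linear ramp in ranked eccentricity-division distance,
  1 at iso-eccentricity;
* **Pol** — the analogous ramp in polar-angle-division distance (computed
  through the vertical meridian for inter-hemisphere pairs, whose minimum
  angular distance is 1).

A homotopic-RF variant reflects one hemisphere's response fields about the
vertical meridian before computing overlap, and a Cholesky-based control
regenerates data with a target local correlation structure plus sheet
smoothing to bound how much point-spread blur could inflate RF overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_data import ECC_MAX, ECC_MIN, NodeTable, RunTimeseries, ValidationError
from .eccbin_analysis import _corr_between, average_over_runs
from .preprocess import PreprocessConfig, preprocess_run
from .synthetic_data import FWHM_TO_SIGMA, SimConfig, _sheet_groups, simulate_noise_dataset

#: published linear pRF size endpoints: sigma (deg) at 0.5 and 12.5 deg
#: eccentricity.  V3AB and VO12 are excluded for lack of published sizes.
PRF_ENDPOINTS = {
    "V1": (0.4, 1.6),
    "V2": (0.48, 2.3),
    "V3": (1.0, 4.15),
    "hV4": (1.2, 5.8),
}

#: eccentricity divisions = merged pairs of the 12 analysis bins
TOPO_ECC_BOUNDARIES = (0.50, 1.24, 2.27, 3.71, 5.73, 8.55, 12.50)
#: six 30-deg polar angle divisions over the hemifield
TOPO_ANGLE_BOUNDARIES = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)


def prf_sigma(area: str, eccentricity: float | np.ndarray) -> np.ndarray:
    """pRF Gaussian spread (deg) from the area's linear size law.

    The line passes through the published sizes at 0.5 and 12.5 deg;
    eccentricities outside that range are clamped to the endpoints.
    """
    if area not in PRF_ENDPOINTS:
        raise ValidationError(
            f"no published pRF size law for area {area!r} "
            f"(available: {', '.join(PRF_ENDPOINTS)})"
        )
    s_lo, s_hi = PRF_ENDPOINTS[area]
    e = np.clip(np.asarray(eccentricity, float), ECC_MIN, ECC_MAX)
    return s_lo + (e - ECC_MIN) * (s_hi - s_lo) / (ECC_MAX - ECC_MIN)


@dataclass
class VisualFieldGrid:
    """Cartesian visual-field sampling grid for pRF integration."""

    step_deg: float = 0.1
    extent_deg: float = 20.0  # grid spans [-extent, +extent] in x and y

    def axes(self) -> np.ndarray:
        n = int(round(2 * self.extent_deg / self.step_deg)) + 1
        return np.linspace(-self.extent_deg, self.extent_deg, n)

    @property
    def cell_area(self) -> float:
        return self.step_deg**2


@dataclass
class PRFModel:
    """Gaussian pRF model g(x, y) = A exp(-[(x-x0)^2+(y-y0)^2] / (2 sigma^2)).

    The normalization constant A is chosen so the discretized integral of g
    over the visual-field grid is 1.
    """

    grid: VisualFieldGrid = field(default_factory=VisualFieldGrid)

    def node_prf(self, area: str, x0: float, y0: float, ecc: float) -> np.ndarray:
        axes = self.grid.axes()
        sigma = float(prf_sigma(area, ecc))
        gx = np.exp(-0.5 * ((axes - x0) / sigma) ** 2)
        gy = np.exp(-0.5 * ((axes - y0) / sigma) ** 2)
        g = gx[:, None] * gy[None, :]
        total = g.sum() * self.grid.cell_area
        return g / total

    def integral(self, prf: np.ndarray) -> float:
        return float(prf.sum() * self.grid.cell_area)


@dataclass
class TopoBinGrid:
    """6 eccentricity x 6 polar-angle divisions per hemifield = 36 bins.

    Bin index = 6 * (E - 1) + (A - 1) for E, A in 1..6, i.e. ecc-major
    ordering.
    """

    ecc_boundaries: tuple[float, ...] = TOPO_ECC_BOUNDARIES
    angle_boundaries: tuple[float, ...] = TOPO_ANGLE_BOUNDARIES

    @property
    def n_ecc(self) -> int:
        return len(self.ecc_boundaries) - 1

    @property
    def n_angle(self) -> int:
        return len(self.angle_boundaries) - 1

    @property
    def n_bins(self) -> int:
        return self.n_ecc * self.n_angle

    def assign(self, nodes: NodeTable) -> np.ndarray:
        """Bin labels 1..36 (ecc-major); 0 outside the hemifield region."""
        ecc = nodes.df["eccentricity_deg"].to_numpy(float)
        theta = nodes.df["polar_angle_deg"].to_numpy(float)
        be = np.asarray(self.ecc_boundaries)
        ba = np.asarray(self.angle_boundaries)
        ei = np.searchsorted(be, ecc, side="right")
        ei[ecc == be[-1]] = self.n_ecc
        ai = np.searchsorted(ba, theta, side="right")
        ai[theta == ba[-1]] = self.n_angle
        ok = (ei >= 1) & (ei <= self.n_ecc) & (ai >= 1) & (ai <= self.n_angle)
        labels = np.where(ok, (ei - 1) * self.n_angle + ai, 0)
        return labels

    def ecc_index(self) -> np.ndarray:
        """E division (1..6) for each of the 36 bins."""
        return np.repeat(np.arange(1, self.n_ecc + 1), self.n_angle)

    def angle_index(self) -> np.ndarray:
        """A division (1..6) for each of the 36 bins."""
        return np.tile(np.arange(1, self.n_angle + 1), self.n_ecc)


@dataclass
class PredictorMatrix:
    kind: str  # NSE | RF | Ecc | Pol | RF_homotopic | RF_cholesky
    values: np.ndarray
    area_a: str = ""
    area_b: str = ""
    hemi_a: str = ""
    hemi_b: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


# ---------------------------------------------------------------------------
# response fields and overlap
# ---------------------------------------------------------------------------


def bin_response_fields(
    nodes: NodeTable,
    area: str,
    hemisphere: str,
    grid: TopoBinGrid | None = None,
    prf: PRFModel | None = None,
    flip_x: bool = False,
) -> np.ndarray:
    """Mean of member-node normalized pRFs per topographic bin.

    Returns (36, nx, ny) with NaN planes for empty bins; each nonempty
    field is renormalized to unit integral.  ``flip_x`` mirrors the node
    centers about the vertical meridian (for the homotopic predictor).
    """
    if grid is None:
        grid = TopoBinGrid()
    if prf is None:
        prf = PRFModel()
    labels = grid.assign(nodes)
    mask = nodes.select(area=area, hemisphere=hemisphere)
    x0, y0 = nodes.visual_field_xy()
    if flip_x:
        x0 = -x0
    ecc = nodes.df["eccentricity_deg"].to_numpy(float)
    axes = prf.grid.axes()
    out = np.full((grid.n_bins, axes.size, axes.size), np.nan)
    for b in range(1, grid.n_bins + 1):
        idx = np.flatnonzero(mask & (labels == b))
        if idx.size == 0:
            continue
        acc = np.zeros((axes.size, axes.size))
        for i in idx:
            acc += prf.node_prf(area, x0[i], y0[i], ecc[i])
        acc /= idx.size
        out[b - 1] = acc / (acc.sum() * prf.grid.cell_area)
    return out


def rf_overlap(field_a: np.ndarray, field_b: np.ndarray) -> float:
    """Overlap of two density fields: integral(min) / integral(max).

    A function-level Jaccard index: 1 for identical fields, ~0 for fields
    with centers many sigma apart.  Both fields must share the grid.
    """
    if field_a.shape != field_b.shape:
        raise ValidationError("fields must share the same grid")
    if not (np.isfinite(field_a).all() and np.isfinite(field_b).all()):
        return np.nan
    num = np.minimum(field_a, field_b).sum()
    den = np.maximum(field_a, field_b).sum()
    return float(num / den) if den > 0 else np.nan


def rf_overlap_matrix(
    fields_a: np.ndarray, fields_b: np.ndarray, metric: str = "min_over_max"
) -> np.ndarray:
    """Pairwise overlap between two stacks of response fields.

    ``metric``: ``min_over_max`` (default) or ``jaccard``
    (integral(min) / (A + B - min)); both are symmetric and bounded [0, 1].
    """
    na = fields_a.shape[0]
    nb = fields_b.shape[0]
    A = fields_a.reshape(na, -1)
    B = fields_b.reshape(nb, -1)
    out = np.full((na, nb), np.nan)
    good_a = np.isfinite(A).all(axis=1)
    good_b = np.isfinite(B).all(axis=1)
    sum_a = A.sum(axis=1)
    sum_b = B.sum(axis=1)
    for i in np.flatnonzero(good_a):
        mins = np.minimum(A[i][None, :], B[good_b]).sum(axis=1)
        if metric == "min_over_max":
            maxs = np.maximum(A[i][None, :], B[good_b]).sum(axis=1)
            out[i, good_b] = mins / maxs
        elif metric == "jaccard":
            out[i, good_b] = mins / (sum_a[i] + sum_b[good_b] - mins)
        else:
            raise ValidationError(f"unknown overlap metric {metric!r}")
    return out


def rf_predictor(
    nodes: NodeTable,
    area_a: str,
    hemi_a: str,
    area_b: str,
    hemi_b: str,
    grid: TopoBinGrid | None = None,
    prf: PRFModel | None = None,
    metric: str = "min_over_max",
) -> PredictorMatrix:
    """Overlapping-RF predictor: pairwise response-field overlap."""
    fa = bin_response_fields(nodes, area_a, hemi_a, grid, prf)
    fb = bin_response_fields(nodes, area_b, hemi_b, grid, prf)
    return PredictorMatrix(
        kind="RF",
        values=rf_overlap_matrix(fa, fb, metric),
        area_a=area_a,
        area_b=area_b,
        hemi_a=hemi_a,
        hemi_b=hemi_b,
    )


def homotopic_predictor(
    nodes: NodeTable,
    area_a: str,
    hemi_a: str,
    area_b: str,
    hemi_b: str,
    grid: TopoBinGrid | None = None,
    prf: PRFModel | None = None,
    metric: str = "min_over_max",
) -> PredictorMatrix:
    """Homotopic-RF predictor: flip one hemisphere's fields about x = 0.

    Only defined for opposite hemifields; mirror-symmetric bin pairs get
    the self-overlap value (1 for identical mirrored fields).
    """
    if hemi_a == hemi_b:
        raise ValidationError("homotopic predictor requires opposite hemispheres")
    fa = bin_response_fields(nodes, area_a, hemi_a, grid, prf)
    fb = bin_response_fields(nodes, area_b, hemi_b, grid, prf, flip_x=True)
    return PredictorMatrix(
        kind="RF_homotopic",
        values=rf_overlap_matrix(fa, fb, metric),
        area_a=area_a,
        area_b=area_b,
        hemi_a=hemi_a,
        hemi_b=hemi_b,
    )


# ---------------------------------------------------------------------------
# distance ramps
# ---------------------------------------------------------------------------


def distance_predictor(
    grid: TopoBinGrid | None = None,
    axis: str = "ecc",
    same_hemisphere: bool = True,
) -> PredictorMatrix:
    """Linear 0-1 ramp in ranked division distance along one retinotopic axis.

    Eccentricity: value = 1 - |E_i - E_j| / 5 (1 at iso-eccentricity).
    Polar angle, same hemisphere: value = 1 - |A_i - A_j| / 5.  Polar
    angle, different hemispheres: the angular path runs through the nearer
    vertical meridian, so the minimum inter-hemisphere distance is 1 and
    value = 1 - d / 6.
    """
    if grid is None:
        grid = TopoBinGrid()
    if axis == "ecc":
        e = grid.ecc_index().astype(float)
        d = np.abs(e[:, None] - e[None, :])
        values = 1.0 - d / (grid.n_ecc - 1)
        kind = "Ecc"
    elif axis == "pol":
        a = grid.angle_index().astype(float)
        if same_hemisphere:
            d = np.abs(a[:, None] - a[None, :])
            values = 1.0 - d / (grid.n_angle - 1)
        else:
            n = grid.n_angle
            up = (n - a[:, None]) + (n - a[None, :]) + 1
            low = (a[:, None] - 1) + (a[None, :] - 1) + 1
            d = np.minimum(up, low)
            values = 1.0 - d / n
        kind = "Pol"
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    return PredictorMatrix(kind=kind, values=values)


# ---------------------------------------------------------------------------
# simulation-based predictors
# ---------------------------------------------------------------------------


def topo_bin_matrix(
    runs: list[RunTimeseries],
    nodes: NodeTable,
    area_a: str,
    hemi_a: str,
    area_b: str,
    hemi_b: str,
    grid: TopoBinGrid | None = None,
) -> np.ndarray:
    """Run-averaged 36 x 36 correlation matrix on the topographic grid."""
    if grid is None:
        grid = TopoBinGrid()
    labels = grid.assign(nodes)
    mask_a = nodes.select(area=area_a, hemisphere=hemi_a)
    mask_b = nodes.select(area=area_b, hemisphere=hemi_b)
    acc = []
    for run in runs:
        A = np.full((grid.n_bins, run.n_timepoints), np.nan)
        B = np.full((grid.n_bins, run.n_timepoints), np.nan)
        for b in range(1, grid.n_bins + 1):
            ia = np.flatnonzero(mask_a & (labels == b))
            ib = np.flatnonzero(mask_b & (labels == b))
            if ia.size:
                A[b - 1] = run.matrix[ia].mean(axis=0)
            if ib.size:
                B[b - 1] = run.matrix[ib].mean(axis=0)
        acc.append(_corr_between(A, B))
    return average_over_runs(acc)


def nse_predictor(
    nodes: NodeTable,
    sim_config: SimConfig,
    area_a: str,
    hemi_a: str,
    area_b: str,
    hemi_b: str,
    grid: TopoBinGrid | None = None,
    preprocess_config: PreprocessConfig | None = None,
    n_surrogates: int = 5,
    seed: int = 0,
) -> PredictorMatrix:
    """Instrumental-noise predictor from smoothed random-timeseries surrogates.

    Each surrogate replaces every node's series with independent white
    noise, smooths along the cortical sheet with the psf kernel, passes
    the result through the same preprocessing as real data, and computes
    the 36-bin correlation matrix; surrogates are averaged.
    """
    if preprocess_config is None:
        preprocess_config = PreprocessConfig(enable_nuisance=False)
    mats = []
    for s in range(n_surrogates):
        cfg = SimConfig(**{**sim_config.to_dict(), "rng_seed": seed + 1000 * s + 1})
        runs = simulate_noise_dataset(nodes, cfg, subject=s)
        clean = [preprocess_run(r, None, preprocess_config) for r in runs]
        mats.append(topo_bin_matrix(clean, nodes, area_a, hemi_a, area_b, hemi_b, grid))
    return PredictorMatrix(
        kind="NSE",
        values=average_over_runs(mats),
        area_a=area_a,
        area_b=area_b,
        hemi_a=hemi_a,
        hemi_b=hemi_b,
    )


def cholesky_local_control(
    target: np.ndarray,
    nodes: NodeTable,
    sim_config: SimConfig,
    area_a: str,
    hemi_a: str,
    area_b: str,
    hemi_b: str,
    grid: TopoBinGrid | None = None,
    apply_smoothing: bool = True,
    seed: int = 0,
) -> PredictorMatrix:
    """Regenerate data with a target bin-level correlation structure.

    The target matrix (joint over the two regions' bins) is ridge-
    regularized to positive definiteness (smallest power of ten added to
    the diagonal), factored by Cholesky, and used to color white noise
    into per-bin latent series.  Every node inherits its bin's series,
    optional sheet smoothing at psf_fwhm is applied, and the 36 x 36
    matrix is recomputed — bounding how much point-spread blur could
    inflate a local connectivity pattern.
    """
    if grid is None:
        grid = TopoBinGrid()
    target = np.asarray(target, float)
    if target.shape[0] != target.shape[1]:
        raise ValidationError("target correlation matrix must be square")
    if not np.allclose(target, target.T, atol=1e-10, equal_nan=True):
        raise ValidationError("target correlation matrix must be symmetric")
    C = np.nan_to_num(target, nan=0.0).copy()
    np.fill_diagonal(C, 1.0)
    L = None
    for p in range(-12, 3):
        delta = 10.0**p
        try:
            L = np.linalg.cholesky(C + delta * np.eye(len(C)))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:
        raise ValidationError("target matrix could not be regularized to PD")
    rng = np.random.default_rng(seed)
    T = sim_config.n_timepoints
    latent = L @ rng.standard_normal((len(C), T))

    labels = grid.assign(nodes)
    mask_a = nodes.select(area=area_a, hemisphere=hemi_a)
    mask_b = nodes.select(area=area_b, hemisphere=hemi_b)
    same_region = area_a == area_b and hemi_a == hemi_b
    y = np.zeros((len(nodes), T))
    for b in range(1, grid.n_bins + 1):
        ia = np.flatnonzero(mask_a & (labels == b))
        y[ia] = latent[b - 1]
        if not same_region:
            ib = np.flatnonzero(mask_b & (labels == b))
            y[ib] = latent[grid.n_bins + b - 1]

    if apply_smoothing and sim_config.psf_fwhm > 0:
        sigma_mm = sim_config.psf_fwhm * FWHM_TO_SIGMA
        for idx, n_ecc, n_angle in _sheet_groups(nodes):
            block = y[idx].reshape(n_ecc, n_angle, T)
            step_x = sim_config.ecc_extent_mm / n_ecc
            step_y = sim_config.angle_extent_mm / n_angle
            y[idx] = ndimage.gaussian_filter(
                block, sigma=(sigma_mm / step_x, sigma_mm / step_y, 0.0),
                mode="nearest",
            ).reshape(-1, T)

    run = RunTimeseries(
        matrix=y, tr=sim_config.tr, condition=sim_config.condition, run_id=0
    )
    values = topo_bin_matrix([run], nodes, area_a, hemi_a, area_b, hemi_b, grid)
    return PredictorMatrix(
        kind="RF_cholesky",
        values=values,
        area_a=area_a,
        area_b=area_b,
        hemi_a=hemi_a,
        hemi_b=hemi_b,
    )
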