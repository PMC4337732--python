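"""Synthetic retinotopic sheets and BOLD-like multi-run timeseries.

The generator lays nodes on per-area flattened cortical sheets whose long
axis maps to log-eccentricity (mimicking cortical magnification: a roughly
even distribution of eccentricity preferences across the sheet) and whose
short axis maps linearly to polar angle within the area's quadrant range.
Dorsal and ventral quadrants of V1-V3 are separate sheets that adjoin only
at the fovea.

Each node's timeseries mixes, with configurable non-negative weights:

* ``w_rf``   — a shared spatiotemporal white-noise "movie" filtered through
  the node's population receptive field (pRF), so pairwise correlation
  equals normalized pRF overlap;
* ``w_ecc``  — a zero-mean latent Gaussian-process field over
  log-eccentricity, shared across areas, quadrants, and hemispheres, with
  correlation decaying monotonically in |delta log e|;
* ``w_pol``  — the analogous latent field over polar angle, drawn
  independently per hemifield;
* ``w_homo`` — a drive shared between mirror-symmetric node pairs across
  the two hemispheres (reflection about the vertical meridian);
* nuisance signals (six slow motion traces and their derivatives, a white
  matter trace, a ventricle trace) with per-node random loadings; and
* white measurement noise smoothed along the cortical sheet with a Gaussian
  point-spread kernel (default 3.5 mm FWHM), emulating the intrinsic
  spatial blur of BOLD imaging.

No generative model of the real data exists; the mixture here is a
synthetic stand-in whose ground truth is recorded alongside each dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_data import (
    AREAS,
    QUADRANT_AREAS,
    ECC_MIN,
    ECC_MAX,
    NodeTable,
    RunTimeseries,
    ValidationError,
)

#: pRF size endpoints (sigma at 0.5 deg, sigma at 12.5 deg) used by the
#: generator.  V1-hV4 follow the published linear size laws; V3AB and VO12
#: have no published sizes, so the generator uses synthetic stand-in values
#: chosen to continue the trend of increasing size up the hierarchy.
GENERATOR_PRF_ENDPOINTS = {
    "V1": (0.4, 1.6),
    "V2": (0.48, 2.3),
    "V3": (1.0, 4.15),
    "hV4": (1.2, 5.8),
    "V3AB": (1.2, 5.0),  # synthetic stand-in
    "VO12": (1.5, 6.0),  # synthetic stand-in
}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Weights are unitless and non-negative.  ``psf_fwhm`` is the Gaussian
    point-spread full-width-at-half-max on the cortical sheet in mm;
    ``ecc_corr_length`` is the latent eccentricity-field correlation length
    in log-degrees; ``pol_corr_length_deg`` the polar-angle analog in
    degrees of polar angle.
    """

    areas: tuple[str, ...] = AREAS
    nodes_per_area: int = 192  # per hemisphere
    #: eccentricity columns per sheet; 24 log-uniform columns guarantee every
    #: one of the 12 published (unequal-log-width) analysis bins is populated
    n_ecc_columns: int = 24
    ecc_extent_mm: float = 40.0
    angle_extent_mm: float = 20.0
    tr: float = 1.8
    condition: str = "rest_fix"
    n_timepoints: int = 333  # ~10 min at TR 1.8 s
    n_runs: int = 2
    n_subjects: int = 10
    w_rf: float = 1.0
    w_ecc: float = 0.7
    w_pol: float = 0.3
    w_homo: float = 0.5
    noise_sd: float = 1.0
    psf_fwhm: float = 3.5
    ecc_corr_length: float = 1.0
    pol_corr_length_deg: float = 30.0
    motion_amp: float = 0.2
    wm_amp: float = 0.3
    csf_amp: float = 0.3
    stim_step_deg: float = 0.25
    stim_extent_deg: float = 14.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.w_rf, self.w_ecc, self.w_pol, self.w_homo):
            if w < 0:
                raise ConfigError("connectivity weights must be non-negative")
        if self.psf_fwhm < 0:
            raise ConfigError("psf_fwhm must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.nodes_per_area < 2 * self.n_ecc_columns:
            raise ConfigError(
                f"nodes_per_area must be >= {2 * self.n_ecc_columns} "
                f"({self.n_ecc_columns} eccentricity columns x 2 angle samples)"
            )
        unknown = set(self.areas) - set(AREAS)
        if unknown:
            raise ConfigError(f"unknown area(s): {unknown}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["areas"] = list(self.areas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "areas" in d:
            d["areas"] = tuple(d["areas"])
        return cls(**d)


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# sheet construction
# ---------------------------------------------------------------------------

LOG_ECC_LO = np.log(ECC_MIN)
LOG_ECC_HI = np.log(ECC_MAX)


def sheet_x_to_ecc(sheet_x_mm: np.ndarray, ecc_extent_mm: float) -> np.ndarray:
    """Closed-form log map from sheet position to eccentricity.

    sheet_x = 0 maps to 0.5 deg, sheet_x = extent maps to 12.5 deg, with
    log-eccentricity uniform in between (the sheet midpoint maps to
    sqrt(0.5 * 12.5) = 2.5 deg).
    """
    frac = np.asarray(sheet_x_mm, float) / ecc_extent_mm
    return np.exp(LOG_ECC_LO + frac * (LOG_ECC_HI - LOG_ECC_LO))


def _sheet_grid(n_ecc: int, n_angle: int, config: SimConfig):
    """Cell-center positions along the two sheet axes (mm)."""
    xs = (np.arange(n_ecc) + 0.5) / n_ecc * config.ecc_extent_mm
    ys = (np.arange(n_angle) + 0.5) / n_angle * config.angle_extent_mm
    return xs, ys


def build_retinotopic_sheet(config: SimConfig) -> NodeTable:
    """Lay out nodes on per-area/hemisphere sheets for both hemispheres.

    Quadrant areas (V1-V3) are split into dorsal (polar angle < 0) and
    ventral (> 0) sheets with half the area's nodes each; hV4, V3AB and
    VO12 get a single hemifield sheet spanning [-90, +90] deg of angle.
    """
    rows = []
    node_id = 0
    for area in config.areas:
        if area in QUADRANT_AREAS:
            sheets = [("dorsal", -90.0, 0.0), ("ventral", 0.0, 90.0)]
            n_sheet = config.nodes_per_area // 2
        else:
            sheets = [("none", -90.0, 90.0)]
            n_sheet = config.nodes_per_area
        n_ecc = config.n_ecc_columns
        n_angle = max(1, n_sheet // n_ecc)
        xs, ys = _sheet_grid(n_ecc, n_angle, config)
        eccs = sheet_x_to_ecc(xs, config.ecc_extent_mm)
        for hemi in ("L", "R"):
            for quad, a_lo, a_hi in sheets:
                angles = a_lo + (np.arange(n_angle) + 0.5) / n_angle * (a_hi - a_lo)
                for j, (x_mm, e) in enumerate(zip(xs, eccs)):
                    for k, (y_mm, theta) in enumerate(zip(ys, angles)):
                        rows.append(
                            {
                                "node_id": node_id,
                                "subject_id": "sim",
                                "hemisphere": hemi,
                                "area": area,
                                "quadrant": quad,
                                "eccentricity_deg": e,
                                "polar_angle_deg": theta,
                                "sheet_x_mm": x_mm,
                                "sheet_y_mm": y_mm,
                            }
                        )
                        node_id += 1
    return NodeTable.from_frame(pd.DataFrame(rows))


def _mirror_slots(nodes: NodeTable) -> np.ndarray:
    """Integer id shared by mirror-symmetric node pairs across hemispheres.

    Sheets are built identically in both hemispheres, so the mirror partner
    of a node is the node with the same (area, quadrant, sheet position) in
    the other hemisphere.
    """
    df = nodes.df
    key = list(
        zip(
            df["area"],
            df["quadrant"],
            np.round(df["sheet_x_mm"], 6),
            np.round(df["sheet_y_mm"], 6),
        )
    )
    codes, _ = pd.factorize(pd.Series(key, dtype=object))
    return codes


def _sheet_groups(nodes: NodeTable):
    """Yield (index array, n_ecc, n_angle) per (area, hemi, quadrant) sheet.

    Within a sheet, nodes are ordered ecc-major, angle-minor by
    construction; the grid shape is recovered from the unique sheet
    coordinates.
    """
    df = nodes.df
    for (_, _, _), idx in df.groupby(
        ["area", "hemisphere", "quadrant"], observed=True, sort=False
    ).groups.items():
        sub = df.loc[idx]
        n_ecc = sub["sheet_x_mm"].nunique()
        n_angle = sub["sheet_y_mm"].nunique()
        order = np.lexsort((sub["sheet_y_mm"].to_numpy(), sub["sheet_x_mm"].to_numpy()))
        yield np.asarray(idx)[order], n_ecc, n_angle


# ---------------------------------------------------------------------------
# latent fields
# ---------------------------------------------------------------------------


def _gp_field(
    grid: np.ndarray, corr_length: float, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a stationary Gaussian-process field on ``grid`` over time.

    Squared-exponential covariance with unit marginal variance; returns a
    (len(grid), T) array whose spatial correlation decays monotonically
    with distance on the grid at scale ``corr_length``.
    """
    d = grid[:, None] - grid[None, :]
    K = np.exp(-0.5 * (d / corr_length) ** 2)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(len(grid)))
    return L @ rng.standard_normal((len(grid), T))


def _interp_field(values: np.ndarray, grid: np.ndarray, field_tt: np.ndarray) -> np.ndarray:
    """Linearly interpolate a (grid x T) field to per-node positions."""
    idx = np.clip(np.searchsorted(grid, values) - 1, 0, len(grid) - 2)
    w = (values - grid[idx]) / (grid[idx + 1] - grid[idx])
    w = np.clip(w, 0.0, 1.0)[:, None]
    return (1 - w) * field_tt[idx] + w * field_tt[idx + 1]


def _prf_drive(
    nodes: NodeTable, config: SimConfig, rng: np.random.Generator, T: int
) -> np.ndarray:
    """Shared white-noise movie filtered through each node's pRF.

    pRF vectors are normalized to unit L2 norm on the stimulus grid, so the
    correlation between two nodes' drives equals the cosine overlap of
    their pRFs.
    """
    step = config.stim_step_deg
    half = config.stim_extent_deg
    axis = np.arange(-half, half + step / 2, step)
    movie = rng.standard_normal((axis.size * axis.size, T))
    x0, y0 = nodes.visual_field_xy()
    ecc = nodes.df["eccentricity_deg"].to_numpy(float)
    out = np.empty((len(nodes), T))
    for area, (s_lo, s_hi) in GENERATOR_PRF_ENDPOINTS.items():
        sel = np.flatnonzero((nodes.df["area"] == area).to_numpy())
        if sel.size == 0:
            continue
        sigma = s_lo + (np.clip(ecc[sel], ECC_MIN, ECC_MAX) - ECC_MIN) * (
            (s_hi - s_lo) / (ECC_MAX - ECC_MIN)
        )
        for chunk in np.array_split(np.arange(sel.size), max(1, sel.size // 128)):
            ii = sel[chunk]
            gx = np.exp(
                -0.5 * ((axis[None, :] - x0[ii][:, None]) / sigma[chunk][:, None]) ** 2
            )
            gy = np.exp(
                -0.5 * ((axis[None, :] - y0[ii][:, None]) / sigma[chunk][:, None]) ** 2
            )
            g = gx[:, :, None] * gy[:, None, :]
            g = g.reshape(len(ii), -1)
            g /= np.linalg.norm(g, axis=1, keepdims=True)
            out[ii] = g @ movie
    return out


def _sheet_noise(
    nodes: NodeTable, config: SimConfig, rng: np.random.Generator, T: int
) -> np.ndarray:
    """White node noise smoothed along each sheet with the psf kernel."""
    out = np.empty((len(nodes), T))
    sigma_mm = config.psf_fwhm * FWHM_TO_SIGMA
    for idx, n_ecc, n_angle in _sheet_groups(nodes):
        raw = rng.standard_normal((n_ecc, n_angle, T))
        if sigma_mm > 0:
            step_x = config.ecc_extent_mm / n_ecc
            step_y = config.angle_extent_mm / n_angle
            raw = ndimage.gaussian_filter(
                raw, sigma=(sigma_mm / step_x, sigma_mm / step_y, 0.0), mode="nearest"
            )
        flat = raw.reshape(n_ecc * n_angle, T)
        sd = flat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out[idx] = flat / sd
    return out


def simulate_nuisance(config: SimConfig, T: int, rng: np.random.Generator | None = None):
    """Six smooth motion traces + derivatives + white-matter and ventricle traces.

    Motion traces are integrated white noise, low-pass smoothed, and scaled
    so peak absolute displacement equals ``motion_amp`` (capped at 1.0 mm,
    mirroring the head-motion inclusion criterion).  Returns a dict of
    arrays: ``motion`` (6, T), ``motion_deriv`` (6, T), ``wm`` (T,),
    ``csf`` (T,).
    """
    if T < 2:
        raise ConfigError("nuisance simulation needs T >= 2")
    if rng is None:
        rng = stage_rng(config.rng_seed, "nuisance")
    cap = min(config.motion_amp, 1.0)
    motion = np.cumsum(rng.standard_normal((6, T)), axis=1)
    motion = ndimage.gaussian_filter1d(motion, sigma=5.0, axis=1, mode="nearest")
    peak = np.abs(motion).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    motion = motion / peak * cap
    deriv = np.diff(motion, axis=1, prepend=motion[:, :1])

    def _trace(amp: float) -> np.ndarray:
        t = ndimage.gaussian_filter1d(
            rng.standard_normal(T), sigma=3.0, mode="nearest"
        )
        sd = t.std()
        return t / sd * amp if sd > 0 and amp > 0 else np.zeros(T)

    return {
        "motion": motion,
        "motion_deriv": deriv,
        "wm": _trace(config.wm_amp),
        "csf": _trace(config.csf_amp),
    }


def nuisance_matrix(nuisance: dict) -> np.ndarray:
    """Stack the nuisance set into a (n_regressors x T) matrix."""
    return np.vstack(
        [nuisance["motion"], nuisance["motion_deriv"], nuisance["wm"], nuisance["csf"]]
    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return a / sd


def simulate_dataset(
    nodes: NodeTable,
    config: SimConfig,
    subject: int = 0,
) -> tuple[list[RunTimeseries], dict]:
    """Simulate one subject's runs with a known ground-truth source mixture.

    For the movie condition the signal latents (stimulus movie, widespread
    fields, homotopic drive) are drawn once and shared across runs
    (stimulus-locked); for rest conditions each run gets independent
    draws.  Noise and nuisance are always independent per run.
    """
    c = config
    if c.w_rf == c.w_ecc == c.w_pol == c.w_homo == c.noise_sd == 0:
        raise ValidationError("degenerate config: all weights and noise_sd are zero")
    T = c.n_timepoints
    log_e = np.log(np.clip(nodes.df["eccentricity_deg"].to_numpy(float), 1e-6, None))
    theta = nodes.df["polar_angle_deg"].to_numpy(float)
    hemi = nodes.df["hemisphere"].to_numpy()
    slots = _mirror_slots(nodes)
    locked = c.condition == "movie"

    ecc_grid = np.linspace(LOG_ECC_LO, LOG_ECC_HI, 64)
    pol_grid = np.linspace(-90.0, 90.0, 64)

    def signal_for(run: int) -> np.ndarray:
        tag = "locked" if locked else f"run{run}"
        y = np.zeros((len(nodes), T))
        if c.w_ecc > 0:
            rng = stage_rng(c.rng_seed, f"s{subject}-{tag}-ecc")
            u = _gp_field(ecc_grid, c.ecc_corr_length, T, rng)
            y += c.w_ecc * _standardize_rows(_interp_field(log_e, ecc_grid, u))
        if c.w_pol > 0:
            for h in ("L", "R"):
                rng = stage_rng(c.rng_seed, f"s{subject}-{tag}-pol-{h}")
                v = _gp_field(pol_grid, c.pol_corr_length_deg, T, rng)
                m = hemi == h
                y[m] += c.w_pol * _standardize_rows(
                    _interp_field(theta[m], pol_grid, v)
                )
        if c.w_homo > 0:
            rng = stage_rng(c.rng_seed, f"s{subject}-{tag}-homo")
            H = rng.standard_normal((slots.max() + 1, T))
            y += c.w_homo * _standardize_rows(H[slots])
        if c.w_rf > 0:
            rng = stage_rng(c.rng_seed, f"s{subject}-{tag}-rf")
            y += c.w_rf * _prf_drive(nodes, c, rng, T)
        return y

    locked_signal = signal_for(0) if locked else None
    runs = []
    for run in range(c.n_runs):
        y = locked_signal.copy() if locked else signal_for(run)
        rng_n = stage_rng(c.rng_seed, f"s{subject}-run{run}-noise")
        if c.noise_sd > 0:
            y += c.noise_sd * _sheet_noise(nodes, c, rng_n, T)
        nuis = simulate_nuisance(
            c, T, stage_rng(c.rng_seed, f"s{subject}-run{run}-nuis")
        )
        # per-node random loadings on unit-SD nuisance shapes, scaled by the
        # configured amplitudes
        rng_l = stage_rng(c.rng_seed, f"s{subject}-run{run}-loadings")
        for amp, traces in (
            (c.motion_amp, nuis["motion"]),
            (c.motion_amp, nuis["motion_deriv"]),
            (c.wm_amp, nuis["wm"][None, :]),
            (c.csf_amp, nuis["csf"][None, :]),
        ):
            if amp > 0 and np.any(traces.std(axis=1) > 0):
                load = amp * rng_l.standard_normal((len(nodes), traces.shape[0]))
                y += load @ _standardize_rows(traces.copy())
        runs.append(
            RunTimeseries(
                matrix=y,
                tr=c.tr,
                condition=c.condition,
                run_id=run,
                subject_id=f"sim{subject:02d}",
            )
        )
    ground_truth = {
        "weights": {
            "w_rf": c.w_rf,
            "w_ecc": c.w_ecc,
            "w_pol": c.w_pol,
            "w_homo": c.w_homo,
        },
        "noise_sd": c.noise_sd,
        "psf_fwhm": c.psf_fwhm,
        "condition": c.condition,
        "stimulus_locked": locked,
        "rng_seed": c.rng_seed,
        "subject": subject,
        "note": "synthetic stand-in mixture; no generative model of real data exists",
    }
    return runs, ground_truth


def simulate_noise_dataset(
    nodes: NodeTable, config: SimConfig, subject: int = 0
) -> list[RunTimeseries]:
    """Pure independent white noise per node, sheet-smoothed at psf_fwhm.

    Basis of the instrumental-noise predictor and the phantom-style
    control: it carries the spatial autocorrelation of the measurement but
    no neural signal.
    """
    c = config
    runs = []
    for run in range(c.n_runs):
        rng = stage_rng(c.rng_seed, f"noise-s{subject}-run{run}")
        y = _sheet_noise(nodes, c, rng, c.n_timepoints)
        runs.append(
            RunTimeseries(
                matrix=y,
                tr=c.tr,
                condition=c.condition,
                run_id=run,
                subject_id=f"nse{subject:02d}",
            )
        )
    return runs
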