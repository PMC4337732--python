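"""Seed-based correlation maps and their visual-field projection.

A seed map holds the Pearson correlation between one node's timeseries and
every node's timeseries, averaged over runs.  For visualization the map can
be projected into visual-field coordinates: each node's (x0, y0) position
is assigned to the nearest cell of a square Cartesian grid spanning
[-12.5, 12.5] deg and cell values are the mean of contributing
correlations.  Sheet smoothing is display-only and guarded against reuse
in the binning/regression analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import NodeTable, RunTimeseries, ValidationError


@dataclass
class SeedMap:
    seed_node_id: int
    r: np.ndarray  # per-node correlation, aligned with the node table rows
    condition: str
    smoothed_fwhm_mm: float | None = None  # set only by smooth_map (display only)

    def __post_init__(self) -> None:
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValidationError("seed map values must lie in [-1, 1]")

    @property
    def display_only(self) -> bool:
        return self.smoothed_fwhm_mm is not None


def seed_correlation_map(
    runs: list[RunTimeseries] | RunTimeseries,
    nodes: NodeTable,
    seed_node_id: int,
) -> SeedMap:
    """Correlation of the seed node's series with every node, run-averaged."""
    if isinstance(runs, RunTimeseries):
        runs = [runs]
    row = np.flatnonzero(nodes.df["node_id"].to_numpy() == seed_node_id)
    if row.size != 1:
        raise ValidationError(f"seed node_id {seed_node_id} not found")
    row = int(row[0])
    maps = []
    for run in runs:
        seed = run.matrix[row]
        if seed.std() == 0:
            raise ValidationError("seed series is constant")
        x = run.matrix - run.matrix.mean(axis=1, keepdims=True)
        s = seed - seed.mean()
        denom = np.linalg.norm(x, axis=1) * np.linalg.norm(s)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x @ s) / denom
        r[denom == 0] = np.nan
        maps.append(np.clip(r, -1, 1))
    return SeedMap(
        seed_node_id=seed_node_id,
        r=np.nanmean(np.stack(maps), axis=0) if len(maps) > 1 else maps[0],
        condition=runs[0].condition,
    )


def project_to_visual_field(
    seed_map: SeedMap,
    nodes: NodeTable,
    grid_n: int = 30,
    extent_deg: float = 12.5,
) -> np.ndarray:
    """Average seed-map values on a grid_n x grid_n visual-field grid.

    Node positions are rounded to the nearest cell center (ties away from
    zero); cells receiving no node are NaN.  Axis 0 indexes x (left to
    right hemifield), axis 1 indexes y (lower to upper field).
    """
    x0, y0 = nodes.visual_field_xy()
    r = seed_map.r
    # map [-extent, extent] onto cell indices 0..grid_n-1
    half = grid_n / 2.0
    scale = half / extent_deg

    def to_idx(v: np.ndarray) -> np.ndarray:
        # round half away from zero, then shift to 0-based cells
        scaled = v * scale
        rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
        return (rounded + half).astype(int)

    ix = to_idx(x0)
    iy = to_idx(y0)
    out = np.full((grid_n, grid_n), np.nan)
    counts = np.zeros((grid_n, grid_n))
    sums = np.zeros((grid_n, grid_n))
    ok = (
        (ix >= 0) & (ix < grid_n) & (iy >= 0) & (iy < grid_n) & np.isfinite(r)
    )
    np.add.at(sums, (ix[ok], iy[ok]), r[ok])
    np.add.at(counts, (ix[ok], iy[ok]), 1)
    nonzero = counts > 0
    out[nonzero] = sums[nonzero] / counts[nonzero]
    return out


def smooth_map(
    seed_map: SeedMap,
    nodes: NodeTable,
    target_fwhm_mm: float = 4.0,
) -> SeedMap:
    """Gaussian smoothing on the cortical sheet, for display only.

    Smoothing runs independently within each (area, hemisphere, quadrant)
    sheet using the node sheet coordinates.  The returned map is flagged
    ``display_only``; feeding it back into binning or model fits raises.
    """
    if seed_map.display_only:
        raise ValidationError("map is already smoothed (display only)")
    sigma = target_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    df = nodes.df
    out = np.full_like(seed_map.r, np.nan)
    for _, idx in df.groupby(
        ["area", "hemisphere", "quadrant"], observed=True, sort=False
    ).groups.items():
        idx = np.asarray(idx)
        x = df.loc[idx, "sheet_x_mm"].to_numpy(float)
        y = df.loc[idx, "sheet_y_mm"].to_numpy(float)
        vals = seed_map.r[idx]
        good = np.isfinite(vals)
        if not good.any():
            continue
        d2 = (x[:, None] - x[None, good]) ** 2 + (y[:, None] - y[None, good]) ** 2
        w = np.exp(-0.5 * d2 / sigma**2)
        out[idx] = (w @ vals[good]) / w.sum(axis=1)
    return SeedMap(
        seed_node_id=seed_map.seed_node_id,
        r=np.clip(out, -1, 1),
        condition=seed_map.condition,
        smoothed_fwhm_mm=target_fwhm_mm,
    )


def guard_display_only(seed_map: SeedMap) -> None:
    """Raise if a display-only (smoothed) map is about to enter an analysis."""
    if seed_map.display_only:
        raise ValidationError(
            "smoothed maps are display-only and must not enter binning or "
            "model-fit analyses"
        )
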