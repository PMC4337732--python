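"""Domain containers and plain-text I/O for retinotopic connectivity analyses.

The analysis operates on three kinds of objects:

* :class:`NodeTable` — one row per cortical-surface node carrying its
  retinotopic coordinates (eccentricity in degrees of visual angle, signed
  polar angle within the hemifield) and its position on a flattened
  per-area cortical sheet (mm).
* :class:`RunTimeseries` — a nodes x timepoints BOLD-like signal matrix for
  one scanning run, with its repetition time and condition label.
* :class:`BinCorrelationMatrix` — Pearson correlations between binned mean
  timeseries for one pair of area/hemisphere/quadrant selections.

Polar angle convention: signed degrees from the horizontal meridian within a
hemifield, 0 = horizontal meridian, +90 = upper vertical meridian, negative
values = lower visual field (dorsal cortex).  The hemisphere label determines
the hemifield: left-hemisphere nodes represent the right hemifield (x0 > 0)
and vice versa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AREAS = ("V1", "V2", "V3", "hV4", "V3AB", "VO12")
QUADRANT_AREAS = ("V1", "V2", "V3")
HEMISPHERES = ("L", "R")
QUADRANTS = ("dorsal", "ventral", "none")
CONDITIONS = ("rest_fix", "rest_closed", "movie")

#: analyses are restricted to the central 12.50 deg of the visual field
ECC_MIN = 0.50
ECC_MAX = 12.50

NODE_TABLE_COLUMNS = [
    "node_id",
    "subject_id",
    "hemisphere",
    "area",
    "quadrant",
    "eccentricity_deg",
    "polar_angle_deg",
    "sheet_x_mm",
    "sheet_y_mm",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Values violate a domain invariant."""


class DimensionError(ValueError):
    """Matrix dimensions are inconsistent with the node table."""


@dataclass
class NodeTable:
    """Per-node retinotopic and anatomical metadata.

    Wraps a :class:`pandas.DataFrame` with the columns in
    ``NODE_TABLE_COLUMNS`` plus a derived boolean ``in_analysis`` column that
    flags nodes inside the [0.50, 12.50] deg eccentricity window.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeTable":
        df = df.copy()
        missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"node table missing column(s): {', '.join(missing)}")
        df["in_analysis"] = (df["eccentricity_deg"] >= ECC_MIN) & (
            df["eccentricity_deg"] <= ECC_MAX
        )
        return cls(df.reset_index(drop=True))

    def validate(self) -> None:
        df = self.df
        if df["node_id"].duplicated().any():
            dup = df.loc[df["node_id"].duplicated(), "node_id"].iloc[0]
            raise ValidationError(f"duplicate node_id: {dup}")
        if (df["eccentricity_deg"] < 0).any():
            raise ValidationError("eccentricity must be non-negative")
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere label(s): {bad_hemi}")
        bad_area = set(df["area"]) - set(AREAS)
        if bad_area:
            raise ValidationError(f"unknown area label(s): {bad_area}")
        bad_quad = set(df["quadrant"]) - set(QUADRANTS)
        if bad_quad:
            raise ValidationError(f"unknown quadrant label(s): {bad_quad}")
        if (df["polar_angle_deg"].abs() > 90).any():
            raise ValidationError("polar angle must lie in [-90, +90]")
        dorsal = df["quadrant"] == "dorsal"
        ventral = df["quadrant"] == "ventral"
        if (df.loc[dorsal, "polar_angle_deg"] >= 0).any():
            raise ValidationError("dorsal nodes must have polar_angle < 0 (lower field)")
        if (df.loc[ventral, "polar_angle_deg"] <= 0).any():
            raise ValidationError("ventral nodes must have polar_angle > 0 (upper field)")

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_flagged(self) -> int:
        """Number of nodes outside the analysis eccentricity window."""
        return int((~self.df["in_analysis"]).sum())

    def select(
        self,
        area: str | None = None,
        hemisphere: str | None = None,
        quadrant: str | None = None,
        analysis_only: bool = True,
    ) -> np.ndarray:
        """Boolean mask (aligned with row order) for a node selection."""
        mask = np.ones(len(self.df), dtype=bool)
        if area is not None:
            mask &= (self.df["area"] == area).to_numpy()
        if hemisphere is not None:
            mask &= (self.df["hemisphere"] == hemisphere).to_numpy()
        if quadrant is not None:
            mask &= (self.df["quadrant"] == quadrant).to_numpy()
        if analysis_only:
            mask &= self.df["in_analysis"].to_numpy()
        return mask

    def subset(self, mask: np.ndarray) -> "NodeTable":
        return NodeTable(self.df.loc[np.asarray(mask, bool)].reset_index(drop=True))

    # -- visual field coordinates ------------------------------------------

    def visual_field_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian visual-field coordinates (x0, y0) in degrees.

        Contralateral representation: left-hemisphere nodes map to the right
        hemifield (x0 > 0), right-hemisphere nodes to the left (x0 < 0).
        Within a hemifield the signed polar angle theta is measured from the
        horizontal meridian, so y0 = e*sin(theta) and |x0| = e*cos(theta).
        """
        e = self.df["eccentricity_deg"].to_numpy(float)
        theta = np.deg2rad(self.df["polar_angle_deg"].to_numpy(float))
        sign = np.where(self.df["hemisphere"].to_numpy() == "L", 1.0, -1.0)
        return sign * e * np.cos(theta), e * np.sin(theta)


def visual_field_to_polar(x0: np.ndarray, y0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :meth:`NodeTable.visual_field_xy` for a known hemifield.

    Returns (eccentricity, signed hemifield polar angle in degrees).  The
    hemifield is inferred from the sign of ``x0``.
    """
    x0 = np.asarray(x0, float)
    y0 = np.asarray(y0, float)
    ecc = np.hypot(x0, y0)
    theta = np.degrees(np.arctan2(y0, np.abs(x0)))
    return ecc, theta


def read_node_table(path: str | Path) -> NodeTable:
    """Read a node table from a TSV file.

    Rows with eccentricity outside [0.50, 12.50] deg are retained but
    flagged ``in_analysis == False``; they never enter binning analyses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"node table {path} missing column(s): {', '.join(missing)}"
        )
    for col in ("eccentricity_deg", "polar_angle_deg", "sheet_x_mm", "sheet_y_mm"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(
                f"non-numeric value in column {col!r} at data row {row} of {path}"
            )
        df[col] = numeric
    return NodeTable.from_frame(df)


def write_node_table(nodes: NodeTable, path: str | Path) -> None:
    nodes.df[NODE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class RunTimeseries:
    """Signal matrix (nodes x timepoints) for one run."""

    matrix: np.ndarray
    tr: float
    condition: str
    run_id: int = 0
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DimensionError("timeseries matrix must be 2-D (nodes x timepoints)")
        if self.matrix.shape[1] < 2:
            raise DimensionError("timeseries must have at least 2 timepoints")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("timeseries contains non-finite values")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]

    def copy_with(self, matrix: np.ndarray) -> "RunTimeseries":
        return RunTimeseries(
            matrix=np.asarray(matrix, float),
            tr=self.tr,
            condition=self.condition,
            run_id=self.run_id,
            subject_id=self.subject_id,
        )


def read_timeseries(path: str | Path, nodes: NodeTable | None = None) -> RunTimeseries:
    """Read a run from either a TSV matrix + JSON sidecar or a .bin + .json pair.

    ``path`` may point at the ``.tsv``/``.bin`` matrix; metadata (tr,
    condition, run id) is read from ``<stem>.json`` next to it.
    """
    path = Path(path)
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    if path.suffix == ".bin":
        matrix = np.fromfile(path, dtype="<f8").reshape(
            meta["n_nodes"], meta["n_timepoints"]
        )
    else:
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    if nodes is not None and matrix.shape[0] != len(nodes):
        raise DimensionError(
            f"timeseries has {matrix.shape[0]} rows but node table has {len(nodes)}"
        )
    return RunTimeseries(
        matrix=matrix,
        tr=float(meta["tr_s"]),
        condition=meta["condition"],
        run_id=int(meta.get("run_id", 0)),
        subject_id=str(meta.get("subject_id", "sim")),
    )


def write_timeseries(ts: RunTimeseries, path: str | Path, binary: bool = False) -> None:
    path = Path(path)
    meta = {
        "n_nodes": ts.n_nodes,
        "n_timepoints": ts.n_timepoints,
        "tr_s": ts.tr,
        "condition": ts.condition,
        "run_id": ts.run_id,
        "subject_id": ts.subject_id,
    }
    if binary:
        ts.matrix.astype("<f8").tofile(path)
    else:
        np.savetxt(path, ts.matrix, delimiter="\t", fmt="%.17g")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


@dataclass
class BinCorrelationMatrix:
    """Pearson correlations between binned mean timeseries for one area pair.

    ``values`` is n_bins_a x n_bins_b with NaN marking missing cells
    (empty or constant bins).  ``bin_grid`` is ``"ecc12"`` for the 12
    eccentricity bins or ``"topo36"`` for the 36-bin topographic grid.
    """

    values: np.ndarray
    area_a: str
    area_b: str
    hemi_a: str
    hemi_b: str
    quadrant_a: str | None = None
    quadrant_b: str | None = None
    bin_grid: str = "ecc12"
    n_runs_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValidationError("correlation values must lie in [-1, 1]")

    @property
    def is_self_pair(self) -> bool:
        return (
            self.area_a == self.area_b
            and self.hemi_a == self.hemi_b
            and self.quadrant_a == self.quadrant_b
        )


def write_matrix(mat: BinCorrelationMatrix, path: str | Path) -> None:
    np.savetxt(path, mat.values, delimiter="\t", fmt="%.17g")
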