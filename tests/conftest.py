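import numpy as np
import pandas as pd
import pytest

from retinocorr.core_data import NodeTable, RunTimeseries
from retinocorr.synthetic_data import SimConfig, build_retinotopic_sheet


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two quadrant areas, small sheets, short runs — fast but structured."""
    return SimConfig(
        areas=("V2", "V3"),
        nodes_per_area=192,  # 96 per quadrant sheet = 24 ecc x 4 angle
        n_timepoints=150,
        n_runs=2,
        n_subjects=3,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_nodes(small_config) -> NodeTable:
    return build_retinotopic_sheet(small_config)


@pytest.fixture
def toy_nodes() -> NodeTable:
    """Hand-built four-node table spanning hemispheres and quadrants."""
    df = pd.DataFrame(
        {
            "node_id": [0, 1, 2, 3],
            "subject_id": ["s"] * 4,
            "hemisphere": ["L", "L", "R", "R"],
            "area": ["V2", "V2", "V2", "V3"],
            "quadrant": ["ventral", "dorsal", "ventral", "ventral"],
            "eccentricity_deg": [1.0, 3.0, 1.0, 6.0],
            "polar_angle_deg": [45.0, -45.0, 45.0, 30.0],
            "sheet_x_mm": [5.0, 15.0, 5.0, 25.0],
            "sheet_y_mm": [5.0, 5.0, 5.0, 10.0],
        }
    )
    return NodeTable.from_frame(df)


def make_run(matrix, tr=1.8, condition="rest_fix", run_id=0):
    return RunTimeseries(
        matrix=np.asarray(matrix, float), tr=tr, condition=condition, run_id=run_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
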