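import numpy as np
import pytest

from retinocorr.core_data import ValidationError
from retinocorr.synthetic_data import SimConfig, build_retinotopic_sheet
from retinocorr.topo_predictors import (
    PRFModel,
    TopoBinGrid,
    VisualFieldGrid,
    bin_response_fields,
    cholesky_local_control,
    distance_predictor,
    homotopic_predictor,
    nse_predictor,
    prf_sigma,
    rf_overlap,
    rf_overlap_matrix,
    rf_predictor,
)


@pytest.fixture(scope="module")
def model_nodes():
    cfg = SimConfig(areas=("V2", "V3"), nodes_per_area=192, n_timepoints=300,
                    n_runs=1, rng_seed=0)
    return build_retinotopic_sheet(cfg), cfg


class TestPRFSizeLaw:
    @pytest.mark.parametrize(
        "area,ecc,expected",
        [
            ("V1", 0.5, 0.4),
            ("V1", 12.5, 1.6),
            ("V1", 6.5, 1.0),  # line through (0.5, 0.4) and (12.5, 1.6)
            ("V2", 0.5, 0.48),
            ("V2", 12.5, 2.3),
            ("V3", 0.5, 1.0),
            ("V3", 12.5, 4.15),
            ("hV4", 0.5, 1.2),
            ("hV4", 12.5, 5.8),
        ],
    )
    def test_published_endpoints_and_interpolation(self, area, ecc, expected):
        assert prf_sigma(area, ecc) == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_clamped(self):
        assert prf_sigma("V1", 0.1) == pytest.approx(0.4)
        assert prf_sigma("V1", 20.0) == pytest.approx(1.6)

    def test_unpublished_areas_rejected(self):
        with pytest.raises(ValidationError, match="V3AB"):
            prf_sigma("V3AB", 3.0)


class TestPRFModel:
    def test_unit_integral_normalization(self):
        prf = PRFModel()
        g = prf.node_prf("V1", 3.0, 0.0, 3.0)
        assert prf.integral(g) == pytest.approx(1.0, abs=1e-3)

    def test_peak_at_center(self):
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.2))
        g = prf.node_prf("V2", 2.0, 1.0, np.hypot(2.0, 1.0))
        axes = prf.grid.axes()
        i, j = np.unravel_index(np.argmax(g), g.shape)
        assert axes[i] == pytest.approx(2.0, abs=0.2)
        assert axes[j] == pytest.approx(1.0, abs=0.2)


class TestResponseFields:
    def test_single_node_bin_field_equals_node_prf(self):
        import pandas as pd

        from retinocorr.core_data import NodeTable

        df = pd.DataFrame(
            {
                "node_id": [0],
                "subject_id": ["s"],
                "hemisphere": ["L"],
                "area": ["V2"],
                "quadrant": ["ventral"],
                "eccentricity_deg": [2.0],
                "polar_angle_deg": [45.0],
                "sheet_x_mm": [10.0],
                "sheet_y_mm": [5.0],
            }
        )
        nodes = NodeTable.from_frame(df)
        grid = TopoBinGrid()
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.25, extent_deg=16))
        fields = bin_response_fields(nodes, "V2", "L", grid, prf)
        b = grid.assign(nodes)[0]
        x0, y0 = nodes.visual_field_xy()
        expected = prf.node_prf("V2", x0[0], y0[0], 2.0)
        np.testing.assert_allclose(fields[b - 1], expected, atol=1e-12)
        # every other bin is empty -> missing field
        others = np.delete(np.arange(grid.n_bins), b - 1)
        assert np.isnan(fields[others]).all()

    def test_fields_have_unit_integral(self, model_nodes):
        nodes, _ = model_nodes
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.25, extent_deg=16))
        fields = bin_response_fields(nodes, "V3", "L", prf=prf)
        good = np.isfinite(fields).all(axis=(1, 2))
        integrals = fields[good].sum(axis=(1, 2)) * prf.grid.cell_area
        np.testing.assert_allclose(integrals, 1.0, atol=1e-6)


class TestOverlap:
    def test_identical_fields_overlap_one(self):
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.2))
        g = prf.node_prf("V1", 2.0, 0.0, 2.0)
        assert rf_overlap(g, g) == pytest.approx(1.0)

    def test_far_fields_overlap_negligible(self):
        prf = PRFModel()
        a = prf.node_prf("V1", 2.0, 5.0, 2.0)  # sigma ~ 0.55
        b = prf.node_prf("V1", 2.0, -5.0, 2.0)  # > 6 sigma apart
        assert rf_overlap(a, b) < 0.01

    def test_overlap_symmetric_and_bounded(self):
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.2))
        a = prf.node_prf("V3", 1.0, 1.0, np.hypot(1, 1))
        b = prf.node_prf("V3", 3.0, -1.0, np.hypot(3, 1))
        assert rf_overlap(a, b) == pytest.approx(rf_overlap(b, a))
        assert 0 <= rf_overlap(a, b) <= 1

    def test_matches_fine_grid_oracle(self):
        """Half-step grid as the independent integration oracle."""
        coarse = PRFModel(grid=VisualFieldGrid(step_deg=0.1))
        fine = PRFModel(grid=VisualFieldGrid(step_deg=0.05))
        rng = np.random.default_rng(0)
        for _ in range(20):
            e1, e2 = rng.uniform(0.6, 10.0, 2)
            t1, t2 = rng.uniform(-80, 80, 2)
            x1, y1 = e1 * np.cos(np.deg2rad(t1)), e1 * np.sin(np.deg2rad(t1))
            x2, y2 = e2 * np.cos(np.deg2rad(t2)), e2 * np.sin(np.deg2rad(t2))
            v_c = rf_overlap(coarse.node_prf("V2", x1, y1, e1),
                             coarse.node_prf("V2", x2, y2, e2))
            v_f = rf_overlap(fine.node_prf("V2", x1, y1, e1),
                             fine.node_prf("V2", x2, y2, e2))
            assert v_c == pytest.approx(v_f, abs=1e-3)

    def test_jaccard_alternative_also_bounded(self):
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.2))
        a = prf.node_prf("V2", 1.0, 0.5, np.hypot(1, 0.5))[None]
        b = prf.node_prf("V2", 2.0, 0.5, np.hypot(2, 0.5))[None]
        m1 = rf_overlap_matrix(a, b, "min_over_max")[0, 0]
        m2 = rf_overlap_matrix(a, b, "jaccard")[0, 0]
        assert 0 <= m2 <= 1
        assert m2 <= m1 + 1e-12  # jaccard denominator is never smaller


class TestDistancePredictors:
    def test_ecc_ramp_endpoints(self):
        P = distance_predictor(axis="ecc").values
        grid = TopoBinGrid()
        E = grid.ecc_index()
        iso = E[:, None] == E[None, :]
        assert (P[iso] == 1.0).all()
        far = np.abs(E[:, None] - E[None, :]) == 5
        assert (P[far] == 0.0).all()

    def test_pol_intra_hemisphere_ramp(self):
        P = distance_predictor(axis="pol", same_hemisphere=True).values
        grid = TopoBinGrid()
        A = grid.angle_index()
        iso = A[:, None] == A[None, :]
        assert (P[iso] == 1.0).all()
        assert P.min() == 0.0

    def test_pol_inter_hemisphere_min_distance_is_one(self):
        P = distance_predictor(axis="pol", same_hemisphere=False).values
        grid = TopoBinGrid()
        A = grid.angle_index()
        # bins adjacent to a vertical meridian (A1 or A6) in both hemifields
        # attain the smallest angular distance, 1 -> largest predictor value
        n = grid.n_angle
        best = P.max()
        assert best == pytest.approx(1.0 - 1.0 / n)
        at_best = np.argwhere(P == best)
        for i, j in at_best:
            assert A[i] in (1, n) and A[j] in (1, n)
        assert (P >= 0).all() and (P < 1).all()  # never exactly iso-polar


class TestHomotopicPredictor:
    def test_mirror_symmetric_bins_attain_unit_overlap(self, model_nodes):
        nodes, _ = model_nodes
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.25, extent_deg=16))
        hp = homotopic_predictor(nodes, "V2", "L", "V2", "R", prf=prf)
        d = np.diag(hp.values)
        # sheets are mirror-built, so bin k in L maps onto bin k in R
        np.testing.assert_allclose(d[np.isfinite(d)], 1.0, atol=1e-9)

    def test_non_mirrored_pairs_weaker_than_mirrored(self, model_nodes):
        nodes, _ = model_nodes
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.25, extent_deg=16))
        hp = homotopic_predictor(nodes, "V2", "L", "V2", "R", prf=prf).values
        good = np.isfinite(hp)
        off = hp[good & ~np.eye(len(hp), dtype=bool)]
        assert np.nanmax(off) < 1.0

    def test_same_hemisphere_rejected(self, model_nodes):
        nodes, _ = model_nodes
        with pytest.raises(ValidationError, match="opposite"):
            homotopic_predictor(nodes, "V2", "L", "V3", "L")

    def test_double_flip_is_identity(self, model_nodes):
        nodes, _ = model_nodes
        grid = TopoBinGrid()
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.5, extent_deg=16))
        once = bin_response_fields(nodes, "V2", "L", grid, prf, flip_x=False)
        x_axis_flipped = bin_response_fields(nodes, "V2", "L", grid, prf,
                                             flip_x=True)[:, ::-1, :]
        # flipping centers and then the grid axis restores the original
        good = np.isfinite(once).all(axis=(1, 2))
        np.testing.assert_allclose(once[good], x_axis_flipped[good], atol=1e-9)


class TestNSEPredictor:
    def test_intra_area_diagonal_exceeds_far_cells(self, model_nodes):
        nodes, cfg = model_nodes
        nse = nse_predictor(nodes, cfg, "V2", "L", "V2", "L", n_surrogates=3,
                            seed=1)
        v = nse.values
        diag = np.nanmean(np.diag(v))
        grid = TopoBinGrid()
        E = grid.ecc_index()
        A = grid.angle_index()
        far = (np.abs(E[:, None] - E[None, :]) >= 3) | (
            np.abs(A[:, None] - A[None, :]) >= 3
        )
        assert diag > np.nanmean(v[far]) + 0.1

    def test_inter_hemisphere_flat(self, model_nodes):
        nodes, cfg = model_nodes
        nse = nse_predictor(nodes, cfg, "V2", "L", "V2", "R", n_surrogates=3,
                            seed=1)
        v = nse.values
        assert abs(np.nanmean(np.diag(v)) - np.nanmean(v)) < 0.05

    def test_surrogate_averaging_stabilizes(self, model_nodes):
        nodes, cfg = model_nodes
        a = nse_predictor(nodes, cfg, "V2", "L", "V2", "L", n_surrogates=10,
                          seed=1).values
        b = nse_predictor(nodes, cfg, "V2", "L", "V2", "L", n_surrogates=10,
                          seed=99).values
        ok = np.isfinite(a) & np.isfinite(b)
        r = np.corrcoef(a[ok], b[ok])[0, 1]
        assert r > 0.9


class TestCholeskyControl:
    def test_identity_target_recovers_identity(self, model_nodes):
        nodes, cfg = model_nodes
        out = cholesky_local_control(
            np.eye(36), nodes, cfg, "V2", "L", "V2", "L",
            apply_smoothing=False, seed=0,
        ).values
        ok = np.isfinite(out)
        off = out[ok & ~np.eye(36, dtype=bool)]
        assert np.abs(off).mean() < 3.0 / np.sqrt(cfg.n_timepoints)

    def test_known_pairwise_correlation_recovered(self, model_nodes):
        nodes, cfg = model_nodes
        target = np.eye(36)
        target[0, 1] = target[1, 0] = 0.5
        out = cholesky_local_control(
            target, nodes, cfg, "V2", "L", "V2", "L",
            apply_smoothing=False, seed=3,
        ).values
        assert out[0, 1] == pytest.approx(0.5, abs=3.0 / np.sqrt(cfg.n_timepoints))

    def test_smoothing_raises_adjacent_bin_correlation(self, model_nodes):
        nodes, cfg = model_nodes
        raw = cholesky_local_control(np.eye(36), nodes, cfg, "V2", "L", "V2",
                                     "L", apply_smoothing=False, seed=5).values
        sm = cholesky_local_control(np.eye(36), nodes, cfg, "V2", "L", "V2",
                                    "L", apply_smoothing=True, seed=5).values
        grid = TopoBinGrid()
        E = grid.ecc_index()
        A = grid.angle_index()
        adjacent = (np.abs(E[:, None] - E[None, :]) == 1) & (
            A[:, None] == A[None, :]
        )
        ok = np.isfinite(raw) & np.isfinite(sm)
        assert np.nanmean(sm[adjacent & ok]) > np.nanmean(raw[adjacent & ok])

    def test_asymmetric_target_rejected(self, model_nodes):
        nodes, cfg = model_nodes
        bad = np.eye(36)
        bad[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            cholesky_local_control(bad, nodes, cfg, "V2", "L", "V2", "L")


class TestPredictorCollinearity:
    def test_rf_correlates_with_widespread_predictors_intra_hemisphere(
        self, model_nodes
    ):
        """On realistic grids the local RF predictor shares substantial
        variance with the eccentricity and polar-angle ramps for self
        pairs (sign and magnitude class, not an exact value)."""
        nodes, _ = model_nodes
        prf = PRFModel(grid=VisualFieldGrid(step_deg=0.25, extent_deg=16))
        rf = rf_predictor(nodes, "V2", "L", "V2", "L", prf=prf).values
        ecc = distance_predictor(axis="ecc").values
        pol = distance_predictor(axis="pol").values
        ok = np.isfinite(rf)
        r_ecc = np.corrcoef(rf[ok], ecc[ok])[0, 1]
        r_pol = np.corrcoef(rf[ok], pol[ok])[0, 1]
        assert r_ecc > 0.3
        assert r_pol > 0.3
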