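"""The occupancy statistic, normalization, encoding, and pixel scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapocc.density import DensityGrid, map_values_at_points
from mapocc.errors import ParameterError, ValidationError
from mapocc.occupancy import (
    OccupancyMatrix,
    apply_manual_categories,
    encode_manual_category,
    feature_occupancy,
    normalize_matrix,
    occupancy_matrix,
    refine_pixel_size,
)
from mapocc.models import AtomSelection
from mapocc.synthetic import FeatureState, make_toy_model, simulate_class_map


def flat_grid(value, n=12):
    return DensityGrid(np.full((n, n, n), value), (1.0,) * 3)


def toy_selection(model):
    return AtomSelection("all", np.arange(len(model)))


class TestFeatureOccupancy:
    def test_uniform_density_above_threshold_scores_one(self, toy_model):
        model, _ = toy_model
        grid = DensityGrid(np.full((90, 90, 90), 0.2), (1.0,) * 3, origin=(-45.0,) * 3)
        assert feature_occupancy(grid, toy_selection(model), model, 0.05) == 1.0

    def test_zero_map_scores_zero(self, toy_model):
        model, _ = toy_model
        grid = DensityGrid(np.zeros((90, 90, 90)), (1.0,) * 3, origin=(-45.0,) * 3)
        assert feature_occupancy(grid, toy_selection(model), model, 0.05) == 0.0

    def test_empty_selection_scores_zero_with_warning(self, toy_model, caplog):
        model, _ = toy_model
        grid = flat_grid(0.2)
        empty = AtomSelection("none", np.empty(0, dtype=int))
        with caplog.at_level("WARNING"):
            assert feature_occupancy(grid, empty, model, 0.05) == 0.0
        assert "empty" in caplog.text

    def test_planted_seven_of_ten_counts_exactly(self):
        """7 atoms in 0.1 density, 3 in 0 density -> 0.7, vs a recount oracle."""
        n = 40
        data = np.zeros((n, n, n))
        data[: n // 2] = 0.1  # hot half-space
        grid = DensityGrid(data, (1.0,) * 3)
        hot = [(5.0 + i, 20.0, 20.0) for i in range(7)]
        cold = [(30.0 + i, 20.0, 20.0) for i in range(3)]
        positions = np.array(hot + cold)

        class Stub:
            pass

        model = Stub()
        model.positions = positions
        sel = AtomSelection("f", np.arange(10))
        got = feature_occupancy(grid, sel, model, 0.05)
        oracle = sum(
            1 for p in positions if map_values_at_points(grid, p[None]) > 0.05
        ) / len(positions)
        assert got == oracle == 0.7

    def test_monotone_non_increasing_in_threshold(self, rng, toy_model):
        model, _ = toy_model
        data = rng.uniform(0, 0.2, size=(90, 90, 90))
        grid = DensityGrid(data, (1.0,) * 3, origin=(-45.0,) * 3)
        sel = toy_selection(model)
        occs = [feature_occupancy(grid, sel, model, t) for t in np.linspace(0, 0.2, 9)]
        assert all(a >= b for a, b in zip(occs, occs[1:]))

    def test_gray_scale_covariance(self, toy_model):
        """Scaling map and threshold together leaves occupancy unchanged."""
        model, seg = toy_model
        states = {f.feature_id: FeatureState("partial", alpha=0.5) for f in seg.features}
        grid = simulate_class_map(model, seg, states, noise_sigma=0.0, seed=3)
        m1 = occupancy_matrix({"c": grid}, model, seg, threshold=0.05)
        scaled = grid.with_data(grid.data * 7.5)
        m2 = occupancy_matrix({"c": scaled}, model, seg, threshold=0.05 * 7.5)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)


class TestOccupancyMatrix:
    def test_single_full_feature_gives_unit_matrix(self, toy_model):
        model, seg = toy_model
        states = {f.feature_id: FeatureState("full") for f in seg.features}
        grid = simulate_class_map(model, seg, states, noise_sigma=0.0, seed=1)
        m = occupancy_matrix({"only": grid}, model, seg)
        assert m.values.shape == (len(seg), 1)
        np.testing.assert_allclose(m.values, 1.0)

    def test_defaults_recorded_in_provenance(self, toy_model):
        model, seg = toy_model
        states = {f.feature_id: FeatureState("full") for f in seg.features}
        grid = simulate_class_map(model, seg, states, seed=1)
        m = occupancy_matrix({"c": grid}, model, seg)
        assert m.provenance["threshold"] == 0.05
        assert m.provenance["lowpass_A"] == 5.0

    def test_series_recovery_within_tolerance(self, series6):
        m = occupancy_matrix(series6.maps, series6.model, series6.segmentation)
        errors = []
        for j, cid in enumerate(m.class_ids):
            for i, fid in enumerate(m.feature_ids):
                expected = series6.manifest.expected_occupancy[cid][fid]
                if expected is not None:
                    errors.append(abs(m.values[i, j] - expected))
        assert np.mean(errors) < 0.05


class TestNormalization:
    def test_hand_evaluated_two_by_two(self):
        """[[0.8,0.4],[0.2,0.1]]: median 0.3; rows divided by 0.8 and 0.3."""
        m = OccupancyMatrix(np.array([[0.8, 0.4], [0.2, 0.1]]), ["f1", "f2"], ["c1", "c2"])
        out = normalize_matrix(m)
        np.testing.assert_allclose(out.values[0], [1.0, 0.5])
        np.testing.assert_allclose(out.values[1], [0.2 / 0.3, 0.1 / 0.3])

    def test_hand_evaluated_four_by_four(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 1, size=(4, 4))
        out = normalize_matrix(OccupancyMatrix(values, list("abcd"), list("wxyz")))
        # independent recomputation, spreadsheet style
        med = float(np.median(values))
        expected = np.array(
            [row / max(row.max(), med) for row in values]
        )
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_single_cell_normalizes_to_one(self):
        out = normalize_matrix(OccupancyMatrix([[0.6]], ["f"], ["c"]))
        assert out.values[0, 0] == 1.0

    def test_all_zero_matrix_stays_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_matrix(OccupancyMatrix(np.zeros((3, 2)), list("abc"), list("xy")))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_double_normalization_rejected(self):
        out = normalize_matrix(OccupancyMatrix([[0.5]], ["f"], ["c"]))
        with pytest.raises(ParameterError):
            normalize_matrix(out)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_outputs_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 8), rng.integers(1, 8))
        values = rng.uniform(0, 1, size=shape)
        out = normalize_matrix(
            OccupancyMatrix(
                values,
                [f"f{i}" for i in range(shape[0])],
                [f"c{j}" for j in range(shape[1])],
            )
        )
        assert np.all(out.values >= 0.0) and np.all(out.values <= 1.0 + 1e-12)
        med = np.median(values)
        for i in range(shape[0]):
            if values[i].max() >= med and values[i].max() > 0:
                assert out.values[i].max() == pytest.approx(1.0)


class TestManualCategories:
    @pytest.mark.parametrize(
        "label, value",
        [
            ("near_native", 0.1),
            ("slightly_distorted", 0.085),
            ("highly_distorted", 0.045),
            ("disordered", 0.0),
        ],
    )
    def test_encoding_values(self, label, value):
        assert encode_manual_category(label) == value

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            encode_manual_category("wobbly")

    def test_replacement_happens_before_normalization(self):
        import pandas as pd

        m = OccupancyMatrix(np.array([[0.9, 0.8]]), ["H1"], ["c1", "c2"])
        table = pd.DataFrame(
            [{"feature_id": "H1", "class_id": "c2", "label": "highly_distorted"}]
        )
        patched = apply_manual_categories(m, table)
        assert patched.values[0, 1] == 0.045
        assert patched.values[0, 0] == 0.9


class TestPixelSizeScan:
    def make_mislabeled(self, true_voxel=1.07, labeled=1.09, noise=0.005, seed=7):
        model, seg = make_toy_model(8, 12, seed=5)
        states = {f.feature_id: FeatureState("full") for f in seg.features}
        grid = simulate_class_map(
            model, seg, states, voxel_size=true_voxel, noise_sigma=noise, seed=seed
        )
        n = grid.shape[0]
        center = grid.center()
        mislabeled = DensityGrid(
            grid.data, (labeled,) * 3, tuple(center - (n - 1) / 2.0 * labeled)
        )
        return model, grid, mislabeled

    def test_recovers_planted_miscalibration(self):
        model, _, mislabeled = self.make_mislabeled()
        res = refine_pixel_size(mislabeled, model, scan_range=(0.96, 1.06), steps=11)
        assert res.converged
        assert abs(res.voxel_size - 1.07) / 1.07 < 0.005

    def test_self_consistent_map_peaks_at_unit_scale(self):
        model, grid, _ = self.make_mislabeled()
        res = refine_pixel_size(grid, model, scan_range=(0.97, 1.03), steps=7)
        step = (1.03 - 0.97) / 6
        assert res.converged
        assert abs(res.scale - 1.0) <= step

    def test_pure_noise_flags_unconverged(self, rng):
        model, _, mislabeled = self.make_mislabeled()
        noise = DensityGrid(
            rng.normal(0, 0.01, size=mislabeled.shape), mislabeled.voxel_size
        )
        res = refine_pixel_size(noise, model, steps=5)
        assert not res.converged

    def test_scan_range_must_bracket_one(self, toy_model):
        model, _ = toy_model
        grid = flat_grid(0.1, n=32)
        with pytest.raises(ParameterError):
            refine_pixel_size(grid, model, scan_range=(1.01, 1.05))
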