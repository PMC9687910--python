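"""Map I/O, interpolation, Fourier filtering, and mask construction."""

import numpy as np
import pytest
from scipy import ndimage

from mapocc.density import (
    DensityGrid,
    lowpass_filter,
    make_solvent_mask,
    map_value_at_point,
    map_values_at_points,
    read_map,
    write_map,
)
from mapocc.errors import EmptyMaskError, MapFormatError, ParameterError


def brute_trilinear(data, voxel, origin, point):
    """Independent 8-corner interpolation, written from the definition."""
    f = [(point[a] - origin[a]) / voxel[a] for a in range(3)]
    n = data.shape
    if any(f[a] < 0 or f[a] > n[a] - 1 for a in range(3)):
        return 0.0
    i0 = [min(int(np.floor(f[a])), n[a] - 2) for a in range(3)]
    t = [f[a] - i0[a] for a in range(3)]
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[0] if dx else 1 - t[0])
                    * (t[1] if dy else 1 - t[1])
                    * (t[2] if dz else 1 - t[2])
                )
                total += w * data[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return total


class TestMapIO:
    def test_round_trip_is_bitwise_lossless(self, tmp_path, rng):
        grid = DensityGrid(
            rng.normal(size=(16, 16, 16)), (1.09, 1.09, 1.09), origin=(3.5, -2.0, 0.25)
        )
        write_map(grid, tmp_path / "m.mrc")
        back = read_map(tmp_path / "m.mrc")
        assert np.array_equal(grid.data, back.data)
        assert back.voxel_size == pytest.approx(grid.voxel_size, abs=1e-5)
        assert back.origin == pytest.approx(grid.origin, abs=1e-5)

    def test_anisotropic_voxels_survive_the_header(self, tmp_path, rng):
        grid = DensityGrid(rng.normal(size=(8, 10, 12)), (1.0, 1.1, 1.2))
        write_map(grid, tmp_path / "a.mrc")
        back = read_map(tmp_path / "a.mrc")
        assert back.voxel_size == pytest.approx((1.0, 1.1, 1.2), abs=1e-5)
        assert back.shape == (8, 10, 12)

    def test_unsupported_mode_is_rejected_naming_the_field(self, tmp_path, rng):
        grid = DensityGrid(rng.normal(size=(8, 8, 8)), (1.0,) * 3)
        path = tmp_path / "bad.mrc"
        write_map(grid, path)
        raw = bytearray(path.read_bytes())
        raw[12:16] = (6).to_bytes(4, "little")  # mode 6 = uint16, outside contract
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="MODE"):
            read_map(path)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ParameterError):
            DensityGrid(np.zeros((1, 8, 8)), (1.0,) * 3)


class TestInterpolation:
    def test_voxel_center_returns_stored_value(self, rng):
        grid = DensityGrid(rng.normal(size=(8, 8, 8)), (1.3, 1.3, 1.3), origin=(5.0, 0.0, -2.0))
        point = (5.0 + 3 * 1.3, 0.0 + 4 * 1.3, -2.0 + 2 * 1.3)
        assert map_value_at_point(grid, point) == pytest.approx(grid.data[3, 4, 2], rel=1e-6)

    def test_reproduces_linear_fields_exactly(self):
        i, j, k = np.indices((12, 12, 12), dtype=float)
        grid = DensityGrid(2.0 * i + 3.0 * j - 1.5 * k + 4.0, (1.0,) * 3)
        rng = np.random.default_rng(5)
        for point in rng.uniform(0.5, 10.5, size=(25, 3)):
            expected = 2.0 * point[0] + 3.0 * point[1] - 1.5 * point[2] + 4.0
            assert map_value_at_point(grid, point) == pytest.approx(expected, rel=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        grid = DensityGrid(
            rng.normal(size=(12, 12, 12)), (1.07, 1.07, 1.07), origin=(-3.0, 1.0, 2.0)
        )
        points = rng.uniform(-2.0, 12.0, size=(60, 3))
        got = map_values_at_points(grid, points)
        want = [brute_trilinear(grid.data, grid.voxel_size, grid.origin, p) for p in points]
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_outside_hull_is_exactly_zero(self, rng):
        grid = DensityGrid(rng.normal(size=(8, 8, 8)) + 10.0, (1.0,) * 3)
        assert map_value_at_point(grid, (-0.5, 2.0, 2.0)) == 0.0
        assert map_value_at_point(grid, (2.0, 2.0, 7.5)) == 0.0

    def test_continuity_near_hull_boundary(self, rng):
        grid = DensityGrid(rng.normal(size=(8, 8, 8)), (1.0,) * 3)
        a = map_value_at_point(grid, (3.2, 4.1, 5.0 - 5e-7))
        b = map_value_at_point(grid, (3.2, 4.1, 5.0 + 5e-7))
        span = grid.data.max() - grid.data.min()
        assert abs(a - b) < 1e-5 * span


class TestLowpass:
    def test_constant_grid_unchanged(self):
        grid = DensityGrid(np.full((16, 16, 16), 2.5), (1.0,) * 3)
        out = lowpass_filter(grid, 5.0)
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-6)

    def test_mean_preserved(self, rng):
        grid = DensityGrid(rng.normal(size=(24, 24, 24)), (1.1,) * 3)
        out = lowpass_filter(grid, 6.0)
        assert out.data.mean() == pytest.approx(grid.data.mean(), abs=1e-9)

    def test_near_idempotent_on_smooth_data(self):
        i, j, k = np.indices((48, 48, 48), dtype=float)
        blob = np.exp(-((i - 24) ** 2 + (j - 20) ** 2 + (k - 28) ** 2) / 18.0)
        grid = DensityGrid(blob, (1.0,) * 3)
        once = lowpass_filter(grid, 5.0)
        twice = lowpass_filter(once, 5.0)
        span = grid.data.max() - grid.data.min()
        assert np.abs(twice.data - once.data).max() < 1e-3 * span

    @pytest.mark.parametrize(
        "wavelength, check",
        [(3.0, "blocked"), (20.0, "passed")],
    )
    def test_sinusoid_response_at_5A(self, wavelength, check):
        n = 60
        x = np.arange(n)
        wave = np.sin(2 * np.pi * x / wavelength)
        grid = DensityGrid(
            np.broadcast_to(wave[:, None, None], (n, n, n)).copy(), (1.0,) * 3
        )
        out = lowpass_filter(grid, 5.0)
        if check == "blocked":
            assert out.data.max() < 1.0 / 100.0
        else:
            assert out.data.max() == pytest.approx(1.0, rel=0.01)

    def test_linearity(self, rng):
        a = DensityGrid(rng.normal(size=(16, 16, 16)), (1.0,) * 3)
        b = DensityGrid(rng.normal(size=(16, 16, 16)), (1.0,) * 3)
        combo = DensityGrid(2.0 * a.data + 3.0 * b.data, (1.0,) * 3)
        lhs = lowpass_filter(combo, 5.0).data
        rhs = 2.0 * lowpass_filter(a, 5.0).data + 3.0 * lowpass_filter(b, 5.0).data
        # atol reflects float32 map storage
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_sub_nyquist_resolution_rejected(self):
        grid = DensityGrid(np.zeros((8, 8, 8)), (1.5,) * 3)
        with pytest.raises(ParameterError):
            lowpass_filter(grid, 2.9)


class TestSolventMask:
    def _cube_map(self, value=1.0, n=48):
        data = np.zeros((n, n, n))
        data[20:28, 20:28, 20:28] = value
        return DensityGrid(data, (1.0,) * 3)

    def test_bright_cube_masked_with_monotone_soft_edge(self):
        grid = self._cube_map()
        mask = make_solvent_mask(grid, sphere_radius=20, prefilter_resolution=8,
                                 threshold=0.05, expand=3, soft_edge=4)
        assert mask.data.min() >= 0.0 and mask.data.max() <= 1.0
        assert mask.data[24, 24, 24] >= 0.5
        assert mask.data[2, 2, 2] == 0.0
        ray = mask.data[24, 24, 28:]
        drops = np.diff(ray)
        assert np.all(drops <= 1e-9)  # non-increasing leaving the region

    def test_equals_one_on_predilation_binary_set(self):
        grid = self._cube_map()
        filtered = lowpass_filter(
            DensityGrid(np.where(
                np.sum((np.indices(grid.shape) - 23.5) ** 2, axis=0) <= 400,
                grid.data, 0.0), (1.0,) * 3),
            8.0,
        )
        binary = filtered.data > 0.05
        mask = make_solvent_mask(grid, 20, 8, 0.05, expand=3, soft_edge=4)
        assert np.all(mask.data[binary] == 1.0)

    def test_two_blob_volume_matches_distance_transform_oracle(self):
        n = 48
        data = np.zeros((n, n, n))
        data[10:16, 10:16, 10:16] = 1.0
        data[30:36, 30:36, 30:36] = 1.0
        grid = DensityGrid(data, (1.0,) * 3)
        expand, soft = 3, 4
        mask = make_solvent_mask(grid, 30, 8, 0.05, expand=expand, soft_edge=soft)
        # oracle: recompute the binary region independently, then bound the
        # mask support by distance-transform shells
        sphered = np.where(
            np.sum((np.indices((n, n, n)) - (n - 1) / 2.0) ** 2, axis=0) <= 30**2,
            data, 0.0,
        )
        filt = lowpass_filter(DensityGrid(sphered, (1.0,) * 3), 8.0).data
        binary = filt > 0.05
        dist = ndimage.distance_transform_edt(~binary)
        assert np.all(mask.data[dist <= expand] == 1.0)
        assert np.all(mask.data[dist >= expand + soft] == 0.0)
        # half-voxel margin absorbs lattice EDT discretization
        inner = (dist > expand + 0.8) & (dist < expand + soft - 0.8)
        assert np.all((mask.data[inner] > 0.0) & (mask.data[inner] < 1.0))

    def test_threshold_above_maximum_raises(self):
        grid = self._cube_map(value=0.01)
        with pytest.raises(EmptyMaskError):
            make_solvent_mask(grid, 20, 8, threshold=5.0, expand=2, soft_edge=2)

    def test_default_recipe_recorded_in_provenance(self, rng):
        n = 40
        data = np.zeros((n, n, n))
        data[15:25, 15:25, 15:25] = 1.0
        mask = make_solvent_mask(DensityGrid(data, (2.0,) * 3, origin=(0.0,) * 3))
        assert mask.provenance == {
            "sphere_radius_A": 155.0,
            "prefilter_resolution_A": 15.0,
            "threshold": 0.012,
            "expand_voxels": 5,
            "soft_edge_voxels": 5,
        }
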