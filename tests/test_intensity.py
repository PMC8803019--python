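"""RNFL projection and fingerprint-style ridge orientation estimation."""

import numpy as np
import pytest

from rnfbtrace.core import AxialAngleMap
from rnfbtrace.intensity import (
    ProjectionImage,
    estimation_weights,
    initial_orientation,
    model_distance_map,
    neighbor_distance_map,
    normalize_projection,
    project_rnfl,
    scaled_parameters,
    smooth_orientation,
)
from rnfbtrace.polarization import LayerBoundaries


def grating(theta_deg, shape=(80, 80), period=8.0, contrast=0.5):
    """Sinusoidal grating whose ridges run along ``theta_deg``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    t = np.deg2rad(theta_deg)
    phase = (xx * np.sin(t) - yy * np.cos(t)) * 2 * np.pi / period
    return ProjectionImage(values=0.5 + contrast * np.cos(phase), normalized=True)


def wrap_axial_deg(a_rad, b_deg):
    return np.abs(((np.degrees(a_rad) - b_deg) + 90) % 180 - 90)


class TestProjectRNFL:
    def _boundaries(self, h, w, ilm, bng, boo):
        return LayerBoundaries(
            ilm=np.full((h, w), ilm), rnfl_gcl=np.full((h, w), bng), opl_onl=np.full((h, w), boo)
        )

    def test_constant_volume_projects_constant(self):
        vol = np.full((5, 6, 30), 7.0)
        img = project_rnfl(vol, self._boundaries(5, 6, 2, 20, 28), max_len=15)
        assert np.allclose(img.values, 7.0)
        assert img.valid.all()

    def test_band_clamped_by_rnfl_thickness(self):
        vol = np.zeros((4, 4, 30))
        vol[:, :, 10:20] = 1.0  # RNFL occupies z in [10, 20)
        b = self._boundaries(4, 4, 10, 20, 28)  # thickness 10 < max_len 15
        img = project_rnfl(vol, b, max_len=15)
        assert np.allclose(img.values, 1.0)  # band never crosses the ILM

    def test_bright_lamina_against_loop_oracle(self):
        rng = np.random.default_rng(4)
        h, w, d = 6, 7, 25
        vol = rng.uniform(0, 1, (h, w, d))
        ilm = rng.integers(0, 3, (h, w))
        bng = ilm + rng.integers(1, 18, (h, w))
        b = LayerBoundaries(ilm=ilm, rnfl_gcl=bng, opl_onl=np.full((h, w), d - 1))
        img = project_rnfl(vol, b, max_len=15)
        for y in range(h):
            for x in range(w):
                be = min(bng[y, x] - ilm[y, x], 15)
                expected = np.mean([vol[y, x, bng[y, x] - i] for i in range(1, be + 1)])
                assert img.values[y, x] == pytest.approx(expected, abs=1e-12)

    def test_zero_band_invalid(self):
        vol = np.ones((3, 3, 10))
        b = self._boundaries(3, 3, 4, 4, 8)
        img = project_rnfl(vol, b, max_len=15)
        assert not img.valid.any()


class TestNormalize:
    def test_ramp_background_suppressed(self):
        rng = np.random.default_rng(6)
        h = w = 120
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ramp = 0.01 * xx + 0.005 * yy
        ridges = 0.2 * np.cos(xx * 2 * np.pi / 7)
        img = ProjectionImage(values=ramp + ridges + 0.02 * rng.random((h, w)))
        out = normalize_projection(img, window=31)
        # the smooth ramp is gone: local windowed means sit near mid-range
        from rnfbtrace.core import masked_window_mean

        local, _ = masked_window_mean(out.values, np.ones_like(out.values, bool), 31)
        interior = local[20:-20, 20:-20]
        assert np.abs(interior - interior.mean()).max() < 0.1

    def test_output_range_and_extremes(self):
        rng = np.random.default_rng(7)
        img = ProjectionImage(values=rng.normal(5, 2, (60, 60)))
        out = normalize_projection(img, window=21)
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        assert out.normalized and not out.degenerate

    def test_constant_image_degenerate_flat_half(self):
        out = normalize_projection(ProjectionImage(values=np.full((40, 40), 3.3)), window=15)
        assert out.degenerate
        assert np.allclose(out.values, 0.5)

    def test_window_validation(self):
        img = ProjectionImage(values=np.zeros((10, 10)))
        with pytest.raises(ValueError):
            normalize_projection(img, window=10)


class TestInitialOrientation:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 65.0, 90.0, 140.0])
    def test_grating_orientation_recovered(self, theta):
        phi = initial_orientation(grating(theta), halfsize=4)
        interior = np.zeros(phi.shape, bool)
        interior[12:-12, 12:-12] = True
        sel = interior & phi.valid
        err = wrap_axial_deg(phi.values[sel], theta)
        assert np.median(err) < 1.0

    def test_uniform_image_all_invalid(self):
        img = ProjectionImage(values=np.full((40, 40), 0.5), normalized=True)
        phi = initial_orientation(img)
        assert not phi.valid.any()

    def test_perpendicular_gratings_differ_by_90(self):
        a = initial_orientation(grating(25.0), halfsize=4)
        b = initial_orientation(grating(115.0), halfsize=4)
        sel = np.zeros(a.shape, bool)
        sel[12:-12, 12:-12] = True
        d = np.degrees(np.abs(((a.values - b.values) + np.pi / 2) % np.pi - np.pi / 2))
        assert np.median(np.abs(d[sel] - 90) % 180) < 2.0

    def test_vessel_values_cannot_leak(self):
        """Mask-awareness: arbitrary values under the vessel mask never
        change the estimate."""
        base = grating(40.0)
        mask = np.zeros(base.shape, bool)
        mask[30:40, 30:40] = True
        img1 = ProjectionImage(values=base.values.copy(), vessel_mask=mask, normalized=True)
        vals2 = base.values.copy()
        vals2[mask] = 123.0
        img2 = ProjectionImage(values=vals2, vessel_mask=mask, normalized=True)
        p1 = initial_orientation(img1, halfsize=4)
        p2 = initial_orientation(img2, halfsize=4)
        assert np.array_equal(p1.valid, p2.valid)
        assert np.allclose(p1.values[p1.valid], p2.values[p2.valid])


class TestDistancesAndWeights:
    def _field(self, values, valid=None):
        valid = np.ones(values.shape, bool) if valid is None else valid
        return AxialAngleMap(values=values, valid=valid)

    def test_model_distance_trivial_and_oracle(self):
        rng = np.random.default_rng(12)
        a = self._field(rng.uniform(0, np.pi, (20, 20)))
        b = self._field(rng.uniform(0, np.pi, (20, 20)))
        assert np.allclose(model_distance_map(a, a), 0.0)
        perp = self._field((a.values + np.pi / 2) % np.pi)
        assert np.allclose(model_distance_map(a, perp), 2.0, atol=1e-12)
        d = model_distance_map(a, b)
        # per-pixel scalar oracle
        expected = np.hypot(
            np.sin(2 * a.values) - np.sin(2 * b.values),
            np.cos(2 * a.values) - np.cos(2 * b.values),
        )
        assert np.allclose(d, expected)

    def test_neighbor_distance_constant_field_zero(self):
        f = self._field(np.full((30, 30), 1.0))
        assert np.allclose(neighbor_distance_map(f, halfsize=3), 0.0, atol=1e-12)

    def test_neighbor_distance_flags_flipped_pixel(self):
        vals = np.full((31, 31), 0.4)
        vals[15, 15] = 0.4 + np.pi / 2
        d = neighbor_distance_map(self._field(vals), halfsize=3)
        assert d[15, 15] == d.max()
        assert d.max() <= 2.0 + 1e-12

    def test_weights_reference_points(self):
        zeros = np.zeros((10, 10))
        w = estimation_weights(zeros, zeros, avg_window=3)
        assert np.allclose(w.values, 1.0)
        w2 = estimation_weights(np.full((10, 10), 2.0), zeros, avg_window=1)
        assert np.allclose(w2.values, 0.0)
        # 1 - 0.5*sqrt(8) < 0 clamps to 0
        w3 = estimation_weights(np.full((10, 10), 2.0), np.full((10, 10), 2.0), avg_window=1)
        assert np.allclose(w3.values, 0.0)


class TestSmoothOrientation:
    def test_constant_field_preserved(self):
        from rnfbtrace.core import WeightMap

        f = AxialAngleMap(values=np.full((40, 40), 0.9), valid=np.ones((40, 40), bool))
        w = WeightMap(values=np.full((40, 40), 0.7))
        out = smooth_orientation(f, w, n_max=5)
        assert np.allclose(out.values[out.valid], 0.9, atol=1e-12)

    def test_salt_and_pepper_noise_suppressed(self):
        from rnfbtrace.core import WeightMap

        rng = np.random.default_rng(3)
        vals = np.full((60, 60), np.deg2rad(30.0))
        flip = rng.random((60, 60)) < 0.10
        vals[flip] += np.pi / 2
        f = AxialAngleMap(values=vals, valid=np.ones((60, 60), bool))
        out = smooth_orientation(f, WeightMap(values=np.ones((60, 60))), n_max=6)
        interior = np.zeros((60, 60), bool)
        interior[10:-10, 10:-10] = True
        err = wrap_axial_deg(out.values[interior], 30.0)
        assert np.median(err) < 2.0

    def test_window_shrinks_to_exclude_fovea(self):
        from rnfbtrace.core import WeightMap

        h = w = 41
        fovea = (20.0, 20.0)
        vals = np.full((h, w), 0.3)
        vals[20, 20] = 0.3 + np.pi / 2  # a deviant fovea pixel
        f = AxialAngleMap(values=vals, valid=np.ones((h, w), bool))
        out = smooth_orientation(f, WeightMap(values=np.ones((h, w))), n_max=8, fovea_xy=fovea)
        # any pixel >1 px from the fovea must be untouched by the fovea value
        yy, xx = np.mgrid[0:h, 0:w]
        away = np.maximum(np.abs(xx - 20), np.abs(yy - 20)) > 1
        assert np.allclose(out.values[away & out.valid], 0.3, atol=1e-12)

    def test_zero_weight_window_invalid(self):
        from rnfbtrace.core import WeightMap

        f = AxialAngleMap(values=np.zeros((10, 10)), valid=np.zeros((10, 10), bool))
        out = smooth_orientation(f, WeightMap(values=np.zeros((10, 10))), n_max=2)
        assert not out.valid.any()


def test_scaled_parameters_reference_grid_identity():
    p = scaled_parameters(8.2)
    assert p["tensor_halfsize"] == 7
    assert p["bg_window"] == 145
    assert p["smooth_halfsize"] == 30
    coarse = scaled_parameters(75.0)
    assert coarse["tensor_halfsize"] < 7 and coarse["bg_window"] % 2 == 1
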