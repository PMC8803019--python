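"""Polar resampling, circular entry-angle statistics, ICC, RMSE, reports."""

import numpy as np
import pandas as pd
import pytest

from rnfbtrace.core import RetinalGeometry
from rnfbtrace.evaluation import (
    GARWAY_HEATH_SECTORS,
    PolarTrace,
    VFGrid,
    build_report,
    circular_difference,
    entry_angle_stats,
    icc_ak,
    load_vf_grid,
    mean_polar_trace,
    to_polar,
    trace_rmse,
)
from rnfbtrace.tracing import Trace


@pytest.fixture()
def geom():
    return RetinalGeometry(
        fovea_xy=(0.0, 50.0), onh_xy=(60.0, 50.0), onh_radius_deg=4.0,
        um_per_deg=300.0, spacing_x=75.0, spacing_y=75.0,
    )


def radial_trace(geom, angle_from_temporal_deg, r_from=15.0, r_to=3.5, n=200):
    """Straight trace along a fixed angular position, periphery -> ONH."""
    # temporal direction is -x here; angle increases toward +y side
    a = np.deg2rad(180.0 - angle_from_temporal_deg)
    rs = np.linspace(r_from, r_to, n) * geom.um_per_deg
    onh = geom.onh_um
    pts = np.stack([onh[0] + rs * np.cos(a), onh[1] + rs * np.sin(a)], axis=1) / 75.0
    return Trace(points=pts, step_px=1.0, seed=tuple(pts[0]), direction_mode="inward",
                 termination="onh_reached")


class TestToPolar:
    def test_straight_radial_trace(self, geom):
        tr = radial_trace(geom, 57.0)
        pol = to_polar(tr, geom)
        assert pol.has_entry
        assert pol.entry_angle == pytest.approx(57.0, abs=1e-6)
        assert np.allclose(pol.angle_deg, 57.0, atol=1e-6)
        assert np.all(np.diff(pol.r_deg) > 0)
        assert pol.r_deg[0] == pytest.approx(4.0)

    def test_circular_arc_degenerate(self, geom):
        a = np.linspace(0, np.pi / 3, 50)
        onh = geom.onh_um
        pts = np.stack([onh[0] + 8 * 300 * np.cos(a), onh[1] + 8 * 300 * np.sin(a)], axis=1) / 75.0
        tr = Trace(points=pts, step_px=1.0, seed=tuple(pts[0]),
                   direction_mode="inward", termination="max_steps")
        pol = to_polar(tr, geom)
        assert pol.degenerate and not pol.has_entry

    def test_unwrap_across_the_cut(self, geom):
        # trace crossing the temporal horizontal: angles pass through 0/360
        angs = np.linspace(-20.0, 20.0, 80)  # around the cut
        rs = np.linspace(14.0, 3.8, 80)
        a = np.deg2rad(180.0 - angs)
        onh = geom.onh_um
        pts = np.stack(
            [onh[0] + rs * 300 * np.cos(a), onh[1] + rs * 300 * np.sin(a)], axis=1
        ) / 75.0
        tr = Trace(points=pts, step_px=1.0, seed=tuple(pts[0]),
                   direction_mode="inward", termination="onh_reached")
        pol = to_polar(tr, geom)
        assert np.max(np.abs(np.diff(pol.angle_deg))) < 5.0

    def test_trace_not_reaching_circle_has_no_entry(self, geom):
        tr = radial_trace(geom, 30.0, r_from=15.0, r_to=7.0)
        pol = to_polar(tr, geom)
        assert not pol.has_entry
        assert not pol.degenerate


class TestEntryAngleStats:
    def test_wraparound_range(self):
        rng, off = entry_angle_stats([359.0, 1.0, 3.0])
        assert rng == pytest.approx(4.0)

    def test_brute_force_oracle(self):
        rng_ = np.random.default_rng(14)
        eas = rng_.uniform(0, 360, 7)
        rng, off = entry_angle_stats(eas)
        brute = max(
            abs(((a - b) + 180) % 360 - 180) for a in eas for b in eas
        )
        assert rng == pytest.approx(brute)

    def test_identical_angles(self):
        rng, off = entry_angle_stats([42.0, 42.0, 42.0])
        assert rng == 0.0 and off == 0.0

    def test_symmetric_degenerate_raises(self):
        with pytest.raises(ValueError):
            entry_angle_stats([0.0, 120.0, 240.0])

    def test_range_at_least_offset(self):
        rng_ = np.random.default_rng(3)
        for _ in range(20):
            eas = rng_.uniform(0, 60, 5)
            r, o = entry_angle_stats(eas)
            assert r >= o >= 0


class TestICC:
    def test_identical_raters_give_one(self):
        m = np.tile(np.array([[10.0], [20.0], [30.0], [40.0]]), (1, 3))
        assert icc_ak(m) == pytest.approx(1.0)

    def test_matches_explicit_anova_and_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.normal(180, 30, size=(5, 3))
            mine = icc_ak(m)
            # independent oracle 1: explicit ANOVA mean squares
            n, k = m.shape
            grand = m.mean()
            msr = k * np.sum((m.mean(1) - grand) ** 2) / (n - 1)
            msc = n * np.sum((m.mean(0) - grand) ** 2) / (k - 1)
            mse = (np.sum((m - grand) ** 2) - msr * (n - 1) - msc * (k - 1)) / (
                (n - 1) * (k - 1)
            )
            oracle = (msr - mse) / (msr + (msc - mse) / n)
            assert mine == pytest.approx(oracle, abs=1e-10)
            # independent oracle 2: pingouin ICC(A,k)
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "s": m.ravel(),
                }
            )
            tab = pg.intraclass_corr(data=df, targets="t", raters="r", ratings="s")
            ref = float(tab.loc[tab.Type == "ICC(A,k)", "ICC"].iloc[0])
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_full_turn_on_one_rater_changes_nothing(self):
        rng = np.random.default_rng(1)
        m = rng.normal(90, 15, size=(6, 3))
        m2 = m.copy()
        m2[:, 1] += 360.0
        assert icc_ak(m) == pytest.approx(icc_ak(m2), abs=1e-9)

    def test_wraparound_compensation_across_the_cut(self):
        # traces near the 0/360 cut with small disagreement: ICC must be
        # high, not destroyed by the wrap
        base = np.array([358.0, 2.0, 356.0, 4.0, 359.0])
        m = np.stack([base, (base + 1) % 360, (base - 1) % 360], axis=1)
        assert icc_ak(m) > 0.8

    def test_zero_between_trace_variance_undefined(self):
        with pytest.raises(ValueError):
            icc_ak(np.full((4, 3), 15.0))


class TestTraceRMSE:
    def _pt(self, r, a, ea=None):
        return PolarTrace(r_deg=np.asarray(r), angle_deg=np.asarray(a), entry_angle=ea)

    def test_identical_traces_zero(self, geom):
        r = np.arange(4, 12.001, 0.1)
        t = self._pt(r, np.full_like(r, 80.0), 80.0)
        assert trace_rmse(t, [t], geom) == 0.0

    def test_constant_offset_closed_form(self, geom):
        r = np.arange(4, 10.001, 0.1)
        t1 = self._pt(r, np.full_like(r, 100.0), 100.0)
        t2 = self._pt(r, np.full_like(r, 101.0), 101.0)
        expected = np.sqrt(np.mean((np.deg2rad(1.0) * r * 300.0) ** 2))
        assert trace_rmse(t1, [t2], geom) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_single_pair(self, geom):
        rng = np.random.default_rng(9)
        r = np.arange(4, 9.001, 0.1)
        t1 = self._pt(r, 50 + np.cumsum(rng.normal(0, 0.2, r.size)))
        t2 = self._pt(r, 50 + np.cumsum(rng.normal(0, 0.2, r.size)))
        assert trace_rmse(t1, [t2], geom) == pytest.approx(trace_rmse(t2, [t1], geom))

    def test_rotation_invariance(self, geom):
        rng = np.random.default_rng(10)
        r = np.arange(4, 9.001, 0.1)
        a1 = 30 + np.cumsum(rng.normal(0, 0.3, r.size))
        a2 = a1 + rng.normal(0, 1.0, r.size)
        base = trace_rmse(self._pt(r, a1), [self._pt(r, a2)], geom)
        rot = trace_rmse(self._pt(r, a1 + 90), [self._pt(r, a2 + 90)], geom)
        assert base == pytest.approx(rot, abs=1e-9)

    def test_no_overlap_raises(self, geom):
        t1 = self._pt(np.arange(4, 6.001, 0.1), np.zeros(21))
        t2 = self._pt(np.arange(8, 10.001, 0.1), np.zeros(21))
        with pytest.raises(ValueError):
            trace_rmse(t1, [t2], geom)


class TestVFGridAndReport:
    def test_bundled_grid_contract(self):
        vf = load_vf_grid()
        assert len(vf) == 52
        assert set(vf.points["sector"]) == set(GARWAY_HEATH_SECTORS)
        # blind spot excluded
        assert not ((vf.points["x_deg"] == 15) & (vf.points["y_deg"].abs() == 3)).any()

    def test_grid_validates_sectors(self):
        df = pd.DataFrame({"id": ["a"], "x_deg": [3], "y_deg": [3], "sector": ["XX"]})
        with pytest.raises(ValueError):
            VFGrid(points=df)

    def test_seed_mapping_blind_spot_lands_on_onh(self, fit, geometry):
        df = pd.DataFrame({"id": ["bs"], "x_deg": [15.0], "y_deg": [0.0], "sector": ["T"]})
        pt = VFGrid(points=df).seed_points_px(fit)[0]
        assert np.allclose(pt, geometry.onh_xy, atol=1e-6)

    def _polar_sets(self, geom, sigma_deg, seed=0):
        rng = np.random.default_rng(seed)
        vf = load_vf_grid()
        raters = {}
        base_angles = {pid: rng.uniform(10, 350) for pid in vf.points["id"]}
        r = np.arange(4, 12.001, 0.1)
        for rater in ("g1", "g2", "g3"):
            traces = {}
            for pid in vf.points["id"]:
                a = base_angles[pid] + rng.normal(0, sigma_deg)
                traces[pid] = PolarTrace(
                    r_deg=r, angle_deg=np.full_like(r, a), entry_angle=a % 360
                )
            raters[rater] = traces
        return raters, vf

    def test_duplicated_rater_perfect_agreement(self, geom):
        raters, vf = self._polar_sets(geom, sigma_deg=5.0, seed=2)
        dup = {"g1": raters["g1"], "g2": raters["g1"], "g3": raters["g1"]}
        report = build_report(dup, vf, geom)
        df = report.to_frame()
        overall = df[df.sector == "Overall"].iloc[0]
        assert overall["ea_range_mean"] == pytest.approx(0.0, abs=1e-9)
        assert overall["ea_offset_mean"] == pytest.approx(0.0, abs=1e-9)
        assert overall["trace_rmse_um_mean"] == pytest.approx(0.0, abs=1e-9)
        assert overall["ea_icc"] == pytest.approx(1.0)

    def test_offset_grows_with_rater_noise(self, geom):
        offsets = []
        for sigma in (1.0, 2.0, 4.0):
            raters, vf = self._polar_sets(geom, sigma_deg=sigma, seed=7)
            df = build_report(raters, vf, geom).to_frame()
            offsets.append(float(df[df.sector == "Overall"]["ea_offset_mean"].iloc[0]))
        assert offsets[0] < offsets[1] < offsets[2]

    def test_overall_row_aggregates_all_sectors(self, geom):
        raters, vf = self._polar_sets(geom, sigma_deg=2.0, seed=3)
        df = build_report(raters, vf, geom).to_frame()
        per_sector = df[df.sector != "Overall"]["n_traces"].sum()
        overall_n = int(df[df.sector == "Overall"]["n_traces"].iloc[0])
        assert overall_n == per_sector == 52

    def test_insufficient_sector_flagged(self, geom):
        raters, vf = self._polar_sets(geom, sigma_deg=2.0, seed=4)
        small = vf.points.head(3).copy()  # only IT points
        vf_small = VFGrid(points=small)
        df = build_report(raters, vf_small, geom).to_frame()
        t_row = df[df.sector == "T"].iloc[0]
        assert bool(t_row["insufficient"])


def test_mean_polar_trace_circular_average():
    r = np.arange(4, 8.001, 0.1)
    t1 = PolarTrace(r_deg=r, angle_deg=np.full_like(r, 359.0), entry_angle=359.0)
    t2 = PolarTrace(r_deg=r, angle_deg=np.full_like(r, 1.0), entry_angle=1.0)
    mean = mean_polar_trace([t1, t2])
    d = np.abs(circular_difference(mean.angle_deg, 0.0))
    assert np.max(d) < 1e-9
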