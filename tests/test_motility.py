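"""Motility metrics: speeds, displacement, persistence, MSD, diffusion."""

import numpy as np
import pytest

import dermadisperse as dd
from dermadisperse.datamodel import Track, TrackSet
from dermadisperse.motility import PhaseWindow, default_fit_window
from tests.conftest import make_track


def brownian_tracks(rng, n, n_steps, D, dt=10.0):
    sig = np.sqrt(2 * D * dt)
    out = []
    for i in range(n):
        steps = rng.normal(0, sig, size=(n_steps, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        out.append(Track(f"b{i}", f"b{i}", "non_dividing",
                         np.arange(n_steps + 1) * dt, pos[:, 0], pos[:, 1]))
    return out


class TestInstantaneousSpeed:
    def test_stationary_track_zero_speed(self):
        tr = make_track(points=[(1, 1)] * 5)
        _, v = dd.instantaneous_speed(tr)
        assert np.all(v == 0)

    def test_straight_track_constant_speed(self):
        tr = make_track(points=[(i, 0) for i in range(6)])  # 1 um per 10-min frame
        t, v = dd.instantaneous_speed(tr)
        np.testing.assert_allclose(v, 0.1)
        np.testing.assert_allclose(t, tr.t[1:])

    def test_single_point_track_warns_empty(self):
        tr = make_track(points=[(0, 0)])
        with pytest.warns(UserWarning):
            t, v = dd.instantaneous_speed(tr)
        assert len(v) == 0

    def test_population_mean_speed_matches_generator_target(self):
        ts, truth = dd.gen_trackset(dd.TrackGenParams(
            n_nondividing=200, n_lineages=0, duration=1000.0, seed=5))
        speeds = [np.mean(dd.instantaneous_speed(tr)[1]) for tr in ts.tracks]
        assert np.mean(speeds) == pytest.approx(truth["interphase_speed_um_min"], rel=0.05)


class TestDisplacementMetrics:
    W = PhaseWindow("non_dividing", 0.0, 1e6)

    @pytest.mark.parametrize("points,euclid,accum,pers", [
        ([(0, 0), (1, 0), (2, 0), (3, 0)], 3.0, 3.0, 1.0),      # straight
        ([(0, 0), (2, 0), (0, 0)], 0.0, 4.0, 0.0),              # out-and-back
        ([(0, 0), (3, 0), (3, 4)], 5.0, 7.0, 5.0 / 7.0),        # 3-4-5 triangle
    ])
    def test_hand_computed_paths(self, points, euclid, accum, pers):
        m = dd.displacement_metrics(make_track(points=points), self.W)
        assert m.euclidean == pytest.approx(euclid)
        assert m.accumulated == pytest.approx(accum)
        assert (m.persistence or 0.0) == pytest.approx(pers)

    def test_stationary_persistence_flagged_undefined(self):
        m = dd.displacement_metrics(make_track(points=[(0, 0)] * 3), self.W)
        assert m.persistence is None

    def test_too_few_points_gives_no_data(self):
        m = dd.displacement_metrics(make_track(points=[(0, 0), (1, 1)]),
                                    PhaseWindow("x", 500.0, 600.0))
        assert m is None


class TestPhaseWindows:
    def test_lineage_windows_follow_division_time(self):
        mother = make_track("mo", role="mother", division_time=300.0,
                            points=[(0, 0)] * 19)  # t = 0..180... placed 120..300 below
        mother.t = 120.0 + np.arange(19) * 10.0
        daughter = make_track("da", role="daughter", division_time=300.0,
                              points=[(0, 0)] * 37)  # 300..660
        ts = TrackSet([mother, daughter], 10.0, (-1, -1, 1, 1))
        w = dd.assign_phase_windows(ts)
        (mw, midx), = w["mo"]
        assert (mw.t_start, mw.t_end) == (120.0, 300.0)
        labels = [x[0].label for x in w["da"]]
        assert labels == ["daughter_0_180", "daughter_180_360"]
        w0, i0 = w["da"][0]
        assert (w0.t_start, w0.t_end) == (300.0, 480.0)
        assert len(i0) == 18  # [300, 480) at 10-min frames

    def test_non_dividing_single_window_covers_track(self, simple_trackset):
        w = dd.assign_phase_windows(simple_trackset)
        for tid, entries in w.items():
            assert len(entries) == 1
            assert len(entries[0][1]) == 3

    def test_division_at_first_frame_warns_empty_mother_window(self):
        mother = make_track("mo", role="mother", division_time=0.0, points=[(0, 0)])
        ts = TrackSet([mother], 10.0, (-1, -1, 1, 1))
        with pytest.warns(UserWarning):
            dd.assign_phase_windows(ts)


class TestMSD:
    def test_stationary_msd_zero(self):
        tracks = [make_track(points=[(2, 3)] * 10)]
        c = dd.msd_time_ensemble(tracks, 50.0, 10.0)
        assert np.all(c.msd == 0)

    def test_ballistic_msd_closed_form(self):
        v = 0.1  # um/min -> 1 um per frame
        tr = make_track(points=[(v * 10 * i, 0) for i in range(21)])
        c = dd.msd_time_ensemble([tr], 100.0, 10.0)
        np.testing.assert_allclose(c.msd, (v * c.lags) ** 2, rtol=1e-12)

    def test_largest_single_pair_lag_is_exact(self):
        tr = make_track(points=[(0, 0), (1, 1), (3, 0), (0, 4)])
        c = dd.msd_time_ensemble([tr], 30.0, 10.0)
        assert c.n_pairs[-1] == 1
        assert c.msd[-1] == pytest.approx(16.0)  # (0,0)->(0,4)

    def test_gap_pairs_skipped_not_interpolated(self):
        tr = Track("g", "g", "non_dividing", np.array([0.0, 10.0, 30.0]),
                   np.array([0.0, 1.0, 3.0]), np.zeros(3))
        c = dd.msd_time_ensemble([tr], 30.0, 10.0)
        # lag 10: only (0,10); lag 20: only (10,30); lag 30: (0,30)
        np.testing.assert_array_equal(c.n_pairs, [1, 1, 1])
        np.testing.assert_allclose(c.msd, [1.0, 4.0, 9.0])

    def test_brownian_slope_recovers_4D(self, rng):
        D = 0.05
        tracks = brownian_tracks(rng, 500, 100, D)
        curve = dd.msd_time_ensemble(tracks, 250.0, 10.0)
        est = dd.diffusion_coefficient(curve, default_fit_window(curve, tracks))
        assert est.slope == pytest.approx(4 * D, rel=0.10)
        assert est.d_normalised == pytest.approx(D, rel=0.10)

    def test_rotation_translation_invariance(self, rng):
        tracks = brownian_tracks(rng, 5, 30, 0.05)
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = []
        for tr in tracks:
            xy = (R @ np.vstack([tr.x, tr.y])).T + np.array([55.0, -12.0])
            rotated.append(Track(tr.track_id, tr.lineage_id, tr.role, tr.t,
                                 xy[:, 0], xy[:, 1]))
        c1 = dd.msd_time_ensemble(tracks, 100.0, 10.0)
        c2 = dd.msd_time_ensemble(rotated, 100.0, 10.0)
        np.testing.assert_allclose(c1.msd, c2.msd, rtol=1e-9)
        v1 = np.concatenate([dd.instantaneous_speed(t)[1] for t in tracks])
        v2 = np.concatenate([dd.instantaneous_speed(t)[1] for t in rotated])
        np.testing.assert_allclose(v1, v2, rtol=1e-9)


class TestDiffusionCoefficient:
    def test_exact_line_recovered(self):
        lags = np.arange(1, 11) * 10.0
        curve = dd.MSDCurve(lags, 0.2 * lags, np.ones(10, int))
        est = dd.diffusion_coefficient(curve)
        assert est.slope == pytest.approx(0.2, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0)

    def test_flat_curve_zero_slope(self):
        lags = np.arange(1, 6) * 10.0
        est = dd.diffusion_coefficient(dd.MSDCurve(lags, np.zeros(5), np.ones(5, int)))
        assert est.slope == 0.0

    def test_single_lag_window_rejected(self):
        lags = np.arange(1, 6) * 10.0
        curve = dd.MSDCurve(lags, lags * 0.1, np.ones(5, int))
        with pytest.raises(ValueError):
            dd.diffusion_coefficient(curve, (10.0, 10.0))

    def test_fast_phase_daughters_diffuse_faster(self):
        ts, _ = dd.gen_trackset(dd.TrackGenParams(n_nondividing=60, n_lineages=40,
                                                  duration=1200.0, seed=9))
        fast = dd.phase_tracks(ts, "daughter_0_180")
        slow = dd.phase_tracks(ts, "non_dividing")
        cf = dd.msd_time_ensemble(fast, 90.0, 10.0)
        cs = dd.msd_time_ensemble(slow, 90.0, 10.0)
        assert dd.diffusion_coefficient(cf).slope > dd.diffusion_coefficient(cs).slope
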