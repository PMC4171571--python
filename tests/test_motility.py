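"""Trajectory statistics: unit semantics, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streaklab import motility, synth
from tests.conftest import make_brownian_tracks, straight_track

DT = 1.0 / 6.0


class TestInstantVelocities:
    def test_stationary_track_has_zero_speed(self):
        t = synth.Track("s", np.arange(10) * DT, np.full(10, 3.0), np.full(10, -2.0))
        assert (motility.instant_velocities(t).v == 0).all()

    def test_unit_arithmetic_ten_minute_frame(self):
        # 6 μm in one 10-min frame is 36 μm/h
        t = synth.Track("u", [0.0, DT], [0.0, 6.0], [0.0, 0.0])
        assert motility.instant_velocities(t).v[0] == pytest.approx(36.0)

    def test_sixty_one_frames_give_sixty_samples(self):
        ser = motility.instant_velocities(straight_track(n_frames=61))
        assert len(ser) == 60
        # timestamps are frame-pair midpoints
        assert ser.t[0] == pytest.approx(DT / 2.0)

    def test_short_track_warns_and_flags(self):
        t = synth.Track.__new__(synth.Track)  # bypass validation for the edge
        t.cell_id, t.times = "tiny", np.array([0.0])
        t.x, t.y, t.g = np.array([0.0]), np.array([0.0]), None
        with pytest.warns(UserWarning, match="fewer than 2"):
            ser = motility.instant_velocities(t)
        assert not ser.ok and len(ser) == 0


class TestVelocityBinning:
    def test_paper_default_edges_partition_a_uniform_grid(self):
        ser = motility.instant_velocities(straight_track(v_um_h=10.0, n_frames=601))
        bins = motility.bin_velocities_by_start(
            [ser], motility.DEFAULT_BIN_EDGES)
        in_range = np.sum((ser.t >= 0) & (ser.t < 60))
        assert sum(b.n for b in bins) == in_range
        # abutting bins never share a sample
        assert sum(b.n for b in bins) == len(set(map(float, ser.t[ser.t < 60])))

    def test_samples_before_first_edge_fall_in_no_bin(self):
        ser = motility.instant_velocities(straight_track(n_frames=13))  # 2 h span
        bins = motility.bin_velocities_by_start([ser], [50.0, 60.0])
        assert all(b.n == 0 for b in bins)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            motility.bin_velocities_by_start([], [0.0, 40.0, 20.0])


class TestCumulativeDistance:
    def test_stationary_and_straight_line_limits(self):
        still = synth.Track("s", np.arange(5) * DT, np.zeros(5), np.zeros(5))
        assert (motility.cumulative_distance(still) == 0).all()
        line = straight_track(v_um_h=36.0, n_frames=7)  # exactly 1 h
        cum = motility.cumulative_distance(line)
        assert cum[-1] == pytest.approx(36.0)
        net = np.hypot(line.x[-1] - line.x[0], line.y[-1] - line.y[0])
        assert cum[-1] == pytest.approx(net)

    def test_total_distance_bounds_net_displacement(self, act_chi):
        ts = synth.simulate_trajectories(act_chi, 100, 10.0, DT, seed=21)
        for tr in ts:
            total = motility.cumulative_distance(tr)[-1]
            net = np.hypot(tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0])
            assert total >= net - 1e-9


def brute_force_msd(track, max_k):
    """Independent oracle: double loop over all index pairs."""
    out = np.zeros(max_k + 1)
    for k in range(1, max_k + 1):
        acc = []
        for i in range(track.n - k):
            acc.append((track.x[i + k] - track.x[i]) ** 2
                       + (track.y[i + k] - track.y[i]) ** 2)
        out[k] = np.mean(acc)
    return out


class TestMSD:
    def test_stationary_msd_is_zero(self):
        t = synth.Track("s", np.arange(10) * DT, np.zeros(10), np.zeros(10))
        assert (motility.msd_curve(t, 1.0).msd == 0).all()

    def test_ballistic_msd_is_exactly_quadratic(self):
        v = 24.0
        t = straight_track(v_um_h=v, n_frames=31, angle=0.7)
        c = motility.msd_curve(t, 3.0)
        np.testing.assert_allclose(c.msd, (v * c.lags) ** 2, rtol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(n=st.integers(5, 20), seed=st.integers(0, 10_000))
    def test_msd_matches_brute_force_on_small_tracks(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 2.0, size=(n, 2)), axis=0)
        t = synth.Track("h", np.arange(n) * DT, pos[:, 0], pos[:, 1])
        max_k = n - 1
        c = motility.msd_curve(t, max_k * DT)
        np.testing.assert_allclose(c.msd[1:], brute_force_msd(t, max_k)[1:],
                                   rtol=1e-10)
        assert c.msd[0] == 0.0
        assert (np.diff(c.n_pairs[1:]) <= 0).all()

    def test_random_walk_msd_linear_in_lag(self):
        # uncorrelated steps of fixed length ℓ: msd(τ) ≈ ℓ²·τ/dt
        rng = np.random.default_rng(3)
        ln = 4.0
        ang = rng.uniform(-np.pi, np.pi, 499)
        pos = np.vstack([[0, 0], np.cumsum(
            np.column_stack([ln * np.cos(ang), ln * np.sin(ang)]), axis=0)])
        t = synth.Track("rw", np.arange(500) * DT, pos[:, 0], pos[:, 1])
        c = motility.msd_curve(t, 2.0)
        k = np.arange(1, len(c.lags))
        np.testing.assert_allclose(c.msd[1:], ln * ln * k, rtol=0.15)

    def test_invalid_max_lag(self):
        t = straight_track(n_frames=10)
        with pytest.raises(ValueError, match="max_lag"):
            motility.msd_curve(t, DT / 2.0)


class TestEnsembleMSD:
    def test_single_track_equals_clipped_per_cell_curve(self, act_chi_tracks):
        tr = act_chi_tracks.tracks[0]
        one = synth.TrackSet([tr], dt=DT)
        ens = motility.ensemble_msd(one, (0.0, 20.0), max_lag=2.0, min_pairs=1)
        mask = (tr.times >= 0) & (tr.times < 20.0)
        clip = synth.Track(tr.cell_id, tr.times[mask], tr.x[mask], tr.y[mask])
        solo = motility.msd_curve(clip, 2.0)
        np.testing.assert_allclose(ens.msd, solo.msd, rtol=1e-12)

    def test_duplicated_track_changes_nothing(self, act_chi_tracks):
        tr = act_chi_tracks.tracks[0]
        one = motility.ensemble_msd(synth.TrackSet([tr], dt=DT), None, 2.0)
        two = motility.ensemble_msd(synth.TrackSet([tr, tr], dt=DT), None, 2.0)
        np.testing.assert_allclose(one.msd, two.msd, rtol=1e-12)

    def test_heterogeneous_population_recovers_mean_diffusivity(self):
        rng = np.random.default_rng(11)
        ds = rng.uniform(50, 800, 200)
        ts = make_brownian_tracks(ds, seed=11)
        est = motility.fit_effective_diffusivity(
            motility.ensemble_msd(ts, None, max_lag=1.0), (0.0, 1.0))
        assert est.d_eff == pytest.approx(float(ds.mean()), rel=0.10)

    def test_no_overlap_is_an_error(self, act_chi_tracks):
        with pytest.raises(motility.EmptyResultError):
            motility.ensemble_msd(act_chi_tracks, (1000.0, 1010.0), 2.0)

    def test_censoring_biases_long_lag_msd_downwards(self, act_chi):
        """Field-of-view censoring truncates the fast excursions, so the
        long-lag ensemble MSD must not exceed the uncensored value on
        matched seeds."""
        base = act_chi.replace(confine_radius_post=500.0)
        unc = synth.simulate_trajectories(
            base.replace(fov_halfwidth=1e6), 100, 40.0, DT, seed=13)
        cen = synth.simulate_trajectories(
            base.replace(fov_halfwidth=150.0), 100, 40.0, DT, seed=13)
        assert any(t.censored_at is not None for t in cen)
        mu = motility.ensemble_msd(unc, None, max_lag=10.0)
        mc = motility.ensemble_msd(cen, None, max_lag=10.0)
        assert mc.msd[-1] <= mu.msd[-1]


class TestDiffusivityFit:
    def test_exact_line_recovers_unit_diffusivity(self):
        lags = np.arange(13) * DT
        c = motility.MSDCurve(lags, 4.0 * lags, np.full(13, 100))
        est = motility.fit_effective_diffusivity(c, (0.0, 2.0))
        assert est.d_eff == pytest.approx(1.0)
        assert est.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_zero_msd_gives_zero_diffusivity(self):
        lags = np.arange(13) * DT
        c = motility.MSDCurve(lags, np.zeros(13), np.full(13, 100))
        assert motility.fit_effective_diffusivity(c, (0.0, 2.0)).d_eff == 0.0

    def test_too_few_points_rejected(self):
        lags = np.arange(3) * DT
        c = motility.MSDCurve(lags, 4.0 * lags, np.full(3, 10))
        with pytest.raises(motility.InsufficientDataError):
            motility.fit_effective_diffusivity(c, (0.0, DT * 1.5))

    def test_timecourse_flat_for_homogeneous_brownian_motion(self):
        ts = make_brownian_tracks(np.full(150, 300.0), n_frames=241, seed=17)
        ests = motility.diffusivity_timecourse(ts, window_len=10.0,
                                               fit_window=(0.0, 1.0))
        vals = [e.d_eff for e in ests if np.isfinite(e.d_eff)]
        assert len(vals) >= 4
        assert max(vals) - min(vals) < 0.3 * 300.0

    def test_timecourse_stationary_population_is_zero(self):
        still = [synth.Track(f"s{i}", np.arange(121) * DT, np.zeros(121),
                             np.zeros(121)) for i in range(5)]
        ests = motility.diffusivity_timecourse(
            synth.TrackSet(still, dt=DT), 10.0, (0.0, 1.0))
        for e in ests:
            if np.isfinite(e.d_eff):
                assert e.d_eff == pytest.approx(0.0, abs=1e-9)

    def test_act_chi_diffusivity_rises_peaks_and_dominates(self):
        """The Act/Chi population reaches a higher motility plateau, and
        does so earlier, than Act or Chi alone."""
        from streaklab.presets import get_preset
        curves = {}
        for name in ("act_chi", "act", "chi"):
            ts = synth.simulate_trajectories(get_preset(name), 100, 96.0, DT,
                                             seed=5)
            curves[name] = np.array([e.d_eff for e in
                                     motility.diffusivity_timecourse(ts)])
        ac = curves["act_chi"]
        assert np.nanmax(ac) > np.nanmax(curves["act"])
        assert np.nanmax(ac) > np.nanmax(curves["chi"])
        # rises from baseline to a maximum, then persists at a high level
        assert ac[0] < 0.5 * np.nanmax(ac)
        assert ac[-1] > 0.6 * np.nanmax(ac)
        # reaches half its maximum earlier than the single treatments
        half = {k: int(np.argmax(v > 0.5 * np.nanmax(v)))
                for k, v in curves.items()}
        assert half["act_chi"] <= half["chi"] <= half["act"]


class TestTurningAngles:
    def test_collinear_motion_turns_zero(self):
        t = straight_track(n_frames=20)
        assert (motility.turning_angles(t) == 0).all()

    def test_exact_reversal_maps_to_plus_pi(self):
        t = synth.Track("r", np.arange(3) * DT, [0.0, 5.0, 0.0], [0.0, 0.0, 0.0])
        a = motility.turning_angles(t)
        assert a[0] == pytest.approx(np.pi)
        assert a[0] > 0

    def test_right_turn_is_negative_in_y_up_frame(self):
        t = synth.Track("rt", np.arange(3) * DT, [0.0, 5.0, 5.0], [0.0, 0.0, -5.0])
        assert motility.turning_angles(t)[0] == pytest.approx(-np.pi / 2.0)

    def test_short_steps_break_the_chain(self):
        x = [0.0, 5.0, 5.2, 10.0, 15.0]  # 2nd step is sub-threshold
        t = synth.Track("g", np.arange(5) * DT, x, np.zeros(5))
        assert len(motility.turning_angles(t, min_step=1.0)) == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_angles_always_in_half_open_interval(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 3.0, size=(30, 2)), axis=0)
        t = synth.Track("p", np.arange(30) * DT, pos[:, 0], pos[:, 1])
        a = motility.turning_angles(t)
        assert ((a > -np.pi) & (a <= np.pi)).all()


class TestKSUniformity:
    def test_persistent_walk_rejects_decisively(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.6, 5000)
        a = np.arctan2(np.sin(a), np.cos(a))  # wrap
        res = motility.ks_uniformity_test(a)
        assert res.p_value < 1e-5

    def test_degenerate_identical_angles_have_large_statistic(self):
        res = motility.ks_uniformity_test(np.full(50, 0.3))
        assert res.ks_stat >= 0.5

    def test_too_few_angles_rejected(self):
        with pytest.raises(motility.InsufficientDataError):
            motility.ks_uniformity_test(np.zeros(7))


class TestExpressionMotilityAssociation:
    def test_reporter_coupled_population_shows_positive_association(self, act_chi):
        ts = synth.simulate_trajectories(act_chi, 200, 60.0, DT, seed=19)
        rep = motility.expression_motility_association(ts, n_boot=200, seed=0)
        assert rep.pearson_r > 0.0
        assert rep.distance_ratio > 1.0

    def test_uncoupled_population_is_null(self, act_chi):
        p = act_chi.replace(expr_speed_coupling=1e-9, emt_speed_mult=1.0 + 1e-9)
        ts = synth.simulate_trajectories(p, 200, 60.0, DT, seed=19)
        rep = motility.expression_motility_association(ts, n_boot=200, seed=0)
        assert abs(rep.pearson_r) < 0.05
        assert rep.distance_ratio == pytest.approx(1.0, abs=0.15)

    def test_reporterless_tracks_rejected(self):
        bare = [synth.Track(f"b{i}", np.arange(10) * DT,
                            np.arange(10.0), np.zeros(10)) for i in range(12)]
        with pytest.raises(motility.MissingChannelError):
            motility.expression_motility_association(synth.TrackSet(bare, dt=DT))


class TestPlateauOnset:
    def test_exact_saturating_exponential_recovers_tau(self):
        lags = np.arange(0, 73) * DT
        tau_c, plateau = 3.0, 2000.0
        msd = plateau * (1.0 - np.exp(-lags / tau_c))
        c = motility.MSDCurve(lags, msd, np.full(lags.size, 50))
        fit = motility.msd_plateau_onset(c, (0.0, 0.5))
        assert fit.tau_c == pytest.approx(tau_c, rel=1e-3)
        # the slope over (0, 0.5 h] slightly under-reads the τ→0 tangent,
        # so the intersection lands just above τc
        assert fit.onset_time == pytest.approx(tau_c, rel=0.12)
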