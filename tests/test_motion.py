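"""Motion statistics: linking, clustering, R_rev, J4, MSD, diffusion, hovering."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbodytrack.detect import Spot
from pbodytrack.motion import (
    bud_distance_series,
    cluster_betweenness,
    cluster_positions,
    detect_hovering,
    diffusion_coefficient,
    diffusion_in_window,
    ks_compare,
    link_spots,
    msd,
    reversibility_rate,
    steps_and_velocities,
    windowed_diffusion,
)
from pbodytrack.simulate import SimConfig, simulate_trajectory
from pbodytrack.tracks import Trajectory


def _spot(x_um, y_um, frame):
    return Spot(frame=frame, x_px=x_um / 0.2, y_px=y_um / 0.2, x_um=x_um,
                y_um=y_um, sigma_px=2.0, amplitude=50.0, score=10.0)


def straight_track(n=10, step=1.0, dt=10.0):
    xy = np.stack([np.arange(n) * step, np.zeros(n)], axis=1)
    return Trajectory(times=np.arange(n) * dt, xy=xy)


def brownian_track(n, D, dt, seed, start=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n - 1, 2))
    xy = np.vstack([np.array(start), np.array(start) + np.cumsum(steps, axis=0)])
    return Trajectory(times=np.arange(n) * dt, xy=xy)


class TestLinking:
    def test_single_moving_spot_yields_one_full_track(self):
        spots = [[_spot(1.0 + 0.1 * f, 2.0, f)] for f in range(20)]
        tracks = link_spots(spots, max_disp_um=1.0, dt_s=60.0)
        assert len(tracks) == 1 and tracks[0].n == 20

    def test_distant_spots_stay_separate(self):
        spots = [[_spot(1.0, 1.0, f), _spot(20.0, 20.0, f)] for f in range(10)]
        tracks = link_spots(spots, max_disp_um=2.0, dt_s=60.0)
        assert len(tracks) == 2
        assert all(t.n == 10 for t in tracks)

    def test_jump_beyond_gate_splits_track(self):
        spots = [[_spot(1.0, 1.0, 0)], [_spot(9.0, 1.0, 1)]]
        tracks = link_spots(spots, max_disp_um=2.0, dt_s=60.0)
        assert len(tracks) == 2


class TestClustering:
    def test_perfectly_separated_points(self):
        xy = np.array([(0.0, 0.0)] * 50 + [(10.0, 0.0)] * 50)
        tr = Trajectory(times=np.arange(100) * 10.0, xy=xy)
        res = cluster_positions(tr, seed=0)
        assert res.labels.tolist() == [1] * 50 + [2] * 50
        assert np.allclose(sorted(res.centers[:, 0]), [0.0, 10.0])
        assert res.tau == 1 and res.r_rev == pytest.approx(1 / 99)

    def test_labels_anchored_to_time_not_kmeans_order(self):
        """Cluster 1 is always the earlier-occupied cluster."""
        xy = np.array([(10.0, 0.0)] * 30 + [(0.0, 0.0)] * 30)
        tr = Trajectory(times=np.arange(60) * 10.0, xy=xy)
        res = cluster_positions(tr, seed=0)
        assert res.labels[0] == 1 and res.labels[-1] == 2
        assert res.centers[0, 0] == pytest.approx(10.0)

    def test_degenerate_identical_points_flagged(self):
        tr = Trajectory(times=np.arange(10) * 1.0, xy=np.zeros((10, 2)))
        res = cluster_positions(tr, seed=0)
        assert res.degenerate

    def test_transported_track_single_transition(self):
        """A mother->daughter transported granule, clustered over its division
        window, shows exactly one 1 -> 2 transition."""
        cfg = SimConfig(n_frames=200, dt=60.0, rng_seed=11)
        tr = simulate_trajectory(
            cfg, 100, (2.2, 0.0), mother=((0, 0), 2.5),
            division_time=145, daughter=((4.3, 0.0), 1.8),
        )
        win = tr.subwindow(100 * 60 - 1800, 100 * 60 + 90 * 60)
        res = cluster_positions(win, seed=0)
        assert res.tau == 1
        assert res.labels[0] == 1 and res.labels[-1] == 2

    def test_resident_track_many_transitions(self):
        """A granule that never leaves the mother produces an arbitrary
        spatial split with many transitions."""
        cfg = SimConfig(n_frames=200, dt=60.0, hover_start_offset=-1e12,
                        rng_seed=11)
        tr = simulate_trajectory(cfg, 100, (2.2, 0.0), mother=((0, 0), 2.5))
        res = cluster_positions(tr, seed=0)
        assert res.tau > 5


class TestReversibilityRate:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, 1, 2, 2, 2], 1 / 5),
            ([1, 2, 1, 2, 1, 2], 1.0),
            ([1, 1, 1, 1], 0.0),
            ([1] * 500 + [2] * 500, 1 / 999),
        ],
    )
    def test_known_series(self, labels, expected):
        assert reversibility_rate(labels) == pytest.approx(expected)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            reversibility_rate([1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 2), min_size=2, max_size=50))
    def test_bounds_and_terminal_duplicate(self, labels):
        r = reversibility_rate(labels)
        assert 0.0 <= r <= 1.0
        tau = round(r * (len(labels) - 1))
        tau_dup = round(
            reversibility_rate(labels + [labels[-1]]) * len(labels)
        )
        assert tau_dup == tau  # duplicating the last point never adds a switch


class TestClusterBetweenness:
    def test_coincident_cluster_means_give_zero(self):
        pos = np.array([(0, 0), (2, 0), (0, 2), (2, 2)], dtype=float)
        j4, s_b, _ = cluster_betweenness(pos, [1, 2, 2, 1])
        assert j4 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(s_b, 0.0)

    def test_hand_computed_example(self):
        pos = np.array([(0, 0), (0, 1), (10, 0), (10, 1)], dtype=float)
        j4, s_b, s_w = cluster_betweenness(pos, [1, 1, 2, 2])
        assert np.trace(s_b) == pytest.approx(25.0)
        assert np.trace(s_w) == pytest.approx(0.25)
        assert j4 == pytest.approx(100.0)

    def test_all_points_on_centers_flagged_infinite(self):
        pos = np.array([(0, 0), (0, 0), (5, 5), (5, 5)], dtype=float)
        j4, _, _ = cluster_betweenness(pos, [1, 1, 2, 2])
        assert np.isinf(j4)

    def test_increasing_separation_increases_j4(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.5, size=(40, 2))
        vals = []
        for sep in (1.0, 2.0, 4.0, 8.0):
            pos = np.vstack([base, base + (sep, 0.0)])
            labels = [1] * 40 + [2] * 40
            vals.append(cluster_betweenness(pos, labels)[0])
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_bruteforce_definition(self):
        """Vectorized scatter matrices equal a literal per-point loop."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(4, 100)
            pos = rng.normal(size=(n, 2))
            labels = rng.integers(1, 3, size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = 1
                labels[1] = 2
            j4, _, _ = cluster_betweenness(pos, labels)
            # brute force straight from the definition
            mu = pos.mean(axis=0)
            sw = np.zeros((2, 2))
            sb = np.zeros((2, 2))
            for k in np.unique(labels):
                pk = pos[labels == k]
                mk = pk.mean(axis=0)
                for p in pk:
                    sw += np.outer(p - mk, p - mk) / n
                sb += (len(pk) / n) * np.outer(mk - mu, mk - mu)
            assert j4 == pytest.approx(np.trace(sb) / np.trace(sw), rel=1e-10)


class TestStepsVelocitiesBudDistance:
    def test_stationary_track_zero_steps(self):
        tr = Trajectory(times=np.arange(5) * 10.0, xy=np.ones((5, 2)))
        steps, vel = steps_and_velocities(tr)
        assert np.all(steps == 0) and np.all(vel == 0)

    def test_straight_line_arithmetic(self):
        tr = straight_track(n=6, step=1.0, dt=10.0)
        steps, vel = steps_and_velocities(tr)
        assert np.allclose(steps, 1.0) and np.allclose(vel, 0.1)

    def test_free_diffusion_mean_squared_step(self):
        tr = brownian_track(10_001, D=0.01, dt=10.0, seed=8)
        steps, _ = steps_and_velocities(tr)
        assert np.mean(steps**2) == pytest.approx(4 * 0.01 * 10.0, rel=0.05)

    def test_nonuniform_dt_warns(self):
        tr = Trajectory(times=np.array([0.0, 10.0, 30.0]), xy=np.zeros((3, 2)))
        with pytest.warns(UserWarning, match="non-uniform"):
            steps_and_velocities(tr)

    def test_bud_distance_trivial_cases(self):
        tr = Trajectory(times=np.arange(4) * 10.0,
                        xy=np.tile([3.0, 4.0], (4, 1)))
        assert np.allclose(bud_distance_series(tr, (3.0, 4.0)), 0.0)
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        circle = np.stack([2 * np.cos(theta), 2 * np.sin(theta)], axis=1)
        tr2 = Trajectory(times=np.arange(12) * 10.0, xy=circle)
        assert np.allclose(bud_distance_series(tr2, (0.0, 0.0)), 2.0)

    def test_hovering_reduces_bud_distance(self):
        cfg = SimConfig(n_frames=240, dt=60.0, rng_seed=0)
        tr = simulate_trajectory(cfg, 120, (1.5, 0.0), mother=((0, 0), 2.5))
        d = bud_distance_series(tr, (1.5, 0.0))
        hover = slice(90, 135)  # ground-truth hover frames
        assert d[hover].mean() < d[:90].mean()


class TestMsdAndDiffusion:
    def test_stationary_msd_zero(self):
        tr = Trajectory(times=np.arange(30) * 10.0, xy=np.ones((30, 2)))
        curve = msd(tr, max_lag=5)
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        tr = straight_track(n=50, step=1.0, dt=10.0)  # v = 0.1 µm/s
        curve = msd(tr, max_lag=6)
        assert np.allclose(curve.msd, (0.1 * curve.lags_s) ** 2)

    def test_time_reversal_invariance(self):
        tr = brownian_track(200, D=0.02, dt=10.0, seed=3)
        rev = Trajectory(times=tr.times, xy=tr.xy[::-1].copy())
        a = msd(tr, max_lag=10)
        b = msd(rev, max_lag=10)
        assert np.allclose(a.msd, b.msd)

    def test_exact_line_recovers_D(self):
        from pbodytrack.motion import MSDCurve

        lags = np.arange(8) * 10.0
        curve = MSDCurve(lags_s=lags, msd=4 * 0.02 * lags,  # exactly 4 D t
                         n_pairs=np.full(8, 100), dt_s=10.0)
        assert diffusion_coefficient(curve).D == pytest.approx(0.02)

    def test_ballistic_curvature_flagged(self):
        tr = straight_track(n=60, step=1.0, dt=10.0)
        fit = diffusion_coefficient(msd(tr, max_lag=6))
        assert fit.ballistic_flag

    def test_negative_slope_clipped_and_flagged(self):
        from pbodytrack.motion import MSDCurve

        lags = np.arange(6) * 10.0
        curve = MSDCurve(lags_s=lags, msd=np.array([0, 5, 4, 3, 2, 1.0]),
                         n_pairs=np.full(6, 50), dt_s=10.0)
        fit = diffusion_coefficient(curve)
        assert fit.D == 0.0 and fit.negative_slope

    def test_confined_plateau_below_free_diffusion(self):
        """Long-lag MSD of confined motion plateaus near 4 sigma^2, so the
        apparent D at long lags sits far below the free-diffusion D."""
        cfg = SimConfig(n_frames=2000, dt=10.0, corral_sigma=0.2,
                        corral_tau=20.0, hover_start_offset=-1e9,
                        hover_duration=2e9, rng_seed=4)
        tr = simulate_trajectory(cfg, 1000, (0.0, 0.0), mother=((0, 0), 2.5))
        curve = msd(tr, max_lag=100)
        plateau = curve.msd[50:].mean()
        assert plateau == pytest.approx(4 * 0.2**2, rel=0.2)
        long_fit = diffusion_coefficient(curve, fit_lags=(50, 100))
        assert long_fit.D < 0.1 * 0.01

    def test_brownian_D_recovery_across_decades(self):
        """Median per-track relative error < 15% for D over three decades."""
        for D in (0.001, 0.01, 0.1):
            errs = []
            for seed in range(50):
                tr = brownian_track(600, D=D, dt=10.0, seed=seed)
                fit = diffusion_coefficient(msd(tr, max_lag=4))
                errs.append(abs(fit.D - D) / D)
            assert np.median(errs) < 0.15


class TestWindowedDiffusion:
    def test_homogeneous_free_diffusion_ratios_near_one(self):
        ratios = []
        for seed in range(50):
            tr = brownian_track(600, D=0.01, dt=10.0, seed=100 + seed)
            wd = windowed_diffusion(tr, bud_time_s=3000.0, window_s=900.0)
            ratios.append(wd.D_during / wd.D_before)
        assert 0.7 <= np.mean(ratios) <= 1.4

    def test_window_outside_track_rejected(self):
        tr = brownian_track(100, D=0.01, dt=10.0, seed=0)
        with pytest.raises(ValueError):
            windowed_diffusion(tr, bud_time_s=50_000.0)

    def test_too_few_points_rejected(self):
        tr = brownian_track(100, D=0.01, dt=10.0, seed=0)
        with pytest.raises(ValueError):
            diffusion_in_window(tr, 0.0, 50.0)  # 5 points only


class TestHovering:
    def test_noiseless_step_mobility_recovered_exactly(self):
        steps = [1.0] * 60 + [0.1] * 60 + [1.0] * 60
        p = np.zeros(2)
        xy = [p.copy()]
        for i, s in enumerate(steps):
            p = p + np.array([s * (1 if i % 2 == 0 else -1), 0.0])
            xy.append(p.copy())
        tr = Trajectory(times=np.arange(len(xy)) * 60.0, xy=np.array(xy))
        hv = detect_hovering(tr, bud_time_s=90 * 60.0)
        assert hv.hovering
        assert hv.H_start == pytest.approx(-30 * 60.0)
        assert hv.H_stop == pytest.approx(30 * 60.0)
        assert hv.T_hov == pytest.approx(3600.0)

    def test_track_not_spanning_bud_rejected(self):
        tr = brownian_track(100, D=0.01, dt=60.0, seed=0)
        with pytest.raises(ValueError):
            detect_hovering(tr, bud_time_s=99 * 60.0)

    def test_free_diffusion_rarely_reports_hovering(self):
        false_pos = 0
        for seed in range(20):
            cfg = SimConfig(n_frames=240, dt=60.0, hover_start_offset=-1e12,
                            rng_seed=seed)
            tr = simulate_trajectory(cfg, 120, (1.5, 0.0), mother=((0, 0), 2.5))
            if detect_hovering(tr, 120 * 60.0).hovering:
                false_pos += 1
        assert false_pos <= 2

    def test_hover_window_recovered(self):
        cfg = SimConfig(n_frames=240, dt=60.0, rng_seed=1)
        tr = simulate_trajectory(cfg, 120, (1.5, 0.0), mother=((0, 0), 2.5))
        hv = detect_hovering(tr, 120 * 60.0)
        assert hv.hovering
        assert abs(hv.H_start - (-1800.0)) <= 3 * 60.0
        assert abs(hv.H_stop - 900.0) <= 3 * 60.0


class TestKsCompare:
    def test_identical_samples(self):
        stat, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_compare([0.0, 0.1, 0.2, 0.3], [5.0, 5.1, 5.2])
        assert stat == 1.0

    def test_null_p_values_calibrated(self):
        """Equal-law Normal samples give p-values centred near 0.5."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=(2, 100))
            ps.append(ks_compare(a, b)[1])
        assert 0.35 <= np.median(ps) <= 0.65

    def test_tiny_sample_warns(self):
        with pytest.warns(UserWarning):
            ks_compare([1.0, 2.0], [1.0, 2.0, 3.0])
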