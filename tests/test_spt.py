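"""Detection, linking, MSD and diffusion fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmic import spt, synth
from ssmic.spt import Trajectory


def brute_force_msd(traj):
    """O(N^2) all-ordered-pairs oracle, including gap handling."""
    out = {}
    for i in range(len(traj)):
        for j in range(i + 1, len(traj)):
            lag = traj.frames[j] - traj.frames[i]
            d = traj.positions[j] - traj.positions[i]
            out.setdefault(lag, []).append(d @ d)
    lags = sorted(out)
    return (np.array([lag * traj.frame_time for lag in lags]),
            np.array([np.mean(out[lag]) for lag in lags]),
            np.array([len(out[lag]) for lag in lags]))


def random_gappy_track(rng, n=20):
    frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False))
    pos = rng.normal(0, 0.5, (n, 2))
    return Trajectory(frames=frames, positions=pos)


class TestDetect:
    def test_single_spot_subpixel_accuracy(self):
        tr = Trajectory(frames=[0], positions=[[2.751, 3.301]])
        movie = synth.render_movie([tr], shape=(64, 64), noise=False,
                                   background=0, photon_rate=1000)
        det = spt.detect(movie.channel(0)[0], threshold=1e-6)
        assert len(det) == 1
        assert det[0, 0] == pytest.approx(2.751, abs=0.011)  # 0.1 px
        assert det[0, 1] == pytest.approx(3.301, abs=0.011)

    def test_blank_frame_detects_nothing(self):
        assert len(spt.detect(np.zeros((32, 32)))) == 0

    def test_grid_of_spots_all_found(self):
        trs = []
        for i in range(5):
            for j in range(5):
                trs.append(Trajectory(frames=[0],
                                      positions=[[1.1 + 1.1 * i, 1.1 + 1.1 * j]]))
        movie = synth.render_movie(trs, shape=(64, 64), photon_rate=800, seed=0)
        det = spt.detect(movie.channel(0)[0])
        assert len(det) == 25

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            spt.detect(np.zeros((8, 8)), dog_sigma1=-1)


class TestLink:
    def _dets(self, positions_by_frame):
        return {f: np.asarray(p, dtype=float).reshape(-1, 2)
                for f, p in positions_by_frame.items()}

    def test_slow_spot_yields_single_full_track(self):
        dets = self._dets({f: [[0.1 * f, 0.0]] for f in range(10)})
        tracks = spt.link(dets)
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_displacement_beyond_cap_breaks_track(self):
        dets = self._dets({f: [[0.6 * f, 0.0]] for f in range(5)})
        tracks = spt.link(dets, max_link=0.5)
        assert all(len(t) == 1 for t in tracks)

    def test_gap_of_two_frames_bridged_within_radius(self):
        dets = self._dets({0: [[1.0, 1.0]], 1: [[1.05, 1.0]],
                           4: [[1.15, 1.0]], 5: [[1.2, 1.0]]})
        tracks = spt.link(dets, max_gap=2, gap_close=0.25)
        assert len(tracks) == 1
        assert list(tracks[0].frames) == [0, 1, 4, 5]
        assert tracks[0].gaps.tolist() == [False, False, True, False]

    def test_gap_beyond_max_not_bridged(self):
        dets = self._dets({0: [[1.0, 1.0]], 4: [[1.1, 1.0]]})
        tracks = spt.link(dets, max_gap=2)
        assert len(tracks) == 2

    def test_two_particles_do_not_swap(self):
        dets = self._dets({f: [[0.05 * f, 0.0], [0.05 * f, 2.0]] for f in range(8)})
        tracks = spt.link(dets)
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.positions[:, 1]) < 1e-9


class TestFilterTracks:
    def test_short_tracks_removed_at_ten(self):
        mk = lambda n: Trajectory(frames=np.arange(n),
                                  positions=np.random.default_rng(n).normal(0, 0.1, (n, 2)))
        tracks = [mk(9), mk(10), mk(15)]
        kept = spt.filter_tracks(tracks)
        assert [len(t) for t in kept] == [10, 15]

    def test_straight_track_removed(self):
        straight = Trajectory(frames=np.arange(50),
                              positions=np.column_stack([np.linspace(0, 5, 50),
                                                         np.zeros(50)]))
        with pytest.warns(UserWarning):
            assert spt.filter_tracks([straight]) == []

    def test_brownian_track_kept(self):
        m = synth.SwitchingModel(D=[0.05])
        trajs, _ = synth.simulate_trajectories(m, 5, 100, seed=0)
        kept = spt.filter_tracks(trajs)
        assert len(kept) == 5
        assert all(spt.straightness(t) < 0.5 for t in kept)


class TestMSD:
    def test_static_track_msd_zero(self):
        tr = Trajectory(frames=np.arange(5), positions=np.ones((5, 2)))
        assert np.allclose(spt.msd(tr).msd, 0.0)

    def test_three_point_line_arithmetic(self):
        tr = Trajectory(frames=[0, 1, 2],
                        positions=[[0.0, 0], [1.0, 0], [2.0, 0]])
        curve = spt.msd(tr)
        assert curve.msd == pytest.approx([1.0, 4.0])
        assert curve.n_pairs.tolist() == [2, 1]

    def test_equals_brute_force_on_random_gappy_tracks(self, rng):
        for _ in range(100):
            tr = random_gappy_track(rng)
            curve = spt.msd(tr)
            lags, vals, npairs = brute_force_msd(tr)
            assert np.allclose(curve.lags, lags)
            assert np.allclose(curve.msd, vals)
            assert np.array_equal(curve.n_pairs, npairs)


class TestFitAlpha:
    def test_exact_power_law_recovered(self):
        lags = 0.05 * np.arange(1, 11)
        curve = spt.MSDCurve(lags=lags, msd=4 * 0.05 * lags ** 0.5,
                             n_pairs=np.full(10, 100))
        fit = spt.fit_alpha(curve)
        assert fit.alpha == pytest.approx(0.5, abs=1e-9)
        assert fit.D_apparent == pytest.approx(0.05, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_confined_ensemble_subdiffusive(self):
        m = synth.SwitchingModel(D=[0.05], confinement_radius=0.15)
        trajs, _ = synth.simulate_trajectories(m, 300, 120, seed=2)
        fit = spt.fit_alpha([spt.msd(t, max_lag=12) for t in trajs])
        assert fit.alpha < 1.0

    def test_localization_noise_adds_offset_not_slope(self):
        # static + dynamic: MSD_noisy(tau) = MSD_clean(tau) + 4 sigma^2
        sigma = 0.03
        m = synth.SwitchingModel(D=[0.05])
        t_clean, _ = synth.simulate_trajectories(m, 600, 80, seed=3)
        t_noisy, _ = synth.simulate_trajectories(m, 600, 80, loc_noise_sd=sigma, seed=3)
        c_clean = spt.ensemble_msd([spt.msd(t, max_lag=40) for t in t_clean])
        c_noisy = spt.ensemble_msd([spt.msd(t, max_lag=40) for t in t_noisy])
        offsets = c_noisy.msd - c_clean.msd
        assert np.mean(offsets) == pytest.approx(4 * sigma ** 2, rel=0.15)
        # offset is flat: slope at long lags unaffected
        slope_clean = np.polyfit(c_clean.lags[20:], c_clean.msd[20:], 1)[0]
        slope_noisy = np.polyfit(c_noisy.lags[20:], c_noisy.msd[20:], 1)[0]
        assert slope_noisy == pytest.approx(slope_clean, rel=0.05)

    def test_per_track_mode_returns_fit_per_curve(self):
        m = synth.SwitchingModel(D=[0.05])
        trajs, _ = synth.simulate_trajectories(m, 4, 60, seed=1)
        fits = spt.fit_alpha([spt.msd(t, max_lag=12) for t in trajs],
                             mode="per_track")
        assert len(fits) == 4


class TestSpeedsAndKymograph:
    def test_static_track_zero_speed(self):
        tr = Trajectory(frames=np.arange(5), positions=np.ones((5, 2)))
        assert np.allclose(spt.instantaneous_speeds(tr), 0.0)

    def test_constant_step_speed_arithmetic(self):
        tr = Trajectory(frames=np.arange(4),
                        positions=np.column_stack([0.1 * np.arange(4), np.zeros(4)]),
                        frame_time=0.050)
        assert np.allclose(spt.instantaneous_speeds(tr), 2.0)

    @given(st.integers(2, 30))
    @settings(max_examples=20, deadline=None)
    def test_speeds_equal_oracle_diff(self, n):
        rng = np.random.default_rng(n)
        tr = Trajectory(frames=np.arange(n), positions=rng.normal(0, 1, (n, 2)),
                        frame_time=0.05)
        oracle = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1) / 0.05
        assert np.allclose(spt.instantaneous_speeds(tr), oracle)

    def test_static_pixel_gives_horizontal_line(self):
        stack = np.zeros((10, 16, 16))
        stack[:, 8, 8] = 100.0
        kymo = spt.kymograph(stack, [[2, 8], [14, 8]])
        row = np.argmax(kymo, axis=0)
        assert np.ptp(row) == 0

    def test_moving_spot_gives_diagonal_streak(self):
        stack = np.zeros((12, 16, 32))
        for t in range(12):
            stack[t, 8, 4 + 2 * t] = 100.0
        kymo = spt.kymograph(stack, [[0, 8], [31, 8]])
        peaks = np.argmax(kymo, axis=0)
        slope = np.polyfit(np.arange(12), peaks, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_width_averaging_identity_on_uniform_image(self):
        stack = np.full((3, 16, 16), 5.0)
        k1 = spt.kymograph(stack, [[2, 8], [13, 8]], width=1)
        k3 = spt.kymograph(stack, [[2, 8], [13, 8]], width=3)
        assert np.allclose(k1, k3)

    def test_path_outside_image_rejected(self):
        with pytest.raises(ValueError):
            spt.kymograph(np.zeros((2, 8, 8)), [[0, 0], [20, 0]])
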