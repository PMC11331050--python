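"""Generators must produce what they claim: verifiable ground truth."""

import numpy as np
import pytest

from ssmic import afm, spt, synth


class TestSpotFilamentStack:
    def test_on_fraction_one_places_all_spots_on_filament(self):
        stack, truth = synth.make_spot_filament_stack(n_spots=30, on_fraction=1.0, seed=0)
        px = stack.pixel_size
        mask = truth.filament_mask_2d
        for x, y, _ in truth.spot_centers:
            assert mask[int(round(y / px)), int(round(x / px))]
        assert truth.intensity_on_fraction == 1.0

    def test_on_fraction_zero_keeps_spots_off_mask(self):
        from scipy import ndimage
        stack, truth = synth.make_spot_filament_stack(n_spots=30, on_fraction=0.0, seed=0)
        px = stack.pixel_size
        dist = ndimage.distance_transform_edt(~truth.filament_mask_2d)
        for x, y, _ in truth.spot_centers:
            assert dist[int(round(y / px)), int(round(x / px))] >= 5

    @pytest.mark.parametrize("target", [0.25, 0.6, 0.75])
    def test_intensity_fraction_matches_request(self, target):
        _, truth = synth.make_spot_filament_stack(n_spots=50, on_fraction=target, seed=1)
        assert truth.intensity_on_fraction == pytest.approx(target, abs=0.02)

    def test_truth_fraction_is_self_consistent(self):
        _, truth = synth.make_spot_filament_stack(n_spots=40, on_fraction=0.4, seed=2)
        recomputed = (truth.spot_intensities[truth.on_actin_flags].sum()
                      / truth.spot_intensities.sum())
        assert truth.intensity_on_fraction == pytest.approx(recomputed, rel=1e-12)

    def test_zero_spots_requires_unspecified_fraction(self):
        with pytest.raises(ValueError):
            synth.make_spot_filament_stack(n_spots=0, on_fraction=0.5)
        stack, truth = synth.make_spot_filament_stack(
            shape=(3, 96, 96), n_spots=0, seed=0)
        assert len(truth.spot_intensities) == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synth.make_spot_filament_stack(shape=(0, 64, 64))
        with pytest.raises(ValueError):
            synth.make_spot_filament_stack(on_fraction=1.5)
        with pytest.raises(ValueError):
            synth.make_spot_filament_stack(snr=-1)

    def test_bit_reproducible(self):
        s1, t1 = synth.make_spot_filament_stack(shape=(3, 96, 96), n_spots=10, seed=7)
        s2, t2 = synth.make_spot_filament_stack(shape=(3, 96, 96), n_spots=10, seed=7)
        assert np.array_equal(s1.pixels, s2.pixels)
        assert np.array_equal(t1.spot_centers, t2.spot_centers)


class TestSimulateTrajectories:
    def test_zero_diffusion_is_static(self):
        m = synth.SwitchingModel(D=[0.0])
        trajs, _ = synth.simulate_trajectories(m, 5, 20, seed=0)
        for t in trajs:
            assert np.allclose(t.positions, t.positions[0])

    def test_brownian_msd_slope_is_one(self):
        m = synth.SwitchingModel(D=[0.05])
        trajs, _ = synth.simulate_trajectories(m, 1000, 300, seed=4)
        fit = spt.fit_alpha([spt.msd(t, max_lag=12) for t in trajs], n_lags=10)
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_per_state_step_variance_matches_model(self):
        m = synth.SwitchingModel(D=[0.001, 0.1], pi=[0.5, 0.5],
                                 T=[[0.9, 0.1], [0.1, 0.9]])
        trajs, labels = synth.simulate_trajectories(m, 400, 80, seed=3)
        steps = np.stack([np.diff(t.positions, axis=0) for t in trajs])
        for k, D in enumerate(m.D):
            var = steps[labels == k].var()
            assert var == pytest.approx(2 * D * m.frame_time, rel=0.05)

    def test_single_state_reduces_to_brownian_step_variance(self):
        m = synth.SwitchingModel(D=[0.05])
        trajs, _ = synth.simulate_trajectories(m, 500, 201, seed=9)
        s = np.concatenate([np.diff(t.positions, axis=0).ravel() for t in trajs])
        assert s.size >= 1e5
        assert s.var() == pytest.approx(2 * 0.05 * 0.05, rel=0.01)

    def test_confinement_bounds_positions(self):
        m = synth.SwitchingModel(D=[0.1], confinement_radius=0.15)
        trajs, _ = synth.simulate_trajectories(m, 20, 100, seed=5)
        for t in trajs:
            assert np.all(np.linalg.norm(t.positions - t.positions[0], axis=1)
                          <= 0.15 + 1e-9)

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            synth.SwitchingModel(D=[0.1, 0.2], T=[[0.5, 0.4], [0.1, 0.9]])


class TestRenderMovie:
    def test_static_spot_argmax_fixed(self):
        tr = spt.Trajectory(frames=np.arange(10),
                            positions=np.tile([3.0, 2.0], (10, 1)))
        movie = synth.render_movie([tr], shape=(48, 48), noise=False, background=0)
        for f in range(10):
            r, c = np.unravel_index(np.argmax(movie.channel(0)[f]), (48, 48))
            assert (r, c) == (round(2.0 / 0.11), round(3.0 / 0.11))

    def test_bleach_decay_rate_recovered(self):
        tr = spt.Trajectory(frames=np.arange(200),
                            positions=np.tile([3.0, 3.0], (200, 1)))
        movie = synth.render_movie([tr], shape=(48, 48), noise=False,
                                   background=0, bleach=0.99)
        totals = movie.channel(0).sum(axis=(1, 2))
        rate = -np.polyfit(np.arange(200), np.log(totals), 1)[0]
        assert rate == pytest.approx(-np.log(0.99), rel=0.01)

    def test_crossing_trajectories_both_detected(self):
        f = np.arange(20)
        a = spt.Trajectory(frames=f, positions=np.column_stack([0.1 * f + 1.0,
                                                                np.full(20, 2.0)]))
        b = spt.Trajectory(frames=f, positions=np.column_stack([0.1 * f + 1.0,
                                                                np.full(20, 4.0)]))
        movie = synth.render_movie([a, b], shape=(64, 64), photon_rate=800, seed=0)
        dets = spt.detect(movie.channel(0)[10])
        for truth in ([2.0, 2.0], [2.0, 4.0]):
            d = np.linalg.norm(dets[:, :2] - truth, axis=1)
            assert d.min() < 0.11  # each spot recovered within one pixel

    def test_out_of_field_warns(self):
        tr = spt.Trajectory(frames=np.arange(3),
                            positions=np.array([[1, 1], [2, 2], [900, 900.0]]))
        with pytest.warns(UserWarning, match="clipped"):
            synth.render_movie([tr], shape=(32, 32))


class TestForceCurves:
    def test_round_trip_recovers_modulus(self):
        truth = synth.ForceCurveTruth(E_true=16000, contact_index=150)
        fit = afm.fit_young_modulus(synth.make_force_curve(truth, seed=0))
        assert fit.E == pytest.approx(16000, rel=0.01)

    def test_force_ratio_linear_in_modulus(self):
        t1 = synth.ForceCurveTruth(E_true=2000, contact_index=100)
        t2 = synth.ForceCurveTruth(E_true=180000, contact_index=100)
        c1 = synth.make_force_curve(t1)
        c2 = synth.make_force_curve(t2)
        model = afm.IndenterModel()
        # compare model force at equal indentation rather than equal z
        f1 = afm.pyramid_force(0.5, model, 2000)
        f2 = afm.pyramid_force(0.5, model, 180000)
        assert f2 / f1 == pytest.approx(90, rel=1e-9)
        assert c2.deflection_um[-1] > c1.deflection_um[-1]

    def test_noise_reproducible_with_seed(self):
        truth = synth.ForceCurveTruth(E_true=2000, contact_index=100, noise_sd=1e-10)
        c1 = synth.make_force_curve(truth, seed=42)
        c2 = synth.make_force_curve(truth, seed=42)
        assert np.array_equal(c1.deflection_um, c2.deflection_um)

    def test_contact_index_beyond_curve_rejected(self):
        truth = synth.ForceCurveTruth(E_true=2000, contact_index=600)
        with pytest.raises(ValueError):
            synth.make_force_curve(truth, n_samples=500)


class TestContactMovie:
    def test_two_cells_deterministic_truth(self):
        _, t1 = synth.make_contact_movie([[(5, 10)], [(12, 18)]], n_frames=25, seed=3)
        _, t2 = synth.make_contact_movie([[(5, 10)], [(12, 18)]], n_frames=25, seed=3)
        assert np.array_equal(t1["paths_um"], t2["paths_um"])

    def test_zero_cells_gives_empty_tracks(self):
        from ssmic import synapse
        stack, truth = synth.make_contact_movie([], n_frames=10, seed=0)
        tracks = synapse.track_bcells(stack, cell_channel=0)
        assert tracks == []

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            synth.make_contact_movie([[(5, 10), (8, 12)]], n_frames=20)

    def test_contact_frames_inside_footprint(self):
        stack, truth = synth.make_contact_movie([[(4, 8)]], n_frames=12, seed=1)
        c = truth["footprint_center_um"]
        path = truth["paths_um"][0]
        for f in range(12):
            d = np.linalg.norm(path[f] - c)
            if 4 <= f <= 8:
                assert d <= truth["footprint_radius_um"]
            else:
                assert d > truth["footprint_radius_um"] + truth["cell_radius_um"]


class TestNfkbCell:
    def test_ratio_one_no_noise_is_uniform(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(1.0, noise=0.0)
        assert np.ptp(img) == 0

    def test_prescribed_ratio_is_exact(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(2.0, noise=0.0)
        assert img[nuc].mean() / img[cell & ~nuc].mean() == pytest.approx(2.0)

    def test_nucleus_strictly_inside_cell(self):
        with pytest.raises(ValueError):
            synth.make_nfkb_cell(2.0, cell_radius=10, nucleus_radius=12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            synth.make_nfkb_cell(0.0)
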