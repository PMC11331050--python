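"""SSM-B cell synapse metrics: profiles, tracking, contacts, NF-kB, uptake."""

import numpy as np
import pytest

from ssmic import spt, synapse, synth


def gauss_peak(shape, cx, sigma=3.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.exp(-((xx - cx) ** 2) / (2 * sigma ** 2))


class TestLineProfile:
    def test_coincident_peaks_zero_offset(self):
        img = gauss_peak((32, 64), 30.0)
        prof = synapse.line_profile((img, img), ((5, 16), (60, 16)))
        assert prof.peak_offset == pytest.approx(0.0, abs=1e-9)

    def test_shifted_factin_peak_offset_half_micron(self):
        px = 0.110
        shift_px = 0.5 / px
        membrane = gauss_peak((32, 64), 30.0)
        factin = gauss_peak((32, 64), 30.0 + shift_px)
        prof = synapse.line_profile((membrane, factin), ((5, 16), (60, 16)),
                                    pixel_size=px)
        assert prof.peak_offset == pytest.approx(0.5, abs=px)

    def test_uniform_channel_has_no_peak(self):
        img = np.ones((32, 64))
        with pytest.raises(ValueError, match="uniform"):
            synapse.line_profile((img, img), ((5, 16), (60, 16)))

    def test_line_outside_image_rejected(self):
        img = np.ones((16, 16))
        with pytest.raises(ValueError):
            synapse.line_profile((img, img), ((0, 0), (40, 0)))


class TestTrackBcells:
    def test_single_cell_full_track(self):
        stack, truth = synth.make_contact_movie([[(3, 6)]], n_frames=20, seed=0)
        tracks = synapse.track_bcells(stack, cell_channel=0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20
        # centroids track the truth path within half a cell radius
        err = np.linalg.norm(tracks[0].positions - truth["paths_um"][0], axis=1)
        assert err.max() < truth["cell_radius_um"] / 2

    def test_jump_beyond_cap_splits_track(self):
        dets = {f: np.array([[0.0 + (8.0 if f >= 3 else 0.0), 5.0]])
                for f in range(6)}
        tracks = spt.link(dets, max_link=7.0, gap_close=3.5, max_gap=2,
                          frame_time=20.0)
        assert len(tracks) == 2

    def test_known_tracks_recovered(self):
        stack, truth = synth.make_contact_movie([[(10, 20)], [(25, 30)]],
                                                n_frames=40, seed=1)
        tracks = synapse.track_bcells(stack, cell_channel=0)
        assert sorted(len(t) for t in tracks) == [40, 40]


class TestContactMetrics:
    def test_duration_follows_inclusive_frame_grid(self):
        stack, truth = synth.make_contact_movie([[(10, 20)]], n_frames=40, seed=0)
        tracks = synapse.track_bcells(stack, cell_channel=0)
        events = synapse.contact_metrics(tracks, truth["footprint_mask"],
                                         stack.pixel_size, 20.0,
                                         cell_radius_um=truth["cell_radius_um"])
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (10, 20)
        assert events[0].duration == 11 * 20.0

    def test_never_contacting_track_has_no_events(self):
        mask = np.zeros((64, 64), bool)
        mask[28:36, 28:36] = True
        tr = spt.Trajectory(frames=np.arange(10),
                            positions=np.tile([1.0, 1.0], (10, 1)))
        assert synapse.contact_metrics([tr], mask, 0.325, 20.0) == []

    def test_velocity_arithmetic(self):
        # 0.1 um per 20 s step -> 0.3 um/min
        mask = np.zeros((64, 64), bool)
        mask[30:34, 30:34] = True
        pos = np.column_stack([np.arange(10) * 0.1 + 9.75, np.full(10, 10.0)])
        tr = spt.Trajectory(frames=np.arange(10), positions=pos)
        events = synapse.contact_metrics([tr], mask, 0.325, 20.0,
                                         cell_radius_um=3.0)
        assert events[0].mean_velocity == pytest.approx(0.3)

    def test_short_gaps_bridged_into_one_event(self):
        mask = np.zeros((64, 64), bool)
        mask[28:36, 28:36] = True
        center = np.array([32 * 0.325, 32 * 0.325])
        out = np.array([1.0, 1.0])
        pos = [center if f not in (5, 6) else out for f in range(12)]
        tr = spt.Trajectory(frames=np.arange(12), positions=np.array(pos))
        events = synapse.contact_metrics([tr], mask, 0.325, 20.0, max_gap=2)
        assert len(events) == 1
        assert events[0].duration == 10 * 20.0   # ten actual contact frames


class TestNfkbRatio:
    def test_uniform_cell_not_activated(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(1.0, noise=0.0)
        res = synapse.nfkb_ratio(img, nuc, cell)
        assert res.ratio == pytest.approx(1.0)
        assert res.activated is False

    def test_ratio_two_phantom_exact_and_activated(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(2.0, noise=0.0)
        res = synapse.nfkb_ratio(img, nuc, cell)
        assert res.ratio == pytest.approx(2.0)
        assert res.activated is True

    def test_sub_unity_ratio_not_activated(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(0.5, noise=0.0)
        res = synapse.nfkb_ratio(img, nuc, cell)
        assert res.ratio == pytest.approx(0.5)
        assert res.activated is False

    def test_zero_nuclear_intensity_gives_ratio_zero(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(1.0, noise=0.0)
        img[nuc] = 0.0
        res = synapse.nfkb_ratio(img, nuc, cell)
        assert res.ratio == 0.0 and res.activated is False

    def test_invariant_to_gain(self):
        img, nuc, cell, _ = synth.make_nfkb_cell(1.7, noise=0.05, seed=3)
        r1 = synapse.nfkb_ratio(img, nuc, cell).ratio
        r2 = synapse.nfkb_ratio(img * 3.7, nuc, cell).ratio
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_nucleus_outside_cell_rejected(self):
        img = np.ones((16, 16))
        nuc = np.zeros((16, 16), bool)
        nuc[2:4, 2:4] = True
        cell = np.zeros((16, 16), bool)
        cell[8:14, 8:14] = True
        with pytest.raises(ValueError):
            synapse.nfkb_ratio(img, nuc, cell)


class TestInternalization:
    def _cell(self):
        zz, yy, xx = np.mgrid[0:9, 0:64, 0:64]
        return ((zz - 4) ** 2 / 9 + ((yy - 32) ** 2 + (xx - 32) ** 2) / 400) <= 1

    def _stack_with_clusters(self, specs):
        st = np.zeros((9, 64, 64))
        for z, y, x, total in specs:
            st[z, y - 1:y + 2, x - 1:x + 2] = total / 9.0
        return st

    def test_interior_clusters_counted_exactly(self):
        st = self._stack_with_clusters([(4, 26, 26, 100), (4, 38, 38, 200),
                                        (5, 30, 40, 300)])
        res = synapse.internalization(st, self._cell(), threshold=0.5)
        assert res.n_clusters == 3
        assert res.total_ic_intensity == pytest.approx(600.0)
        assert sorted(res.intensity_per_cluster) == pytest.approx([100, 200, 300])

    def test_surface_clusters_excluded(self):
        cell = self._cell()
        st = np.zeros((9, 64, 64))
        st[4, 32, 51] = 100.0    # on the membrane shell
        res = synapse.internalization(st, cell, threshold=0.5)
        assert res.n_clusters == 0

    def test_empty_cell_zero(self):
        res = synapse.internalization(np.zeros((9, 64, 64)), self._cell(),
                                      threshold=0.5)
        assert res.n_clusters == 0 and res.total_ic_intensity == 0.0

    def test_splitting_a_cluster_preserves_total(self):
        st1 = self._stack_with_clusters([(4, 30, 30, 300)])
        st2 = self._stack_with_clusters([(4, 28, 28, 150), (4, 34, 34, 150)])
        cell = self._cell()
        t1 = synapse.internalization(st1, cell, threshold=0.5).total_ic_intensity
        t2 = synapse.internalization(st2, cell, threshold=0.5).total_ic_intensity
        assert t1 == pytest.approx(t2, rel=0.05)

    def test_open_surface_rejected(self):
        flat = np.zeros((3, 16, 16), bool)
        flat[1, 8, :] = True     # a sheet with no interior
        with pytest.raises(ValueError, match="open|interior"):
            synapse.internalization(np.zeros((3, 16, 16)), flat, threshold=0.5)
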