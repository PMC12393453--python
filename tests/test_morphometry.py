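"""Morphometry: loops, nucleus snapping, segment density, permeability."""

import numpy as np
import pytest

from capnet.morphometry import (
    detect_loops,
    extravascular_permeability,
    segment_density,
    snap_nuclei,
)
from capnet.synthetic import generate_vessel_geometry
from capnet.traces import Recording


def square_annulus(outer=20, hole=10):
    mask = np.zeros((outer + 8, outer + 8), bool)
    o0 = 4
    mask[o0 : o0 + outer, o0 : o0 + outer] = True
    h0 = o0 + (outer - hole) // 2
    mask[h0 : h0 + hole, h0 : h0 + hole] = False
    return mask


class TestDetectLoops:
    def test_square_annulus_closed_forms(self):
        (loop,) = detect_loops(square_annulus(20, 10), pixel_size_um=2.0)
        assert loop.area_px == 100.0
        assert loop.area_um2 == 400.0
        assert loop.equivalent_diameter_px == pytest.approx(
            np.sqrt(400 / np.pi), abs=1e-9
        )
        # 8-connected boundary contour of a 10x10 square: 36 unit steps
        assert loop.perimeter_px == pytest.approx(36.0)
        assert loop.centroid == (pytest.approx(13.5), pytest.approx(13.5))

    def test_broken_ring_is_not_a_loop(self):
        mask = square_annulus(20, 10)
        mask[14, 4:10] = False  # cut a channel from the hole to the outside
        assert detect_loops(mask) == []

    def test_two_disjoint_annuli(self):
        a = square_annulus(16, 6)
        side = a.shape[0]
        mask = np.zeros((side, 2 * side), bool)
        mask[:, :side] = a
        mask[:, side:] = a
        loops = detect_loops(mask)
        assert len(loops) == 2
        assert loops[0].loop_id != loops[1].loop_id
        assert abs(loops[0].centroid[1] - loops[1].centroid[1]) == pytest.approx(side)

    def test_min_area_filter(self):
        mask = square_annulus(8, 1)
        assert detect_loops(mask, min_area_px=4) == []
        assert len(detect_loops(mask, min_area_px=1)) == 1

    def test_total_hole_area_conserved(self):
        mask, _, _, truth = generate_vessel_geometry(6, rng_seed=1, nuclei_per_segment=(1,))
        loops = detect_loops(mask, min_area_px=1)
        assert sum(l.area_px for l in loops) == sum(l["area_px"] for l in truth.loops)

    def test_empty_mask(self):
        assert detect_loops(np.zeros((10, 10), bool)) == []


class TestSnapNuclei:
    def make_skeleton(self):
        sk = np.zeros((40, 40), bool)
        sk[20, 5:35] = True
        return sk

    def test_nucleus_on_skeleton(self):
        assignments, exclusions = snap_nuclei(np.array([[20.0, 10.0]]), self.make_skeleton())
        assert exclusions == []
        (px, dist) = assignments[0]
        assert px == (20, 10) and dist == 0.0

    def test_nucleus_beyond_10um_excluded(self):
        assignments, exclusions = snap_nuclei(np.array([[8.0, 10.0]]), self.make_skeleton())
        assert assignments == {}
        assert exclusions == [(0, pytest.approx(12.0))]

    def test_boundary_10um_is_excluded(self):
        # the retention rule is strict: exactly 10 um does not qualify
        _, exclusions = snap_nuclei(np.array([[10.0, 10.0]]), self.make_skeleton())
        assert exclusions == [(0, pytest.approx(10.0))]

    def test_tie_resolves_lexicographically(self):
        sk = np.zeros((10, 10), bool)
        sk[2, 5] = sk[8, 5] = True
        assignments, _ = snap_nuclei(np.array([[5.0, 5.0]]), sk)
        assert assignments[0][0] == (2, 5)

    def test_retention_monotone_in_radius(self, rng):
        sk = self.make_skeleton()
        nuclei = rng.uniform(0, 40, (30, 2))
        kept = [
            len(snap_nuclei(nuclei, sk, max_snap_um=r)[0]) for r in (2, 5, 10, 20)
        ]
        assert kept == sorted(kept)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            snap_nuclei(np.array([[1.0, 1.0]]), np.zeros((5, 5), bool))


class TestSegmentDensity:
    def test_straight_path_length_and_density(self):
        sk = np.zeros((10, 120), bool)
        sk[5, 5:106] = True  # 101 pixels
        nuclei = np.array([[5.0, 20.0], [5.0, 80.0]])
        assignments, _ = snap_nuclei(nuclei, sk, pixel_size_um=0.5)
        (seg,) = segment_density(sk, assignments, pixel_size_um=0.5)
        assert seg.geodesic_length_um == pytest.approx(50.0)  # (101-1) x 0.5
        assert seg.n_nuclei == 2
        assert seg.linear_density_per_100um == pytest.approx(4.0)

    def test_diagonal_path_sqrt2_steps(self):
        sk = np.zeros((20, 20), bool)
        for k in range(11):
            sk[4 + k, 4 + k] = True
        (seg,) = segment_density(sk, {}, pixel_size_um=1.0)
        assert seg.geodesic_length_um == pytest.approx(10 * np.sqrt(2))
        assert seg.n_nuclei == 0
        assert seg.linear_density_per_100um == 0.0

    def test_t_junction_splits_into_three_segments(self):
        sk = np.zeros((30, 30), bool)
        sk[10, 5:26] = True
        sk[11:21, 15] = True
        segs = segment_density(sk, {}, pixel_size_um=1.0)
        assert len(segs) == 3
        assert sum(s.geodesic_length_um for s in segs) == pytest.approx(
            20 + 10, abs=3  # node-cluster internal steps are not double counted
        )

    def test_generator_truth_recovered(self):
        _, skeleton, nuclei, truth = generate_vessel_geometry(
            0, pixel_size_um=1.0, nuclei_per_segment=(2, 3, 1), rng_seed=5
        )
        assignments, _ = snap_nuclei(nuclei, skeleton)
        segs = segment_density(skeleton, assignments)
        got = sorted((round(s.geodesic_length_um, 6), s.n_nuclei) for s in segs)
        want = sorted(
            (round(t["length_um"], 6), n)
            for t, n in zip(
                truth.segments,
                [
                    sum(1 for v in truth.nuclei_true_segment.values() if v == s)
                    for s in range(3)
                ],
            )
        )
        assert got == want


class TestPermeability:
    def make_movies(self, post_scale=1.0, n_frames=10):
        mask = np.zeros((20, 20), bool)
        mask[8:12, :] = True
        pre = Recording(np.full((5, 20, 20), 10.0), frame_interval=3.44)
        post = Recording(
            np.full((n_frames, 20, 20), 10.0 * post_scale), frame_interval=3.44
        )
        return pre, post, mask

    def test_identity_movies_give_unity(self):
        pre, post, mask = self.make_movies()
        series = extravascular_permeability(post, mask, pre)
        assert np.allclose(series.normalized, 1.0)

    def test_simple_ratio(self):
        pre, post, mask = self.make_movies(post_scale=2.5)
        series = extravascular_permeability(post, mask, pre, dilation_px=0)
        assert np.allclose(series.normalized, 2.5)

    def test_scale_invariance(self):
        pre, post, mask = self.make_movies(post_scale=1.7)
        s1 = extravascular_permeability(post, mask, pre)
        pre2 = Recording(pre.frames * 3.0, 3.44)
        post2 = Recording(post.frames * 3.0, 3.44)
        s2 = extravascular_permeability(post2, mask, pre2)
        assert np.allclose(s1.normalized, s2.normalized)

    def test_leak_ramp_slope_recovered(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, :] = True
        slope = 0.04  # per frame, in units of the pre-dextran mean
        n = 50
        frames = np.empty((n, 20, 20))
        for t in range(n):
            frames[t] = 10.0 * (1.0 + slope * t)
        pre = Recording(np.full((5, 20, 20), 10.0), 3.44)
        series = extravascular_permeability(Recording(frames, 3.44), mask, pre)
        fit = np.polyfit(np.arange(n), series.normalized, 1)
        assert fit[0] == pytest.approx(slope, rel=1e-6)

    def test_zero_pre_mean_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[4:6, :] = True
        pre = Recording(np.zeros((3, 10, 10)), 3.44)
        post = Recording(np.ones((3, 10, 10)), 3.44)
        with pytest.raises(ValueError, match="positive"):
            extravascular_permeability(post, mask, pre)
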