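"""Footprint distances, orientation-distance maps, envelope and cutoff."""

import math

import numpy as np
import pytest

from explode_orient.detector import gaussian_blur, project_to_detectors
from explode_orient.retrieval import (
    CutoffReport,
    OrientationDistanceMap,
    build_orientation_distance_map,
    distance_cutoff,
    efficiency_sweep,
    footprint_distance,
    under_cutoff_stats,
    upper_envelope,
)
from explode_orient.rotations import Rotation, sample_uniform_rotations

from conftest import make_footprint


def random_footprint(rng, orientation=None, label="fake", realization=0):
    counts = rng.integers(0, 5, size=(36, 18))
    return make_footprint(counts, orientation, label, realization)


def make_map(d, theta, n=None):
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if n is None:
        # smallest n with n(n-1)/2 >= len(d); pad arrays to match exactly
        n = int(math.ceil((1 + math.sqrt(1 + 8 * len(d))) / 2))
    iu, ju = np.triu_indices(n, k=1)
    assert len(iu) == len(d), "pair count must equal n(n-1)/2"
    return OrientationDistanceMap(i=iu, j=ju, d=d, theta=theta, n=n)


class TestFootprintDistance:
    def test_identical_footprints_have_zero_distance(self):
        rng = np.random.default_rng(0)
        fp = random_footprint(rng)
        assert footprint_distance(fp, fp) == 0.0

    def test_single_pixel_difference(self):
        a = np.zeros((36, 18), dtype=int)
        b = a.copy()
        b[4, 7] = 3
        assert footprint_distance(make_footprint(a), make_footprint(b)) == 3.0

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(1)
        fa, fb = random_footprint(rng), random_footprint(rng)
        brute = 0.0
        for r in range(36):
            for c in range(18):
                diff = float(fa.counts[r, c]) - float(fb.counts[r, c])
                brute += diff * diff
        brute = math.sqrt(brute)
        assert footprint_distance(fa, fb) == pytest.approx(brute, abs=1e-12)

    def test_blurred_pair_is_supported(self):
        rng = np.random.default_rng(2)
        fa, fb = random_footprint(rng), random_footprint(rng)
        d = footprint_distance(gaussian_blur(fa, 0.5), gaussian_blur(fb, 0.5))
        assert d >= 0

    def test_mixing_raw_and_blurred_raises(self):
        rng = np.random.default_rng(3)
        fa, fb = random_footprint(rng), random_footprint(rng)
        with pytest.raises(ValueError, match="mix"):
            footprint_distance(fa, gaussian_blur(fb, 0.5))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            footprint_distance(np.zeros((36, 18)), np.zeros((20, 10)))


class TestOrientationDistanceMap:
    def test_two_footprints_give_one_pair(self):
        rng = np.random.default_rng(4)
        odm = build_orientation_distance_map(
            [random_footprint(rng), random_footprint(rng)], blur_sigma=None
        )
        assert odm.n_pairs == 1

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(5)
        quats = sample_uniform_rotations(100, rng)
        fps = [random_footprint(rng, Rotation(q)) for q in quats]
        odm = build_orientation_distance_map(fps, blur_sigma=None)
        assert odm.n_pairs == 4950

    def test_replicated_footprint_gives_zero_distance_and_angle(self):
        rng = np.random.default_rng(6)
        fp = random_footprint(rng)
        odm = build_orientation_distance_map([fp, fp, fp], blur_sigma=None)
        assert np.all(odm.d == 0.0)
        assert np.all(odm.theta == 0.0)

    def test_mixed_sources_rejected_unless_allowed(self):
        rng = np.random.default_rng(7)
        fps = [random_footprint(rng, label="a"), random_footprint(rng, label="b")]
        with pytest.raises(ValueError, match="mixed sources"):
            build_orientation_distance_map(fps, blur_sigma=None)
        odm = build_orientation_distance_map(
            fps, blur_sigma=None, allow_mixed_sources=True
        )
        assert odm.n_pairs == 1

    def test_distance_matches_footprint_distance_on_blurred_images(self):
        rng = np.random.default_rng(8)
        fps = [random_footprint(rng), random_footprint(rng), random_footprint(rng)]
        odm = build_orientation_distance_map(fps, blur_sigma=0.5)
        expected = footprint_distance(gaussian_blur(fps[0], 0.5), gaussian_blur(fps[1], 0.5))
        assert odm.d[0] == pytest.approx(expected, abs=1e-12)


class TestEnvelope:
    def test_recovers_hand_placed_bin_maxima(self):
        # two pairs per bin at known distances; the larger angle must win
        d = np.array([0.5, 0.5, 1.5, 1.5, 2.5, 2.5])
        theta = np.array([0.2, 0.7, 1.1, 0.4, 2.0, 3.0])
        odm = make_map(d, theta, n=4)
        env = upper_envelope(odm, n_bins=2)
        # range [0.5, 2.5] in 2 bins: [0.5,1.5) and [1.5,2.5]
        assert env.occupied.all()
        np.testing.assert_allclose(env.occupied_values, [0.7, 3.0])

    def test_single_occupied_bin_when_all_pairs_coincide(self):
        odm = make_map([1.0, 1.0, 1.0], [0.3, 0.9, 0.5], n=3)
        env = upper_envelope(odm, n_bins=10)
        assert env.occupied.sum() >= 1
        assert np.nanmax(env.f_values) == 0.9

    def test_envelope_never_exceeds_pi(self):
        rng = np.random.default_rng(9)
        odm = make_map(rng.uniform(0, 10, 45), rng.uniform(0, math.pi, 45), n=10)
        env = upper_envelope(odm, n_bins=8)
        assert np.nanmax(env.f_values) <= math.pi

    def test_rejects_too_few_bins(self):
        odm = make_map([1.0], [0.5], n=2)
        with pytest.raises(ValueError):
            upper_envelope(odm, n_bins=1)


class TestDistanceCutoff:
    def test_step_envelope_puts_cutoff_at_left_of_jump(self):
        # plateau at 0.5 up to d=5, then plateau at 3.0: max slope at the jump
        d = np.concatenate([np.linspace(0, 4.9, 25), np.linspace(5.1, 10, 20)])
        theta = np.concatenate([np.full(25, 0.5), np.full(20, 3.0)])
        odm = make_map(d, theta, n=10)
        env = upper_envelope(odm, n_bins=20)
        cutoff = distance_cutoff(env)
        centers = env.occupied_centers
        jump_left = centers[np.searchsorted(centers, 5.0) - 1]
        assert cutoff == pytest.approx(jump_left)

    def test_linear_envelope_ties_break_to_smallest_distance(self):
        # exactly equal slopes everywhere: the documented tie-break picks
        # the first (smallest-distance) difference
        from explode_orient.retrieval import EnvelopeCurve

        edges = np.arange(11.0)
        env = EnvelopeCurve(
            bin_edges=edges,
            f_values=np.arange(10) * 0.25,
            occupied=np.ones(10, dtype=bool),
        )
        assert distance_cutoff(env) == pytest.approx(env.occupied_centers[0])

    def test_saturating_envelope_cutoff_falls_in_rise_region(self):
        # rapid rise then a plateau near pi, as in a real orientation-distance
        # map: well-aligned pairs sit at small d, random pairs in a broad
        # saturated cloud at d >= 1
        rng = np.random.default_rng(10)
        n = 120
        quats = sample_uniform_rotations(n, rng)
        from explode_orient.rotations import pairwise_relative_angles

        theta = pairwise_relative_angles(quats)
        aligned = theta < 0.5
        d = np.where(aligned, 2 * theta, 1.0 + 4.0 * rng.random(len(theta)))
        odm = make_map(d, theta, n=n)
        env = upper_envelope(odm, n_bins=40)
        cutoff = distance_cutoff(env)
        assert cutoff < 1.2  # at the rise, far below the plateau's bulk
        assert cutoff < np.median(d)

    def test_sparse_envelope_raises(self):
        odm = make_map([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], n=3)
        env = upper_envelope(odm, n_bins=10)
        with pytest.raises(ValueError, match="sparse"):
            distance_cutoff(env)


class TestUnderCutoffStats:
    def test_three_pair_arithmetic(self):
        odm = make_map([1.0, 2.0, 3.0], [0.1, 0.5, 3.0], n=3)
        report = under_cutoff_stats(odm, 2.0)
        assert report.n_pairs_under == 2
        assert report.mean_angle_under == pytest.approx(0.3)
        assert report.n_pairs_total == 3

    def test_cutoff_below_all_distances_flags_undefined_mean(self):
        odm = make_map([1.0, 2.0, 3.0], [0.1, 0.5, 3.0], n=3)
        report = under_cutoff_stats(odm, 0.5)
        assert report.n_pairs_under == 0
        assert math.isnan(report.mean_angle_under)
        assert not report.valid

    def test_cutoff_above_all_distances_recovers_global_random_mean(self):
        rng = np.random.default_rng(11)
        n = 1500
        quats = sample_uniform_rotations(n, rng)
        from explode_orient.rotations import pairwise_relative_angles

        theta = pairwise_relative_angles(quats)
        d = rng.uniform(0, 1, len(theta))
        odm = make_map(d, theta, n=n)
        report = under_cutoff_stats(odm, 2.0)
        assert report.n_pairs_under == odm.n_pairs
        assert report.mean_angle_under == pytest.approx(
            math.pi / 2 + 2 / math.pi, abs=0.01
        )

    def test_report_json_round_trip(self):
        report = CutoffReport(
            x_cutoff=1.5,
            mean_angle_under=0.4,
            n_pairs_under=10,
            n_pairs_total=100,
            efficiency=0.6,
            source_label="x",
        )
        assert CutoffReport.from_json(report.to_json()) == report


class TestEfficiencySweep:
    def test_single_efficiency_gives_single_report(self):
        rng = np.random.default_rng(12)
        quats = sample_uniform_rotations(40, rng)
        fps = [random_footprint(rng, Rotation(q)) for q in quats]
        reports = efficiency_sweep({1.0: fps}, n_bins=10)
        assert len(reports) == 1
        assert reports[0].efficiency == 1.0

    def test_zero_efficiency_set_is_flagged_invalid(self):
        fps = [
            make_footprint(np.zeros((36, 18), dtype=int), Rotation.identity())
            for _ in range(5)
        ]
        reports = efficiency_sweep({0.0: fps}, n_bins=10)
        assert not reports[0].valid
        assert reports[0].n_pairs_under == 0


class TestContinuity:
    def test_footprint_distance_grows_with_orientation_offset(self, ejecta300, geom):
        # same explosion viewed at slowly diverging orientations: the
        # pixel-space distance rises monotonically from exactly zero
        base = Rotation.identity()
        distances = []
        for angle in (0.0, 0.05, 0.1):
            R = Rotation.from_axis_angle([0, 1, 0], angle)
            fa = project_to_detectors(ejecta300, geom, base)
            fb = project_to_detectors(ejecta300, geom, R)
            distances.append(
                footprint_distance(gaussian_blur(fa, 0.5), gaussian_blur(fb, 0.5))
            )
        assert distances[0] == 0.0
        assert distances[0] <= distances[1] <= distances[2]
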