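import itertools

import numpy as np
import pytest

from azquant.segmentation import (
    SeedPoint,
    apply_intensity_threshold,
    compute_cluster_stats,
    compute_density,
    find_maxima_3d,
    match_to_ground_truth,
    segment_spots,
)

VS = (0.37, 0.079, 0.079)
ISO = (0.2, 0.2, 0.2)  # isotropic, keeps hand geometry simple


def embed_1d(profile):
    """Embed a 1D intensity profile as a (1, 1, n) volume."""
    return np.asarray(profile, dtype=float)[None, None, :]


class TestThreshold:
    def test_absolute_zero_all_true(self, rng):
        vol = rng.random((4, 5, 6)) + 0.1
        mask, thr = apply_intensity_threshold(vol, "absolute", 0.0)
        assert thr == 0.0 and mask.all()

    def test_percentile_matches_quantile_oracle(self):
        vol = np.arange(1.0, 101.0).reshape(4, 5, 5)
        mask, thr = apply_intensity_threshold(vol, "percentile", 90)
        assert thr == pytest.approx(np.percentile(vol, 90))
        assert mask.sum() == (vol >= thr).sum()

    def test_mean_plus_zero_sd_is_mean(self, rng):
        vol = rng.random((4, 5, 6))
        _, thr = apply_intensity_threshold(vol, "mean_plus_k_sd", 0.0)
        assert thr == pytest.approx(vol.mean())

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            apply_intensity_threshold(np.ones((2, 2, 2)), "otsu", 0)


class TestFindMaxima:
    def test_single_blob_single_seed(self):
        z, y, x = np.mgrid[0:9, 0:9, 0:9]
        vol = 100 * np.exp(-((z - 4) ** 2 + (y - 4) ** 2 + (x - 4) ** 2) / 4.0)
        seeds = find_maxima_3d(vol, ISO, mask=vol > 1)
        assert len(seeds) == 1 and seeds[0].voxel == (4, 4, 4)

    def test_two_blobs_two_seeds(self):
        vol = np.zeros((5, 5, 21))
        for cx, amp in ((4, 100.0), (16, 80.0)):
            x = np.arange(21)
            vol[2, 2] += amp * np.exp(-((x - cx) ** 2) / 2.0)
        seeds = find_maxima_3d(vol, ISO, mask=vol > 1)
        assert sorted(s.voxel[2] for s in seeds) == [4, 16]

    def test_plateau_tie_lexicographic(self):
        # 2-voxel plateau of equal maxima -> single seed at lower z
        vol = np.zeros((4, 3, 3))
        vol[1, 1, 1] = vol[2, 1, 1] = 50.0
        seeds = find_maxima_3d(vol, ISO, mask=vol > 0)
        assert len(seeds) == 1 and seeds[0].voxel == (1, 1, 1)

    def test_min_distance_keeps_brighter(self):
        vol = np.zeros((3, 3, 11))
        vol[1, 1, 2] = 80.0
        vol[1, 1, 5] = 100.0  # 0.6 µm away at 0.2 µm voxels
        seeds = find_maxima_3d(vol, ISO, mask=vol > 0, min_distance_um=1.0)
        assert [s.voxel for s in seeds] == [(1, 1, 5)]

    def test_min_distance_respects_anisotropy(self):
        # 3 voxels apart along z is 1.11 µm at 0.37 µm spacing: kept;
        # the same voxel gap along x (0.079 µm) is 0.237 µm: suppressed
        vol = np.zeros((9, 9, 9))
        vol[2, 4, 4] = 90.0
        vol[5, 4, 4] = 100.0
        seeds = find_maxima_3d(vol, VS, mask=vol > 0, min_distance_um=0.5)
        assert len(seeds) == 2
        vol2 = np.zeros((9, 9, 9))
        vol2[4, 4, 2] = 90.0
        vol2[4, 4, 5] = 100.0
        seeds2 = find_maxima_3d(vol2, VS, mask=vol2 > 0, min_distance_um=0.5)
        assert [s.voxel for s in seeds2] == [(4, 4, 5)]

    def test_noise_tolerance_drops_shallow_peak(self):
        vol = np.zeros((3, 3, 9))
        vol[1, 1, :] = [0, 0, 10, 12, 10, 0, 50, 0, 0]
        seeds = find_maxima_3d(vol, ISO, mask=vol > 0, noise_tolerance=20.0)
        assert [s.voxel for s in seeds] == [(1, 1, 6)]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            find_maxima_3d(np.ones((3, 3, 3)), ISO, mask=np.zeros((3, 3, 3), bool))


class TestSegmentSpots:
    def test_isolated_cube_full_inclusion(self):
        vol = np.zeros((9, 9, 9))
        vol[3:6, 3:6, 3:6] = 100.0
        seeds = [SeedPoint((4, 4, 4), 100.0)]
        labels, recs = segment_spots(vol, seeds, ISO, fraction=0.5, max_radius_um=2.0)
        assert len(recs) == 1
        assert recs[0].volume_voxels == 27
        assert (labels > 0).sum() == 27

    def test_hand_traced_two_cluster_profile(self):
        # profile 0,60,100,60,0,60,100,60,0 with seeds at both 100s and
        # f = 0.5: thresholds 50, zeros stop growth -> two 3-voxel clusters
        vol = embed_1d([0, 60, 100, 60, 0, 60, 100, 60, 0])
        seeds = [SeedPoint((0, 0, 2), 100.0), SeedPoint((0, 0, 6), 100.0)]
        labels, recs = segment_spots(
            vol, seeds, ISO, fraction=0.5, max_radius_um=5.0, split="nearest-seed"
        )
        assert sorted(r.volume_voxels for r in recs) == [3, 3]
        assert labels[0, 0, 4] == 0

    def test_fraction_one_keeps_only_seed(self):
        vol = embed_1d([0, 60, 100, 60, 0])
        seeds = [SeedPoint((0, 0, 2), 100.0)]
        _, recs = segment_spots(vol, seeds, ISO, fraction=1.0, max_radius_um=5.0)
        assert recs[0].volume_voxels == 1

    def test_scale_equivariance(self, rng):
        vol = rng.random((6, 8, 8)) * 100
        seeds = find_maxima_3d(vol, ISO, mask=vol > 50)
        labels1, _ = segment_spots(vol, seeds, ISO, fraction=0.6, max_radius_um=0.5)
        seeds_scaled = find_maxima_3d(vol * 3, ISO, mask=vol * 3 > 150)
        labels2, _ = segment_spots(vol * 3, seeds_scaled, ISO, fraction=0.6, max_radius_um=0.5)
        np.testing.assert_array_equal(labels1 > 0, labels2 > 0)

    def test_cluster_contains_seed_and_count_bound(self, rng):
        vol = rng.random((6, 10, 10)) * 100
        seeds = find_maxima_3d(vol, ISO, mask=vol > 60, min_distance_um=0.3)
        labels, recs = segment_spots(vol, seeds, ISO, fraction=0.5, max_radius_um=0.6,
                                     split="nearest-seed")
        assert len(recs) <= len(seeds)
        by_id = {r.id: r for r in recs}
        for lab, seed in enumerate(
            sorted(seeds, key=lambda s: (-s.intensity, s.voxel)), start=1
        ):
            if lab in by_id:
                assert labels[seed.voxel] == lab

    def test_seed_below_floor_dropped_with_warning(self):
        vol = embed_1d([0, 5, 0, 0, 100, 0])
        seeds = [SeedPoint((0, 0, 1), 5.0), SeedPoint((0, 0, 4), 100.0)]
        with pytest.warns(UserWarning, match="below floor"):
            _, recs = segment_spots(vol, seeds, ISO, fraction=0.5, floor=10.0)
        assert len(recs) == 1

    def test_dilate_adds_shell_without_overwrite(self):
        vol = embed_1d([0, 0, 100, 0, 0, 100, 0, 0])
        seeds = [SeedPoint((0, 0, 2), 100.0), SeedPoint((0, 0, 5), 100.0)]
        labels, _ = segment_spots(vol, seeds, ISO, fraction=0.9, max_radius_um=3.0, dilate=1)
        assert labels[0, 0, 1] == labels[0, 0, 2] != 0
        assert labels[0, 0, 5] == labels[0, 0, 6] != 0
        # contested voxels between the two clusters keep a single owner each
        assert (labels[0, 0] > 0).sum() >= 6


class TestClusterStats:
    def test_direct_arithmetic(self):
        vol = embed_1d([10.0, 20.0, 30.0])
        labels = np.array([[[1, 1, 1]]], dtype=np.int32)
        (rec,) = compute_cluster_stats(labels, vol, ISO)
        assert rec.sum_intensity == 60
        assert rec.mean_intensity == 20
        assert rec.median_intensity == 20
        assert rec.max_intensity == 30
        assert rec.volume_voxels == 3

    def test_empty_labels_empty_list(self):
        assert compute_cluster_stats(np.zeros((2, 2, 2), np.int32), np.ones((2, 2, 2)), ISO) == []

    def test_anisotropic_volume_um3(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[1, 1, :] = 1
        (rec,) = compute_cluster_stats(labels, np.ones((3, 3, 3)), VS)
        assert rec.volume_um3 == pytest.approx(3 * 0.370 * 0.079 * 0.079, abs=1e-12)

    def test_intensity_weighted_centroid(self):
        vol = embed_1d([0.0, 1.0, 3.0, 0.0])
        labels = np.array([[[0, 1, 1, 0]]], np.int32)
        (rec,) = compute_cluster_stats(labels, vol, ISO)
        # centroid x = (1*1 + 2*3)/4 voxels = 1.75 * 0.2 µm
        assert rec.centroid_um[2] == pytest.approx(1.75 * 0.2)


class TestDensity:
    @staticmethod
    def _recs_at(xs):
        return [
            type("R", (), {"centroid_um": (0.2, 0.2, x)})() for x in xs
        ]

    def test_basic_projected_area(self):
        mask = np.zeros((4, 5, 5), bool)
        mask[:, :2, :5] = True  # projects to 10 pixels of 1 µm² at 1 µm voxels
        recs = [type("R", (), {"centroid_um": (1.0, 0.5, float(i))})() for i in range(5)]
        d, ok = compute_density(recs, mask, (1.0, 1.0, 1.0))
        assert ok and d == pytest.approx(0.5)

    def test_empty_compartment_flagged(self):
        d, ok = compute_density([], np.zeros((2, 2, 2), bool), ISO)
        assert d == 0.0 and not ok

    def test_density_linear_in_count(self):
        mask = np.ones((2, 4, 4), bool)
        d1, _ = compute_density(self._recs_at([0.2, 0.4]), mask, ISO)
        d2, _ = compute_density(self._recs_at([0.2, 0.4, 0.1, 0.5]), mask, ISO)
        assert d2 == pytest.approx(2 * d1)

    def test_volume_denominator(self):
        mask = np.ones((2, 2, 2), bool)
        d, _ = compute_density(self._recs_at([0.2]), mask, (1.0, 1.0, 1.0), denominator="volume")
        assert d == pytest.approx(1 / 8)


class TestMatching:
    def test_perfect_match(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 0, 1.0]])
        m = match_to_ground_truth(pts, pts, 0.3)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_three_of_four(self):
        tru = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5.0]])
        det = tru[:3] + 0.01
        m = match_to_ground_truth(det, tru, 0.3)
        assert m.precision == 1.0
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(6 / 7)

    def test_two_detections_one_truth(self):
        tru = np.array([[0.0, 0.0, 0.0]])
        det = np.array([[0.0, 0.0, 0.05], [0.0, 0.05, 0.0]])
        m = match_to_ground_truth(det, tru, 0.3)
        assert len(m.true_positives) == 1
        assert len(m.false_positive_idx) == 1

    def test_optimal_beats_greedy_on_crossing(self):
        # brute-force over assignments: optimal pairing must reach the
        # minimum total distance among all one-to-one pairings
        rng = np.random.default_rng(4)
        tru = rng.random((5, 3))
        det = tru[::-1] + rng.normal(0, 0.05, (5, 3))
        m = match_to_ground_truth(det, tru, max_dist_um=1.0)
        got = sum(
            np.linalg.norm(det[i] - tru[j]) for i, j in m.true_positives
        )
        best = min(
            sum(np.linalg.norm(det[i] - tru[p[i]]) for i in range(5))
            for p in itertools.permutations(range(5))
        )
        assert got == pytest.approx(best, abs=1e-9)

    def test_empty_inputs(self):
        m = match_to_ground_truth(np.empty((0, 3)), np.array([[0, 0, 0.0]]), 0.3)
        assert m.recall == 0.0 and m.precision == 0.0
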