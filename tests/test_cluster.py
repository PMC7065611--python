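"""Two-channel manual clustering and full-cube k-means."""

import itertools

import numpy as np
import pytest

from stainscan import (
    cleaned_overlay,
    jaccard,
    kmeans_cluster,
    overlay_render,
    select_channel,
    separation_score,
    two_channel_features,
)
from stainscan.cluster import SEPARATION_CAP, PixelFeatureSet
from stainscan.cube import ChannelMeta, Region
from stainscan.errors import ComparisonError, DegenerateInputError, GeometryError, InputError

from conftest import make_stack

GREEN_500 = ("green", 500.0)
RED_500 = ("red", 500.0)

# crops mirroring the manual workflow: a stain patch and a background patch
STAIN_REGION = Region(40, 35, 10, 10)  # inside the 60 x 30 px planted stain
BACKGROUND_REGION = Region(5, 5, 10, 10)


def _fig3_features(stack):
    return two_channel_features(
        stack, GREEN_500, RED_500,
        {"stain": STAIN_REGION, "background": BACKGROUND_REGION},
    )


class TestTwoChannelFeatures:
    def test_count_conservation(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        feats = _fig3_features(dirty)
        assert feats.features.shape == (200, 2)
        assert (feats.labels == "stain").sum() == 100

    def test_stain_points_brighter_under_green_excitation(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        feats = _fig3_features(dirty)
        stain = feats.subset("stain")
        background = feats.subset("background")
        assert stain[:, 0].min() > background[:, 0].max()

    def test_duplicated_condition_puts_points_on_diagonal(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        feats = two_channel_features(
            dirty, GREEN_500, GREEN_500, {"background": BACKGROUND_REGION}
        )
        np.testing.assert_array_equal(feats.features[:, 0], feats.features[:, 1])


class TestSeparationScore:
    def _point_set(self, points, label):
        points = np.asarray(points, dtype=float)
        return points, [label] * len(points)

    def _fs(self, a, b):
        fa, la = self._point_set(a, "A")
        fb, lb = self._point_set(b, "B")
        return PixelFeatureSet(
            features=np.vstack([fa, fb]),
            pixel_index=np.zeros((len(fa) + len(fb), 2), dtype=int),
            labels=np.array(la + lb, dtype=object),
        )

    def test_identical_sets_score_zero(self):
        pts = [[0.1, 0.2], [0.3, 0.4]]
        assert separation_score(self._fs(pts, pts), "A", "B") == 0.0

    def test_point_masses_at_distance_capped(self):
        fs = self._fs([[0, 0], [0, 0]], [[1, 1], [1, 1]])
        assert separation_score(fs, "A", "B") == SEPARATION_CAP

    def test_phantom_groups_well_separated(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        feats = _fig3_features(dirty)
        assert separation_score(feats, "stain", "background") > 5.0

    def test_empty_group_rejected(self):
        fs = self._fs([[0, 0]], [[1, 1]])
        with pytest.raises(InputError):
            separation_score(fs, "A", "missing")


class TestCleanedOverlay:
    def test_cleaned_stain_falls_with_background(self, noise_free_pair):
        _, dirty, clean, _ = noise_free_pair
        fd = _fig3_features(dirty)
        fc = _fig3_features(clean)
        merged = cleaned_overlay(fd, fc)
        c_bg = merged.subset("background").mean(axis=0)
        c_stain = merged.subset("stain").mean(axis=0)
        c_cleaned = merged.subset("cleaned-stain").mean(axis=0)
        # noise-free: the cleaned stain area is the background exactly
        np.testing.assert_allclose(c_cleaned, c_bg)
        assert np.linalg.norm(c_stain - c_bg) > np.linalg.norm(c_cleaned - c_bg)

    def test_condition_mismatch_rejected(self, noise_free_pair):
        _, dirty, clean, _ = noise_free_pair
        fd = _fig3_features(dirty)
        fc = two_channel_features(
            clean, GREEN_500, ("red", 520.0),
            {"stain": STAIN_REGION, "background": BACKGROUND_REGION},
        )
        with pytest.raises(ComparisonError):
            cleaned_overlay(fd, fc)


def brute_force_best_2partition(points):
    """Minimal within-cluster sum of squares over every 2-partition."""
    n = len(points)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        if 0 < sum(bits) < n:
            obj = 0.0
            for c in (0, 1):
                grp = points[np.array(bits) == c]
                obj += ((grp - grp.mean(axis=0)) ** 2).sum()
            best = min(best, obj)
    return best


class TestKMeans:
    def test_noise_free_phantom_recovered_exactly(self, noise_free_pair):
        _, dirty, _, truth = noise_free_pair
        region = Region(0, 0, dirty.width, dirty.height)
        result = kmeans_cluster(dirty, region, k=2, seed=0)
        assert jaccard(result.stain_mask().mask, truth.mask) == 1.0

    def test_constant_region_is_degenerate(self):
        stack = make_stack(np.full((2, 6, 6), 0.3), filters=[420, 440])
        with pytest.raises(DegenerateInputError):
            kmeans_cluster(stack, Region(0, 0, 6, 6), k=2)

    def test_same_seed_same_assignment(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        region = Region(20, 20, 40, 30)
        r1 = kmeans_cluster(dirty, region, k=2, seed=5)
        r2 = kmeans_cluster(dirty, region, k=2, seed=5)
        np.testing.assert_array_equal(r1.assignment, r2.assignment)

    def test_stain_designation_invariant_to_restart_seed(self, noise_free_pair):
        _, dirty, _, truth = noise_free_pair
        region = Region(0, 0, dirty.width, dirty.height)
        masks = [
            kmeans_cluster(dirty, region, k=2, seed=s).stain_mask().mask for s in (0, 1, 2)
        ]
        for m in masks[1:]:
            np.testing.assert_array_equal(m, masks[0])

    def test_objective_matches_exhaustive_enumeration(self):
        """On <= 12 points the seeded k-means partition attains the global
        2-partition optimum found by brute force."""
        rng = np.random.default_rng(3)
        frames = rng.random((2, 3, 4))  # 12 pixels, 2 channels
        stack = make_stack(frames, filters=[420, 440])
        result = kmeans_cluster(
            stack, Region(0, 0, 4, 3), k=2, seed=0, n_restarts=50, standardize=False
        )
        points = frames.reshape(2, -1).T
        assert result.inertia == pytest.approx(brute_force_best_2partition(points), rel=1e-9)


class TestOverlay:
    def test_empty_stain_cluster_leaves_background_untouched(self):
        frames = np.zeros((1, 6, 6))
        frames[0, 2, 2] = 0.5
        stack = make_stack(frames)
        from stainscan.cluster import ClusterResult

        result = ClusterResult(
            assignment=np.zeros((6, 6), dtype=int),
            centroids=np.zeros((2, 1)),
            stain_cluster=1,
            k=2,
            seed=0,
            region=Region(0, 0, 6, 6),
        )
        rgb = overlay_render(result, frames[0])
        np.testing.assert_array_equal(rgb, np.repeat(frames[0][:, :, None], 3, axis=2))

    def test_phantom_highlight_coincides_with_truth(self, noise_free_pair):
        _, dirty, _, truth = noise_free_pair
        region = Region(0, 0, dirty.width, dirty.height)
        result = kmeans_cluster(dirty, region, k=2, seed=0)
        bg = select_channel(dirty, "green", 500.0)
        rgb = overlay_render(result, bg)
        highlighted = (rgb[:, :, 0] == 1.0) & (rgb[:, :, 1] == 0.6) & (rgb[:, :, 2] == 0.0)
        np.testing.assert_array_equal(highlighted, truth.mask)

    def test_dimension_mismatch_rejected(self, noise_free_pair):
        _, dirty, _, _ = noise_free_pair
        result = kmeans_cluster(dirty, Region(0, 0, dirty.width, dirty.height), k=2, seed=0)
        with pytest.raises(GeometryError):
            overlay_render(result, np.zeros((10, 10)))
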