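"""Morphospace: embedding determinism, KDE+watershed region recovery,
composites, failure-mode labelling, and frozen-boundary assignment."""

import numpy as np
import pytest

from gastrumap.morphospace import (
    angular_asymmetry,
    assign_points,
    assign_region,
    call_teratogen,
    composite,
    embed_tsne,
    kde_watershed,
)
from gastrumap.records import PhenotypeVector
from gastrumap.synth import PatternSpec, gen_colony


class TestEmbed:
    def test_seed_determinism(self):
        X = np.random.default_rng(0).normal(size=(95, 150))
        a = embed_tsne(X, perplexity=30, seed=1)
        b = embed_tsne(X, perplexity=30, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_too_few_rows_names_perplexity(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(np.zeros((10, 150)), perplexity=30)

    def test_separated_classes_stay_separated(self, screen_vectors, screen_truth, morpho):
        # silhouette of the embedding against generator pattern classes
        from sklearn.metrics import silhouette_score

        classes, _ = screen_truth
        keep_classes = {"canonical", "loss_sox2", "loss_bra"}
        idx = [i for i, c in enumerate(classes) if c in keep_classes]
        score = silhouette_score(morpho.coords[idx], np.array(classes)[idx])
        assert score > 0.5


class TestKdeWatershed:
    def _blobs(self, centers, n=100, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([rng.normal(c, sd, size=(n, 2)) for c in centers])
        labels = np.repeat(np.arange(len(centers)), n)
        return pts, labels

    def test_two_far_blobs_two_regions(self):
        pts, _ = self._blobs([(0, 0), (12, 0)], sd=1.0)
        _, label_map, _, pl = kde_watershed(pts)
        assert len(np.unique(pl)) == 2

    def test_single_blob_one_region(self):
        pts, _ = self._blobs([(0, 0)], n=200)
        _, label_map, _, pl = kde_watershed(pts)
        assert len(np.unique(label_map)) == 1

    def test_four_blob_grid_purity(self):
        pts, truth = self._blobs([(0, 0), (14, 0), (0, 14), (14, 14)], n=80, seed=2)
        _, _, _, pl = kde_watershed(pts)
        regions = np.unique(pl)
        assert len(regions) == 4
        for g in range(4):
            members = pl[truth == g]
            dominant = np.bincount(members).max()
            assert dominant / members.size >= 0.95

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_watershed(np.zeros((5, 2)), bandwidth_factor=0.0)


class TestCompositeAndFailures:
    def test_composite_identity_and_mean(self, morpho, screen_vectors):
        scaled, _ = screen_vectors
        cid = morpho.cluster_ids[0]
        comp = composite(morpho, cid, scaled)
        members = morpho.members(cid)
        oracle = np.mean([scaled[i].values for i in members], axis=0)
        np.testing.assert_allclose(comp.values, oracle)

    def test_two_member_average(self, morpho):
        a = PhenotypeVector(np.zeros(150))
        b = PhenotypeVector(np.ones(150))
        vecs = [a, b] * (len(morpho.labels) // 2 + 1)
        cid = morpho.cluster_ids[0]
        m = morpho.members(cid)[:2]
        pair_mean = (vecs[m[0]].values + vecs[m[1]].values) / 2
        assert pair_mean.shape == (150,)

    def test_failure_clusters_contain_planted_failures(self, morpho, screen, screen_truth):
        _, failure_truth = screen_truth
        called = np.array([lab in morpho.failure_set for lab in morpho.labels])
        # the labelled failure regions capture the planted failure colonies
        sens = np.mean(called[failure_truth])
        spec = np.mean(~called[~failure_truth])
        assert sens >= 0.95
        assert spec >= 0.95

    def test_asymmetry_statistic_separates_crescent(self):
        sym = gen_colony(PatternSpec(density=800, noise_sd=2.0, seed=0))
        asym = gen_colony(PatternSpec(pattern_class="asymmetric", density=800,
                                      noise_sd=2.0, seed=0))
        assert angular_asymmetry(sym) < 0.25
        assert angular_asymmetry(asym) > 0.25


class TestAssignRegion:
    def test_grid_pixel_identity(self, morpho):
        ix, iy = 100, 200
        p = np.array([morpho.grid_x[ix], morpho.grid_y[iy]])
        assert assign_region(morpho, p) == morpho.label_map[iy, ix]

    def test_member_centroid_maps_to_cluster(self, morpho):
        for cid in morpho.cluster_ids:
            members = morpho.members(cid)
            if members.size < 5:
                continue
            centroid = morpho.coords[members].mean(axis=0)
            if assign_region(morpho, centroid) == cid:
                return
        pytest.fail("no cluster centroid mapped back to its own region")

    def test_training_points_reproduce_labels(self, morpho):
        relabeled = assign_points(morpho.label_map, morpho.grid_x, morpho.grid_y,
                                  morpho.coords)
        assert np.mean(relabeled == morpho.labels) >= 0.99

    def test_outside_point_snaps_with_warning(self, morpho):
        far = np.array([morpho.grid_x[-1] + 100, morpho.grid_y[-1] + 100])
        with pytest.warns(UserWarning, match="snapped"):
            lab = assign_region(morpho, far)
        assert lab in morpho.cluster_ids or lab in np.unique(morpho.label_map)

    def test_teratogen_call_equals_region_membership(self, morpho):
        rng = np.random.default_rng(0)
        lo = np.array([morpho.grid_x[0], morpho.grid_y[0]])
        hi = np.array([morpho.grid_x[-1], morpho.grid_y[-1]])
        pts = rng.uniform(lo, hi, size=(1000, 2))
        for p in pts:
            assert call_teratogen(morpho, p) == (assign_region(morpho, p) in morpho.failure_set)
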