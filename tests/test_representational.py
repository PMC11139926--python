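"""RDMs, RSA permutation tests, MDS, and hierarchical clustering."""

import itertools

import numpy as np
import pytest

from shapecat import RDM, synth
from shapecat import rdm as R


def _patterned_per_trial(patterns, n_trials=4, noise=0.0, seed=0):
    """Noise-free (or noisy) per-trial tensor from channel patterns.

    ``patterns`` is (n_channels, n_stimuli); each trial repeats the
    stimulus pattern exactly (plus optional Gaussian noise).
    """
    rng = np.random.default_rng(seed)
    n_ch, n_stim = patterns.shape
    pt = np.repeat(patterns[:, :, None], n_trials, axis=2).astype(float)
    if noise:
        pt += rng.normal(0, noise, size=pt.shape)
    return pt


class TestSplitHalfRDM:
    def test_analytic_values_identical_orthogonal_anticorrelated(self):
        # four channels; stimulus patterns engineered so that, across
        # channels, corr(s0, s1) = 1, corr(s0, s2) = 0, corr(s0, s3) = -1
        p0 = np.array([1.0, -1.0, 1.0, -1.0])
        p2 = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to p0
        patterns = np.stack([p0, p0, p2, -p0], axis=1)
        pt = _patterned_per_trial(patterns)
        rdm = R.splithalf_rdm(pt, np.arange(1, 5), n_iter=3, seed=0)
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert rdm.values[0, 2] == pytest.approx(1.0, abs=1e-6)
        assert rdm.values[0, 3] == pytest.approx(2.0, abs=1e-6)

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        pt = rng.normal(size=(6, 8, 6))
        rdm = R.splithalf_rdm(pt, np.arange(1, 9), n_iter=20, seed=2)
        assert np.allclose(rdm.values, rdm.values.T)
        assert np.all(np.diag(rdm.values) == 0)
        assert rdm.values.min() >= 0.0 and rdm.values.max() <= 2.0

    def test_seed_convergence_with_iterations(self):
        # two different split seeds converge to the same RDM as n_iter grows
        rng = np.random.default_rng(3)
        patterns = rng.normal(size=(10, 8))
        pt = _patterned_per_trial(patterns, n_trials=10, noise=1.0, seed=4)
        a = R.splithalf_rdm(pt, np.arange(1, 9), n_iter=200, seed=5)
        b = R.splithalf_rdm(pt, np.arange(1, 9), n_iter=200, seed=6)
        corr = np.corrcoef(a.triu_vector(), b.triu_vector())[0, 1]
        assert corr > 0.98

    def test_single_trial_stimulus_named_in_error(self):
        pt = np.full((3, 4, 2), 1.0)
        pt[:, 2, 1] = np.nan  # stimulus 3 has one trial
        with pytest.raises(ValueError, match=r"\[3\]"):
            R.splithalf_rdm(pt, np.arange(1, 5), n_iter=2, seed=0)


class TestSilhouetteRDM:
    def _design_with(self, masks):
        d = synth.generate_design(2, 2)
        return type(d)(d.table, {i + 1: m for i, m in enumerate(masks)})

    def test_identical_masks_zero(self):
        m = np.ones((8, 8), dtype=np.uint8)
        d = self._design_with([m, m, m, m])
        assert R.silhouette_rdm(d).values.max() == 0.0

    def test_all_pixels_differ_gives_one(self):
        a = np.zeros((8, 8))
        b = np.ones((8, 8))
        d = self._design_with([a, b, a, b])
        assert R.silhouette_rdm(d).values[0, 1] == pytest.approx(1.0)

    def test_half_pixels_differ(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        b[:2] = 1.0
        d = self._design_with([a, b, a, b])
        assert R.silhouette_rdm(d).values[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_mismatched_dimensions_rejected(self):
        d = self._design_with(
            [np.ones((4, 4)), np.ones((5, 5)), np.ones((4, 4)), np.ones((4, 4))]
        )
        with pytest.raises(ValueError, match="dimensions"):
            R.silhouette_rdm(d)


class TestAspectRatio:
    def test_disc_near_one(self):
        yy, xx = np.mgrid[0:256, 0:256]
        disc = (xx - 128) ** 2 + (yy - 128) ** 2 <= 100**2
        assert R.aspect_ratio(disc) == pytest.approx(1.0, rel=0.15)

    def test_square_near_four_over_pi(self):
        m = np.zeros((256, 256), dtype=bool)
        m[50:200, 50:200] = True
        assert R.aspect_ratio(m) == pytest.approx(4 / np.pi, rel=0.12)

    def test_elongation_increases_ratio(self):
        m1 = np.zeros((128, 128), dtype=bool)
        m1[56:72, 14:114] = True  # 16 x 100 bar
        m2 = np.zeros((128, 128), dtype=bool)
        m2[44:84, 44:84] = True  # 40 x 40 square
        assert R.aspect_ratio(m1) > R.aspect_ratio(m2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            R.aspect_ratio(np.zeros((8, 8)))

    def test_rdm_is_absolute_difference(self, design54_masks):
        rdm = R.aspect_ratio_rdm(design54_masks)
        ids = design54_masks.stimulus_ids
        a0 = R.aspect_ratio(design54_masks.silhouettes[int(ids[0])])
        a5 = R.aspect_ratio(design54_masks.silhouettes[int(ids[5])])
        assert rdm.values[0, 5] == pytest.approx(abs(a0 - a5), abs=1e-12)


def _random_rdm(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return RDM(m, np.arange(1, n + 1))


class TestRSAPermutation:
    def test_self_correlation_maximal(self):
        rng = np.random.default_rng(0)
        r = _random_rdm(12, rng)
        rho, p = R.rsa_permutation(r, r, n_perm=199, seed=1)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1 / 200)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        a, b = _random_rdm(10, rng), _random_rdm(10, rng)
        rho, _ = R.rsa_permutation(a, b, n_perm=100, seed=0)
        perm = rng.permutation(10)
        rho2, _ = R.rsa_permutation(
            RDM(a.values[np.ix_(perm, perm)], a.labels),
            RDM(b.values[np.ix_(perm, perm)], b.labels),
            n_perm=100,
            seed=0,
        )
        assert rho2 == pytest.approx(rho, abs=1e-12)

    def test_observed_rho_matches_scipy(self):
        from scipy.stats import pearsonr, spearmanr

        rng = np.random.default_rng(3)
        a, b = _random_rdm(14, rng), _random_rdm(14, rng)
        rho_s, _ = R.rsa_permutation(a, b, n_perm=100, seed=0, method="spearman")
        assert rho_s == pytest.approx(
            spearmanr(a.triu_vector(), b.triu_vector()).statistic, abs=1e-10
        )
        rho_p, _ = R.rsa_permutation(a, b, n_perm=100, seed=0, method="pearson")
        assert rho_p == pytest.approx(
            pearsonr(a.triu_vector(), b.triu_vector()).statistic, abs=1e-10
        )

    def test_constant_rdm_rejected(self):
        flat = RDM(np.ones((5, 5)) - np.eye(5), np.arange(1, 6))
        zero = RDM(np.zeros((5, 5)), np.arange(1, 6))
        with pytest.raises(ValueError, match="constant"):
            R.rsa_permutation(flat, zero, n_perm=100, seed=0)


class TestMDS:
    def test_equilateral_triangle_embeds_with_zero_stress(self):
        vals = np.ones((3, 3)) - np.eye(3)
        rdm = RDM(vals, np.arange(1, 4))
        coords, stress = R.mds_embed(rdm, n_dims=2, seed=0)
        assert stress == pytest.approx(0.0, abs=1e-3)
        d = np.linalg.norm(coords[0] - coords[1]), np.linalg.norm(coords[0] - coords[2])
        assert d[0] == pytest.approx(d[1], rel=0.05)

    def test_planted_configuration_rank_recovery(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform
        from scipy.stats import spearmanr

        dist = squareform(pdist(pts))
        rdm = RDM(dist, np.arange(1, 10))
        coords, stress = R.mds_embed(rdm, n_dims=2, seed=0)
        got = pdist(coords)
        assert spearmanr(got, pdist(pts)).statistic > 0.95

    def test_stress_curve_non_increasing(self):
        rng = np.random.default_rng(5)
        rdm = _random_rdm(12, rng)
        curve = R.stress_curve(rdm, max_dims=10, seed=0, n_init=4)
        assert np.all(np.diff(curve) <= 1e-9)

    def test_too_many_dims_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            R.mds_embed(_random_rdm(5, rng), n_dims=5)


class TestIntraInter:
    def test_clustered_embedding_detected(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2, 3], 8)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        coords = centers[labels - 1] + rng.normal(0, 0.3, size=(24, 2))
        res = R.intra_inter_distances(coords, labels)
        assert res["intra_mean"] < res["inter_mean"]
        assert res["p"] < 1e-10

    def test_pair_counts_partition(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([1, 2], 6)
        coords = rng.normal(size=(12, 2))
        res = R.intra_inter_distances(coords, labels)
        assert len(res["intra"]) + len(res["inter"]) == 12 * 11 // 2

    def test_singleton_group_warns(self):
        rng = np.random.default_rng(2)
        labels = np.array([1, 1, 1, 2])
        with pytest.warns(UserWarning, match="one member"):
            R.intra_inter_distances(rng.normal(size=(4, 2)), labels)


def single_linkage_oracle(dist):
    """Exhaustive nearest-pair merging; returns merge heights."""
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = min(dist[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)


class TestClustering:
    def test_two_blocks_split_first(self):
        n = 8
        vals = np.full((n, n), 1.0)
        vals[:4, :4] = 0.1
        vals[4:, 4:] = 0.1
        np.fill_diagonal(vals, 0)
        rdm = RDM(vals, np.arange(1, n + 1))
        z, labels = R.cluster_hierarchical(rdm, max_clusters=2)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:4])) == 1 and len(np.unique(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        rdm = _random_rdm(10, rng)
        z, _ = R.cluster_hierarchical(rdm)
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            rdm = _random_rdm(6, rng)
            z, _ = R.cluster_hierarchical(rdm)
            np.testing.assert_allclose(
                np.sort(z[:, 2]), np.sort(single_linkage_oracle(rdm.values)), atol=1e-12
            )

    def test_single_stimulus_rejected(self):
        with pytest.raises(ValueError):
            R.cluster_hierarchical(RDM(np.zeros((1, 1)), np.array([1])))


class TestModelRelations:
    def test_silhouette_rdm_tracks_behavioral_shape_model(self, design54_masks):
        sil = R.silhouette_rdm(design54_masks)
        shape_m, _ = synth.generate_behavioral_rdms(design54_masks, seed=0)
        rho, p = R.rsa_permutation(sil, shape_m, n_perm=200, seed=1)
        assert rho > 0
        assert p < 0.05
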