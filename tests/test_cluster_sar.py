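"""K-means selection, PCA, bit frequencies, SAR correlations and MCS."""

import itertools

import numpy as np
import pytest

from chemfuse.cluster_sar import (
    bit_frequency_profile,
    clustering_features,
    kmeans_select,
    mcs_contains_hydroxyl,
    mcs_for_cluster,
    pca_project,
    sar_correlations,
)


class TestClusteringFeatures:
    def test_pic50_column_standardized(self):
        rng = np.random.default_rng(0)
        fps = (rng.random((50, 16)) < 0.3).astype(float)
        pic = rng.normal(6, 1.2, size=50)
        feats = clustering_features(fps, pic)
        assert feats.shape == (50, 17)
        assert abs(feats[:, -1].mean()) < 1e-8
        assert abs(feats[:, -1].std() - 1) < 1e-8


class TestKmeansSelect:
    def test_sse_zero_when_k_equals_distinct_points(self):
        pts = np.array([[0.0, 0], [5, 5], [10, 0], [0, 10]])
        rep = kmeans_select(pts, k_range=[2, 3, 4], n_init=10, seed=0)
        assert rep.sse_curve[4] == pytest.approx(0.0, abs=1e-12)

    def test_three_separated_blobs_selected(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.0, 0], [10, 0], [0, 10]])
        pts = np.vstack([rng.normal(c, 0.1, size=(30, 2)) for c in centers])
        rep = kmeans_select(pts, k_range=range(2, 7), seed=1)
        assert rep.k == 3
        assert rep.silhouette_curve[3] > 0.9

    def test_sse_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(60, 5))
        rep = kmeans_select(pts, k_range=range(2, 8), seed=2)
        sses = [rep.sse_curve[k] for k in sorted(rep.sse_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_more_inits_never_worse(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 3))
        r1 = kmeans_select(pts, k_range=[2, 3, 4], n_init=1, seed=3)
        r20 = kmeans_select(pts, k_range=[2, 3, 4], n_init=20, seed=3)
        for k in (2, 3, 4):
            assert r20.sse_curve[k] <= r1.sse_curve[k] + 1e-9

    def test_exhaustive_partition_oracle_k2(self):
        """Best-of-inits SSE equals the exhaustive-partition minimum on 8 points."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 2))

        def partition_sse(mask):
            groups = [pts[mask], pts[~mask]]
            return sum(((g - g.mean(axis=0)) ** 2).sum() for g in groups if len(g))

        best = min(
            partition_sse(np.array(bits, dtype=bool))
            for bits in itertools.product([0, 1], repeat=8)
            if 0 < sum(bits) < 8
        )
        rep = kmeans_select(pts, k_range=[2, 3], n_init=100, seed=4)
        assert rep.sse_curve[2] == pytest.approx(best, rel=1e-9)

    def test_silhouette_matches_direct_formula_on_toy(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]])
        rep = kmeans_select(pts, k_range=[2, 3], n_init=10, seed=5)

        labels = rep.assignments
        # direct formula: s(i) = (b - a) / max(a, b)
        svals = []
        for i in range(len(pts)):
            same = [j for j in range(len(pts)) if labels[j] == labels[i] and j != i]
            other_clusters = set(labels) - {labels[i]}
            a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in same])
            b = min(
                np.mean([np.linalg.norm(pts[i] - pts[j]) for j in range(len(pts)) if labels[j] == c])
                for c in other_clusters
            )
            svals.append((b - a) / max(a, b))
        assert rep.silhouette_curve[2] == pytest.approx(np.mean(svals), abs=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kmeans_select(np.zeros((3, 2)), k_range=[2, 5])


class TestPCA:
    def test_rank_one_data_recovered(self):
        t = np.linspace(0, 1, 30)
        pts = np.outer(t, [1.0, 2.0, -1.0])
        coords, ev = pca_project(pts)
        assert ev[0] > 0.999

    def test_explained_variance_ordered_and_bounded(self):
        rng = np.random.default_rng(6)
        coords, ev = pca_project(rng.normal(size=(40, 6)), dims=3)
        assert all(a >= b for a, b in zip(ev, ev[1:]))
        assert ev.sum() <= 1 + 1e-12

    def test_mean_shift_invariance_up_to_sign(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 4))
        c1, _ = pca_project(X)
        c2, _ = pca_project(X + 100.0)
        for j in range(2):
            assert np.allclose(c1[:, j], c2[:, j], atol=1e-8) or np.allclose(c1[:, j], -c2[:, j], atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 4))
        coords, ev = pca_project(X, dims=2)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / 5)  # population covariance
        order = np.argsort(w)[::-1]
        expected = Xc @ V[:, order[:2]]
        for j in range(2):
            assert np.allclose(coords[:, j], expected[:, j], atol=1e-8) or np.allclose(
                coords[:, j], -expected[:, j], atol=1e-8
            )

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pca_project(np.ones((10, 3)))


class TestBitFrequency:
    def test_identical_cluster_members_give_binary_frequencies(self):
        fps = np.tile(np.array([1, 0, 1, 0], dtype=float), (4, 1))
        prof = bit_frequency_profile(np.zeros(4, dtype=int), fps)
        assert set(np.unique(prof[0])) <= {0.0, 1.0}

    def test_hand_counted_toy(self):
        fps = np.array([[1, 1], [1, 0], [0, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        prof = bit_frequency_profile(labels, fps)
        assert prof[0].tolist() == [2 / 3, 1 / 3]
        assert prof[1].tolist() == [1 / 3, 2 / 3]

    def test_total_frequency_is_weighted_cluster_mean(self):
        rng = np.random.default_rng(9)
        fps = (rng.random((30, 8)) < 0.4).astype(float)
        labels = rng.integers(0, 3, size=30)
        prof = bit_frequency_profile(labels, fps)
        weights = np.bincount(labels) / 30
        recombined = sum(weights[c] * prof[c] for c in prof)
        assert np.allclose(recombined, fps.mean(axis=0))


class TestSarCorrelations:
    def desc_matrix(self, hba):
        d = np.zeros((len(hba), 6))
        d[:, 4] = hba
        d[:, 1] = np.linspace(100, 400, len(hba))  # MolWt varies
        return d

    def test_exact_linear_relation(self):
        hba = np.array([1.0, 2, 3, 4, 5])
        res = sar_correlations(self.desc_matrix(hba), 2 * hba + 1)
        assert res["per_descriptor"]["NumHAcceptors"]["r"] == pytest.approx(1.0)

    def test_constant_descriptor_flagged_not_nan(self):
        hba = np.array([2.0, 2, 2, 2])
        res = sar_correlations(self.desc_matrix(hba), np.array([5.0, 6, 7, 8]))
        entry = res["per_descriptor"]["NumHAcceptors"]
        assert entry["undefined"] and entry["r"] is None

    def test_five_point_brute_force_oracle(self):
        hba = np.array([1.0, 3, 2, 5, 4])
        y = np.array([5.5, 6.1, 5.9, 7.3, 6.6])
        res = sar_correlations(self.desc_matrix(hba), y)
        x, yy = hba - hba.mean(), y - y.mean()
        expected = (x * yy).sum() / np.sqrt((x**2).sum() * (yy**2).sum())
        assert res["per_descriptor"]["NumHAcceptors"]["r"] == pytest.approx(expected, abs=1e-12)

    def test_small_cluster_flagged(self):
        res = sar_correlations(self.desc_matrix(np.array([1.0, 2])), np.array([5.0, 6]))
        assert res["small_sample"]
        assert res["per_descriptor"]["NumHAcceptors"]["r"] is None


class TestMCS:
    def test_phenol_aniline_share_benzene(self):
        res = mcs_for_cluster(["c1ccccc1O", "c1ccccc1N"])
        assert res["atom_count"] == 6
        assert res["bond_count"] == 6
        assert not res["timed_out"]

    def test_identical_molecules_full_match(self):
        res = mcs_for_cluster(["CCO", "CCO"])
        assert res["atom_count"] == 3
        assert res["bond_count"] == 2

    @staticmethod
    def boost_cluster(truth, n=10):
        """Boost-bearing members sharing scaffold and boost attachment point:
        the structurally coherent group fingerprint clustering produces."""
        groups: dict[tuple, list[str]] = {}
        for recipe, (_, row) in zip(truth.recipes, truth.table.iterrows()):
            if row.boost:
                slot = "sub_a" if recipe["sub_a"].endswith("CO") else "sub_b"
                groups.setdefault((recipe["scaffold"], slot, recipe[slot]), []).append(row.smiles)
        return max(groups.values(), key=len)[:n]

    def test_pattern_matches_every_member(self, small_truth):
        from rdkit import Chem

        members = self.boost_cluster(small_truth, 8)
        res = mcs_for_cluster(members, timeout=10)
        q = Chem.MolFromSmarts(res["smarts"])
        for s in members:
            assert Chem.MolFromSmiles(s).HasSubstructMatch(q)

    def test_planted_high_activity_motif_contains_hydroxyl(self, small_truth):
        members = self.boost_cluster(small_truth, 10)
        res = mcs_for_cluster(members, timeout=10)
        assert not res["empty"]
        assert mcs_contains_hydroxyl(res["smarts"], members)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            mcs_for_cluster(["CCO"])
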