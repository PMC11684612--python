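import numpy as np
import pytest

from micropick import (DistanceMatrix, FeatureTable, class_centroid,
                       dissimilarity_matrix, pca_scores, select,
                       select_discriminant, select_distinct, select_diverse,
                       select_extreme, select_pca, select_representative,
                       to_relative_frequency)
from micropick.selection import extreme_merge_order, pam, pam_exhaustive
from .conftest import random_relative_table


def naive_merge_order(d, linkage="average"):
    """Independent agglomerative-clustering oracle: repeatedly merge the
    two closest clusters and record each leaf at its first merge."""
    clusters = [[i] for i in range(d.shape[0])]
    order, seen = [], set()
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pair_d = [d[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    val = float(np.mean(pair_d))
                elif linkage == "complete":
                    val = float(np.max(pair_d))
                else:
                    val = float(np.min(pair_d))
                if val < best - 1e-15:
                    best, pair = val, (a, b)
        a, b = pair
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        for leaf in sorted(set(merged) - seen):
            order.append(leaf)
            seen.add(leaf)
    return order


class TestRepresentative:
    def test_single_medoid_hand_example(self):
        # total distances: s1 -> 1.0, s2 -> 0.9, s3 -> 1.7
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        medoids, obj = pam(d, 1)
        assert medoids == [1]
        assert obj == pytest.approx(0.9)

    def test_k_equals_n_selects_all(self):
        rng = np.random.default_rng(0)
        t = random_relative_table(rng, 6, 5)
        r = select_representative(t, 6)
        assert set(r.selected) == set(t.sample_ids)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pam_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            t = random_relative_table(rng, n, 10)
            d = dissimilarity_matrix(t).d
            _, obj = pam(d, k)
            _, opt = pam_exhaustive(d, k)
            assert obj == pytest.approx(opt, abs=1e-9)

    def test_local_optimality_no_improving_swap(self):
        rng = np.random.default_rng(3)
        t = random_relative_table(rng, 12, 8)
        d = dissimilarity_matrix(t).d
        medoids, obj = pam(d, 4)
        for mi in range(4):
            for h in range(12):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                assert d[trial].min(axis=0).sum() >= obj - 1e-12

    def test_requires_relative_mode(self, counts_table):
        with pytest.raises(ValueError, match="relative"):
            select_representative(counts_table, 2)

    def test_k_out_of_range(self):
        rng = np.random.default_rng(0)
        t = random_relative_table(rng, 4, 5)
        with pytest.raises(ValueError, match="out of range"):
            select_representative(t, 5)


class TestDiverse:
    @pytest.fixture
    def lambda_table(self):
        # lambda = 0.9, 0.5, 1/3 -> inverse Simpson ranks s3 > s2 > s1
        a = (2 + np.sqrt(3.2)) / 4  # solves a^2 + (1-a)^2 = 0.9
        return FeatureTable(
            ("s1", "s2", "s3"), ("f1", "f2", "f3"),
            np.array([[a, 1 - a, 0.0], [0.5, 0.5, 0.0], [1 / 3, 1 / 3, 1 / 3]]),
            mode="relative",
        )

    def test_top_one_is_most_even(self, lambda_table):
        r = select_diverse(lambda_table, 1)
        assert r.selected == ("s3",)
        assert r.scores["s3"] == pytest.approx(3.0)

    def test_saturation_returns_full_ranking(self, lambda_table):
        r = select_diverse(lambda_table, 3)
        assert r.selected == ("s3", "s2", "s1")

    def test_nested_across_k(self):
        rng = np.random.default_rng(11)
        t = random_relative_table(rng, 15, 10)
        small = set(select_diverse(t, 5).selected)
        large = set(select_diverse(t, 10).selected)
        assert small < large


class TestExtreme:
    def test_most_dissimilar_pair_first(self):
        # pair (A, B) has BC = 0.95; every other pair <= 0.3
        ids = ("A", "B", "C", "D")
        d = np.array([
            [0.0, 0.95, 0.25, 0.30],
            [0.95, 0.0, 0.28, 0.22],
            [0.25, 0.28, 0.0, 0.12],
            [0.30, 0.22, 0.12, 0.0],
        ])
        dm = DistanceMatrix(ids, d)
        rng = np.random.default_rng(0)
        t = random_relative_table(rng, 4, 6)
        t = FeatureTable(ids, t.feature_ids, t.values, mode="relative")
        r = select_extreme(t, 2, distances=dm)
        assert set(r.selected) == {"A", "B"}

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_merge_order_matches_naive_oracle(self, linkage):
        rng = np.random.default_rng(21)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            t = random_relative_table(rng, n, 8)
            dm = dissimilarity_matrix(t)
            got = extreme_merge_order(dm, linkage_method=linkage)
            # oracle works on the inverted metric with zero diagonal
            inv = 1.0 - dm.d
            np.fill_diagonal(inv, 0.0)
            assert got == naive_merge_order(inv, linkage)

    def test_k_equals_n(self):
        rng = np.random.default_rng(2)
        t = random_relative_table(rng, 5, 6)
        assert set(select_extreme(t, 5).selected) == set(t.sample_ids)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        t = random_relative_table(rng, 6, 7)
        r = select_extreme(t, 3)
        perm = [4, 2, 0, 5, 1, 3]
        tp = t.select_samples([t.sample_ids[i] for i in perm])
        rp = select_extreme(tp, 3)
        assert set(rp.selected) == set(r.selected)

    def test_k_below_two_rejected(self):
        rng = np.random.default_rng(0)
        t = random_relative_table(rng, 4, 5)
        with pytest.raises(ValueError):
            select_extreme(t, 1)


class TestDiscriminantDistinct:
    def test_centroid_of_two_members(self):
        t = FeatureTable(("x", "y"), ("f1", "f2"),
                         np.array([[0.2, 0.8], [0.6, 0.4]]), mode="relative")
        np.testing.assert_allclose(class_centroid(t, ["x", "y"]), [0.4, 0.6])
        np.testing.assert_allclose(class_centroid(t, ["x"]), [0.2, 0.8])
        assert class_centroid(t, ["x", "y"]).sum() == pytest.approx(1.0)

    def test_empty_members_rejected(self, two_class_table):
        t, _ = two_class_table
        with pytest.raises(ValueError):
            class_centroid(t, [])

    def test_hand_computed_discriminant_order(self, two_class_table):
        # distances to opposite centroid: A=0.55, B=0.35, C=0.60, D=0.30
        t, ph = two_class_table
        r = select_discriminant(t, ph, 4)
        assert r.selected == ("D", "B", "A", "C")
        assert r.scores["A"] == pytest.approx(0.55)
        assert r.scores["D"] == pytest.approx(0.30)

    def test_distinct_is_reverse_order(self, two_class_table):
        t, ph = two_class_table
        assert select_distinct(t, ph, 4).selected == ("C", "A", "B", "D")

    def test_top_one_disagreement(self, two_class_table):
        t, ph = two_class_table
        assert select_discriminant(t, ph, 1).selected != select_distinct(t, ph, 1).selected

    def test_saturation_same_set(self, two_class_table):
        t, ph = two_class_table
        assert set(select_discriminant(t, ph, 4).selected) == \
            set(select_distinct(t, ph, 4).selected)

    def test_zero_distance_sample_first(self):
        # sample "mid" sits exactly at the control centroid
        t = FeatureTable(
            ("mid", "c1", "c2", "far"), ("f1", "f2"),
            np.array([[0.5, 0.5], [0.4, 0.6], [0.6, 0.4], [0.95, 0.05]]),
            mode="relative")
        from micropick import PhenotypeMetadata
        ph = PhenotypeMetadata(labels={"mid": "case", "far": "case",
                                       "c1": "control", "c2": "control"})
        r = select_discriminant(t, ph, 1)
        assert r.selected == ("mid",)
        assert r.scores["mid"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_class_rejected(self, two_class_table):
        t, _ = two_class_table
        from micropick import PhenotypeMetadata
        ph = PhenotypeMetadata(labels={s: "case" for s in t.sample_ids})
        with pytest.raises(ValueError, match="control"):
            select_discriminant(t, ph, 2)

    def test_nested_across_k(self, two_class_table):
        t, ph = two_class_table
        assert set(select_discriminant(t, ph, 2).selected) < \
            set(select_discriminant(t, ph, 3).selected)


class TestPca:
    @pytest.fixture
    def rank_one_table(self):
        """Variance concentrated in one feature; other features constant."""
        n = 10
        base = np.full((n, 4), 0.2)
        base[:, 0] = np.linspace(0.05, 0.75, n)
        vals = base / base.sum(axis=1, keepdims=True)
        return FeatureTable(tuple(f"s{i:02d}" for i in range(n)),
                            ("dom", "b", "c", "d"), vals, mode="relative")

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        t = random_relative_table(rng, 5, 4)
        m = pca_scores(t, 2)
        xc = t.values - t.values.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        oracle = xc @ vt[:2].T
        np.testing.assert_allclose(np.abs(m.scores), np.abs(oracle), atol=1e-10)

    def test_rank_one_pc1_is_dominant_feature(self, rank_one_table):
        m = pca_scores(rank_one_table, 2)
        assert abs(m.loadings[0, 0]) > 0.7
        assert m.explained_variance_fraction[0] > 0.99

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(14)
        t = random_relative_table(rng, 12, 8)
        m = pca_scores(t, 4)
        evf = m.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1 + 1e-9

    def test_sparse_full_keep_matches_dense(self):
        rng = np.random.default_rng(4)
        t = random_relative_table(rng, 12, 8)
        dense = pca_scores(t, 3)
        sparse = pca_scores(t, 3, sparse=True, keep_count=8)
        np.testing.assert_allclose(sparse.scores, dense.scores, atol=1e-8)

    def test_sparse_respects_keep_count(self):
        rng = np.random.default_rng(6)
        t = random_relative_table(rng, 15, 10)
        m = pca_scores(t, 2, sparse=True, keep_count=3)
        assert (np.abs(m.loadings) > 1e-12).sum(axis=0).max() <= 3

    def test_degenerate_table_rejected(self):
        t = FeatureTable(("s1", "s2"), ("a", "b"),
                         np.array([[0.5, 0.5], [0.5, 0.5]]), mode="relative")
        with pytest.raises(ValueError, match="variance"):
            pca_scores(t, 1)

    def test_allocation_k6(self, rank_one_table):
        r = select_pca(rank_one_table, 6)
        alloc = r.params["allocation"]
        assert alloc == {"pc1_per_extreme": 2, "pc2_per_extreme": 1, "remainder": 0}
        # PC1 extremes are the extremes of the dominant feature
        dom = rank_one_table.values[:, 0]
        expected = {rank_one_table.sample_ids[i]
                    for i in list(np.argsort(dom)[:2]) + list(np.argsort(dom)[-2:])}
        assert expected <= set(r.selected)

    def test_k_equals_n(self, rank_one_table):
        r = select_pca(rank_one_table, 10)
        assert set(r.selected) == set(rank_one_table.sample_ids)

    def test_no_duplicate_selection(self):
        rng = np.random.default_rng(19)
        for k in range(1, 13):
            t = random_relative_table(rng, 12, 6)
            r = select_pca(t, k)
            assert len(set(r.selected)) == k

    def test_spca_variant_runs(self, rank_one_table):
        r = select_pca(rank_one_table, 4, sparse=True, keep_count=2)
        assert r.method == "spca"
        assert len(r.selected) == 4


class TestDispatchAndDeterminism:
    def test_unknown_method(self):
        rng = np.random.default_rng(0)
        t = random_relative_table(rng, 5, 4)
        with pytest.raises(ValueError, match="unknown method"):
            select("bogus", t, 2)

    def test_all_methods_deterministic(self, two_class_table):
        rng = np.random.default_rng(23)
        t = random_relative_table(rng, 14, 9)
        _, _ = two_class_table
        from micropick import PhenotypeMetadata
        labels = {s: ("case" if i % 3 == 0 else "control")
                  for i, s in enumerate(t.sample_ids)}
        ph = PhenotypeMetadata(labels=labels)
        for method in ("representative", "diverse", "extreme", "discriminant",
                       "distinct", "pca", "spca"):
            r1 = select(method, t, 5, phenotype=ph)
            r2 = select(method, t, 5, phenotype=ph)
            assert r1.selected == r2.selected
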