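import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spatialfuse as sf


def pair_counting_ari_oracle(a, b):
    """O(n^2) reference: count agreeing/disagreeing sample pairs directly."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and not sb
            n01 += (not sa) and sb
    total = n * (n - 1) / 2
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0 if index == max_index else 0.0
    return (index - expected) / (max_index - expected)


label_lists = st.integers(2, 50).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
    )
)


class TestContingency:
    def test_direct_count(self):
        t = sf.contingency([0, 0, 1], [1, 1, 0])
        np.testing.assert_array_equal(t.counts, [[0, 2], [1, 0]])
        assert t.n == 3
        np.testing.assert_array_equal(t.row_sums, [2, 1])
        np.testing.assert_array_equal(t.col_sums, [1, 2])

    def test_identical_labelings_diagonal(self):
        t = sf.contingency([0, 1, 2, 1], [0, 1, 2, 1])
        assert np.all(t.counts == np.diag(np.diag(t.counts)))

    def test_matches_per_sample_tally(self, rng):
        a = rng.integers(0, 4, 60)
        b = rng.integers(0, 3, 60)
        t = sf.contingency(a, b)
        ua, ub = np.unique(a), np.unique(b)
        for i, va in enumerate(ua):
            for j, vb in enumerate(ub):
                assert t.counts[i, j] == int(np.sum((a == va) & (b == vb)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sf.contingency([0, 1], [0, 1, 2])


class TestAdjustedRandIndex:
    def test_identical_partitions_give_one(self, rng):
        lab = rng.integers(0, 5, 40)
        assert sf.adjusted_rand_index(lab, lab) == 1.0

    def test_hand_evaluated_case(self):
        # sum C(n_ij,2)=0; sum C(a_i,2)=sum C(b_j,2)=2; C(4,2)=6
        # ARI = (0 - 4/6) / (2 - 4/6) = -0.5
        assert sf.adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 50))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            assert sf.adjusted_rand_index(a, b) == pytest.approx(
                pair_counting_ari_oracle(a, b), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(20):
            a = rng.integers(0, 5, 30)
            b = rng.integers(0, 4, 30)
            assert sf.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    @given(label_lists)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetry_and_relabeling_invariance(self, ab):
        a, b = ab
        ari = sf.adjusted_rand_index(a, b)
        assert ari == pytest.approx(sf.adjusted_rand_index(b, a), abs=1e-12)
        remap = [x + 17 for x in a]  # renaming labels changes nothing
        assert ari == pytest.approx(sf.adjusted_rand_index(remap, b), abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            sf.adjusted_rand_index([0], [0])


class TestClusterEmbeddings:
    def test_separated_blobs_recovered(self, rng):
        Z = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
        truth = np.repeat([0, 1], 30)
        labels = sf.cluster_embeddings(Z, k=2, seed=0)
        assert sf.adjusted_rand_index(labels, truth) == 1.0

    def test_k_one_all_zero(self, rng):
        assert np.all(sf.cluster_embeddings(rng.normal(size=(10, 3)), k=1) == 0)

    def test_seeded_determinism(self, rng):
        Z = rng.normal(size=(50, 4))
        l1 = sf.cluster_embeddings(Z, k=3, seed=5)
        l2 = sf.cluster_embeddings(Z, k=3, seed=5)
        np.testing.assert_array_equal(l1, l2)

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sf.cluster_embeddings(rng.normal(size=(3, 2)), k=5)

    @pytest.mark.parametrize("method", ["gmm", "gmm_full", "kmeans"])
    def test_methods_fill_k_clusters(self, rng, method):
        Z = np.vstack([rng.normal(c * 8, 0.3, (20, 2)) for c in range(3)])
        labels = sf.cluster_embeddings(Z, k=3, seed=0, method=method)
        assert set(labels) == {0, 1, 2}


class TestRankGenes:
    def test_perfectly_separating_gene_is_top(self, rng):
        n = 100
        labels = np.repeat(["A", "B"], 50)
        X = rng.uniform(0.5, 1.5, (n, 20))
        X[labels == "A", 7] = 10.0
        X[labels == "B", 7] = 0.0
        table = sf.rank_genes(X, labels, [f"g{i}" for i in range(20)])
        top_a = table.table[table.table.cluster == "A"].iloc[0]
        assert top_a.gene == "g7"
        assert top_a.is_deg

    def test_null_calibration_under_permutation(self, rng):
        # permuted labels: on average <= 5% of null genes flagged per cluster
        rates = []
        for rep in range(20):
            X = rng.normal(5.0, 1.0, (200, 50)) ** 2
            labels = rng.permutation(np.repeat([0, 1, 2, 3], 50))
            table = sf.rank_genes(X, labels, alpha=0.05, lfc_min=0.0)
            rates.append(np.mean(list(table.deg_counts.values())) / 50)
        assert np.mean(rates) <= 0.05

    def test_counts_consistent_with_table(self, small_benchmark):
        _, dataset, _, truth = small_benchmark
        ds = sf.SpatialCellDataset(
            expression=dataset.expression.copy(),
            gene_names=list(dataset.gene_names),
            cell_ids=list(dataset.cell_ids),
            coords=dataset.coords.copy(),
        )
        sf.preprocess_dataset(ds)
        table = sf.rank_genes(ds.layers["norm"], truth.domain_labels, ds.gene_names)
        for c, count in table.deg_counts.items():
            sub = table.table[table.table.cluster == c]
            assert count == int(sub.is_deg.sum())
        assert np.all(table.table.padj >= table.table.pval - 1e-15)

    def test_tiny_cluster_skipped_with_warning(self, rng):
        X = rng.normal(size=(41, 5)) ** 2
        labels = np.array([0] * 20 + [1] * 20 + [2])
        with pytest.warns(UserWarning, match="skipped"):
            table = sf.rank_genes(X, labels)
        assert 2 not in table.deg_counts

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            sf.rank_genes(rng.normal(size=(10, 3)) ** 2, np.zeros(10))


class TestCompareRawEnhanced:
    def test_identical_inputs(self):
        res = sf.compare_raw_enhanced(np.arange(10.0), np.arange(10.0))
        assert res == {"t": 0.0, "p": 1.0, "direction": "none"}

    def test_exact_shift_reports_tiny_p(self):
        raw = np.arange(10.0)
        res = sf.compare_raw_enhanced(raw, raw + 1.0)
        assert res["direction"] == "up"
        assert 0 < res["p"] < 1e-6
        assert res["t"] == np.inf

    def test_closed_form_oracle(self, rng):
        raw = rng.normal(size=(25,))
        enh = raw + rng.normal(0.3, 1.0, size=(25,))
        res = sf.compare_raw_enhanced(raw, enh)
        diff = enh - raw
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert res["t"] == pytest.approx(t, abs=1e-9)
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df=len(diff) - 1)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_region_mask_applied(self, rng):
        raw = np.zeros(20)
        enh = np.zeros(20)
        enh[:10] = 1.0
        res = sf.compare_raw_enhanced(raw, enh, region_mask=np.arange(20) < 10)
        assert res["direction"] == "up"

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            sf.compare_raw_enhanced(np.ones(2), np.ones(2))


class TestProject2D:
    def test_shape_determinism_and_separability(self, rng):
        Z = np.vstack([rng.normal(0, 0.2, (40, 6)), rng.normal(5, 0.2, (40, 6))])
        truth = np.repeat([0, 1], 40)
        P1 = sf.project_2d(Z, seed=1)
        P2 = sf.project_2d(Z, seed=1)
        assert P1.shape == (80, 2)
        np.testing.assert_allclose(P1, P2)
        from sklearn.linear_model import LogisticRegression

        acc = LogisticRegression().fit(P1, truth).score(P1, truth)
        assert acc > 0.95

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            sf.project_2d(rng.normal(size=(5, 3)))
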