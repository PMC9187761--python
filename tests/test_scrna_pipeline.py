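import numpy as np
import pytest

from lshgan import (ExpressionMatrix, cluster_and_score, cv2_index, fano_factor,
                    hvg_dispersion, log_normalize, qc_filter)
from lshgan.scrna_pipeline import EmptyAfterFilterError


def counts_matrix(values, **kw):
    return ExpressionMatrix(values=np.asarray(values, dtype=float),
                            layer="counts", **kw)


@pytest.fixture()
def toy_counts():
    # 3 cells x 1100 genes: cell 0 expresses 1001 genes, cells 1-2 express 10
    vals = np.zeros((3, 1100))
    vals[0, :1001] = 10.0
    vals[1, :10] = 10.0
    vals[2, 5:15] = 10.0
    return counts_matrix(vals)


class TestQcFilter:
    def test_cell_threshold(self, toy_counts):
        kept = qc_filter(toy_counts)
        assert kept.cell_ids == ["cell0"]

    def test_gene_boundary_exactly_ten_percent(self):
        # 10 cells all pass the (relaxed) cell filter; gene 0 has count 6 in
        # exactly 1 of 10 cells -> kept (>5 in >=10%); gene 1 has count 5 -> dropped
        vals = np.ones((10, 30)) * 10
        vals[:, 0] = 0.0
        vals[0, 0] = 6.0
        vals[:, 1] = 0.0
        vals[0, 1] = 5.0
        m = counts_matrix(vals)
        kept = qc_filter(m, min_genes_per_cell=5)
        assert "gene0" in kept.gene_names
        assert "gene1" not in kept.gene_names

    def test_all_zero_matrix_errors(self):
        with pytest.raises(EmptyAfterFilterError, match="cell"):
            qc_filter(counts_matrix(np.zeros((4, 10))))

    def test_idempotent(self, small_mixture):
        rng = np.random.default_rng(0)
        vals = rng.poisson(8, size=(20, 1200)).astype(float)
        m = counts_matrix(vals)
        once = qc_filter(m)
        twice = qc_filter(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.gene_names == twice.gene_names
        assert once.cell_ids == twice.cell_ids


class TestLogNormalize:
    def test_log2_pseudocount_values(self):
        m = counts_matrix([[0.0, 1.0, 3.0]])
        out = log_normalize(m)
        np.testing.assert_allclose(out.values, [[0.0, 1.0, 2.0]])
        assert out.layer == "lognorm"

    def test_monotone(self):
        m = counts_matrix([[1.0, 2.0, 50.0]])
        out = log_normalize(m).values.ravel()
        assert np.all(np.diff(out) > 0)

    def test_double_application_rejected(self):
        m = log_normalize(counts_matrix([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="lognorm"):
            log_normalize(m)

    def test_library_size_scaling_equalises_totals(self):
        m = counts_matrix([[10.0, 10.0], [40.0, 40.0], [20.0, 20.0]])
        out = log_normalize(m, library_size=True)
        totals = (2 ** out.values - 1).sum(axis=1)
        np.testing.assert_allclose(totals, totals[0])


class TestVariabilityScores:
    def test_fano_hand_computed(self):
        m = counts_matrix([[0.0, 5.0, 0.0], [2.0, 5.0, 0.0]])
        t = fano_factor(m)
        # gene0: var 2 (ddof 1) / mean 1 = 2; constant gene 0; all-zero gene 0
        np.testing.assert_allclose(t.scores, [2.0, 0.0, 0.0])

    def test_cv2_hand_computed_and_scale_invariance(self):
        m = counts_matrix([[0.0, 0.0], [2.0, 20.0]])
        t = cv2_index(m)
        np.testing.assert_allclose(t.scores, [2.0, 2.0])  # x10 leaves CV^2 alone

    def test_agree_with_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 3.0, size=(10, 20))
        m = counts_matrix(vals)
        mean = vals.mean(axis=0)
        var = np.array([np.sum((vals[:, j] - mean[j]) ** 2) / 9 for j in range(20)])
        np.testing.assert_allclose(fano_factor(m).scores, var / mean, atol=1e-10)
        np.testing.assert_allclose(cv2_index(m).scores, var / mean**2, atol=1e-10)

    def test_ranking_descending_with_index_ties(self):
        m = counts_matrix([[0.0, 0.0, 0.0], [4.0, 2.0, 4.0]])
        t = fano_factor(m)
        assert t.order.tolist() == [0, 2, 1]


class TestHvgDispersion:
    def test_flat_matrix_all_zero_scores(self):
        m = ExpressionMatrix(values=np.ones((5, 40)), layer="lognorm")
        t = hvg_dispersion(m, n_bins=4, n_top=10)
        np.testing.assert_array_equal(t.scores, 0.0)
        assert t.top(10) == [f"gene{j}" for j in range(10)]

    def test_spiked_gene_ranks_first(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5.0, 1.0, size=(50, 60))
        vals[:, 17] = 5.0 + rng.normal(0.0, 6.0, size=50)  # inflated variance
        m = ExpressionMatrix(values=np.abs(vals), layer="lognorm")
        t = hvg_dispersion(m, n_bins=5, n_top=10)
        assert t.order[0] == 17

    def test_top_size_clipped_to_gene_count(self):
        m = ExpressionMatrix(values=np.random.default_rng(7).random((5, 30)),
                             layer="lognorm")
        assert len(hvg_dispersion(m, n_bins=3, n_top=500).top(500)) == 30

    def test_counts_layer_rejected(self):
        with pytest.raises(ValueError):
            hvg_dispersion(counts_matrix(np.ones((5, 30))))


class TestClusterAndScore:
    def test_perfect_and_chance_levels(self, small_mixture):
        m = ExpressionMatrix(values=small_mixture.values, layer="lognorm")
        truth = small_mixture.labels
        ari, nmi = cluster_and_score(m, m.gene_names, 2, truth, seed=0)
        assert ari == pytest.approx(1.0)
        assert nmi == pytest.approx(1.0)

    def test_random_truth_scores_near_zero(self):
        rng = np.random.default_rng(8)
        m = ExpressionMatrix(values=rng.normal(size=(500, 10)), layer="lognorm")
        for seed in range(5):
            truth = np.random.default_rng(100 + seed).integers(0, 2, 500)
            ari, _ = cluster_and_score(m, m.gene_names, 2, truth, seed=seed)
            assert abs(ari) < 0.1

    def test_top_fano_genes_separate_mixture(self, small_mixture):
        m = ExpressionMatrix(values=small_mixture.values, layer="lognorm")
        genes = fano_factor(m).top(25)
        ari, nmi = cluster_and_score(m, genes, 2, small_mixture.labels, seed=1)
        assert ari >= 0.95 and nmi >= 0.9

    def test_unknown_gene_rejected(self, small_mixture):
        m = ExpressionMatrix(values=small_mixture.values, layer="lognorm")
        with pytest.raises(ValueError, match="unknown gene"):
            cluster_and_score(m, ["nope"], 2, small_mixture.labels)

    def test_scores_invariant_under_label_permutation(self, small_mixture):
        from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
        truth = small_mixture.labels
        pred = (truth == 1).astype(int)
        flipped = 1 - pred
        assert adjusted_rand_score(truth, pred) == adjusted_rand_score(truth, flipped)
        assert normalized_mutual_info_score(truth, pred) == pytest.approx(
            normalized_mutual_info_score(truth, flipped))
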