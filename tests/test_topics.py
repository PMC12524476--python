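import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycledecon import GeneSet, TimeCourseMatrix, TopicModel, geneset_simplex, match_topics
from cycledecon.topics import TopicModelError


def well_separated_data(n_samples=12, genes_per_topic=30, k=3, total=1e6, seed=3):
    """Mixture data satisfying separability on both axes: anchor genes per
    topic and near-pure samples per topic, so the factorization is unique."""
    rng = np.random.default_rng(seed)
    L = np.full((n_samples, k), 0.02 / (k - 1))
    for i in range(n_samples):
        L[i, i % k] = 0.98
    F = np.zeros((genes_per_topic * k, k))
    for c in range(k):
        block = slice(c * genes_per_topic, (c + 1) * genes_per_topic)
        F[block, c] = rng.dirichlet(np.ones(genes_per_topic))
    x = total * (L @ F.T)                    # samples x genes, exact expectations
    genes = [f"g{i}" for i in range(F.shape[0])]
    cols = [f"D{i + 1}" for i in range(n_samples)]
    mat = TimeCourseMatrix(pd.DataFrame(x.T, index=genes, columns=cols), layer="normalized")
    return mat, L, F


class TestFit:
    def test_k1_closed_form(self, tiny_matrix):
        res = TopicModel(tiny_matrix.with_layer("normalized"), k=1).fit()
        totals = tiny_matrix.values.sum(axis=1)
        np.testing.assert_allclose(res.F.to_numpy()[:, 0], totals / totals.sum(), atol=1e-12)
        np.testing.assert_allclose(res.L.to_numpy()[:, 0], 1.0)

    def test_loglik_trace_never_decreases(self, tiny_matrix):
        res = TopicModel(tiny_matrix.with_layer("normalized"), k=2).fit(seed=1, n_restarts=2)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-7).all()

    def test_simplex_constraints_on_fit(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=2, max_iter=200)
        np.testing.assert_allclose(res.L.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.F.sum(axis=0), 1.0, atol=1e-9)
        assert (res.L.to_numpy() >= 0).all() and (res.F.to_numpy() >= 0).all()

    def test_recovery_on_well_separated_mixture(self):
        mat, L_true, _ = well_separated_data()
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=5)
        perm = match_topics(res, L_true)
        Lm = res.L.to_numpy()[:, perm]
        assert np.abs(Lm - L_true).max() < 0.05
        for j in range(3):
            assert np.corrcoef(Lm[:, j], L_true[:, j])[0, 1] > 0.9

    def test_restarts_agree_when_identifiable(self):
        mat, L_true, _ = well_separated_data()
        fits = [TopicModel(mat, k=3).fit(seed=s, n_restarts=1) for s in range(3)]
        aligned = [f.L.to_numpy()[:, match_topics(f, L_true)] for f in fits]
        for i in range(len(aligned)):
            for j in range(i + 1, len(aligned)):
                assert np.abs(aligned[i] - aligned[j]).max() < 0.02

    def test_best_restart_has_highest_loglik(self):
        mat, _, _ = well_separated_data(seed=8)
        model = TopicModel(mat, k=3)
        best = model.fit(seed=4, n_restarts=4)
        singles = [model.fit(seed=4, n_restarts=1)]
        assert best.loglik >= max(s.loglik for s in singles) - 1e-6

    def test_topic_order_is_by_peak_time(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=2, max_iter=300)
        peaks = [int(np.argmax(res.L[c].to_numpy())) for c in res.L.columns]
        assert peaks == sorted(peaks)

    def test_invalid_inputs(self, tiny_matrix):
        with pytest.raises(TopicModelError):
            TopicModel(tiny_matrix.with_layer("normalized"), k=9)  # > n_samples
        zero = TimeCourseMatrix(
            pd.DataFrame(np.zeros((2, 5)), index=["a", "b"],
                         columns=[f"D{i+1}" for i in range(5)]), layer="normalized")
        with pytest.raises(TopicModelError):
            TopicModel(zero, k=2)

    def test_summary_mentions_dimensions(self, tiny_matrix):
        res = TopicModel(tiny_matrix.with_layer("normalized"), k=2).fit(
            seed=0, n_restarts=1, max_iter=50)
        text = res.summary()
        assert "topics: 2" in text and "log-likelihood" in text


@given(st.integers(0, 10_000))
@settings(max_examples=100)
def test_simplex_conservation_on_random_inputs(seed):
    """L rows, F columns and posterior rows stay on the simplex for
    arbitrary small non-negative matrices."""
    rng = np.random.default_rng(seed)
    n, m, k = rng.integers(3, 6), rng.integers(4, 9), rng.integers(1, 4)
    x = rng.gamma(1.0, 10.0, size=(m, n))
    mat = TimeCourseMatrix(
        pd.DataFrame(x, index=[f"g{i}" for i in range(m)],
                     columns=[f"D{i+1}" for i in range(n)]), layer="normalized")
    res = TopicModel(mat, k=int(min(k, n))).fit(seed=int(seed) % 100, n_restarts=1, max_iter=40)
    np.testing.assert_allclose(res.L.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(res.F.sum(axis=0), 1.0, atol=1e-9)
    post = res.posterior()
    sums = post.probs.sum(axis=1).to_numpy()
    defined = ~np.isnan(sums)
    np.testing.assert_allclose(sums[defined], 1.0, atol=1e-12)


class TestMatchTopics:
    def test_self_match_is_identity(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=100)
        np.testing.assert_array_equal(match_topics(res, res.L), [0, 1, 2])

    def test_column_swap_is_recovered(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=100)
        swapped = res.L.iloc[:, [2, 0, 1]]
        perm = match_topics(res, swapped)
        np.testing.assert_array_equal(perm, [2, 0, 1])

    def test_large_k_refused(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=7).fit(seed=0, n_restarts=1, max_iter=5)
        with pytest.raises(TopicModelError, match="greedy"):
            match_topics(res, res.L)


class TestDiffExpression:
    def test_allocation_conserves_grand_total(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=200)
        diff = res.diff_expression()
        assert diff.table.n_gk.sum() == pytest.approx(diff.grand_total, rel=1e-6)

    def test_single_topic_gene_has_positive_signal(self):
        mat, L_true, _ = well_separated_data()
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=3)
        diff = res.diff_expression()
        perm = match_topics(res, L_true)
        topic0 = res.L.columns[perm[0]]       # fitted topic matching block 0
        row = diff.table[(diff.table.gene_id == "g0") & (diff.table.topic == topic0)].iloc[0]
        assert row.log2fc > 0 and row.z_score > 0

    def test_zero_contrast_gives_zero_z(self):
        # hand-built two-topic fit where one gene is split identically
        mat, _, _ = well_separated_data(n_samples=4, genes_per_topic=3, k=2)
        res = TopicModel(mat, k=2).fit(seed=0, n_restarts=2)
        diff = res.diff_expression()
        tab = diff.table
        near = tab[np.isclose(tab.p_in_topic, tab.p_rest, rtol=1e-12, atol=1e-15)]
        assert np.allclose(near.z_score, 0.0, atol=1e-9)

    def test_matches_direct_two_proportion_oracle(self):
        """Hand example (p=0.75 vs q=0, pooled 0.3, N=(40,60)) gives
        z = 0.75/sqrt(0.21*(1/40+1/60)); and on a fitted model every
        reported z equals a scalar re-evaluation of the pooled
        two-proportion formula from the reported allocation table."""
        z_hand = 0.75 / np.sqrt(0.3 * 0.7 * (1 / 40 + 1 / 60))
        assert z_hand == pytest.approx(8.0178373, rel=1e-6)

        mat, _, _ = well_separated_data(n_samples=6, genes_per_topic=4, k=2, seed=1)
        res = TopicModel(mat, k=2).fit(seed=0, n_restarts=2)
        diff = res.diff_expression()
        totals = {t: diff.table[diff.table.topic == t].n_gk.sum()
                  for t in res.L.columns}
        grand = sum(totals.values())
        for _, row in diff.table.iterrows():
            N_c = totals[row.topic]
            N_rest = grand - N_c
            n_rest = row.p_rest * N_rest
            pbar = (row.n_gk + n_rest) / grand
            var = pbar * (1 - pbar) * (1 / N_c + 1 / N_rest)
            z_direct = (row.p_in_topic - row.p_rest) / np.sqrt(var) if var > 0 else 0.0
            assert row.z_score == pytest.approx(z_direct, rel=1e-9, abs=1e-9)


class TestPosterior:
    def test_flat_gene_row_gives_uniform_posterior(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=50)
        res.F.iloc[0] = [0.001, 0.001, 0.001]
        post = res.posterior()
        np.testing.assert_allclose(post.probs.iloc[0], 1 / 3, atol=1e-12)

    def test_proportional_arithmetic(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=50)
        res.F.iloc[0] = [0.2, 0.1, 0.1]
        post = res.posterior()
        np.testing.assert_allclose(post.probs.iloc[0], [0.5, 0.25, 0.25], atol=1e-12)

    def test_degenerate_prior_concentrates(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=50)
        post = res.posterior(prior=np.array([1.0, 0.0, 0.0]))
        defined = post.probs.dropna()
        np.testing.assert_allclose(defined.to_numpy()[:, 0], 1.0, atol=1e-12)

    def test_all_zero_row_flagged_not_uniform(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=50)
        res.F.iloc[0] = 0.0
        post = res.posterior()
        gene = res.F.index[0]
        assert gene in post.undefined_genes
        assert post.probs.loc[gene].isna().all()

    def test_invalid_prior_rejected(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=1, max_iter=50)
        with pytest.raises(TopicModelError):
            res.posterior(prior=np.array([0.9, 0.9, -0.8]))


class TestGenesetSimplex:
    def _post(self, noisy_filtered):
        mat = noisy_filtered[0]
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=2, max_iter=300)
        return res, res.posterior()

    def test_single_gene_centroid_is_its_posterior(self, noisy_filtered):
        res, post = self._post(noisy_filtered)
        g = str(post.probs.index[0])
        coords, centroid, missing = geneset_simplex(post, GeneSet("one", [g]))
        np.testing.assert_allclose(centroid.to_numpy(), post.probs.loc[g].to_numpy())

    def test_missing_genes_reported(self, noisy_filtered):
        res, post = self._post(noisy_filtered)
        g = str(post.probs.index[0])
        coords, centroid, missing = geneset_simplex(post, GeneSet("s", [g, "NOPE"]))
        assert missing == ["NOPE"]

    def test_empty_intersection_is_error(self, noisy_filtered):
        res, post = self._post(noisy_filtered)
        with pytest.raises(TopicModelError):
            geneset_simplex(post, GeneSet("none", ["NOPE"]))

    def test_oscillatory_set_centroid_points_to_matched_topic(self, noisy_filtered):
        mat, _, _, truth = noisy_filtered
        res = TopicModel(mat, k=3).fit(seed=0, n_restarts=3)
        perm = match_topics(res, truth.component_proportions)
        post = res.posterior()
        coords, centroid, _ = geneset_simplex(post, GeneSet("oscA", truth.genes_of("osc_A")))
        assert centroid.idxmax() == res.L.columns[perm[0]]
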