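import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from exhaustclass import nmf
from exhaustclass.io import ExpressionMatrix, ValidationError


def _em(arr, genes=None, samples=None, unit="log2"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), unit)


def brute_force_cophenetic(C):
    """Independent oracle: naive average-linkage agglomeration + Pearson."""
    D = 1.0 - np.asarray(C, dtype=float)
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    iu = np.triu_indices(n, 1)
    return pearsonr(D[iu], coph[iu])[0]


class TestFactorize:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0.5, 2.0, size=(20, 2))
        H0 = rng.uniform(0.5, 2.0, size=(2, 10))
        em = _em(W0 @ H0)
        model = nmf.factorize(em, 2, seed=1, max_iter=2000, tol=1e-12)
        err = np.abs(model.reconstruct() - W0 @ H0).max() / (W0 @ H0).max()
        assert err < 1e-3

    def test_objective_trace_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        em = _em(rng.uniform(0.1, 5.0, size=(30, 15)))
        model = nmf.factorize(em, 3, seed=2, max_iter=150, tol=0.0)
        tr = model.objective_trace
        assert len(tr) == 150
        assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]) + 1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        em = _em(rng.uniform(0.1, 5.0, size=(20, 10)))
        a = nmf.factorize(em, 3, seed=7)
        b = nmf.factorize(em, 3, seed=7)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(3)
        em = _em(rng.uniform(0.0, 5.0, size=(20, 10)))
        model = nmf.factorize(em, 2, seed=0, max_iter=50)
        assert (model.W >= 0).all() and (model.H >= 0).all()

    def test_negative_input_rejected(self):
        em = _em([[1.0, -0.5], [0.2, 0.3]])
        with pytest.raises(ValidationError, match="non-negative"):
            nmf.factorize(em, 1, seed=0)

    def test_zero_rows_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        arr = rng.uniform(0.1, 5.0, size=(10, 8))
        arr[3] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            model = nmf.factorize(_em(arr), 2, seed=0, max_iter=20)
        assert len(model.gene_ids) == 9 and "G3" not in model.gene_ids

    def test_rank_bound_enforced(self):
        em = _em(np.ones((5, 4)) + np.eye(5)[:, :4])
        with pytest.raises(ValidationError, match="k="):
            nmf.factorize(em, 4, seed=0)

    def test_scale_consistency_of_factorization(self):
        # normalizing W columns to unit L1 with inverse rescale of H keeps WH
        rng = np.random.default_rng(5)
        em = _em(rng.uniform(0.1, 5.0, size=(20, 10)))
        m = nmf.factorize(em, 3, seed=1, max_iter=100)
        norms = m.W.sum(axis=0)
        W2 = m.W / norms
        H2 = m.H * norms[:, None]
        np.testing.assert_allclose(W2 @ H2, m.reconstruct(), rtol=1e-10)


class TestAssignClusters:
    def test_argmax_column(self):
        m = nmf.NMFModel(
            k=4, W=np.ones((2, 4)),
            H=np.array([[0.1], [5.0], [0.0], [0.2]]),
            gene_ids=["G0", "G1"], sample_ids=["S0"],
            objective_trace=np.array([]), seed=0, n_iter=0, converged=True)
        assert nmf.assign_clusters(m).iloc[0] == 2

    def test_tie_breaks_to_lowest_index(self):
        m = nmf.NMFModel(
            k=2, W=np.ones((2, 2)), H=np.array([[1.0], [1.0]]),
            gene_ids=["G0", "G1"], sample_ids=["S0"],
            objective_trace=np.array([]), seed=0, n_iter=0, converged=True)
        assert nmf.assign_clusters(m).iloc[0] == 1


class TestConsensus:
    def test_single_run_entries_binary(self):
        rng = np.random.default_rng(6)
        em = _em(rng.uniform(0.1, 5.0, size=(30, 12)))
        res = nmf.consensus_matrix(em, 2, n_runs=1, seed=0, max_iter=50)
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        em = _em(rng.uniform(0.1, 5.0, size=(30, 12)))
        res = nmf.consensus_matrix(em, 3, n_runs=4, seed=1, max_iter=50)
        C = res.consensus
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert C.min() >= 0.0 and C.max() <= 1.0


class TestCophenetic:
    def test_perfect_two_blocks_is_exactly_one(self):
        C = np.ones((6, 6))
        C[:3, 3:] = 0.0
        C[3:, :3] = 0.0
        assert nmf.cophenetic_coefficient(C) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_fixed_example(self):
        C = np.array([[1, .9, .2, .1], [.9, 1, .3, .2], [.2, .3, 1, .8], [.1, .2, .8, 1]])
        assert nmf.cophenetic_coefficient(C) == pytest.approx(brute_force_cophenetic(C), abs=1e-10)

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, size=(7, 7))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        perm = rng.permutation(7)
        assert nmf.cophenetic_coefficient(C[np.ix_(perm, perm)]) == pytest.approx(
            nmf.cophenetic_coefficient(C), abs=1e-12)

    def test_constant_off_diagonal_rejected(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        with pytest.raises(ValidationError, match="constant"):
            nmf.cophenetic_coefficient(C)


class TestFeatureScores:
    def _model(self, W):
        W = np.asarray(W, dtype=float)
        return nmf.NMFModel(
            k=W.shape[1], W=W, H=np.ones((W.shape[1], 3)),
            gene_ids=[f"G{i}" for i in range(W.shape[0])], sample_ids=["a", "b", "c"],
            objective_trace=np.array([]), seed=0, n_iter=0, converged=True)

    def test_point_mass_scores_one(self):
        fs = nmf.metagene_feature_scores(self._model([[1, 0, 0, 0], [1, 1, 1, 1]]))
        assert fs.loc["G0", "score"] == pytest.approx(1.0)

    def test_uniform_scores_zero(self):
        fs = nmf.metagene_feature_scores(self._model([[1, 1, 1, 1], [2, 0, 0, 0]]))
        assert fs.loc["G0", "score"] == pytest.approx(0.0, abs=1e-12)

    def test_half_split_scores_half(self):
        # p = (0.5, 0.5, 0, 0) at k=4: s = 1 - 1/2
        fs = nmf.metagene_feature_scores(self._model([[2, 2, 0, 0], [1, 0, 0, 0]]))
        assert fs.loc["G0", "score"] == pytest.approx(0.5)

    def test_zero_rows_excluded(self):
        fs = nmf.metagene_feature_scores(self._model([[0, 0], [1, 0]]))
        assert list(fs.index) == ["G1"]

    def test_extract_empty_when_scores_equal(self):
        fs = pd.DataFrame({"score": [0.5, 0.5, 0.5], "dominant": [1, 1, 2]},
                          index=["G0", "G1", "G2"])
        assert nmf.extract_metagene_genes(fs, 1) == set()

    def test_extract_empty_for_metagene_without_dominant_genes(self):
        fs = pd.DataFrame({"score": [0.9, 0.05, 0.04, 0.06], "dominant": [1, 1, 1, 1]},
                          index=list("ABCD"))
        assert nmf.extract_metagene_genes(fs, 2) == set()


class TestSelectRank:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(9)
        em = _em(rng.uniform(0.1, 5.0, size=(40, 16)))
        best, diag = nmf.select_rank(em, k_candidates=(4,), n_runs=3, seed=0, max_iter=50)
        assert best == 4 and set(diag) == {4}

    def test_prepare_keeps_most_variable_genes(self):
        rng = np.random.default_rng(10)
        arr = np.round(rng.uniform(0, 50, size=(50, 10)))
        arr[0] = 5.0  # constant row: minimal variance
        em = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"G{i}" for i in range(50)],
                         columns=[f"S{j}" for j in range(10)]), "counts")
        prep = nmf.prepare_nmf_input(em, n_top_genes=20)
        assert prep.unit == "log2"
        assert prep.shape[0] == 20
        assert "G0" not in prep.gene_ids
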