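import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from exhaustclass import scoring
from exhaustclass.io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError


def make_em(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j:03d}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), "log2")


def collection(**sets):
    return GeneSetCollection(
        [GeneSet(name, "", frozenset(members)) for name, members in sets.items()]
    )


def ssgsea_oracle(values, gene_ids, members, alpha):
    """Direct per-position summation, independent of the implementation."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    N = len(values)
    w_total = sum((N - pos) ** alpha for pos, i in enumerate(order) if gene_ids[i] in members)
    n_out = N - sum(1 for g in gene_ids if g in members)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        if gene_ids[i] in members:
            p_in += (N - pos) ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_singleton_top_gene_hand_value(self):
        # N=4, set = {top gene}: ES = 1 + 2/3 + 1/3 + 0 = 2
        em = make_em([[4.0], [3.0], [2.0], [1.0]], genes=list("ABCD"))
        table = scoring.ssgsea_scores(em, collection(top={"A"}), alpha=0.25, normalize=False)
        assert table.scores.iloc[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            arr = rng.normal(size=(50, 8))
            genes = [f"G{i:03d}" for i in range(50)]
            members = set(rng.choice(genes, size=rng.integers(3, 20), replace=False))
            em = make_em(arr, genes=genes)
            table = scoring.ssgsea_scores(em, collection(sig=members), alpha=0.25,
                                          normalize=False)
            for j, s in enumerate(em.sample_ids):
                expected = ssgsea_oracle(arr[:, j], genes, members, 0.25)
                assert table.scores.loc[s, "sig"] == pytest.approx(expected, abs=1e-10)

    def test_identical_samples_identical_scores(self):
        arr = np.tile(np.arange(10, dtype=float)[:, None], (1, 3))
        em = make_em(arr)
        table = scoring.ssgsea_scores(em, collection(s={"G000", "G004"}))
        assert table.scores.nunique().eq(1).all()

    def test_bottom_singleton_minimizes_over_singletons(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.arange(1.0, 9.0))[:, None]
        genes = [f"G{i:03d}" for i in range(8)]
        em = make_em(vals, genes=genes)
        sets = collection(**{f"set_{g}": {g} for g in genes})
        table = scoring.ssgsea_scores(em, sets, normalize=False)
        bottom = genes[int(np.argmin(vals[:, 0]))]
        assert table.scores.iloc[0].idxmin() == f"set_{bottom}"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(20, 4))
        em = make_em(arr)
        members = {f"G{i:03d}" for i in rng.choice(20, size=5, replace=False)}
        base = scoring.ssgsea_scores(em, collection(s=members), normalize=False)
        transformed = make_em(np.exp(arr / 3.0) + 1.0)  # strictly monotone
        other = scoring.ssgsea_scores(transformed, collection(s=members), normalize=False)
        pd.testing.assert_frame_equal(base.scores, other.scores, atol=1e-12)

    def test_range_normalization_preserves_ordering(self):
        rng = np.random.default_rng(2)
        em = make_em(rng.normal(size=(30, 6)))
        members = {f"G{i:03d}" for i in range(4)}
        raw = scoring.ssgsea_scores(em, collection(a=members, b={"G010", "G011"}),
                                    normalize=False)
        norm = scoring.ssgsea_scores(em, collection(a=members, b={"G010", "G011"}),
                                     normalize=True)
        r = raw.scores.to_numpy().ravel()
        n = norm.scores.to_numpy().ravel()
        assert (np.argsort(r) == np.argsort(n)).all()

    def test_no_overlap_dropped_with_warning(self):
        em = make_em(np.arange(8, dtype=float).reshape(4, 2))
        with pytest.warns(UserWarning, match="no overlap"):
            table = scoring.ssgsea_scores(em, collection(absent={"ZZZ"}, ok={"G000"}))
        assert list(table.scores.columns) == ["ok"]

    def test_full_universe_set_rejected(self):
        em = make_em(np.arange(8, dtype=float).reshape(4, 2))
        with pytest.raises(ValidationError, match="universe"):
            scoring.ssgsea_scores(em, collection(all_={"G000", "G001", "G002", "G003"}))


class TestTwoClassGsea:
    def _planted(self, seed=0, n_genes=120, n=40):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(n_genes, n))
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        arr[:20, labels == "A"] += 2.0  # planted up-set in class A
        genes = [f"G{i:03d}" for i in range(n_genes)]
        em = make_em(arr, genes=genes)
        lab = pd.Series(labels, index=em.sample_ids)
        return em, lab, set(genes[:20])

    def test_planted_set_enriched_with_minimal_p(self):
        em, lab, members = self._planted()
        res = scoring.two_class_gsea(em, collection(planted=members), lab,
                                     n_perm=199, seed=1)
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "pval"] <= 1.0 / (199 + 1) + 1e-12

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(15):
            arr = rng.normal(size=(60, 30))
            em = make_em(arr)
            lab = pd.Series(["A"] * 15 + ["B"] * 15, index=em.sample_ids)
            members = {f"G{i:03d}" for i in rng.choice(60, 10, replace=False)}
            res = scoring.two_class_gsea(em, collection(s=members), lab,
                                         n_perm=100, seed=rep)
            pvals.append(res.loc["s", "pval"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_class_rejected(self):
        em = make_em(np.arange(20, dtype=float).reshape(4, 5))
        lab = pd.Series(["A"] * 5, index=em.sample_ids)
        with pytest.raises(ValidationError, match="2 classes"):
            scoring.two_class_gsea(em, collection(s={"G000"}), lab, n_perm=100)


class TestWilcoxon:
    def test_exact_small_sample_enumeration(self):
        # x={1,2}, y={3,4}: 1 of 6 orderings as extreme each tail -> p = 2/6
        u, p = scoring.wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = scoring.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_separation_is_arbitrarily_significant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 1, 100)
        y = rng.normal(0, 1, 100)
        _, p = scoring.wilcoxon_rank_sum(x, y, alternative="greater")
        assert p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            scoring.wilcoxon_rank_sum([], [1.0])


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.arange(10, dtype=float)
        assert scoring.pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert scoring.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            x, y = rng.normal(size=(2, 1000))
            r, _ = scoring.pearson_correlation(x, y)
            hits += abs(r) < 0.1
        assert hits == 20

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            scoring.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
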