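"""Signature enrichment scoring and the elementary two-group statistics.

ssGSEA scores one sample at a time: genes are ranked by expression
(largest value gets rank N, ties broken deterministically by gene id) and
the enrichment score is the sum over the ranked list of the difference
between the rank^alpha-weighted ECDF of set members and the unweighted
ECDF of non-members. Two-class GSEA ranks genes by signal-to-noise between
classes and assesses a weighted Kolmogorov-Smirnov running sum against a
phenotype-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger("exhaustclass")


@dataclass
class ScoreTable:
    scores: pd.DataFrame  # samples x signatures
    alpha: float
    normalized: bool

    def __getitem__(self, signature: str) -> pd.Series:
        return self.scores[signature]


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices of genes from highest to lowest expression; ties by gene id order."""
    # lexsort: last key is primary. Sort ascending by (-value, gene_id).
    order = np.lexsort((gene_ids, -values))
    return order


def _ssgsea_sample(values, gene_ids, member_mask_by_set, alpha):
    """Direct ssGSEA for one sample; vectorized over positions per set."""
    N = len(values)
    order = _rank_order(values, gene_ids)
    # rank value of gene at position i (0-based) is N - i
    ranks = (N - np.arange(N)).astype(float)
    out = []
    for mask in member_mask_by_set:
        in_set = mask[order]
        w = np.where(in_set, ranks ** alpha, 0.0)
        denom_in = w.sum()
        p_in = np.cumsum(w) / denom_in
        n_out = N - in_set.sum()
        p_out = np.cumsum(~in_set) / n_out
        out.append(float(np.sum(p_in - p_out)))
    return out


def ssgsea_scores(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreTable:
    """Per-sample enrichment score for every signature in the collection.

    Signatures with no overlap with the matrix genes are dropped with a
    warning; a signature covering the entire gene universe is an error
    (the non-member ECDF would be undefined). When ``normalize`` is on,
    all scores are divided by the global (max - min) of the table.
    """
    genes = np.asarray(matrix.gene_ids)
    if len(genes) < 2:
        raise ValidationError("ssGSEA requires at least 2 genes")
    gene_set = set(genes)
    masks, kept_names = [], []
    for s in sets:
        overlap = s.members & gene_set
        if not overlap:
            warnings.warn(f"signature {s.name!r} has no overlap with the expression matrix; dropped")
            continue
        if len(overlap) == len(genes):
            raise ValidationError(f"signature {s.name!r} covers the entire gene universe")
        masks.append(np.isin(genes, list(overlap)))
        kept_names.append(s.name)
    if not masks:
        raise ValidationError("no signature overlaps the expression matrix")

    V = matrix.values.to_numpy(dtype=float)
    rows = []
    for j in range(V.shape[1]):
        rows.append(_ssgsea_sample(V[:, j], genes, masks, alpha))
    scores = pd.DataFrame(rows, index=matrix.sample_ids, columns=kept_names)
    if normalize:
        rng_ = scores.to_numpy().max() - scores.to_numpy().min()
        if rng_ > 0:
            scores = scores / rng_
    return ScoreTable(scores=scores, alpha=alpha, normalized=normalize)


def _signal_to_noise(V: np.ndarray, is_pos: np.ndarray) -> np.ndarray:
    a, b = V[:, is_pos], V[:, ~is_pos]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    denom = np.maximum(sa + sb, 1e-8)
    return (ma - mb) / denom


def _gsea_es(metric_order: np.ndarray, in_set_ordered: np.ndarray) -> float:
    """Weighted KS running-sum ES (weight = |ranking metric|) for one ordering."""
    w = np.where(in_set_ordered, np.abs(metric_order), 0.0)
    denom = w.sum()
    if denom <= 0:
        w = in_set_ordered.astype(float)
        denom = w.sum()
    p_hit = np.cumsum(w) / denom
    n_miss = len(in_set_ordered) - in_set_ordered.sum()
    p_miss = np.cumsum(~in_set_ordered) / n_miss
    run = p_hit - p_miss
    return float(run[np.argmax(np.abs(run))])


def two_class_gsea(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class GSEA with a phenotype-permutation null.

    ``labels`` maps samples to exactly two classes; genes are ranked by
    signal-to-noise (first class in sorted label order = positive).
    Returns per-set ES, NES (ES / mean |null ES| of the same sign),
    permutation p and Benjamini-Hochberg FDR.
    """
    labels = labels.loc[list(matrix.sample_ids)]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    is_pos = (labels == classes[0]).to_numpy()
    if is_pos.sum() == 0 or (~is_pos).sum() == 0:
        raise ValidationError("both classes must be non-empty")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")

    genes = np.asarray(matrix.gene_ids)
    gene_universe = set(genes)
    V = matrix.values.to_numpy(dtype=float)
    masks, names = [], []
    for s in sets:
        overlap = s.members & gene_universe
        if not overlap:
            warnings.warn(f"signature {s.name!r} has no overlap; dropped")
            continue
        masks.append(np.isin(genes, list(overlap)))
        names.append(s.name)

    def observed_es(pos_mask):
        metric = _signal_to_noise(V, pos_mask)
        order = np.lexsort((genes, -metric))
        metric_o = metric[order]
        return [_gsea_es(metric_o, m[order]) for m in masks]

    es = np.asarray(observed_es(is_pos))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(masks)))
    for p in range(n_perm):
        null[p] = observed_es(rng.permutation(is_pos))

    pvals, nes = [], []
    for j, e in enumerate(es):
        # two-sided permutation p on |ES|; NES normalized by same-sign null
        exceed = int((np.abs(null[:, j]) >= abs(e)).sum())
        pvals.append((1 + exceed) / (1 + n_perm))
        same_sign = null[:, j] * np.sign(e) > 0 if e != 0 else np.ones(n_perm, bool)
        n_same = int(same_sign.sum())
        mean_null = np.abs(null[same_sign, j]).mean() if n_same else np.nan
        nes.append(e / mean_null if mean_null and np.isfinite(mean_null) else np.nan)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"es": es, "nes": nes, "pval": pvals, "fdr": fdr}, index=names
    )


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple:
    """Rank-sum (Mann-Whitney U) test.

    Exact enumeration when n_x + n_y <= 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple:
    """Product-moment correlation with its t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("Pearson correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
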