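"""Discovery logic for the exhausted immune class (EIC).

The immune-stromal NMF cluster — the cluster maximizing the combined mean
of immune and stromal ssGSEA enrichment — defines the EIC; every other
sample is the rest class. Classifier genes are the metagene-specific genes
that are also differentially expressed between the classes, the EIC score
is the ssGSEA enrichment of the up-regulated classifier genes, and the
score is evaluated by ROC analysis and responder comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError
from .scoring import ScoreTable, ssgsea_scores, wilcoxon_rank_sum

logger = logging.getLogger("exhaustclass")

EIC = "EIC"
REST = "REST"


@dataclass
class ClassLabels:
    """Total EIC/REST partition of the analyzed samples."""

    labels: pd.Series  # sample -> {"EIC", "REST"}
    provenance: str = "discovery"  # or "classifier"

    def __post_init__(self):
        bad = set(self.labels.unique()) - {EIC, REST}
        if bad:
            raise ValidationError(f"labels must be EIC/REST, got {sorted(bad)}")

    @property
    def eic_samples(self) -> list:
        return list(self.labels.index[self.labels == EIC])

    @property
    def rest_samples(self) -> list:
        return list(self.labels.index[self.labels == REST])


@dataclass
class ClassifierGeneSet:
    """Classifier gene set with per-gene direction (up/down in the EIC)."""

    genes: list
    direction: pd.Series  # gene -> {"up", "down"}
    params: dict = field(default_factory=dict)

    @property
    def up_genes(self) -> list:
        return [g for g in self.genes if self.direction[g] == "up"]

    def to_collection(self, name: str = "EIC_classifier") -> GeneSetCollection:
        return GeneSetCollection([GeneSet(name, "exhausted immune classifier genes (up)",
                                          frozenset(self.up_genes))])


def identify_immune_stromal_cluster(
    cluster_labels: pd.Series,
    score_table: ScoreTable,
    immune_signature: str = "immune",
    stromal_signature: str = "stromal",
) -> tuple:
    """Return (cluster index, per-cluster signature means).

    The immune-stromal cluster maximizes the mean of (mean immune score,
    mean stromal score) over its samples. Identical combined means (to
    1e-12) between the top clusters are an error demanding manual review.
    """
    scores = score_table.scores
    for name in (immune_signature, stromal_signature):
        if name not in scores.columns:
            raise ValidationError(f"score table lacks a {name!r} signature")
    scores = scores.loc[list(cluster_labels.index)]
    per_cluster = scores.groupby(cluster_labels)[[immune_signature, stromal_signature]].mean()
    combined = per_cluster.mean(axis=1).sort_values(ascending=False)
    if len(combined) > 1 and abs(combined.iloc[0] - combined.iloc[1]) <= 1e-12:
        raise ValidationError(
            "tie between clusters for immune-stromal identity; manual review required"
        )
    best = int(combined.index[0])
    logger.info("immune-stromal cluster = %d (combined means: %s)",
                best, combined.round(4).to_dict())
    return best, per_cluster


def label_eic(cluster_labels: pd.Series, immune_stromal_cluster: int) -> ClassLabels:
    """EIC = samples of the immune-stromal cluster; everything else is REST."""
    in_cluster = cluster_labels == immune_stromal_cluster
    if not in_cluster.any():
        raise ValidationError(f"cluster {immune_stromal_cluster} is empty")
    labels = pd.Series(np.where(in_cluster, EIC, REST), index=cluster_labels.index,
                       name="class")
    logger.info("label_eic: %d/%d samples labelled EIC (%.1f%%)",
                int(in_cluster.sum()), len(labels), 100 * in_cluster.mean())
    return ClassLabels(labels, provenance="discovery")


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (genes x samples counts)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    finite = np.all(np.isfinite(logc), axis=1)
    if finite.sum() >= 10:
        loggeo = logc[finite].mean(axis=1)
        sf = np.exp(np.median(logc[finite] - loggeo[:, None], axis=0))
    else:
        # too many zeros for the ratio estimator: fall back to total-count scaling
        lib = counts.sum(axis=0).astype(float)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
        logger.info("size factors: fell back to total-count scaling (%d all-positive genes)",
                    int(finite.sum()))
    return sf


def _ranksum_vectorized(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values per row (normal approximation, tie correction)."""
    n1, n2 = A.shape[1], B.shape[1]
    X = np.hstack([A, B])
    ranks = stats.rankdata(X, axis=1)
    R1 = ranks[:, :n1].sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(X.shape[0])
    Xs = np.sort(X, axis=1)
    for i in range(X.shape[0]):
        _, counts = np.unique(Xs[i], return_counts=True)
        tie_term[i] = np.sum(counts ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (np.abs(U1 - mu) - 0.5) / sigma
    z = np.maximum(z, 0.0)
    return 2.0 * stats.norm.sf(z)


def derive_classifier_genes(
    counts: ExpressionMatrix,
    labels: ClassLabels,
    candidates,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> tuple:
    """Differential expression over the metagene-specific candidates.

    Counts are normalized by median-of-ratios size factors, each candidate
    gene is compared between classes with a rank-sum test on
    log2(normalized+1), log2FC is the difference of class means of
    log2(normalized+1), and Benjamini-Hochberg FDR is taken over the
    candidate set. The classifier is the candidates with
    fdr < fdr_threshold and |log2FC| >= lfc_threshold, with direction.
    The stricter published preset is fdr_threshold=0.01 (fold-change > 2
    equals |log2FC| > 1).

    Returns (DE result table, ClassifierGeneSet).
    """
    if counts.unit != "counts":
        raise ValidationError("derive_classifier_genes expects a counts matrix")
    eic, rest = labels.eic_samples, labels.rest_samples
    if len(eic) < 3 or len(rest) < 3:
        raise ValidationError("both classes need >= 3 samples")

    candidates = list(candidates)
    present = [g for g in candidates if g in set(counts.gene_ids)]
    dropped = sorted(set(candidates) - set(present))
    if dropped:
        logger.warning("derive_classifier_genes: %d candidates absent from matrix: %s...",
                       len(dropped), dropped[:5])
    if not present:
        raise ValidationError("no candidate gene present in the expression matrix")

    raw = counts.values.to_numpy(dtype=float)
    sf = _size_factors(raw)
    norm = counts.values / sf
    L = np.log2(norm + 1.0)

    A = L.loc[present, eic].to_numpy()
    B = L.loc[present, rest].to_numpy()
    lfc = A.mean(axis=1) - B.mean(axis=1)
    pvals = _ranksum_vectorized(A, B)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    de = pd.DataFrame({
        "log2fc": lfc,
        "p": pvals,
        "fdr": fdr,
        "mean_eic": A.mean(axis=1),
        "mean_rest": B.mean(axis=1),
    }, index=present)
    de["significant"] = (de["fdr"] < fdr_threshold) & (de["log2fc"].abs() >= lfc_threshold)

    sig = de.index[de["significant"]]
    direction = pd.Series(np.where(de.loc[sig, "log2fc"] > 0, "up", "down"), index=sig)
    classifier = ClassifierGeneSet(
        genes=list(sig),
        direction=direction,
        params=dict(fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold,
                    n_candidates=len(present)),
    )
    logger.info("derive_classifier_genes: %d/%d candidates pass (fdr<%g, |lfc|>=%g)",
                len(sig), len(present), fdr_threshold, lfc_threshold)
    return de, classifier


def eic_score(matrix: ExpressionMatrix, classifier: ClassifierGeneSet) -> pd.Series:
    """ssGSEA enrichment of the up-direction classifier genes, one score per sample."""
    up = set(classifier.up_genes)
    if not up & set(matrix.gene_ids):
        raise ValidationError("classifier genes have no overlap with the expression matrix")
    table = ssgsea_scores(matrix, classifier.to_collection(), normalize=True)
    return table.scores.iloc[:, 0].rename("eic_score")


def roc_auc(scores: pd.Series, labels: ClassLabels) -> tuple:
    """AUC (Mann-Whitney probability, ties 0.5) and the ROC points.

    Returns (auc, DataFrame with fpr/tpr/threshold rows).
    """
    y = (labels.labels.loc[scores.index] == EIC).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("ROC needs both classes present")
    s = scores.to_numpy(dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def compare_responders(
    scores: pd.Series,
    response_labels: pd.Series,
    alternative: str = "greater",
) -> tuple:
    """One-sided rank-sum test of EIC scores, non-responders vs responders.

    The default alternative 'greater' tests whether non-responders have
    higher scores (the resistance signature). Returns (U, p).
    """
    response_labels = response_labels.loc[scores.index]
    nonresp = scores[response_labels == "non-responder"]
    resp = scores[response_labels == "responder"]
    if len(nonresp) == 0 or len(resp) == 0:
        raise ValidationError("both responder groups must be non-empty")
    return wilcoxon_rank_sum(nonresp, resp, alternative=alternative)
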