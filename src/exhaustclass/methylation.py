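"""Differential promoter methylation and genomic-burden associations.

Per-CpG class comparison of beta values uses a pooled-variance two-sample
t-test (the linear-model-with-two-level-factor equivalent) with
Benjamini-Hochberg FDR; significance requires fdr < 0.05 and
|deltaBeta| > 0.2 by default, where deltaBeta = mean(EIC) - mean(REST).
Promoter CpGs of differentially expressed genes are then correlated with
their genes' log2 expression. Burden measures are compared between classes
by rank-sum tests, and the EIC score is tested for independence from
tumour mutational burden.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BurdenTable, ExpressionMatrix, MethylationMatrix, ValidationError
from .scoring import pearson_correlation, wilcoxon_rank_sum

logger = logging.getLogger("exhaustclass")

BURDEN_MEASURES = ["n_mutations", "n_neoantigens", "n_cytoband_amp", "n_cytoband_del"]


def differential_methylation(
    methylation: MethylationMatrix,
    labels,
    fdr_threshold: float = 0.05,
    delta_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-CpG two-group comparison of beta values.

    Returns a table indexed by CpG with delta_beta, p, fdr, gene_id,
    is_promoter and the significance flag
    (fdr < fdr_threshold and |delta_beta| > delta_threshold).
    """
    lab = labels.labels if hasattr(labels, "labels") else labels
    lab = lab.loc[list(methylation.sample_ids)]
    eic = lab.index[lab == "EIC"]
    rest = lab.index[lab == "REST"]
    if len(eic) < 3 or len(rest) < 3:
        raise ValidationError("both classes need >= 3 samples")

    A = methylation.betas.loc[:, eic].to_numpy(dtype=float)
    B = methylation.betas.loc[:, rest].to_numpy(dtype=float)
    delta = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(A, B, axis=1, equal_var=True)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance CpGs: no evidence
    fdr = multipletests(pvals, method="fdr_bh")[1]

    ann = methylation.annotation.set_index("cpg_id")
    out = pd.DataFrame({
        "delta_beta": delta,
        "p": pvals,
        "fdr": fdr,
    }, index=methylation.betas.index)
    out["gene_id"] = ann["gene_id"].reindex(out.index)
    out["is_promoter"] = ann["is_promoter"].reindex(out.index).fillna(False).astype(bool)
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["delta_beta"].abs() > delta_threshold)
    logger.info("differential_methylation: %d/%d CpGs significant (fdr<%g, |delta|>%g)",
                int(out["significant"].sum()), len(out), fdr_threshold, delta_threshold)
    return out


def select_promoter_cpgs(dm: pd.DataFrame, de_significant_genes) -> pd.DataFrame:
    """Significant CpGs in promoters of differentially expressed genes."""
    de_set = set(de_significant_genes)
    mask = dm["significant"] & dm["is_promoter"] & dm["gene_id"].isin(de_set)
    logger.info("select_promoter_cpgs: kept %d/%d CpGs", int(mask.sum()), len(dm))
    return dm.loc[mask]


def methylation_expression_correlation(
    methylation: MethylationMatrix,
    expression: ExpressionMatrix,
    cpg_subset=None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of mean promoter beta vs log2 expression.

    ``cpg_subset`` is typically the output of :func:`select_promoter_cpgs`;
    defaults to all promoter-annotated CpGs. Genes whose promoter beta or
    expression is constant across samples are reported with r = NaN and a
    note rather than raised.
    """
    samples = [s for s in methylation.sample_ids if s in set(expression.sample_ids)]
    if len(samples) < 3:
        raise ValidationError("need >= 3 shared samples")
    ann = methylation.annotation
    if cpg_subset is not None:
        cpgs = list(cpg_subset.index) if isinstance(cpg_subset, pd.DataFrame) else list(cpg_subset)
        ann = ann[ann["cpg_id"].isin(set(cpgs))]
    else:
        ann = ann[ann["is_promoter"]]

    logx = np.log2(expression.values.loc[:, samples].astype(float) + 1.0)
    rows = []
    for gene, grp in ann.groupby("gene_id"):
        if gene not in set(expression.gene_ids):
            continue
        beta = methylation.betas.loc[grp["cpg_id"], samples].mean(axis=0).to_numpy()
        x = logx.loc[gene].to_numpy()
        if np.std(beta) == 0 or np.std(x) == 0:
            rows.append((gene, len(grp), np.nan, np.nan, "constant input"))
            continue
        r, p = pearson_correlation(beta, x)
        rows.append((gene, len(grp), r, p, ""))
    return pd.DataFrame(rows, columns=["gene_id", "n_cpgs", "r", "p", "note"]).set_index("gene_id")


def burden_comparison(burden: BurdenTable, labels) -> pd.DataFrame:
    """Rank-sum comparison of each burden measure between EIC and REST.

    Returns per-measure U, p and class medians.
    """
    lab = labels.labels if hasattr(labels, "labels") else labels
    lab = lab.loc[list(burden.sample_ids)]
    eic = lab.index[lab == "EIC"]
    rest = lab.index[lab == "REST"]
    if len(eic) < 2 or len(rest) < 2:
        raise ValidationError("both classes need >= 2 samples for burden comparison")
    rows = []
    for measure in BURDEN_MEASURES:
        x = burden.table.loc[eic, measure].to_numpy(dtype=float)
        y = burden.table.loc[rest, measure].to_numpy(dtype=float)
        u, p = wilcoxon_rank_sum(x, y, alternative="two-sided")
        rows.append((measure, u, p, float(np.median(x)), float(np.median(y))))
    return pd.DataFrame(
        rows, columns=["measure", "U", "p", "median_eic", "median_rest"]
    ).set_index("measure")


def score_tmb_correlation(eic_scores: pd.Series, burden: BurdenTable) -> tuple:
    """Pearson correlation between standardized EIC score and mutation count."""
    common = [s for s in eic_scores.index if s in set(burden.sample_ids)]
    if len(common) < 3:
        raise ValidationError("need >= 3 samples for score-TMB correlation")
    x = eic_scores.loc[common].to_numpy(dtype=float)
    x = (x - x.mean()) / x.std()
    tmb = burden.table.loc[common, "n_mutations"].to_numpy(dtype=float)
    return pearson_correlation(x, tmb)
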