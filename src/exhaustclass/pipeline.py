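"""End-to-end discovery and validation workflows with a machine-readable report.

``discover`` runs the full training pipeline on in-memory objects:
variance filtering -> NMF rank selection -> final factorization -> cluster
assignment -> immune-stromal identification -> EIC labelling -> metagene
feature extraction -> classifier derivation -> EIC scoring -> ROC, then
the survival, methylation and burden stages when those inputs are present.
``validate`` scores a held-out cohort with a frozen classifier and checks
concordance against a fresh NMF discovery on that cohort. ``run_discovery``
/ ``run_validation`` are the file-based wrappers driven by a YAML config;
a single master seed determines every stochastic stage and the report
echoes all parameters and derived per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import eic as eic_mod
from . import io as io_mod
from . import methylation as meth_mod
from . import nmf as nmf_mod
from . import survival as surv_mod
from .io import ExpressionMatrix, ValidationError
from .scoring import ssgsea_scores

logger = logging.getLogger("exhaustclass")

SCHEMA_VERSION = 1

DEFAULT_PARAMS = dict(
    k_candidates=[2, 3, 4, 5, 6],
    n_runs=30,
    n_top_genes=1500,
    max_iter=200,
    tol=1e-4,
    alpha=0.25,
    fdr_threshold=0.05,
    lfc_threshold=1.0,
    immune_signature="immune",
    stromal_signature="stromal",
    horizon_months=60.0,
)


def _stage_seeds(seed: int, names) -> dict:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(0, 2 ** 31 - 1)) for name in names}


def discover(
    expression: ExpressionMatrix,
    signatures: io_mod.GeneSetCollection,
    clinical: io_mod.ClinicalTable = None,
    methylation: io_mod.MethylationMatrix = None,
    burden: io_mod.BurdenTable = None,
    seed: int = 0,
    **params,
) -> dict:
    """Full discovery workflow; returns a dict of artifacts plus a JSON-able report."""
    p = dict(DEFAULT_PARAMS)
    p.update(params)
    seeds = _stage_seeds(seed, ["rank_selection", "final_factorization"])
    report = {"schema_version": SCHEMA_VERSION, "workflow": "discovery",
              "seed": seed, "stage_seeds": seeds, "params": dict(p), "stages": {}}

    prepared = nmf_mod.prepare_nmf_input(expression, n_top_genes=p["n_top_genes"])
    report["stages"]["prepare"] = {
        "genes_in": expression.shape[0], "genes_kept": prepared.shape[0],
        "samples": expression.shape[1],
    }

    if p["n_runs"] < 5:
        logger.warning("n_runs=%d gives an unstable consensus; rank diagnostics are coarse",
                       p["n_runs"])
    best_k, diagnostics = nmf_mod.select_rank(
        prepared, k_candidates=p["k_candidates"], n_runs=p["n_runs"],
        seed=seeds["rank_selection"], max_iter=p["max_iter"], tol=p["tol"],
    )
    report["stages"]["rank_selection"] = {
        "best_k": best_k,
        "cophenetic_by_k": {k: diagnostics[k].cophenetic for k in diagnostics},
        "n_runs": p["n_runs"],
    }

    model = nmf_mod.factorize(prepared, best_k, seed=seeds["final_factorization"],
                              max_iter=p["max_iter"], tol=p["tol"])
    clusters = nmf_mod.assign_clusters(model)

    score_table = ssgsea_scores(expression, signatures, alpha=p["alpha"])
    cluster_idx, cluster_means = eic_mod.identify_immune_stromal_cluster(
        clusters, score_table,
        immune_signature=p["immune_signature"], stromal_signature=p["stromal_signature"],
    )
    labels = eic_mod.label_eic(clusters, cluster_idx)
    report["stages"]["labelling"] = {
        "immune_stromal_cluster": cluster_idx,
        "cluster_sizes": clusters.value_counts().sort_index().to_dict(),
        "n_eic": len(labels.eic_samples),
        "n_rest": len(labels.rest_samples),
        "eic_fraction": len(labels.eic_samples) / len(labels.labels),
    }

    feature_scores = nmf_mod.metagene_feature_scores(model)
    candidates = nmf_mod.extract_metagene_genes(feature_scores, cluster_idx)
    report["stages"]["feature_extraction"] = {"n_metagene_specific": len(candidates)}
    if not candidates:
        raise ValidationError("no metagene-specific genes extracted for the immune-stromal metagene")

    de, classifier = eic_mod.derive_classifier_genes(
        expression, labels, candidates,
        fdr_threshold=p["fdr_threshold"], lfc_threshold=p["lfc_threshold"],
    )
    report["stages"]["classifier"] = {
        "n_candidates": len(candidates),
        "n_classifier_genes": len(classifier.genes),
        "n_up": len(classifier.up_genes),
    }

    scores = eic_mod.eic_score(expression, classifier)
    auc, roc_points = eic_mod.roc_auc(scores, labels)
    report["stages"]["roc"] = {"auc": auc}

    artifacts = {
        "model": model, "clusters": clusters, "score_table": score_table,
        "cluster_signature_means": cluster_means, "labels": labels,
        "feature_scores": feature_scores, "candidates": candidates,
        "de": de, "classifier": classifier, "eic_scores": scores,
        "roc_points": roc_points, "rank_diagnostics": diagnostics,
    }

    if clinical is not None:
        truncated = surv_mod.truncate_followup(clinical, p["horizon_months"])
        t = truncated.table.set_index("sample_id").loc[list(labels.labels.index)]
        chi2, lr_p = surv_mod.logrank_test(
            t["os_time_months"], t["os_event"], labels.labels.to_numpy()
        )
        cox = surv_mod.cox_fit(truncated, labels)
        report["stages"]["survival"] = {
            "logrank_chi2": chi2, "logrank_p": lr_p,
            "cox_class_hr": float(cox.summary.loc["class_EIC", "hr"]),
            "cox_class_p": float(cox.summary.loc["class_EIC", "p"]),
            "n_used": cox.n_used, "n_dropped_missing": cox.n_dropped_missing,
        }
        artifacts["cox"] = cox

    if methylation is not None:
        dm = meth_mod.differential_methylation(methylation, labels)
        de_genes = set(de.index[de["significant"]])
        promoter = meth_mod.select_promoter_cpgs(dm, de_genes)
        corr = meth_mod.methylation_expression_correlation(methylation, expression, promoter)
        report["stages"]["methylation"] = {
            "n_cpgs": len(dm),
            "n_significant": int(dm["significant"].sum()),
            "n_promoter_de": len(promoter),
            "n_genes_correlated": len(corr),
            "mean_promoter_r": float(corr["r"].mean()) if len(corr) else None,
        }
        artifacts.update({"dm": dm, "promoter_cpgs": promoter, "meth_expr_corr": corr})

    if burden is not None:
        cmp_ = meth_mod.burden_comparison(burden, labels)
        r, p_tmb = meth_mod.score_tmb_correlation(scores, burden)
        report["stages"]["burden"] = {
            "comparisons": {m: {"p": float(cmp_.loc[m, "p"]),
                                "median_eic": cmp_.loc[m, "median_eic"],
                                "median_rest": cmp_.loc[m, "median_rest"]}
                            for m in cmp_.index},
            "score_tmb_r": r, "score_tmb_p": p_tmb,
        }
        artifacts["burden_comparison"] = cmp_

    artifacts["report"] = report
    return artifacts


def validate(
    expression: ExpressionMatrix,
    classifier: eic_mod.ClassifierGeneSet,
    signatures: io_mod.GeneSetCollection = None,
    clinical: io_mod.ClinicalTable = None,
    response_labels: pd.Series = None,
    seed: int = 0,
    **params,
) -> dict:
    """Score a new cohort with a frozen classifier; optionally re-discover for concordance.

    When signatures are provided, an independent NMF discovery is run on
    the cohort and the frozen classifier's scores are evaluated by ROC
    against the cohort's own discovery labels (the internal-validation
    design). Survival and responder comparisons run when inputs exist.
    """
    p = dict(DEFAULT_PARAMS)
    p.update(params)
    report = {"schema_version": SCHEMA_VERSION, "workflow": "validation",
              "seed": seed, "params": dict(p), "stages": {}}

    scores = eic_mod.eic_score(expression, classifier)
    report["stages"]["scoring"] = {
        "n_samples": len(scores),
        "n_classifier_genes_present": len(set(classifier.up_genes) & set(expression.gene_ids)),
    }
    artifacts = {"eic_scores": scores, "report": report}

    labels = None
    if signatures is not None:
        seeds = _stage_seeds(seed, ["rank_selection", "final_factorization"])
        prepared = nmf_mod.prepare_nmf_input(expression, n_top_genes=p["n_top_genes"])
        best_k, _ = nmf_mod.select_rank(
            prepared, k_candidates=p["k_candidates"], n_runs=p["n_runs"],
            seed=seeds["rank_selection"], max_iter=p["max_iter"], tol=p["tol"],
        )
        model = nmf_mod.factorize(prepared, best_k, seed=seeds["final_factorization"],
                                  max_iter=p["max_iter"], tol=p["tol"])
        clusters = nmf_mod.assign_clusters(model)
        score_table = ssgsea_scores(expression, signatures, alpha=p["alpha"])
        cluster_idx, _ = eic_mod.identify_immune_stromal_cluster(
            clusters, score_table,
            immune_signature=p["immune_signature"], stromal_signature=p["stromal_signature"],
        )
        labels = eic_mod.label_eic(clusters, cluster_idx)
        auc, roc_points = eic_mod.roc_auc(scores, labels)
        report["stages"]["concordance"] = {
            "best_k": best_k,
            "n_eic": len(labels.eic_samples),
            "eic_fraction": len(labels.eic_samples) / len(labels.labels),
            "auc": auc,
        }
        artifacts.update({"labels": labels, "roc_points": roc_points})

    if clinical is not None and labels is not None:
        truncated = surv_mod.truncate_followup(clinical, p["horizon_months"])
        t = truncated.table.set_index("sample_id").loc[list(labels.labels.index)]
        chi2, lr_p = surv_mod.logrank_test(
            t["os_time_months"], t["os_event"], labels.labels.to_numpy()
        )
        report["stages"]["survival"] = {"logrank_chi2": chi2, "logrank_p": lr_p}

    if response_labels is not None:
        u, p_resp = eic_mod.compare_responders(scores, response_labels)
        report["stages"]["icb_response"] = {
            "U": u, "p": p_resp,
            "n_responder": int((response_labels == "responder").sum()),
            "n_non_responder": int((response_labels == "non-responder").sum()),
        }

    return artifacts


# ---------------------------------------------------------------------------
# Config-driven wrappers
# ---------------------------------------------------------------------------

def _require(config: dict, *keys):
    missing = [k for k in keys if k not in config]
    if missing:
        raise ValidationError(f"config missing mandatory keys: {missing}")


def _load_inputs(config: dict) -> dict:
    out = {}
    out["expression"] = io_mod.read_expression_matrix(
        config["expression"], config.get("expression_unit", "counts"))
    out["signatures"] = io_mod.read_gmt(config["signatures_gmt"])
    out["clinical"] = (io_mod.read_clinical_table(config["clinical"])
                       if config.get("clinical") else None)
    if config.get("methylation"):
        out["methylation"] = io_mod.read_methylation(
            config["methylation"], config["methylation_annotation"])
    else:
        out["methylation"] = None
    out["burden"] = (io_mod.read_burden_table(config["burden"])
                     if config.get("burden") else None)
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_discovery_outputs(artifacts: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts["labels"].labels.rename("class").to_csv(outdir / "labels.tsv", sep="\t",
                                                      index_label="sample_id")
    io_mod.write_gmt(artifacts["classifier"].to_collection(), outdir / "classifier.gmt")
    artifacts["score_table"].scores.to_csv(outdir / "signature_scores.tsv", sep="\t",
                                           index_label="sample_id")
    artifacts["eic_scores"].to_csv(outdir / "eic_scores.tsv", sep="\t",
                                   index_label="sample_id")
    artifacts["de"].to_csv(outdir / "differential_expression.tsv", sep="\t",
                           index_label="gene_id")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(artifacts["report"], fh, indent=2, default=_json_default)


def run_discovery(config: dict, outdir=None) -> dict:
    """File-based discovery workflow: read inputs per config, run, write outputs."""
    _require(config, "expression", "signatures_gmt")
    inputs = _load_inputs(config)
    artifacts = discover(
        inputs["expression"], inputs["signatures"],
        clinical=inputs["clinical"], methylation=inputs["methylation"],
        burden=inputs["burden"], seed=int(config.get("seed", 0)),
        **config.get("params", {}),
    )
    if outdir is not None:
        _write_discovery_outputs(artifacts, Path(outdir))
    return artifacts


def run_validation(config: dict, classifier: eic_mod.ClassifierGeneSet, outdir=None) -> dict:
    """File-based validation workflow with a frozen classifier."""
    _require(config, "expression")
    expression = io_mod.read_expression_matrix(
        config["expression"], config.get("expression_unit", "counts"))
    signatures = io_mod.read_gmt(config["signatures_gmt"]) if config.get("signatures_gmt") else None
    clinical = io_mod.read_clinical_table(config["clinical"]) if config.get("clinical") else None
    response = None
    if config.get("response"):
        resp_df = pd.read_csv(config["response"], sep="\t", dtype=str)
        response = resp_df.set_index("sample_id")["response"]
    artifacts = validate(
        expression, classifier, signatures=signatures, clinical=clinical,
        response_labels=response, seed=int(config.get("seed", 0)),
        **config.get("params", {}),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts["eic_scores"].to_csv(outdir / "eic_scores.tsv", sep="\t",
                                       index_label="sample_id")
        if "labels" in artifacts:
            artifacts["labels"].labels.rename("class").to_csv(
                outdir / "labels.tsv", sep="\t", index_label="sample_id")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(artifacts["report"], fh, indent=2, default=_json_default)
    return artifacts


def read_classifier_gmt(path) -> eic_mod.ClassifierGeneSet:
    """Load a frozen classifier written by the discovery workflow (up genes only)."""
    coll = io_mod.read_gmt(path)
    genes = sorted(coll.sets[0].members)
    direction = pd.Series("up", index=genes)
    return eic_mod.ClassifierGeneSet(genes=genes, direction=direction,
                                     params={"source": str(path)})
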