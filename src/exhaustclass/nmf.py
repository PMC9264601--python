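"""Virtual microdissection: KL-divergence NMF with consensus clustering.

Factorizes a non-negative expression matrix V (genes x samples) as W·H
with multiplicative updates minimizing the generalized Kullback-Leibler
divergence, then stabilizes the sample clustering over random restarts via
a consensus matrix whose cophenetic correlation coefficient drives rank
selection. Metagene-specific genes are extracted with the entropy-based
feature score thresholded at mean + 3 sd.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("exhaustclass")

_EPS = 1e-12


@dataclass
class NMFModel:
    k: int
    W: np.ndarray  # genes x k, >= 0
    H: np.ndarray  # k x samples, >= 0
    gene_ids: list
    sample_ids: list
    objective_trace: np.ndarray  # per-iteration KL divergence
    seed: int
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray  # samples x samples in [0,1], symmetric, unit diagonal
    sample_ids: list
    cophenetic: float
    n_runs: int


def prepare_nmf_input(matrix: ExpressionMatrix, n_top_genes: int = 1500) -> ExpressionMatrix:
    """Library-size-normalize counts, transform to log2(x+1), keep the most variable genes.

    Counts are scaled to the median library size before the log transform
    so the factorization does not spend a metagene on sequencing-depth
    variation; variance filtering to ``n_top_genes`` is standard virtual-
    microdissection practice. Both choices are logged; log2 input is only
    variance-filtered.
    """
    df = matrix.values
    if matrix.unit == "counts":
        lib = df.sum(axis=0).astype(float)
        scale = lib / np.median(lib)
        df = np.log2(df.astype(float) / scale + 1.0)
        logger.info("prepare_nmf_input: scaled %d libraries to the median depth", len(lib))
    if n_top_genes is not None and n_top_genes < len(df):
        variances = df.var(axis=1)
        keep = variances.sort_values(ascending=False).index[:n_top_genes]
        keep = [g for g in df.index if g in set(keep)]  # preserve input order
        logger.info("prepare_nmf_input: kept %d/%d most variable genes", len(keep), len(df))
        df = df.loc[keep]
    return ExpressionMatrix(df, "log2")


def _kl_divergence(V: np.ndarray, WH: np.ndarray, mask=None, const: float = None) -> float:
    """Generalized KL: sum(V*log(V/WH) - V + WH), with 0*log0 := 0.

    ``mask``/``const`` allow the V-only terms (sum V*log V - sum V) to be
    precomputed across iterations.
    """
    WH = np.maximum(WH, _EPS)
    if mask is None:
        mask = V > 0
    if const is None:
        const = float(np.sum(V[mask] * np.log(V[mask]))) - float(np.sum(V))
    div = const + float(np.sum(WH)) - float(np.sum(V[mask] * np.log(WH[mask])))
    return div


def factorize(
    matrix: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    track_objective: bool = True,
    dtype=np.float64,
) -> NMFModel:
    """Lee-Seung multiplicative updates for the generalized KL divergence.

    Initialization is uniform random from ``seed``; iteration stops at
    ``max_iter`` or when the relative objective change drops below ``tol``.
    All-zero gene rows are dropped with a warning (the update rules leave
    them undefined). ``track_objective=False`` skips the per-iteration
    divergence (and hence the tol-based stop), running exactly ``max_iter``
    updates — used by consensus restarts where only the final clustering
    matters.
    """
    V_df = matrix.values.astype(float)
    if (V_df.to_numpy() < 0).any():
        raise ValidationError("NMF input must be non-negative")
    zero_rows = V_df.index[(V_df.to_numpy() == 0).all(axis=1)]
    if len(zero_rows):
        warnings.warn(f"dropping {len(zero_rows)} all-zero gene rows before NMF")
        V_df = V_df.drop(index=zero_rows)
    n_genes, n_samples = V_df.shape
    if not k < min(n_genes, n_samples):
        raise ValidationError(f"k={k} must be < min(genes, samples) = {min(n_genes, n_samples)}")

    V = np.ascontiguousarray(V_df.to_numpy(), dtype=dtype)
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = (rng.uniform(_EPS, 1.0, size=(n_genes, k)) * scale).astype(dtype)
    H = (rng.uniform(_EPS, 1.0, size=(k, n_samples)) * scale).astype(dtype)

    if track_objective:
        mask = V > 0
        vconst = float(np.sum(V[mask] * np.log(V[mask]))) - float(np.sum(V))

    trace = []
    prev = None
    converged = False
    for it in range(max_iter):
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        Q = V / WH
        # H update
        H *= (W.T @ Q) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        np.divide(V, WH, out=Q)
        # W update
        W *= (Q @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if not track_objective:
            continue
        obj = _kl_divergence(V, W @ H, mask=mask, const=vconst)
        trace.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(abs(prev), _EPS):
            converged = True
            break
        prev = obj

    return NMFModel(
        k=k, W=W, H=H,
        gene_ids=list(V_df.index), sample_ids=list(V_df.columns),
        objective_trace=np.asarray(trace), seed=seed,
        n_iter=len(trace) if track_objective else max_iter,
        converged=converged,
    )


def assign_clusters(model: NMFModel) -> pd.Series:
    """Each sample -> argmax metagene of its H column (1-based); ties -> lowest index."""
    labels = np.argmax(model.H, axis=0) + 1
    return pd.Series(labels, index=model.sample_ids, name="cluster")


def consensus_matrix(
    matrix: ExpressionMatrix,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    **factorize_kwargs,
) -> ConsensusResult:
    """Average connectivity over seeded NMF restarts, with its cophenetic coefficient.

    connectivity(i,j) = 1 when samples i and j land in the same argmax
    cluster of a run; the consensus is the mean over runs.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    n = matrix.shape[1]
    consensus = np.zeros((n, n))
    # restarts only need the final clustering, not the objective trace
    factorize_kwargs.setdefault("track_objective", False)
    factorize_kwargs.setdefault("dtype", np.float32)
    for s in run_seeds:
        model = factorize(matrix, k, seed=int(s), **factorize_kwargs)
        labels = assign_clusters(model).to_numpy()
        consensus += (labels[:, None] == labels[None, :]).astype(float)
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    try:
        coph = cophenetic_coefficient(consensus)
    except ValidationError:
        coph = float("nan")
    return ConsensusResult(
        k=k, consensus=consensus, sample_ids=list(matrix.sample_ids),
        cophenetic=coph, n_runs=n_runs,
    )


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Pearson correlation between consensus distances and dendrogram cophenetic distances.

    D = 1 - consensus is clustered by average linkage; the coefficient is
    the correlation of the upper triangles of D and the cophenetic distance
    matrix of the resulting dendrogram. Undefined (raises) when the
    off-diagonal entries are constant.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus must be square")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValidationError("consensus must be symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0]):
        raise ValidationError("cophenetic coefficient undefined: constant off-diagonal distances")
    Z = linkage(condensed, method="average")
    coeff, _ = cophenet(Z, condensed)
    return float(coeff)


def select_rank(
    matrix: ExpressionMatrix,
    k_candidates=(2, 3, 4, 5, 6),
    n_runs: int = 30,
    seed: int = 0,
    **factorize_kwargs,
) -> tuple:
    """Pick the rank maximizing the cophenetic coefficient; ties -> smallest k.

    Returns (best_k, {k: ConsensusResult}) so the per-rank diagnostics can
    be reported alongside the choice.
    """
    results = {}
    rng = np.random.default_rng(seed)
    for k in sorted(k_candidates):
        k_seed = int(rng.integers(0, 2 ** 31 - 1))
        results[k] = consensus_matrix(matrix, k, n_runs=n_runs, seed=k_seed, **factorize_kwargs)
    best_k, best = None, -np.inf
    for k in sorted(results):
        c = results[k].cophenetic
        if np.isfinite(c) and c > best + 1e-12:
            best_k, best = k, c
    if best_k is None:
        raise ValidationError("no candidate rank produced a defined cophenetic coefficient")
    return best_k, results


def metagene_feature_scores(model: NMFModel) -> pd.DataFrame:
    """Entropy-based gene scores over the basis matrix W.

    For gene i with contribution profile p(i,q) = W(i,q)/sum_q W(i,q):
    s(i) = 1 + (1/log2 k) * sum_q p(i,q) log2 p(i,q), so s=1 for a point
    mass (gene specific to one metagene) and s=0 for a uniform profile.
    All-zero rows are excluded. Columns: score, dominant (1-based argmax),
    p_1..p_k.
    """
    W = model.W
    rowsum = W.sum(axis=1)
    keep = rowsum > 0
    if (~keep).any():
        logger.info("metagene_feature_scores: excluding %d all-zero basis rows", int((~keep).sum()))
    P = W[keep] / rowsum[keep, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    score = 1.0 + plogp.sum(axis=1) / np.log2(model.k)
    dominant = np.argmax(P, axis=1) + 1
    genes = np.asarray(model.gene_ids)[keep]
    out = pd.DataFrame({"score": score, "dominant": dominant}, index=genes)
    for q in range(model.k):
        out[f"p_{q + 1}"] = P[:, q]
    return out


def extract_metagene_genes(scores: pd.DataFrame, target_metagene: int) -> set:
    """Metagene-specific genes: score > mean + 3 sd AND dominant == target."""
    s = scores["score"]
    threshold = s.mean() + 3.0 * s.std(ddof=1)
    mask = (s > threshold) & (scores["dominant"] == target_metagene)
    return set(scores.index[mask])
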