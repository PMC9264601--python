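"""Synthetic cohorts with the statistical structure the discovery pipeline assumes.

The generator plants k expression programs in a negative-binomial
(Gamma-Poisson) count model. One program — index 2, the immune-stromal
program — carries the immune / stromal / T-cell-exhaustion signature genes
and defines the planted exhausted immune class (EIC). Program-specific
genes are modeled as near-silent outside their program and switched on by
``2**program_strength`` inside it, the on/off contrast characteristic of
immune and stromal signature genes in immune-cold versus immune-hot bulk
tumours. Survival, promoter methylation, genomic burden and ICB-response
layers are generated on top of the planted class, each as a pure function
of its parameters and seed, and every planted quantity is recorded in a
:class:`SyntheticTruth` so downstream stages have parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import BurdenTable, ClinicalTable, ExpressionMatrix, MethylationMatrix

#: Program index that carries the immune/stromal/exhaustion signature genes.
IMMUNE_STROMAL_PROGRAM = 2

#: Signature block sizes inside the immune-stromal program.
_SIGNATURE_SIZES = {"immune": 10, "stromal": 10, "TEX": 10}
_OTHER_BLOCK_SIZE = 25
#: Mean count of a program marker gene outside its program (near-off state).
_OFF_BASELINE = 0.2
#: Baseline mean count of program companion genes (moderately induced module).
_COMPANION_BASELINE = 5.0


@dataclass
class SyntheticTruth:
    """Ground-truth record for one synthetic cohort family.

    Sample-level fields (cluster, class) describe the cohort returned
    alongside the truth; the program layout (which genes belong to which
    program, gene baselines, noise parameters) is cohort-independent, so
    held-out validation cohorts can be drawn from the same truth with
    :func:`resimulate_expression`.
    """

    planted_k: int
    planted_cluster: pd.Series  # sample -> 1..k
    planted_class: pd.Series  # sample -> {"EIC", "REST"}
    planted_signature_genes: dict  # signature name -> set of gene ids
    planted_de_genes: pd.Series  # gene -> true log2 fold change (EIC vs REST)
    seed: int
    program_genes: dict = field(default_factory=dict)  # program index -> list of genes
    gene_baselines: pd.Series = None  # per-gene baseline mean count
    params: dict = field(default_factory=dict)
    planted_log_hr: float = None
    background_loadings: "np.ndarray" = None  # gene x factor log2 loadings
    companion_genes: dict = field(default_factory=dict)  # program -> co-induced module genes
    planted_coupled_cpgs: set = field(default_factory=set)  # {(cpg, gene, sign)}
    planted_response_model: dict = field(default_factory=dict)

    @property
    def eic_samples(self) -> list:
        return list(self.planted_class.index[self.planted_class == "EIC"])


def _planted_clusters(n_samples: int, k: int, eic_fraction: float, rng) -> np.ndarray:
    """Exact class sizes: round(eic_fraction*n) samples in program 2, rest split evenly."""
    n_eic = int(round(eic_fraction * n_samples))
    if n_eic < 5:
        raise ValueError(
            f"eic_fraction*n_samples = {n_eic} < 5: degenerate planted class"
        )
    others = [q for q in range(1, k + 1) if q != IMMUNE_STROMAL_PROGRAM]
    n_rest = n_samples - n_eic
    sizes = {q: n_rest // len(others) for q in others}
    for q in others[: n_rest % len(others)]:
        sizes[q] += 1
    labels = np.concatenate(
        [np.full(n_eic, IMMUNE_STROMAL_PROGRAM)] + [np.full(sizes[q], q) for q in others]
    )
    return rng.permutation(labels)


def _true_log2fc(strength: float, block_program: int, cluster: np.ndarray) -> float:
    """EIC-vs-REST log2 fold change of count means for a block gene."""
    n = len(cluster)
    n_eic = int((cluster == IMMUNE_STROMAL_PROGRAM).sum())
    if block_program == IMMUNE_STROMAL_PROGRAM:
        return strength
    # gene is on only in its own (non-EIC) program; REST mean is a mixture
    f = (cluster == block_program).sum() / (n - n_eic)
    return -float(np.log2(f * 2.0 ** strength + (1.0 - f)))


def simulate_expression(
    n_genes: int = 2000,
    n_samples: int = 200,
    k: int = 4,
    eic_fraction: float = 0.3,
    program_strength: float = 4.0,
    dispersion: float = 0.2,
    lib_size_range: tuple = (0.7, 1.3),
    n_companion_genes: int = 40,
    companion_strength: float = 2.5,
    activity_range: tuple = (0.75, 1.25),
    mixing_fraction: float = 0.15,
    mixing_level_range: tuple = (0.15, 0.35),
    n_background_factors: int = 0,
    background_factor_sd: float = 0.3,
    seed: int = 0,
) -> tuple:
    """Draw a counts cohort with k planted programs; return (matrix, truth).

    ``program_strength`` is the log2 activation of a program-specific gene
    in its own program's samples; 0 removes all class signal while keeping
    the truth record (a null cohort for which recovery must fail).
    Each program consists of near-silent on/off marker genes (the block
    recorded in ``program_genes``, containing the signature genes for the
    immune-stromal program) plus ``n_companion_genes`` moderately expressed
    companion genes induced 2**companion_strength-fold — the broader
    co-regulated module that gives each program enough mass for the
    factorization to resolve it reliably. Each sample scales its program's
    effects by an activity level drawn from ``activity_range`` — the
    patient-to-patient gradation in how strongly a programme is engaged —
    which keeps consensus matrices from degenerating to block-constant
    form when a factorization rank merges or splits the planted programs.
    A ``mixing_fraction`` of samples additionally express one other
    program at a partial level (``mixing_level_range`` of full strength):
    bulk tumours are mixtures of compartments, and these blended samples
    are what make under-rank merges resolve sample-by-sample rather than
    block-by-block. Optional continuous background
    factors (``n_background_factors`` > 0) add class-independent
    covariation across background genes; they are off by default because
    strong stable background axes are themselves picked up as extra
    metagenes at higher ranks.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < eic_fraction < 1:
        raise ValueError("eic_fraction must be in (0,1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    # program blocks occupy the head of the gene list
    program_genes, cursor = {}, 0
    for q in range(1, k + 1):
        size = sum(_SIGNATURE_SIZES.values()) if q == IMMUNE_STROMAL_PROGRAM else _OTHER_BLOCK_SIZE
        program_genes[q] = gene_ids[cursor: cursor + size]
        cursor += size
    if cursor >= n_genes:
        raise ValueError("n_genes too small for the planted program blocks")

    companion_genes = {}
    for q in range(1, k + 1):
        companion_genes[q] = gene_ids[cursor: cursor + n_companion_genes]
        cursor += n_companion_genes
    if cursor >= n_genes:
        raise ValueError("n_genes too small for the planted program blocks")

    sig_genes, pos = {}, 0
    block2 = program_genes[IMMUNE_STROMAL_PROGRAM]
    for name, size in _SIGNATURE_SIZES.items():
        sig_genes[name] = set(block2[pos: pos + size])
        pos += size

    # baselines: background genes lognormal around ~30 counts, markers near-off,
    # companions at a visible moderate level
    gpos = {g: i for i, g in enumerate(gene_ids)}
    base = np.exp(rng.normal(np.log(30.0), 1.0, size=n_genes))
    for q in range(1, k + 1):
        base[[gpos[g] for g in program_genes[q]]] = _OFF_BASELINE
        base[[gpos[g] for g in companion_genes[q]]] = _COMPANION_BASELINE

    cluster = _planted_clusters(n_samples, k, eic_fraction, rng)
    lib = rng.uniform(*lib_size_range, size=n_samples)
    activity = rng.uniform(*activity_range, size=n_samples)

    # secondary (partial) program membership for a fraction of samples
    secondary = np.zeros(n_samples, dtype=int)
    sec_level = np.zeros(n_samples)
    mixed = rng.random(n_samples) < mixing_fraction
    for i in np.flatnonzero(mixed):
        others = [q for q in range(1, k + 1) if q != cluster[i]]
        secondary[i] = others[rng.integers(len(others))]
        sec_level[i] = rng.uniform(*mixing_level_range)

    log2_effect = np.zeros((n_genes, n_samples))
    for q in range(1, k + 1):
        sidx = np.flatnonzero(cluster == q)
        log2_effect[np.ix_([gpos[g] for g in program_genes[q]], sidx)] = \
            program_strength * activity[sidx]
        log2_effect[np.ix_([gpos[g] for g in companion_genes[q]], sidx)] = \
            companion_strength * activity[sidx]
        tidx = np.flatnonzero(secondary == q)
        if len(tidx):
            log2_effect[np.ix_([gpos[g] for g in program_genes[q]], tidx)] = \
                program_strength * sec_level[tidx]
            log2_effect[np.ix_([gpos[g] for g in companion_genes[q]], tidx)] = \
                companion_strength * sec_level[tidx]

    program_gene_idx = [gpos[g] for q in program_genes for g in program_genes[q]]
    program_gene_idx += [gpos[g] for q in companion_genes for g in companion_genes[q]]
    u = np.zeros((n_genes, max(n_background_factors, 1)))
    if n_background_factors > 0 and background_factor_sd > 0:
        u = rng.normal(0.0, background_factor_sd / np.sqrt(n_background_factors),
                       size=(n_genes, n_background_factors))
        u[program_gene_idx] = 0.0  # class signal genes stay clean
        v = rng.normal(0.0, 1.0, size=(n_background_factors, n_samples))
        log2_effect += u @ v

    mu = base[:, None] * lib[None, :] * 2.0 ** log2_effect
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    values = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cluster_s = pd.Series(cluster, index=sample_ids, name="planted_cluster")
    class_s = pd.Series(
        np.where(cluster == IMMUNE_STROMAL_PROGRAM, "EIC", "REST"),
        index=sample_ids, name="planted_class",
    )
    de = {}
    for q in range(1, k + 1):
        lfc = _true_log2fc(program_strength, q, cluster)
        lfc_c = _true_log2fc(companion_strength, q, cluster)
        for g in program_genes[q]:
            de[g] = lfc
        for g in companion_genes[q]:
            de[g] = lfc_c
    truth = SyntheticTruth(
        planted_k=k,
        planted_cluster=cluster_s,
        planted_class=class_s,
        planted_signature_genes=sig_genes,
        planted_de_genes=pd.Series(de, name="log2fc"),
        seed=seed,
        program_genes=program_genes,
        gene_baselines=pd.Series(base, index=gene_ids),
        params=dict(
            n_genes=n_genes, n_samples=n_samples, k=k, eic_fraction=eic_fraction,
            program_strength=program_strength, dispersion=dispersion,
            lib_size_range=tuple(lib_size_range),
            n_companion_genes=n_companion_genes,
            companion_strength=companion_strength,
            activity_range=tuple(activity_range),
            mixing_fraction=mixing_fraction,
            mixing_level_range=tuple(mixing_level_range),
            n_background_factors=n_background_factors,
            background_factor_sd=background_factor_sd,
        ),
    )
    truth.background_loadings = u
    truth.companion_genes = companion_genes
    return ExpressionMatrix(values, "counts"), truth


def resimulate_expression(truth: SyntheticTruth, n_samples: int, seed: int) -> tuple:
    """Draw a fresh cohort (new samples) from an existing truth's program layout.

    Returns (matrix, truth_of_new_cohort); the new truth shares gene-level
    structure with the input and records the new samples' planted classes.
    """
    p = truth.params
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.gene_baselines.index)
    sample_ids = [f"V{i:03d}" for i in range(n_samples)]
    cluster = _planted_clusters(n_samples, truth.planted_k, p["eic_fraction"], rng)
    lib = rng.uniform(*p["lib_size_range"], size=n_samples)
    activity = rng.uniform(*p.get("activity_range", (1.0, 1.0)), size=n_samples)

    k = truth.planted_k
    secondary = np.zeros(n_samples, dtype=int)
    sec_level = np.zeros(n_samples)
    mixed = rng.random(n_samples) < p.get("mixing_fraction", 0.0)
    for i in np.flatnonzero(mixed):
        others = [q for q in range(1, k + 1) if q != cluster[i]]
        secondary[i] = others[rng.integers(len(others))]
        sec_level[i] = rng.uniform(*p.get("mixing_level_range", (0.15, 0.35)))

    log2_effect = np.zeros((len(gene_ids), n_samples))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for q, genes in truth.program_genes.items():
        sidx = np.flatnonzero(cluster == q)
        log2_effect[np.ix_([gpos[g] for g in genes], sidx)] = \
            p["program_strength"] * activity[sidx]
        if truth.companion_genes:
            log2_effect[np.ix_([gpos[g] for g in truth.companion_genes[q]], sidx)] = \
                p.get("companion_strength", 0.0) * activity[sidx]
        tidx = np.flatnonzero(secondary == q)
        if len(tidx):
            log2_effect[np.ix_([gpos[g] for g in genes], tidx)] = \
                p["program_strength"] * sec_level[tidx]
            if truth.companion_genes:
                log2_effect[np.ix_([gpos[g] for g in truth.companion_genes[q]], tidx)] = \
                    p.get("companion_strength", 0.0) * sec_level[tidx]
    if truth.background_loadings is not None and p.get("n_background_factors", 0) > 0:
        v = rng.normal(0.0, 1.0, size=(truth.background_loadings.shape[1], n_samples))
        log2_effect += truth.background_loadings @ v
    mu = truth.gene_baselines.to_numpy()[:, None] * lib[None, :] * 2.0 ** log2_effect
    shape = 1.0 / p["dispersion"]
    counts = rng.poisson(rng.gamma(shape, mu / shape)).astype(np.int64)

    values = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cluster_s = pd.Series(cluster, index=sample_ids, name="planted_cluster")
    class_s = pd.Series(
        np.where(cluster == IMMUNE_STROMAL_PROGRAM, "EIC", "REST"),
        index=sample_ids, name="planted_class",
    )
    new_truth = SyntheticTruth(
        planted_k=truth.planted_k,
        planted_cluster=cluster_s,
        planted_class=class_s,
        planted_signature_genes=truth.planted_signature_genes,
        planted_de_genes=truth.planted_de_genes,
        seed=seed,
        program_genes=truth.program_genes,
        gene_baselines=truth.gene_baselines,
        params=dict(p, n_samples=n_samples),
    )
    new_truth.background_loadings = truth.background_loadings
    new_truth.companion_genes = truth.companion_genes
    return ExpressionMatrix(values, "counts"), new_truth


def simulate_survival(
    truth: SyntheticTruth,
    log_hr: float = float(np.log(2.0)),
    baseline_median_months: float = 30.0,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential event times; planted EIC hazard multiplied by exp(log_hr).

    Censoring is independent Uniform(0, b), with b solved so the expected
    censored fraction under the baseline hazard equals ``censor_rate``.
    Age, gender and stage covariates are drawn independently of class.
    OS and PFS share the planted hazard structure (PFS at 0.7x the median).
    """
    if baseline_median_months <= 0:
        raise ValueError("baseline_median_months must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    samples = list(truth.planted_class.index)
    n = len(samples)
    is_eic = (truth.planted_class == "EIC").to_numpy()

    def _times(median):
        lam = np.log(2.0) / median
        rate = lam * np.where(is_eic, np.exp(log_hr), 1.0)
        t = rng.exponential(1.0 / rate)
        if censor_rate == 0:
            return t, np.ones(n, dtype=int)
        # P(censored) = P(C < T) = (1 - exp(-lam*b)) / (lam*b) for C ~ U(0, b)
        def frac(b):
            x = lam * b
            return (1.0 - np.exp(-x)) / x - censor_rate
        b = brentq(frac, 1e-9 / lam, 1e9 / lam)
        c = rng.uniform(0.0, b, size=n)
        return np.minimum(t, c), (t <= c).astype(int)

    os_t, os_e = _times(baseline_median_months)
    pfs_t, pfs_e = _times(0.7 * baseline_median_months)

    table = pd.DataFrame({
        "sample_id": samples,
        "os_time_months": os_t,
        "os_event": os_e,
        "pfs_time_months": pfs_t,
        "pfs_event": pfs_e,
        "age": np.round(rng.normal(67.0, 8.0, size=n), 1),
        "gender": rng.choice(["male", "female"], size=n),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.25, 0.35, 0.3, 0.1]),
    })
    truth.planted_log_hr = float(log_hr)
    return ClinicalTable(table)


def simulate_methylation(
    truth: SyntheticTruth,
    expression: ExpressionMatrix,
    n_cpgs: int = 300,
    coupling_strength: float = 1.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> MethylationMatrix:
    """Beta values with promoter CpGs anti-correlated to immune-stromal gene expression.

    Each immune-stromal program gene gets one coupled promoter CpG:
    beta = expit(-coupling_strength * z + noise) where z is the gene's
    standardized log2 expression across samples. Remaining CpGs are noise
    around a random baseline; half are annotated as promoters of random
    background genes so promoter filtering has true negatives.
    """
    rng = np.random.default_rng(seed)
    coupled_genes = list(truth.program_genes[IMMUNE_STROMAL_PROGRAM])
    if n_cpgs < len(coupled_genes):
        raise ValueError(
            f"n_cpgs={n_cpgs} < number of coupled CpGs ({len(coupled_genes)})"
        )
    samples = list(expression.sample_ids)
    n = len(samples)

    logx = np.log2(expression.values.to_numpy(dtype=float) + 1.0)
    logx = pd.DataFrame(logx, index=expression.gene_ids, columns=samples)

    rows, cpg_ids, ann_rows = [], [], []
    truth.planted_coupled_cpgs = set()
    for i, gene in enumerate(coupled_genes):
        cpg = f"cg{i:05d}"
        x = logx.loc[gene].to_numpy()
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        beta = expit(-coupling_strength * z + rng.normal(0.0, noise_sd, size=n))
        rows.append(np.clip(beta, 0.0, 1.0))
        cpg_ids.append(cpg)
        ann_rows.append((cpg, gene, True))
        truth.planted_coupled_cpgs.add((cpg, gene, "-"))

    background = [g for g in expression.gene_ids if g not in set(coupled_genes)]
    for i in range(len(coupled_genes), n_cpgs):
        cpg = f"cg{i:05d}"
        baseline = rng.uniform(0.1, 0.9)
        beta = np.clip(baseline + rng.normal(0.0, noise_sd, size=n), 0.0, 1.0)
        rows.append(beta)
        cpg_ids.append(cpg)
        gene = background[rng.integers(len(background))]
        ann_rows.append((cpg, gene, bool(i % 2)))

    betas = pd.DataFrame(np.vstack(rows), index=cpg_ids, columns=samples)
    ann = pd.DataFrame(ann_rows, columns=["cpg_id", "gene_id", "is_promoter"])
    return MethylationMatrix(betas, ann)


def simulate_burden(
    truth: SyntheticTruth,
    mutation_rate: float = 150.0,
    cna_rate_eic: float = 5.0,
    cna_rate_rest: float = 10.0,
    neoantigen_rate: float = None,
    seed: int = 0,
) -> BurdenTable:
    """Poisson burden counts: mutations/neoantigens class-independent, CNA class-linked."""
    rng = np.random.default_rng(seed)
    samples = list(truth.planted_class.index)
    n = len(samples)
    is_eic = (truth.planted_class == "EIC").to_numpy()
    if neoantigen_rate is None:
        neoantigen_rate = 0.25 * mutation_rate
    cna = np.where(is_eic, cna_rate_eic, cna_rate_rest)
    table = pd.DataFrame({
        "n_mutations": rng.poisson(mutation_rate, size=n),
        "n_neoantigens": rng.poisson(neoantigen_rate, size=n),
        "n_cytoband_amp": rng.poisson(cna),
        "n_cytoband_del": rng.poisson(cna),
    }, index=pd.Index(samples, name="sample_id"))
    return BurdenTable(table)


def simulate_icb_response(
    eic_scores: pd.Series,
    slope: float = 3.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Bernoulli response labels with P(responder) = expit(intercept - slope*z(score)).

    Scores are standardized internally so slope is in z-score units;
    slope > 0 makes non-responders enriched for high EIC scores.
    """
    rng = np.random.default_rng(seed)
    x = eic_scores.to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    p = expit(intercept - slope * z)
    resp = rng.random(len(x)) < p
    return pd.Series(
        np.where(resp, "responder", "non-responder"),
        index=eic_scores.index, name="response",
    )


def simulate_cohort_bundle(
    seed: int = 0,
    n_genes: int = 2000,
    n_samples: int = 200,
    k: int = 4,
    eic_fraction: float = 0.3,
    program_strength: float = 4.0,
    **kwargs,
) -> dict:
    """Generate the full multi-omic bundle (expression, clinical, methylation, burden, truth).

    Per-layer seeds are derived deterministically from the master seed.
    """
    rng = np.random.default_rng(seed)
    s_expr, s_surv, s_meth, s_burd = rng.integers(0, 2 ** 31 - 1, size=4)
    expr, truth = simulate_expression(
        n_genes=n_genes, n_samples=n_samples, k=k, eic_fraction=eic_fraction,
        program_strength=program_strength, seed=int(s_expr), **kwargs,
    )
    clinical = simulate_survival(truth, seed=int(s_surv))
    methylation = simulate_methylation(truth, expr, seed=int(s_meth))
    burden = simulate_burden(truth, seed=int(s_burd))
    return {
        "expression": expr,
        "clinical": clinical,
        "methylation": methylation,
        "burden": burden,
        "truth": truth,
    }
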