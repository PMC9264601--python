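"""Readers, writers and validated containers for every table the pipeline touches.

All flat files are tab-separated, UTF-8, '.' decimal — the dialect of
TCGA/GEO exports. Gene, sample and CpG identifiers are opaque strings
matched exactly (case-sensitive); identifier mapping is the caller's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("exhaustclass")

EXPRESSION_UNITS = ("counts", "log2")


class FormatError(ValueError):
    """A file does not conform to its expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    ``unit='counts'`` requires non-negative integral values (raw RNA-seq
    counts); ``unit='log2'`` requires finite reals (normalized log2 space,
    e.g. log2(x+1) or microarray log intensities).
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        nan = np.argwhere(~np.isfinite(arr))
        if nan.size:
            g, s = nan[0]
            raise ValidationError(
                f"missing/non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.unit == "counts":
            bad = np.argwhere(arr < 0)
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
                )
            bad = np.argwhere(arr != np.round(arr))
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    f"non-integral count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), self.unit)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene-set names: {dup}")
        self._index = {s.name: s for s in self.sets}

    def __getitem__(self, name: str) -> GeneSet:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


#: Required clinical columns; PFS columns are optional.
CLINICAL_REQUIRED = ["sample_id", "os_time_months", "os_event"]
CLINICAL_OPTIONAL = ["pfs_time_months", "pfs_event", "age", "gender", "stage"]


@dataclass
class ClinicalTable:
    """Per-sample outcome and covariate table.

    Times are months (non-negative), event flags are 0/1. Missing
    covariates are permitted and kept as NaN; survival operations drop
    incomplete rows with a logged count.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in CLINICAL_REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicated sample ids: {dup[:5]}")
        for tcol, ecol in (("os_time_months", "os_event"), ("pfs_time_months", "pfs_event")):
            if tcol not in t.columns:
                continue
            times = t[tcol].to_numpy(dtype=float)
            if np.nanmin(times) < 0:
                row = int(np.nanargmin(times))
                raise ValidationError(f"negative {tcol} at row {row} (sample {t['sample_id'].iloc[row]!r})")
            events = t[ecol].to_numpy(dtype=float)
            ok = np.isin(events[~np.isnan(events)], (0.0, 1.0))
            if not ok.all():
                row = int(np.flatnonzero(~np.isin(events, (0.0, 1.0)) & ~np.isnan(events))[0])
                raise ValidationError(
                    f"{ecol} must be 0/1; got {events[row]!r} at row {row} "
                    f"(sample {t['sample_id'].iloc[row]!r})"
                )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset_samples(self, sample_ids) -> "ClinicalTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub)


@dataclass
class MethylationMatrix:
    """CpG x samples beta values in [0,1] plus CpG→gene promoter annotation."""

    betas: pd.DataFrame  # index = cpg ids, columns = sample ids
    annotation: pd.DataFrame  # columns: cpg_id, gene_id, is_promoter

    def __post_init__(self):
        b = self.betas
        if b.index.duplicated().any():
            raise ValidationError("duplicated CpG ids")
        if b.columns.duplicated().any():
            raise ValidationError("duplicated sample ids")
        arr = b.to_numpy(dtype=float)
        bad = np.argwhere(~((arr >= 0) & (arr <= 1)))
        if bad.size:
            c, s = bad[0]
            raise ValidationError(
                f"beta value {arr[c, s]!r} outside [0,1] at CpG {b.index[c]!r}, "
                f"sample {b.columns[s]!r}"
            )
        ann = self.annotation
        for col in ("cpg_id", "gene_id", "is_promoter"):
            if col not in ann.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        missing = set(ann["cpg_id"]) - set(b.index)
        if missing:
            raise ValidationError(f"annotated CpGs absent from matrix: {sorted(missing)[:5]}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.betas.loc[:, list(sample_ids)].copy(), self.annotation.copy())


BURDEN_COLUMNS = ["n_mutations", "n_neoantigens", "n_cytoband_amp", "n_cytoband_del"]


@dataclass
class BurdenTable:
    """Per-sample genomic burden counts (mutations, neoantigens, cytoband amp/del)."""

    table: pd.DataFrame  # index = sample ids, columns = BURDEN_COLUMNS

    def __post_init__(self):
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError("duplicated sample ids in burden table")
        for col in BURDEN_COLUMNS:
            if col not in t.columns:
                raise ValidationError(f"burden table missing column {col!r}")
            vals = t[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals != np.round(vals)):
                row = int(np.flatnonzero(~np.isfinite(vals) | (vals < 0) | (vals != np.round(vals)))[0])
                raise ValidationError(
                    f"{col} must be a non-negative integer; got {t[col].iloc[row]!r} "
                    f"for sample {t.index[row]!r}"
                )
        self.table = t[BURDEN_COLUMNS].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset_samples(self, sample_ids) -> "BurdenTable":
        return BurdenTable(self.table.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name <tab> description <tab> members..."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, expected >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name, desc, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=None)


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


def read_methylation(path, annotation_path) -> MethylationMatrix:
    betas = pd.read_csv(path, sep="\t", index_col=0)
    betas.index = betas.index.astype(str)
    betas.columns = betas.columns.astype(str)
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"cpg_id": str, "gene_id": str})
    if "is_promoter" in ann.columns:
        ann["is_promoter"] = ann["is_promoter"].astype(bool)
    return MethylationMatrix(betas, ann)


def write_methylation(meth: MethylationMatrix, path, annotation_path) -> None:
    out = meth.betas.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t")
    meth.annotation.to_csv(annotation_path, sep="\t", index=False)


def read_burden_table(path) -> BurdenTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return BurdenTable(df)


def write_burden_table(burden: BurdenTable, path) -> None:
    out = burden.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment and configuration
# ---------------------------------------------------------------------------

def align_samples(*objects):
    """Subset all objects to their common samples, in sorted order.

    Accepts any mix of ExpressionMatrix / ClinicalTable / MethylationMatrix /
    BurdenTable (each must expose ``sample_ids`` and ``subset_samples``).
    Returns the aligned objects in the input order. Downstream modules
    require pre-aligned inputs; every exclusion is logged.
    """
    if not objects:
        return ()
    common = set(objects[0].sample_ids)
    for obj in objects[1:]:
        common &= set(obj.sample_ids)
    if not common:
        raise ValidationError("no samples shared across inputs")
    order = sorted(common)
    for obj in objects:
        dropped = len(obj.sample_ids) - len(order)
        if dropped:
            logger.info(
                "align_samples: dropping %d/%d samples from %s",
                dropped, len(obj.sample_ids), type(obj).__name__,
            )
    return tuple(obj.subset_samples(order) for obj in objects)


def load_config(path) -> dict:
    """Load the YAML pipeline configuration (paths, rank range, restarts, thresholds, seed)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level of config must be a mapping")
    return cfg
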