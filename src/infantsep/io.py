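"""Domain containers and file I/O for the merged-cohort pipeline.

The common currency of every analysis stage is an :class:`ExpressionMatrix`
(genes x samples, log2 intensities) paired with per-sample
:class:`SampleMetadata` records.  Expression travels as TSV/CSV with genes in
rows and samples in columns (the dominant GEO series-matrix convention);
metadata as CSV; gene sets as GMT.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "ExpressionMatrix",
    "SampleMetadata",
    "MergedCohort",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "collapse_probes",
    "merge_cohorts",
    "read_gmt",
    "write_gmt",
]


class Group(str, Enum):
    """Clinical group of a sample; controls anchor the co-normalization."""

    HEALTHY_CONTROL = "HealthyControl"
    BACTEREMIA = "Bacteremia"
    SEPTIC_SHOCK = "SepticShock"


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale_tag
        ``"log2"`` for log2 intensities (required by every analysis entry
        point) or ``"linear"``.
    """

    values: pd.DataFrame
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "linear"):
            raise ValueError(f"scale_tag must be 'log2' or 'linear', got {self.scale_tag!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError("expression values must all be finite")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), self.scale_tag)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.scale_tag)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample record: provenance (dataset/platform) and clinical group."""

    sample_id: str
    dataset_id: str
    platform_id: str
    group: Group
    age_days: float | None = None
    sex: str | None = None  # "M", "F" or None

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))
        if self.age_days is not None and self.age_days < 0:
            raise ValueError(f"age_days must be nonnegative, got {self.age_days}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M', 'F' or None, got {self.sex!r}")

    @property
    def is_control(self) -> bool:
        return self.group is Group.HEALTHY_CONTROL


@dataclass
class MergedCohort:
    """Expression plus metadata after the cross-platform merge.

    Every expression sample must carry exactly one metadata record; the gene
    universe is the intersection of the contributing platforms' panels.
    """

    expr: ExpressionMatrix
    meta: list[SampleMetadata]
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        meta_ids = [m.sample_id for m in self.meta]
        counts = Counter(meta_ids)
        dups = [s for s, c in counts.items() if c > 1]
        if dups:
            raise ValueError(f"duplicate metadata sample ids: {dups}")
        expr_ids = set(self.expr.sample_ids)
        if expr_ids != set(meta_ids):
            missing = expr_ids.symmetric_difference(meta_ids)
            raise ValueError(f"expression/metadata sample mismatch: {sorted(missing)[:10]}")

    @property
    def meta_by_id(self) -> dict[str, SampleMetadata]:
        return {m.sample_id: m for m in self.meta}

    @property
    def platforms(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.meta:
            seen.setdefault(m.platform_id)
        return list(seen)

    def sample_ids_of_platform(self, platform_id: str) -> list[str]:
        keep = {m.sample_id for m in self.meta if m.platform_id == platform_id}
        return [s for s in self.expr.sample_ids if s in keep]

    def control_ids(self) -> list[str]:
        keep = {m.sample_id for m in self.meta if m.is_control}
        return [s for s in self.expr.sample_ids if s in keep]

    def case_ids(self) -> list[str]:
        keep = {m.sample_id for m in self.meta if not m.is_control}
        return [s for s in self.expr.sample_ids if s in keep]

    def group_ids(self, group: Group | str) -> list[str]:
        group = Group(group)
        keep = {m.sample_id for m in self.meta if m.group is group}
        return [s for s in self.expr.sample_ids if s in keep]


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-like terms, gene modules)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.sets.items():
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate genes within set {term_id}")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term_id: str) -> list[str]:
        return self.sets[term_id][1]

    def name(self, term_id: str) -> str:
        return self.sets[term_id][0]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read an expression TSV/CSV.

    ``orientation="genes_in_rows"`` expects gene ids in the first column and
    one header row of sample ids; ``"samples_in_rows"`` reads the transpose.
    Non-numeric cells and ragged rows are hard errors.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    if df.columns.str.startswith("Unnamed:").any():
        raise ValueError(f"{path}: ragged rows or trailing delimiter in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if df.isna().any().any() or bad.any().any():
        mask = df.isna() | bad
        rows = mask.any(axis=1)
        r = mask.index[rows][0]
        c = mask.columns[mask.loc[r]][0]
        raise ValueError(f"{path}: non-numeric or missing cell at row {r!r}, column {c!r}")
    if orientation == "samples_in_rows":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    expr.values.to_csv(path, sep=sep, float_format=float_format)


_META_COLUMNS = ["sample_id", "dataset_id", "platform_id", "group"]


def read_metadata(path) -> list[SampleMetadata]:
    """Read sample metadata CSV (columns sample_id,dataset_id,platform_id,group
    plus optional age_days and sex)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata columns {missing}")
    out = []
    for _, row in df.iterrows():
        age = row.get("age_days")
        age_val = float(age) if age is not None and not pd.isna(age) else None
        sex = row.get("sex")
        sex_val = None if sex is None or pd.isna(sex) or sex == "" else str(sex)
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                dataset_id=str(row["dataset_id"]),
                platform_id=str(row["platform_id"]),
                group=Group(row["group"]),
                age_days=age_val,
                sex=sex_val,
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMetadata], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "dataset_id": m.dataset_id,
            "platform_id": m.platform_id,
            "group": m.group.value,
            "age_days": m.age_days,
            "sex": m.sex,
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS + ["age_days", "sex"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def collapse_probes(
    probe_expr: ExpressionMatrix, probe2gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Summarize probe-level rows to genes by the per-sample arithmetic mean.

    Probes absent from the map are dropped (counted in the log).  A probe
    mapping to more than one gene is a hard error upstream of this call since
    the mapping type forbids it; an empty mapping is rejected here.
    """
    if not probe2gene:
        raise ValueError("probe-to-gene mapping is empty")
    probes = probe_expr.values.index
    mapped = probes.isin(probe2gene.keys())
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped.any():
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = probe_expr.values.loc[mapped]
    genes = pd.Index([probe2gene[p] for p in sub.index], name=None)
    collapsed = sub.groupby(genes, sort=False).mean()
    collapsed.index.name = None
    return ExpressionMatrix(collapsed, probe_expr.scale_tag)


def merge_cohorts(
    matrices: Sequence[ExpressionMatrix],
    metas: Sequence[Sequence[SampleMetadata]],
) -> MergedCohort:
    """Merge per-platform matrices on the sorted intersection of their genes.

    Samples are concatenated in input order; per-dataset sample counts are
    recorded as provenance.  Requires at least two matrices, a non-empty gene
    intersection, globally unique sample ids, and >=1 control per platform.
    """
    if len(matrices) < 2:
        raise ValueError("merge requires at least two matrices")
    if len(matrices) != len(metas):
        raise ValueError("one metadata list required per matrix")
    common: set[str] | None = None
    for m in matrices:
        gs = set(m.gene_ids)
        common = gs if common is None else common & gs
    assert common is not None
    if not common:
        raise ValueError("empty gene intersection across platforms")
    gene_order = sorted(common)

    all_ids: list[str] = []
    for meta in metas:
        all_ids.extend(m.sample_id for m in meta)
    dup = [s for s, c in Counter(all_ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate sample ids across inputs: {dup[:10]}")

    for meta in metas:
        platforms = {m.platform_id for m in meta}
        for p in platforms:
            if not any(m.platform_id == p and m.is_control for m in meta):
                raise ValueError(f"platform {p} contributes no control sample")

    blocks = [m.values.loc[gene_order] for m in matrices]
    merged = pd.concat(blocks, axis=1)
    flat_meta = [m for meta in metas for m in meta]
    provenance = Counter(m.dataset_id for m in flat_meta)
    return MergedCohort(
        expr=ExpressionMatrix(merged, matrices[0].scale_tag),
        meta=flat_meta,
        provenance=dict(provenance),
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene ...`` per line.

    Duplicate genes within a set are dropped (count logged); a line with
    fewer than three fields is an error naming the line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    n_dup = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc = fields[0], fields[1]
            if term_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            sets[term_id] = (desc, genes)
    if n_dup:
        logger.info("read_gmt: dropped %d duplicate genes within sets", n_dup)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term_id, (desc, genes) in collection.sets.items():
            fh.write("\t".join([term_id, desc, *genes]) + "\n")
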