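"""Expression matrices, sample labels, and microarray probe collapsing.

Expression values are genes x samples intensities. Probe-level tables are
collapsed to gene level by discarding probes that map to multiple genes and
taking the per-sample median when several probes map to one gene. When data
from several cohorts are analysed jointly, only genes detected in every
cohort are retained.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Label(enum.Enum):
    """Role of a sample in the analysis."""

    REFERENCE = "reference"
    CLASS_A = "class_a"
    CLASS_B = "class_b"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of finite expression intensities.

    ``data`` has unique gene ids as index and unique sample ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SampleLabels:
    """Mapping sample id -> role (reference / disease class A / class B)."""

    mapping: Mapping[str, Label]

    def ids_with(self, label: Label) -> list[str]:
        return [s for s, lab in self.mapping.items() if lab is label]

    @property
    def reference_ids(self) -> list[str]:
        return self.ids_with(Label.REFERENCE)

    @property
    def class_a_ids(self) -> list[str]:
        return self.ids_with(Label.CLASS_A)

    @property
    def class_b_ids(self) -> list[str]:
        return self.ids_with(Label.CLASS_B)

    @property
    def disease_ids(self) -> list[str]:
        return self.class_a_ids + self.class_b_ids

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in self.mapping if s not in set(expr.sample_ids)]
        if missing:
            raise ValueError(f"labelled samples absent from matrix: {missing[:5]}")
        if len(self.reference_ids) < 2:
            raise ValueError("need at least 2 reference samples")


@dataclass(frozen=True)
class ProbeTable:
    """Probe-level expression: probe id, its mapped gene ids, sample values."""

    probe_ids: tuple[str, ...]
    gene_lists: tuple[tuple[str, ...], ...]  # genes each probe maps to
    sample_ids: tuple[str, ...]
    values: np.ndarray  # probes x samples

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("probe value matrix shape mismatch")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header: sample ids; first column: gene id).

    Rows containing missing values are dropped with a logged warning;
    duplicate gene ids or non-numeric cells raise a descriptive error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropping %d gene row(s) with missing values", path, n_missing)
        df = df.dropna(axis=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(data=df)


def read_probe_table(path: str | Path) -> ProbeTable:
    """Read a probe TSV: probe_id, comma-separated gene ids, sample columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected probe_id, gene list and >=1 sample column")
    probe_ids = tuple(df.iloc[:, 0].astype(str))
    gene_lists = tuple(
        tuple(g for g in str(cell).split(",") if g) for cell in df.iloc[:, 1]
    )
    sample_ids = tuple(str(c) for c in df.columns[2:])
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    return ProbeTable(probe_ids=probe_ids, gene_lists=gene_lists,
                      sample_ids=sample_ids, values=values)


def collapse_probes(probes: ProbeTable) -> ExpressionMatrix:
    """Collapse probe-level values to gene level.

    Probes mapping to more than one gene are discarded; when multiple probes
    map to the same gene the per-sample median is taken. Permutation
    invariant in probe row order.
    """
    per_gene: dict[str, list[np.ndarray]] = {}
    n_discarded = 0
    for probe, genes, row in zip(probes.probe_ids, probes.gene_lists, probes.values):
        if len(genes) != 1:
            n_discarded += 1
            continue
        per_gene.setdefault(genes[0], []).append(row)
    if n_discarded:
        logger.warning("discarded %d probe(s) mapping to multiple (or zero) genes",
                       n_discarded)
    gene_ids = sorted(per_gene)
    data = pd.DataFrame(
        [np.median(np.vstack(per_gene[g]), axis=0) for g in gene_ids],
        index=gene_ids, columns=list(probes.sample_ids), dtype=float,
    )
    return ExpressionMatrix(data=data)


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the genes detected in all of them.

    Output matrices share one sorted gene order. Raises if the intersection
    is empty.
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    common: set[str] = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene intersection across matrices is empty")
    order = sorted(common)
    return [ExpressionMatrix(data=m.data.loc[order]) for m in matrices]


def read_labels(path: str | Path, class_a_name: str, class_b_name: str,
                reference_name: str) -> SampleLabels:
    """Read a 2-column sample/label TSV and map label strings onto roles."""
    path = Path(path)
    role_of = {reference_name: Label.REFERENCE, class_a_name: Label.CLASS_A,
               class_b_name: Label.CLASS_B}
    if len(role_of) != 3:
        raise ValueError("class/reference label names must be distinct")
    mapping: dict[str, Label] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, label = fields
            if sample in mapping:
                raise ValueError(f"{path}:{lineno}: sample {sample!r} labelled twice")
            if label not in role_of:
                raise ValueError(
                    f"{path}:{lineno}: unknown label {label!r} "
                    f"(expected one of {sorted(role_of)})")
            mapping[sample] = role_of[label]
    return SampleLabels(mapping=mapping)
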