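"""Differential pathways, disease-gene enrichment, and regulation sets.

PASS features are compared between the two disease classes with a two-sample
t-test (Welch by default); pathways differential in every cohort can be
intersected across datasets. Enrichment of known disease-associated genes
(DAGs) in the differential pathways uses the upper-tail hypergeometric test

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N,n)

with N = genes in all pathways, M = DAGs among them, n = genes in the
differential pathways, m = DAGs among those. Per-gene up/down regulation
sets contrast each disease class against the healthy reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aucpath import PassMatrix
from .expression import ExpressionMatrix, Label, SampleLabels
from .pathways import Pathway

logger = logging.getLogger(__name__)

#: Smallest representable two-sided p, used when variance degenerates to zero
#: with unequal means.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    t_statistic: float
    p_value: float
    mean_class_a: float
    mean_class_b: float


@dataclass(frozen=True)
class EnrichmentCounts:
    """The (N, M, n, m) quadruple of the hypergeometric enrichment test."""

    N: int
    M: int
    n: int
    m: int
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N
                and 0 <= self.m <= min(self.M, self.n)):
            raise ValueError(f"inconsistent counts N={self.N} M={self.M} "
                             f"n={self.n} m={self.m}")
        object.__setattr__(self, "p_value",
                           hypergeometric_enrichment(self.N, self.M, self.n, self.m))

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(max(self.p_value, P_FLOOR))


@dataclass(frozen=True)
class RegulationSets:
    """Up/down regulated gene sets of each disease class vs the reference."""

    up_a: frozenset[str]
    down_a: frozenset[str]
    up_b: frozenset[str]
    down_b: frozenset[str]

    def overlap_summary(self) -> dict[str, int]:
        """Venn-style counts of shared and class-specific regulation."""
        a = self.up_a | self.down_a
        b = self.up_b | self.down_b
        shared_same = (self.up_a & self.up_b) | (self.down_a & self.down_b)
        shared_opposite = (self.up_a & self.down_b) | (self.down_a & self.up_b)
        return {
            "class_a_only": len(a - b),
            "class_b_only": len(b - a),
            "shared_same_direction": len(shared_same),
            "shared_opposite_direction": len(shared_opposite),
        }


def _two_sample_t(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[float, float]:
    """Two-sided two-sample t-test with explicit degenerate conventions."""
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), P_FLOOR
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(max(p, P_FLOOR))


def ttest_features(pass_matrix: PassMatrix, labels: SampleLabels,
                   variant: str = "welch") -> list[DifferentialResult]:
    """Two-sample t-test of every PASS feature between class A and class B.

    Features with missing values are skipped with a warning. Requires at
    least two samples in each class.
    """
    a_ids = [s for s in pass_matrix.sample_ids if labels.mapping.get(s) is Label.CLASS_A]
    b_ids = [s for s in pass_matrix.sample_ids if labels.mapping.get(s) is Label.CLASS_B]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need >= 2 samples per disease class for the t-test")
    results: list[DifferentialResult] = []
    n_skipped = 0
    for fid, row in pass_matrix.data.iterrows():
        if row.isna().any():
            n_skipped += 1
            continue
        a = row[a_ids].to_numpy(dtype=float)
        b = row[b_ids].to_numpy(dtype=float)
        t, p = _two_sample_t(a, b, variant)
        results.append(DifferentialResult(
            feature_id=str(fid), t_statistic=t, p_value=p,
            mean_class_a=float(a.mean()), mean_class_b=float(b.mean())))
    if n_skipped:
        logger.warning("skipped %d feature(s) with missing values", n_skipped)
    return results


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.t_statistic, r.p_value, r.mean_class_a, r.mean_class_b)
         for r in results],
        columns=["feature_id", "t", "p", "mean_class_a", "mean_class_b"])


def differential_across_datasets(
        results_per_dataset: Sequence[Sequence[DifferentialResult]],
        alpha: float) -> set[str]:
    """Feature ids with p < alpha in every dataset (monotone in alpha)."""
    if not results_per_dataset:
        return set()
    sig_sets = [{r.feature_id for r in results if r.p_value < alpha}
                for results in results_per_dataset]
    out = sig_sets[0]
    for s in sig_sets[1:]:
        out &= s
    return out


def hypergeometric_enrichment(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability of drawing >= m special items.

    N items total, M special, n drawn, m special among the drawn.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(M, n)):
        raise ValueError(f"inconsistent counts N={N} M={M} n={n} m={m}")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def feature_pathway_id(feature_id: str) -> str:
    """Pathway id of a PASS feature id ``<pathway>|edge`` / ``<pathway>|node``."""
    return feature_id.rsplit("|", 1)[0]


def dag_enrichment(pathways: Sequence[Pathway], dag_genes: Iterable[str],
                   differential_feature_ids: Iterable[str]) -> EnrichmentCounts:
    """Enrichment of disease-associated genes in the differential pathways.

    A pathway counts as differential when either of its two features is in
    the differential set; n is the deduplicated union of member genes over
    differential pathways.
    """
    by_id = {pw.id: pw for pw in pathways}
    universe: set[str] = set()
    for pw in pathways:
        universe |= pw.genes
    dags = set(dag_genes) & universe
    diff_pathway_ids = {feature_pathway_id(f) for f in differential_feature_ids}
    unknown = diff_pathway_ids - set(by_id)
    if unknown:
        raise ValueError(f"differential features reference unknown pathways: "
                         f"{sorted(unknown)[:5]}")
    diff_genes: set[str] = set()
    for pid in diff_pathway_ids:
        diff_genes |= by_id[pid].genes
    return EnrichmentCounts(N=len(universe), M=len(dags), n=len(diff_genes),
                            m=len(dags & diff_genes))


def regulation_sets(expr: ExpressionMatrix, labels: SampleLabels,
                    genes: Iterable[str], alpha: float,
                    variant: str = "welch") -> RegulationSets:
    """Per-gene up/down regulation of each disease class vs the reference.

    A gene is up (down) in a class when its two-sample t-test against the
    reference cohort has p < alpha and the class mean is above (below) the
    reference mean.
    """
    genes = [g for g in genes]
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    ref = expr.data.loc[genes, labels.reference_ids].to_numpy(dtype=float)
    if ref.shape[1] < 2:
        raise ValueError("need >= 2 reference samples")

    sets: dict[str, set[str]] = {"up_a": set(), "down_a": set(),
                                 "up_b": set(), "down_b": set()}
    for suffix, ids in (("a", labels.class_a_ids), ("b", labels.class_b_ids)):
        if len(ids) < 2:
            raise ValueError(f"need >= 2 class-{suffix} samples")
        cls = expr.data.loc[genes, ids].to_numpy(dtype=float)
        for i, g in enumerate(genes):
            t, p = _two_sample_t(cls[i], ref[i], variant)
            if p < alpha:
                direction = "up" if cls[i].mean() > ref[i].mean() else "down"
                sets[f"{direction}_{suffix}"].add(g)
    return RegulationSets(up_a=frozenset(sets["up_a"]), down_a=frozenset(sets["down_a"]),
                          up_b=frozenset(sets["up_b"]), down_b=frozenset(sets["down_b"]))
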