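"""Synthetic three-class expression cohorts with known pathway ground truth.

The generator emulates a microarray-style study: a healthy reference cohort
and two disease classes whose designated pathways differ from the reference
in co-expression structure (edge view) and mean expression (node view).

Per pathway, genes follow a latent multivariate normal whose correlation is
0.7 along pathway edges. A matrix with 0.7 on the edges and 0 elsewhere is
not positive semidefinite in general, so the latent correlation between two
pathway genes is 0.7^d with d the graph geodesic distance — exact for trees,
with an eigenvalue-clipping correlation repair when cycle-closing edges
perturb it.
Perturbing a pathway in a disease class removes a fraction of its edges from
the correlation model (breaking those co-expression links) and shifts the
latent mean of all its genes. Expression values are baseline log2-intensity
8.0 plus the latent value plus independent Gaussian measurement noise,
floored just above zero so fold changes are always defined.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_clipped

from .expression import ExpressionMatrix, Label, SampleLabels
from .pathways import Edge, Pathway, canonical_edge

logger = logging.getLogger(__name__)

#: Latent correlation placed on each pathway edge.
EDGE_CORRELATION_TARGET = 0.7
#: Baseline expression level (log2-intensity scale typical of microarrays).
BASELINE_EXPRESSION = 8.0
#: Floor keeping expression strictly positive.
EXPRESSION_FLOOR = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the signal-recovery study: 20 samples per group, 30
    pathways of 6-10 genes, five pathways perturbed per disease class with a
    2-unit latent mean shift and 80% of their edge correlations broken, and
    mild measurement noise (sd 0.2).
    """

    n_reference: int = 20
    n_class_a: int = 20
    n_class_b: int = 20
    n_pathways: int = 30
    genes_per_pathway: tuple[int, int] = (6, 10)
    edges_per_pathway: tuple[int, int] = (6, 12)
    perturbed_pathways_a: tuple[int, ...] = (0, 1, 2, 3, 4)
    perturbed_pathways_b: tuple[int, ...] = (5, 6, 7, 8, 9)
    mean_shift: float = 2.0
    correlation_rewire: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0
    n_background_genes: int = 40  # measured genes belonging to no pathway

    def __post_init__(self) -> None:
        if min(self.n_reference, self.n_class_a, self.n_class_b) < 1:
            raise ValueError("sample counts must be positive")
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        idx = set(self.perturbed_pathways_a) | set(self.perturbed_pathways_b)
        if idx and (min(idx) < 0 or max(idx) >= self.n_pathways):
            raise ValueError("perturbed pathway indices out of range")
        if not 0.0 <= self.correlation_rewire <= 1.0:
            raise ValueError("correlation_rewire must lie in [0, 1]")
        if self.genes_per_pathway[0] < 3 or self.genes_per_pathway[0] > self.genes_per_pathway[1]:
            raise ValueError("genes_per_pathway must be a range with lower bound >= 3")
        if self.edges_per_pathway[0] < 2 or self.edges_per_pathway[0] > self.edges_per_pathway[1]:
            raise ValueError("edges_per_pathway must be a range with lower bound >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_pathways(config: SimConfig) -> list[Pathway]:
    """Random connected sparse pathway graphs with disjoint gene namespaces.

    Each pathway draws a gene count from ``genes_per_pathway`` and an edge
    count from ``edges_per_pathway`` (clipped to the connected range
    [g-1, C(g,2)]); the graph is a uniform random recursive spanning tree
    plus randomly chosen extra edges. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    pathways: list[Pathway] = []
    for p in range(config.n_pathways):
        g = int(rng.integers(config.genes_per_pathway[0],
                             config.genes_per_pathway[1] + 1))
        max_edges = g * (g - 1) // 2
        if config.edges_per_pathway[0] > max_edges:
            raise ValueError(
                f"edges_per_pathway lower bound {config.edges_per_pathway[0]} exceeds "
                f"C({g},2)={max_edges}")
        e = int(rng.integers(config.edges_per_pathway[0],
                             config.edges_per_pathway[1] + 1))
        e = int(np.clip(e, g - 1, max_edges))

        genes = [f"P{p:02d}G{j:02d}" for j in range(g)]
        perm = rng.permutation(g)
        edges: set[Edge] = set()
        for k in range(1, g):  # random recursive tree on permuted labels
            parent = int(rng.integers(0, k))
            edges.add(canonical_edge(genes[perm[k]], genes[perm[parent]]))
        non_edges = sorted(
            canonical_edge(genes[i], genes[j])
            for i in range(g) for j in range(i + 1, g)
            if canonical_edge(genes[i], genes[j]) not in edges)
        extra = e - (g - 1)
        if extra > 0:
            for idx in rng.choice(len(non_edges), size=extra, replace=False):
                edges.add(non_edges[int(idx)])
        pathways.append(Pathway(id=f"P{p:02d}", name=f"synthetic pathway {p}",
                                genes=frozenset(genes), edges=frozenset(edges)))
    return pathways


def _geodesic_correlation(genes: Sequence[str], edges: set[Edge],
                          rho: float = EDGE_CORRELATION_TARGET) -> np.ndarray:
    """Latent correlation rho^d from graph geodesic distances (0 if disconnected)."""
    index = {g: i for i, g in enumerate(genes)}
    adj: list[list[int]] = [[] for _ in genes]
    for a, b in edges:
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    n = len(genes)
    sigma = np.eye(n)
    for src in range(n):
        dist = np.full(n, -1)
        dist[src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for j in range(n):
            if j != src and dist[j] > 0:
                sigma[src, j] = rho ** dist[j]
    # cycle edges can push the geodesic model slightly off PSD
    if np.linalg.eigvalsh(sigma).min() < 1e-10:
        sigma = corr_clipped(sigma, threshold=1e-8)
        sigma = (sigma + sigma.T) / 2.0
    return sigma


def generate_cohort(pathways: Sequence[Pathway], config: SimConfig,
                    ) -> tuple[ExpressionMatrix, SampleLabels, dict]:
    """Draw a reference + two-disease-class cohort with implanted pathway signal.

    Returns the expression matrix, the sample labels, and a ground-truth
    record naming the perturbed pathways and broken edges per class.
    """
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = ([f"REF{i:02d}" for i in range(config.n_reference)]
                  + [f"A{i:02d}" for i in range(config.n_class_a)]
                  + [f"B{i:02d}" for i in range(config.n_class_b)])
    groups = {
        Label.REFERENCE: slice(0, config.n_reference),
        Label.CLASS_A: slice(config.n_reference,
                             config.n_reference + config.n_class_a),
        Label.CLASS_B: slice(config.n_reference + config.n_class_a,
                             len(sample_ids)),
    }
    n_per_group = {Label.REFERENCE: config.n_reference,
                   Label.CLASS_A: config.n_class_a,
                   Label.CLASS_B: config.n_class_b}

    truth: dict = {"perturbed_pathways_a": [], "perturbed_pathways_b": [],
                   "broken_edges": {}, "config": asdict(config)}
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    for p_idx, pw in enumerate(pathways):
        genes = pw.sorted_genes
        edges = set(pw.edges)
        base_sigma = _geodesic_correlation(genes, edges)

        perturbed_in = {}
        for cls, indices, key in ((Label.CLASS_A, config.perturbed_pathways_a,
                                   "perturbed_pathways_a"),
                                  (Label.CLASS_B, config.perturbed_pathways_b,
                                   "perturbed_pathways_b")):
            if p_idx in indices:
                truth[key].append(pw.id)
                k = int(round(config.correlation_rewire * len(edges)))
                sorted_edges = sorted(edges)
                chosen = ([] if k == 0 else
                          [sorted_edges[int(i)] for i in
                           rng.choice(len(sorted_edges), size=k, replace=False)])
                truth["broken_edges"].setdefault(pw.id, {})[cls.value] = [
                    list(e) for e in sorted(chosen)]
                perturbed_in[cls] = (
                    _geodesic_correlation(genes, edges - set(chosen)),
                    config.mean_shift,
                )

        block = np.empty((len(genes), len(sample_ids)))
        for cls in (Label.REFERENCE, Label.CLASS_A, Label.CLASS_B):
            sigma, shift = perturbed_in.get(cls, (base_sigma, 0.0))
            latent = rng.multivariate_normal(
                np.full(len(genes), shift), sigma, size=n_per_group[cls],
                check_valid="ignore", method="eigh").T
            block[:, groups[cls]] = latent
        blocks.append(block)
        gene_ids.extend(genes)

    if config.n_background_genes:
        bg = rng.standard_normal((config.n_background_genes, len(sample_ids)))
        blocks.append(bg)
        gene_ids.extend(f"BG{j:03d}" for j in range(config.n_background_genes))

    latent = np.vstack(blocks)
    noise = (rng.normal(0.0, config.noise_sd, size=latent.shape)
             if config.noise_sd > 0 else 0.0)
    values = np.maximum(BASELINE_EXPRESSION + latent + noise, EXPRESSION_FLOOR)

    expr = ExpressionMatrix(data=pd.DataFrame(values, index=gene_ids,
                                              columns=sample_ids))
    mapping = {s: lab for lab, sl in groups.items() for s in sample_ids[sl]}
    labels = SampleLabels(mapping=mapping)
    return expr, labels, truth


def write_fixture(out_dir: str | Path, expr: ExpressionMatrix,
                  labels: SampleLabels, pathways: Sequence[Pathway],
                  truth: dict) -> dict[str, Path]:
    """Write the cohort as the standard file formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "gmt": out / "pathways.gmt",
        "edges": out / "pathways.edges.tsv",
        "truth": out / "ground_truth.json",
    }
    expr.data.to_csv(paths["expression"], sep="\t", index_label="gene_id",
                     float_format="%.12g")
    with paths["labels"].open("w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{labels.mapping[s].value}\n")
    with paths["gmt"].open("w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.id, pw.name, *pw.sorted_genes]) + "\n")
    with paths["edges"].open("w") as fh:
        for pw in pathways:
            for a, b in pw.sorted_edges:
                fh.write(f"{pw.id}\t{a}\t{b}\n")
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
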