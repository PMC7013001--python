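"""The AUCpath activation statistic and assembly of the PASS matrix.

AUCpath measures whether an *attention* set of items (real pathway edges, or
pathway member genes) is enriched at the top of a score ranking:

    AUC = (sum of attention ranks - m(m+1)/2) / (m * n)

with m attention items, n background items and ranks assigned in ascending
score order (midranks for ties). This is the normalised Mann-Whitney U — the
fraction of (attention, background) pairs in which the attention item
scores higher, ties counting one half.

Two activations are computed per pathway and disease sample: the edge view
ranks all edges of the fully connected pathway network by their perturbation
Z, and the node view ranks all pathway-universe genes by their fold change.
Both land in [0, 1]; 0.5 means no enrichment either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix, SampleLabels
from .pathways import (FullyConnectedPathwayNetwork, GeneUniverse, Pathway,
                       build_fully_connected, gene_universe)
from .perturbation import (EdgePerturbationProfile, FoldChangeProfile,
                           edge_perturbations, fold_changes)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedInstance:
    """Scores with attention flags, ready for AUC computation."""

    scores: np.ndarray
    attention: np.ndarray  # bool mask, same length

    def __post_init__(self) -> None:
        if self.scores.shape != self.attention.shape or self.scores.ndim != 1:
            raise ValueError("scores and attention must be equal-length 1-D arrays")

    @property
    def m(self) -> int:
        return int(self.attention.sum())

    @property
    def n(self) -> int:
        return int(self.scores.size - self.m)


@dataclass(frozen=True)
class PassMatrix:
    """Pathway-activation features x disease samples, entries in [0, 1].

    Each retained pathway contributes two features, ``<id>|edge`` and
    ``<id>|node``; the edge feature of a complete pathway (no background
    edges) is missing (NaN).
    """

    data: pd.DataFrame  # features x samples, NaN = missing

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("PASS values must lie in [0, 1] or be missing")


def midrank(scores: Sequence[float]) -> np.ndarray:
    """Ascending ranks 1..N; tied scores share the mean positional rank."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(scores, method="average")


def auc_from_ranks(instance: RankedInstance) -> float:
    """AUC of the attention set under the midrank ordering of the scores.

    Returns NaN (missing) when the background set is empty; raises when the
    attention set is empty.
    """
    m, n = instance.m, instance.n
    if m == 0:
        raise ValueError("attention set is empty")
    if n == 0:
        return float("nan")
    ranks = midrank(instance.scores)
    return float((ranks[instance.attention].sum() - m * (m + 1) / 2.0) / (m * n))


def edge_activation(profile: EdgePerturbationProfile,
                    network: FullyConnectedPathwayNetwork,
                    use_absolute_z: bool = False) -> float:
    """Edge-view activation: are real pathway edges enriched among the most
    perturbed edges of the fully connected network?

    Scores are the per-edge Z values (|Z| when ``use_absolute_z``); missing
    (NaN) for complete pathways with no background edges.
    """
    if profile.pathway_id != network.pathway_id:
        raise ValueError(
            f"profile pathway {profile.pathway_id!r} != network {network.pathway_id!r}")
    if profile.pairs != tuple(network.edges):
        raise ValueError("profile and network edge lists disagree")
    scores = np.abs(profile.z) if use_absolute_z else profile.z
    attention = np.asarray(network.attention_flags, dtype=bool)
    return auc_from_ranks(RankedInstance(scores=scores, attention=attention))


def node_activation(fc_profile: FoldChangeProfile, pathway: Pathway,
                    universe: GeneUniverse) -> float:
    """Node-view activation: are pathway genes enriched among the genes with
    the largest fold change across the pathway-gene universe?"""
    member = set(pathway.genes)
    if not member <= set(universe.genes):
        raise ValueError(f"pathway {pathway.id}: genes not contained in universe")
    if len(member) == len(universe.genes):
        raise ValueError(f"pathway {pathway.id}: universe equals pathway genes "
                         "(no background)")
    if fc_profile.genes != universe.genes:
        raise ValueError("fold-change profile does not cover the universe")
    attention = np.fromiter((g in member for g in universe.genes),
                            dtype=bool, count=len(universe.genes))
    return auc_from_ranks(RankedInstance(scores=fc_profile.fc, attention=attention))


def compute_pass_matrix(expr: ExpressionMatrix, labels: SampleLabels,
                        pathways: Sequence[Pathway],
                        use_absolute_z: bool = False) -> PassMatrix:
    """Full PASS matrix: two activation features per pathway, one column per
    disease sample.

    Each column depends only on that disease sample and the reference set,
    so samples can be scored independently (single-sample locality).
    """
    labels.validate_against(expr)
    ref_ids = labels.reference_ids
    if len(ref_ids) < 3:
        raise ValueError(f"need >= 3 reference samples, got {len(ref_ids)}")
    disease_ids = labels.disease_ids
    if not disease_ids:
        raise ValueError("no disease samples to score")
    if not pathways:
        raise ValueError("no pathways")

    networks = [build_fully_connected(pw) for pw in pathways]
    universe = gene_universe(pathways)

    feature_ids = [f"{pw.id}|{view}" for pw in pathways for view in ("edge", "node")]
    values = np.empty((len(feature_ids), len(disease_ids)))
    n_complete = sum(1 for net in networks if net.n_background == 0)
    if n_complete:
        logger.warning("%d complete pathway(s): edge feature will be missing",
                       n_complete)

    for j, sample in enumerate(disease_ids):
        fc = fold_changes(expr, ref_ids, sample, universe)
        for k, (pw, net) in enumerate(zip(pathways, networks)):
            profile = edge_perturbations(expr, ref_ids, sample, net)
            values[2 * k, j] = edge_activation(profile, net, use_absolute_z)
            values[2 * k + 1, j] = node_activation(fc, pw, universe)

    data = pd.DataFrame(values, index=feature_ids, columns=disease_ids)
    return PassMatrix(data=data)


def write_pass_matrix(pm: PassMatrix, path) -> None:
    """Write the PASS matrix TSV (missing values as ``NA``), deterministically."""
    pm.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id",
                   float_format="%.12g")


def read_pass_matrix(path) -> PassMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return PassMatrix(data=df.astype(float))
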