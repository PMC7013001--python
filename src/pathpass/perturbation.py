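"""Single-sample perturbation statistics.

For one disease sample against a healthy reference cohort of size n this
module computes, per gene pair, the reference Pearson correlation PCC_n,
the augmented correlation PCC_{n+1} after appending the disease sample, the
perturbation dPCC = PCC_{n+1} - PCC_n, and its significance

    Z = dPCC / ((1 - PCC_n^2) / (n - 1)),

the sample-specific network (SSN) Z-statistic: the sampling scale of a
correlation perturbation caused by one added observation shrinks both with
the cohort size and with the strength of the reference correlation. Per
gene, the difference between the disease sample and the reference cohort is
the fold change FC = b / a_mean (disease value over reference mean).

Degenerate gene pairs (zero variance in the reference or augmented set)
carry no correlation signal: their PCC is defined as 0 and their Z forced
to 0, so they fall mid-ranking instead of dominating either tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pathways import Edge, FullyConnectedPathwayNetwork, GeneUniverse

logger = logging.getLogger(__name__)

#: |PCC_n| = 1 is clamped to this before the Z denominator to avoid a zero
#: division while preserving the sign and extremeness of the correlation.
PCC_CLAMP = 1.0 - 1e-8


@dataclass(frozen=True)
class EdgePerturbationProfile:
    """Per-edge perturbation statistics of one disease sample on one pathway."""

    sample_id: str
    pathway_id: str
    pairs: tuple[Edge, ...]
    pcc_ref: np.ndarray
    pcc_aug: np.ndarray
    delta: np.ndarray
    z: np.ndarray
    degenerate: np.ndarray  # bool; implies z == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pathway_id": self.pathway_id,
            "geneA": [a for a, _ in self.pairs],
            "geneB": [b for _, b in self.pairs],
            "pcc_ref": self.pcc_ref,
            "pcc_aug": self.pcc_aug,
            "delta": self.delta,
            "z": self.z,
            "degenerate": self.degenerate,
        })


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-gene fold change of one disease sample vs the reference mean."""

    sample_id: str
    genes: tuple[str, ...]
    fc: np.ndarray


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two equal-length vectors (>= 2 points).

    Returns 0.0 when either vector has zero variance (degenerate pair);
    output is clipped into [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need 1-D vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def delta_pcc_z(pcc_ref: float, delta: float, n_ref: int) -> float:
    """Z-statistic of a correlation perturbation dPCC.

    z = delta / ((1 - pcc_ref^2) / (n_ref - 1)); |pcc_ref| = 1 is clamped
    to sign(pcc_ref) * (1 - 1e-8) so the denominator never vanishes.
    """
    if n_ref < 2:
        raise ValueError(f"need n_ref >= 2, got {n_ref}")
    if abs(pcc_ref) > 1.0:
        raise ValueError(f"|pcc_ref| must be <= 1, got {pcc_ref}")
    r = np.clip(pcc_ref, -PCC_CLAMP, PCC_CLAMP)
    return float(delta * (n_ref - 1) / (1.0 - r * r))


def _corr_with_degenerate(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlation matrix with a zero-variance row mask.

    Degenerate rows yield 0 correlation with everything.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    return np.clip(corr, -1.0, 1.0), degenerate


def edge_perturbations(expr: ExpressionMatrix, reference_ids: Iterable[str],
                       disease_sample_id: str,
                       network: FullyConnectedPathwayNetwork,
                       ) -> EdgePerturbationProfile:
    """Perturbation statistics of one disease sample on one pathway network.

    PCC_n is computed over the reference columns, PCC_{n+1} over reference
    plus the disease sample; Z uses n = number of reference samples.
    """
    ref_ids = sorted(set(reference_ids))  # canonical order: results do not
    # depend on how the caller happened to order the reference cohort
    if len(ref_ids) < 3:
        raise ValueError(f"need >= 3 reference samples, got {len(ref_ids)}")
    if disease_sample_id in ref_ids:
        raise ValueError(f"disease sample {disease_sample_id!r} is in the reference set")
    sample_set = set(expr.sample_ids)
    missing = [s for s in [*ref_ids, disease_sample_id] if s not in sample_set]
    if missing:
        raise ValueError(f"samples absent from expression matrix: {missing}")
    missing_genes = [g for g in network.nodes if g not in set(expr.gene_ids)]
    if missing_genes:
        raise ValueError(f"network genes absent from matrix: {missing_genes[:5]}")

    sub = expr.data.loc[list(network.nodes)]
    ref = sub[ref_ids].to_numpy(dtype=float)
    aug = sub[[*ref_ids, disease_sample_id]].to_numpy(dtype=float)

    corr_ref, deg_ref = _corr_with_degenerate(ref)
    corr_aug, deg_aug = _corr_with_degenerate(aug)

    index = {g: i for i, g in enumerate(network.nodes)}
    n_ref = len(ref_ids)
    pairs = tuple(network.edges)
    ii = np.array([index[a] for a, _ in pairs])
    jj = np.array([index[b] for _, b in pairs])

    pcc_ref = corr_ref[ii, jj]
    pcc_aug = corr_aug[ii, jj]
    delta = pcc_aug - pcc_ref
    degenerate = deg_ref[ii] | deg_ref[jj] | deg_aug[ii] | deg_aug[jj]

    r = np.clip(pcc_ref, -PCC_CLAMP, PCC_CLAMP)
    z = delta * (n_ref - 1) / (1.0 - r * r)
    z[degenerate] = 0.0

    return EdgePerturbationProfile(
        sample_id=disease_sample_id, pathway_id=network.pathway_id,
        pairs=pairs, pcc_ref=pcc_ref, pcc_aug=pcc_aug, delta=delta, z=z,
        degenerate=degenerate,
    )


def fold_changes(expr: ExpressionMatrix, reference_ids: Iterable[str],
                 disease_sample_id: str, universe: GeneUniverse,
                 pseudocount: float | None = None) -> FoldChangeProfile:
    """Fold change of each universe gene: disease value / reference mean.

    A reference mean of exactly zero raises unless ``pseudocount`` is given,
    in which case it is added to both numerator and denominator.
    """
    genes = list(universe.genes)
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"universe genes absent from matrix: {missing[:5]}")
    ref_ids = sorted(set(reference_ids))
    sub = expr.data.loc[genes]
    ref_mean = sub[ref_ids].to_numpy(dtype=float).mean(axis=1)
    b = sub[disease_sample_id].to_numpy(dtype=float)
    if pseudocount is not None:
        ref_mean = ref_mean + pseudocount
        b = b + pseudocount
    zero = np.flatnonzero(ref_mean == 0.0)
    if zero.size:
        raise ValueError(
            f"reference mean is zero for gene(s) {[genes[i] for i in zero[:5]]}; "
            "set a pseudocount to proceed")
    return FoldChangeProfile(sample_id=disease_sample_id, genes=tuple(genes),
                             fc=b / ref_mean)
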