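import numpy as np
import pytest

from pathpass import compute_pass_matrix
from pathpass.synthetic import SimConfig, generate_cohort, generate_pathways


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 6 pathways, 2 perturbed per class."""
    return SimConfig(
        n_reference=10, n_class_a=8, n_class_b=8,
        n_pathways=6, genes_per_pathway=(4, 6), edges_per_pathway=(3, 6),
        perturbed_pathways_a=(0, 1), perturbed_pathways_b=(2, 3),
        mean_shift=2.0, correlation_rewire=0.8, noise_sd=0.2,
        seed=7, n_background_genes=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    pathways = generate_pathways(small_config)
    expr, labels, truth = generate_cohort(pathways, small_config)
    return pathways, expr, labels, truth


@pytest.fixture(scope="session")
def small_pass(small_cohort):
    pathways, expr, labels, truth = small_cohort
    return compute_pass_matrix(expr, labels, pathways)


def pair_count_auc(scores: np.ndarray, attention: np.ndarray) -> float:
    """Mann-Whitney pair-counting oracle: fraction of (attention, background)
    pairs in which the attention item scores higher, ties counting 1/2."""
    att = scores[attention]
    bg = scores[~attention]
    wins = (att[:, None] > bg[None, :]).sum()
    ties = (att[:, None] == bg[None, :]).sum()
    return (wins + 0.5 * ties) / (att.size * bg.size)
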