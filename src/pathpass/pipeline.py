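"""End-to-end orchestration: score, classify, diff, enrich, simulate.

Each run writes its artifacts plus a machine-readable ``provenance.json``
(config echo, package version, pathway/feature counts) sufficient to re-run
the command; outputs are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aucpath import PassMatrix, compute_pass_matrix, read_pass_matrix, write_pass_matrix
from .differential import (dag_enrichment, differential_across_datasets,
                           results_to_frame, ttest_features)
from .evaluation import CvConfig, repeated_cv, write_cv_result
from .expression import ExpressionMatrix, Label, SampleLabels, read_expression, read_labels
from .pathways import (Pathway, filter_pathways, gene_universe, parse_kgml_directory,
                       parse_pathway_files, pathways_to_json)
from .synthetic import SimConfig, generate_cohort, generate_pathways, write_fixture

logger = logging.getLogger(__name__)

# default label strings, matching what synthetic.write_fixture emits
LABEL_NAMES = {"class_a": "class_a", "class_b": "class_b",
               "reference": "reference"}


@dataclass
class RunConfig:
    """Paths and flags shared by the pipeline commands."""

    expression_path: Path | None = None
    labels_path: Path | None = None
    gmt_path: Path | None = None
    edges_path: Path | None = None
    kgml_dir: Path | None = None
    dag_path: Path | None = None
    pass_matrix_path: Path | None = None
    out_dir: Path = Path("pathpass_out")
    class_a_name: str = LABEL_NAMES["class_a"]
    class_b_name: str = LABEL_NAMES["class_b"]
    reference_name: str = LABEL_NAMES["reference"]
    use_absolute_z: bool = False
    input_log2: bool = False
    ttest_variant: str = "welch"
    alpha: float = 0.05
    n_folds: int = 3
    n_repeats: int = 500
    n_trees: int = 500
    seed: int = 0

    def check_paths(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise ValueError(f"missing required input: {name}")
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such path {path}")


def _provenance(config: RunConfig, stage: str, extra: dict) -> dict:
    echo = {k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()}
    return {"tool": "pathpass", "version": __version__, "stage": stage,
            "config": echo, **extra}


def _load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, SampleLabels,
                                             list[Pathway], list[Pathway]]:
    config.check_paths("expression_path", "labels_path")
    expr = read_expression(config.expression_path)
    if config.input_log2:
        expr = ExpressionMatrix(data=np.power(2.0, expr.data))
    labels = read_labels(config.labels_path, config.class_a_name,
                         config.class_b_name, config.reference_name)
    labels.validate_against(expr)
    if config.kgml_dir is not None:
        config.check_paths("kgml_dir")
        raw = parse_kgml_directory(config.kgml_dir)
    else:
        config.check_paths("gmt_path", "edges_path")
        raw = parse_pathway_files(config.gmt_path, config.edges_path)
    kept = filter_pathways(raw, expr.gene_ids)
    if not kept:
        raise ValueError("no pathways survive filtering against the expression genes")
    return expr, labels, raw, kept


def run_score(config: RunConfig) -> PassMatrix:
    """Compute and write the PASS matrix plus provenance."""
    expr, labels, raw, kept = _load_inputs(config)
    pm = compute_pass_matrix(expr, labels, kept, config.use_absolute_z)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pass_matrix(pm, out / "pass_matrix.tsv")
    (out / "pathways_filtered.json").write_text(pathways_to_json(kept))
    prov = _provenance(config, "score", {
        "n_pathways_input": len(raw), "n_pathways_retained": len(kept),
        "n_universe_genes": len(gene_universe(kept)),
        "n_features": len(pm.feature_ids), "n_disease_samples": len(pm.sample_ids),
        "n_missing_edge_features": int(pm.data.isna().any(axis=1).sum()),
    })
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    return pm


def _pass_and_labels(config: RunConfig) -> tuple[PassMatrix, SampleLabels]:
    if config.pass_matrix_path is not None:
        config.check_paths("pass_matrix_path", "labels_path")
        pm = read_pass_matrix(config.pass_matrix_path)
        labels = read_labels(config.labels_path, config.class_a_name,
                             config.class_b_name, config.reference_name)
    else:
        pm = run_score(config)
        labels = read_labels(config.labels_path, config.class_a_name,
                             config.class_b_name, config.reference_name)
    return pm, labels


def run_classify(config: RunConfig):
    """Repeated stratified CV of class A vs class B on PASS features."""
    pm, labels = _pass_and_labels(config)
    cv_config = CvConfig(n_folds=config.n_folds, n_repeats=config.n_repeats,
                         n_trees=config.n_trees, base_seed=config.seed)
    result = repeated_cv(pm, labels, cv_config)
    out = Path(config.out_dir)
    write_cv_result(result, out)
    prov = _provenance(config, "classify", {"mean_auc": result.mean_auc})
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    return result


def run_diff(config: RunConfig) -> pd.DataFrame:
    """Two-sample t-test of every PASS feature between the disease classes."""
    pm, labels = _pass_and_labels(config)
    results = ttest_features(pm, labels, config.ttest_variant)
    frame = results_to_frame(results).sort_values("p", kind="mergesort")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "differential_features.tsv", sep="\t", index=False,
                 float_format="%.12g")
    sig = differential_across_datasets([results], config.alpha)
    prov = _provenance(config, "diff", {
        "n_features_tested": len(results),
        "n_significant": len(sig), "alpha": config.alpha})
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    return frame


def run_enrich(config: RunConfig, differential_tsv: Path | None = None) -> dict:
    """Hypergeometric enrichment of disease-associated genes (one per line)."""
    config.check_paths("dag_path", "gmt_path", "edges_path")
    dag_genes = [line.strip() for line in Path(config.dag_path).read_text().splitlines()
                 if line.strip()]
    if not dag_genes:
        raise ValueError(f"{config.dag_path}: empty disease-gene list")
    pathways = parse_pathway_files(config.gmt_path, config.edges_path)
    if differential_tsv is None:
        differential_tsv = Path(config.out_dir) / "differential_features.tsv"
    diff = pd.read_csv(differential_tsv, sep="\t")
    sig_features = diff.loc[diff["p"] < config.alpha, "feature_id"].tolist()
    counts = dag_enrichment(pathways, dag_genes, sig_features)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {"N": counts.N, "M": counts.M, "n": counts.n, "m": counts.m,
           "p_value": counts.p_value, "neg_log10_p": counts.neg_log10_p,
           "alpha": config.alpha, "n_differential_features": len(sig_features)}
    (out / "enrichment.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def run_simulate(sim_config: SimConfig, out_dir: Path) -> dict[str, Path]:
    """Generate a synthetic cohort fixture on disk."""
    pathways = generate_pathways(sim_config)
    expr, labels, truth = generate_cohort(pathways, sim_config)
    paths = write_fixture(out_dir, expr, labels, pathways, truth)
    prov = {"tool": "pathpass", "version": __version__, "stage": "simulate",
            "config": dataclasses.asdict(sim_config)}
    (Path(out_dir) / "provenance.json").write_text(
        json.dumps(prov, indent=1, sort_keys=True))
    return paths
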