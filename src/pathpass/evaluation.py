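"""Classification performance of PASS features.

Disease class A vs class B is evaluated with a random forest under repeated
stratified k-fold cross-validation: each repeat draws fresh stratified folds,
records out-of-fold predicted probabilities for every sample, and the
per-repeat AUC is computed from those pooled out-of-fold scores (robust to
tiny folds, unlike averaging per-fold AUCs). The aggregate ROC pools the
scores of all repeats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .aucpath import PassMatrix
from .expression import Label, SampleLabels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvConfig:
    """Repeated stratified cross-validation settings.

    Defaults follow the evaluation protocol: 3 folds (small cohorts), 500
    repeats, a 500-tree forest, class A as the positive class.
    """

    n_folds: int = 3
    n_repeats: int = 500
    n_trees: int = 500
    base_seed: int = 0
    positive_class: Label = Label.CLASS_A

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repeats < 1 or self.n_trees < 1:
            raise ValueError("n_repeats and n_trees must be positive")
        if self.positive_class is Label.REFERENCE:
            raise ValueError("positive class must be a disease class")


@dataclass(frozen=True)
class CvResult:
    """Per-repeat AUCs, pooled out-of-fold score table, and aggregate ROC."""

    per_repeat_auc: np.ndarray
    oof_scores: pd.DataFrame  # columns: repeat, sample_id, y_true, score
    config: CvConfig

    @property
    def mean_auc(self) -> float:
        return float(self.per_repeat_auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.per_repeat_auc.std(ddof=1)) if self.per_repeat_auc.size > 1 else 0.0


def _design_matrix(pass_matrix: PassMatrix, labels: SampleLabels,
                   positive_class: Label) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Samples x features design with missing-value features dropped."""
    df = pass_matrix.data
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d feature(s) with missing values before CV", n_missing)
        df = df.dropna(axis=0)
    if df.empty:
        raise ValueError("no complete features available for classification")
    disease = [s for s in df.columns
               if labels.mapping.get(s) in (Label.CLASS_A, Label.CLASS_B)]
    if not disease:
        raise ValueError("no labelled disease samples in the PASS matrix")
    y = np.array([1 if labels.mapping[s] is positive_class else 0 for s in disease])
    if len(set(y)) < 2:
        raise ValueError("need samples from both disease classes")
    X = df[disease].to_numpy(dtype=float).T
    return X, y, disease


def repeated_cv(pass_matrix: PassMatrix, labels: SampleLabels,
                config: CvConfig | None = None) -> CvResult:
    """Repeated stratified k-fold random-forest cross-validation.

    Fold assignment and the forest are re-seeded per repeat from
    ``base_seed + repeat`` so the whole procedure is reproducible.
    """
    config = config or CvConfig()
    X, y, sample_ids = _design_matrix(pass_matrix, labels, config.positive_class)
    class_counts = np.bincount(y)
    if class_counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples < {config.n_folds} folds; "
            "use fewer folds")

    per_repeat = np.empty(config.n_repeats)
    rows: list[tuple[int, str, int, float]] = []
    for r in range(config.n_repeats):
        seed = config.base_seed + r
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        oof = np.empty(len(y))
        for train, test in skf.split(X, y):
            if len(set(y[train])) < 2:
                raise ValueError("a training split lost a class; use fewer folds")
            clf = RandomForestClassifier(n_estimators=config.n_trees,
                                         random_state=seed, n_jobs=1)
            clf.fit(X[train], y[train])
            pos = list(clf.classes_).index(1)
            oof[test] = clf.predict_proba(X[test])[:, pos]
        per_repeat[r] = roc_auc_score(y, oof)
        rows.extend((r, s, int(t), float(p)) for s, t, p in zip(sample_ids, y, oof))

    oof_df = pd.DataFrame(rows, columns=["repeat", "sample_id", "y_true", "score"])
    return CvResult(per_repeat_auc=per_repeat, oof_scores=oof_df, config=config)


def aggregate_roc(result: CvResult) -> np.ndarray:
    """Pooled ROC over all (repeat, sample) out-of-fold scores.

    Returns an array of (false positive rate, true positive rate) rows,
    monotone in both coordinates, including (0,0) and (1,1).
    """
    if result.oof_scores.empty:
        raise ValueError("empty out-of-fold score table")
    fpr, tpr, _ = roc_curve(result.oof_scores["y_true"], result.oof_scores["score"])
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def write_cv_result(result: CvResult, out_dir: str | Path) -> None:
    """Write summary JSON, per-repeat AUC TSV and aggregate ROC TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "mean_auc": result.mean_auc,
        "sd_auc": result.sd_auc,
        "n_repeats": result.config.n_repeats,
        "n_folds": result.config.n_folds,
        "n_trees": result.config.n_trees,
        "base_seed": result.config.base_seed,
        "positive_class": result.config.positive_class.value,
    }
    (out / "cv_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    pd.DataFrame({"repeat": np.arange(result.per_repeat_auc.size),
                  "auc": result.per_repeat_auc}).to_csv(
        out / "cv_per_repeat_auc.tsv", sep="\t", index=False, float_format="%.12g")
    roc = aggregate_roc(result)
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(
        out / "cv_roc_points.tsv", sep="\t", index=False, float_format="%.12g")
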