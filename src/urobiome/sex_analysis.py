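"""Sex-differential taxa and random-forest sex prediction.

Marker discovery delegates to the two-class LDA effect-size ranking; the
classifier is a stratified-split random forest reported with a
Mann-Whitney AUC and normalized Gini importances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cohort_io import TaxonProfileTable
from .urotyping import Marker, lda_effect_scores


def sex_differential(
    table: TaxonProfileTable | np.ndarray,
    sex_labels,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> list[Marker]:
    """Two-class LDA effect-size markers labeled by the enriched sex."""
    labels = np.asarray(sex_labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("sex_differential needs exactly two classes")
    return lda_effect_scores(
        table,
        labels,
        alpha=alpha,
        lda_threshold=lda_threshold,
        n_boot=n_boot,
        seed=seed,
        feature_ids=feature_ids,
    )


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney U) formulation, ties at half weight."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ClassifierReport:
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    train_fraction: float
    stratified: bool
    n_trees: int
    seed: int
    importances: list  # ranked (feature, gini_importance)
    n_train: int
    n_test: int


def _roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ROC curve with one point per distinct threshold (ties grouped), so
    the trapezoid under it equals the half-tie-weight rank AUC exactly."""
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    distinct = np.where(np.diff(scores))[0]
    cut = np.concatenate([distinct, [len(scores) - 1]])
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return np.column_stack([fpr, tpr])


def trapezoid_auc(roc_points: np.ndarray) -> float:
    fpr, tpr = roc_points[:, 0], roc_points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def train_sex_classifier(
    features: np.ndarray,
    labels,
    feature_ids: list[str] | None = None,
    train_fraction: float = 0.7,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified split, random forest, held-out Mann-Whitney AUC.

    Gini importances are the forest's normalized mean impurity decreases,
    returned ranked. Hyperparameters beyond tree count follow library
    defaults (sqrt(p) features per split, unlimited depth).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    y_bin = y == classes[1]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x,
        y_bin,
        train_size=train_fraction,
        stratify=y_bin,
        random_state=seed,
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("a class is absent from the train or test split")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x_tr, y_tr)
    scores = forest.predict_proba(x_te)[:, 1]
    auc = mann_whitney_auc(scores, y_te)
    names = feature_ids or [f"f{j}" for j in range(x.shape[1])]
    imp = forest.feature_importances_
    ranked = sorted(zip(names, imp.tolist()), key=lambda t: -t[1])
    # tie-free ROC for plotting; AUC above is the rank form
    roc = _roc_points(scores, y_te)
    return ClassifierReport(
        auc=auc,
        roc_points=roc,
        train_fraction=train_fraction,
        stratified=True,
        n_trees=n_trees,
        seed=seed,
        importances=ranked,
        n_train=len(y_tr),
        n_test=len(y_te),
    )
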