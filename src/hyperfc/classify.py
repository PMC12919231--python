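"""Binary classification on significant-hyperedge weights.

Protocol: stratified 80/20 train-test split, random-forest hyperparameter
tuning by 5-fold cross-validated accuracy on the training portion, refit
on the full training set, then hold-out accuracy / class-weighted
precision / recall / F1 plus impurity-based feature importances. The
point is not state-of-the-art classification but a standardised probe of
how much group signal each weighting scheme puts into the hyperedge
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .panels import ContractError
from .weighting import WeightTable

__all__ = [
    "ClassifierReport",
    "DEFAULT_GRID",
    "split_train_test",
    "tune_and_fit",
    "evaluate",
    "feature_importance",
    "run_classification",
]

#: Declared hyperparameter grid for the random forest.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, None],
    "min_samples_split": [2, 5, 10],
}


@dataclass
class ClassifierReport:
    """Hold-out evaluation of one binary task."""

    task: tuple[str, str]
    metrics: dict[str, float]
    best_hyperparameters: dict
    feature_importance: pd.Series  # hyperedge_id -> importance, sorted desc
    split_seed: int
    n_train: int = 0
    n_test: int = 0


def split_train_test(
    features: pd.DataFrame, labels: pd.Series, fraction: float = 0.2, seed: int = 0
):
    """Stratified hold-out split preserving class proportions.

    Every class needs at least 5 members so that both the 80/20 split and
    the subsequent 5-fold CV keep each class represented everywhere.
    """
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ContractError(f"expected exactly 2 classes, got {list(counts.index)}")
    if counts.min() < 5:
        raise ContractError(
            f"class {counts.idxmin()!r} has {counts.min()} members; need >= 5 to stratify"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=fraction, stratify=labels, random_state=seed
    )
    return (X_tr, y_tr), (X_te, y_te)


def tune_and_fit(
    train: tuple[pd.DataFrame, pd.Series],
    folds: int = 5,
    seed: int = 0,
    grid: dict[str, list] | None = None,
):
    """Grid-search a random forest by mean CV accuracy and refit on train."""
    X_tr, y_tr = train
    if grid is None:
        grid = DEFAULT_GRID
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        param_grid=grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    return search.best_estimator_, dict(search.best_params_)


def evaluate(model, test: tuple[pd.DataFrame, pd.Series]) -> dict[str, float]:
    """Hold-out accuracy and class-weighted precision/recall/F1."""
    X_te, y_te = test
    if len(y_te) == 0:
        raise ContractError("empty test set")
    pred = model.predict(X_te)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_te, pred, average="weighted", zero_division=0
    )
    return {
        "accuracy": float(accuracy_score(y_te, pred)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def feature_importance(model, feature_names: list[str]) -> pd.Series:
    """Impurity-based importances normalised to sum 1, sorted descending."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=feature_names).sort_values(ascending=False)


def run_classification(
    table: WeightTable,
    task: tuple[str, str],
    significant_ids: list[str] | None = None,
    seed: int = 0,
    fraction: float = 0.2,
    folds: int = 5,
    grid: dict[str, list] | None = None,
) -> ClassifierReport:
    """Full protocol for one binary task on one weight table.

    ``significant_ids`` restricts the features to the hyperedges the
    statistical battery flagged (the protocol's feature-selection step);
    None uses all hyperedges.
    """
    mask = table.group_labels.isin(task)
    features = table.values.loc[mask]
    if significant_ids is not None:
        if not significant_ids:
            raise ContractError("no significant hyperedges to classify on")
        features = features[significant_ids]
    labels = table.group_labels.loc[mask]
    train, test = split_train_test(features, labels, fraction=fraction, seed=seed)
    model, best = tune_and_fit(train, folds=folds, seed=seed, grid=grid)
    metrics = evaluate(model, test)
    importance = feature_importance(model, list(features.columns))
    return ClassifierReport(
        task=task,
        metrics=metrics,
        best_hyperparameters=best,
        feature_importance=importance,
        split_seed=seed,
        n_train=len(train[1]),
        n_test=len(test[1]),
    )
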