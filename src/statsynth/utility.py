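"""Utility assessment: TRTR vs TSTR with four fixed classifiers.

Usefulness of a synthetic table is judged by training downstream
classifiers to predict the outcome column and comparing

* TRTR — train on a stratified real training split, test on the real
  held-out split;
* TSTR — train on the full synthetic table, test on the *same* real
  held-out split.

(TRTS is deliberately not part of the protocol.)  Four classifiers with
fixed hyperparameters are used: random forest, k-nearest neighbours,
decision tree and a multilayer perceptron.  For each, accuracy and
class-weighted precision/recall/F1 are reported along with the absolute
TRTR-TSTR gap; the table is labelled "Excellent" when every gap is below
0.4 (with an artifact-convention extension: "Good" below 0.8, else
"Poor").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    f1_score,
)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .schema import Table, TableSchema, ValidationError

__all__ = [
    "ModelSpec",
    "UtilityReport",
    "split_real",
    "default_model_specs",
    "run_tstr_trtr",
    "utility_label",
    "UTILITY_THRESHOLD",
    "METRICS",
]

UTILITY_THRESHOLD = 0.4
METRICS = ("accuracy", "precision", "recall", "f1")
EXCELLENT, GOOD, POOR = "Excellent", "Good", "Poor"


@dataclass(frozen=True)
class ModelSpec:
    kind: str                      # random_forest | knn | decision_tree | mlp
    hyperparameters: tuple[tuple[str, object], ...]
    random_state: int | None = None

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "random_forest":
            return RandomForestClassifier(random_state=self.random_state, **hp)
        if self.kind == "knn":
            return KNeighborsClassifier(**hp)
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(random_state=self.random_state, **hp)
        if self.kind == "mlp":
            return MLPClassifier(random_state=self.random_state, **hp)
        raise ValidationError(f"unknown model kind {self.kind!r}")


def default_model_specs() -> list[ModelSpec]:
    """The four fixed classifier configurations used by the protocol."""
    return [
        ModelSpec("random_forest",
                  (("n_estimators", 88), ("max_depth", 11),
                   ("criterion", "gini")), random_state=28),
        ModelSpec("knn", (("n_neighbors", 4), ("metric", "cosine"))),
        ModelSpec("decision_tree",
                  (("max_depth", 7), ("max_features", 2)), random_state=27),
        # training stops once the loss improves by <= 1e-4 for 10
        # consecutive epochs (tol / n_iter_no_change), capped at 30 epochs
        ModelSpec("mlp",
                  (("hidden_layer_sizes", (32, 128, 256)), ("max_iter", 30),
                   ("tol", 1e-4), ("n_iter_no_change", 10)), random_state=9),
    ]


@dataclass
class UtilityReport:
    trtr: dict[str, dict[str, float]]        # model kind -> metric -> value
    tstr: dict[str, dict[str, float]]
    differences: dict[str, dict[str, float]]  # |TRTR - TSTR|
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for kind in self.trtr:
            for metric in METRICS:
                rows.append({
                    "model": kind, "metric": metric,
                    "trtr": self.trtr[kind][metric],
                    "tstr": self.tstr[kind][metric],
                    "abs_difference": self.differences[kind][metric],
                })
        return pd.DataFrame(rows)

    @property
    def max_difference(self) -> float:
        return max(v for d in self.differences.values() for v in d.values())


def split_real(table: Table, train_fraction: float = 0.8,
               seed: int = 0) -> tuple[Table, Table]:
    """Stratified train/test split on the outcome column.

    Train size is floor(train_fraction * n_rows); both classes appear on
    both sides.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("split_real: train_fraction must be in (0, 1)")
    y = table.outcome
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("split_real: a class has fewer than 2 rows")
    idx_train, idx_test = train_test_split(
        np.arange(table.n_rows), train_size=train_fraction,
        stratify=y, random_state=seed)
    return (Table(table.values[idx_train], table.schema),
            Table(table.values[idx_test], table.schema))


def _xy(table: Table) -> tuple[np.ndarray, np.ndarray]:
    oj = table.schema.outcome_index
    X = np.delete(table.values, oj, axis=1)
    return X, table.values[:, oj]


def _score(model, X, y_true) -> dict[str, float]:
    y_pred = model.predict(X)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, average="weighted",
                                           zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, average="weighted",
                                     zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, average="weighted",
                             zero_division=0)),
    }


def run_tstr_trtr(real: Table, synth: Table,
                  specs: list[ModelSpec] | None = None,
                  split_seed: int = 0,
                  train_fraction: float = 0.8,
                  threshold: float = UTILITY_THRESHOLD) -> UtilityReport:
    """TRTR on a real split and TSTR on the same real test fold.

    TRTR fits each classifier on the real training split; TSTR fits the
    same configuration on the full synthetic table; both are scored on
    the identical real test split.
    """
    if real.schema.column_names != synth.schema.column_names:
        raise ValidationError("run_tstr_trtr: tables do not share a schema")
    if specs is None:
        specs = default_model_specs()
    real_train, real_test = split_real(real, train_fraction, seed=split_seed)
    Xtr_r, ytr_r = _xy(real_train)
    Xte, yte = _xy(real_test)
    Xtr_s, ytr_s = _xy(synth)
    if len(np.unique(ytr_r)) < 2 or len(np.unique(ytr_s)) < 2:
        raise ValidationError("run_tstr_trtr: single-class training set")

    trtr, tstr, diffs = {}, {}, {}
    for spec in specs:
        m1 = spec.build().fit(Xtr_r, ytr_r)
        trtr[spec.kind] = _score(m1, Xte, yte)
        m2 = spec.build().fit(Xtr_s, ytr_s)
        tstr[spec.kind] = _score(m2, Xte, yte)
        diffs[spec.kind] = {k: abs(trtr[spec.kind][k] - tstr[spec.kind][k])
                            for k in METRICS}
    report = UtilityReport(trtr=trtr, tstr=tstr, differences=diffs)
    report.label = utility_label(report, threshold)
    return report


def utility_label(report: UtilityReport,
                  threshold: float = UTILITY_THRESHOLD) -> str:
    """Excellent iff every |TRTR - TSTR| gap is strictly below ``threshold``.

    The Good/Poor extension (all gaps below twice the threshold -> Good)
    is an artifact convention, not part of the published rule.
    """
    if threshold <= 0:
        raise ValidationError("utility_label: threshold must be positive")
    worst = report.max_difference
    if worst < threshold:
        return EXCELLENT
    if worst < 2 * threshold:
        return GOOD
    return POOR
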