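"""Random-forest screening models with repeated leave-one-out validation.

Four fixed feature sets are evaluated. Model 1 uses the five parameters that
separate the groups (% whispered trials in the Replaced and Masked feedback
conditions, errors/s and reaction time in Reduced feedback, and rhythm
consistency in Normal feedback); Models 2 and 3 drop the Masked or Replaced
whispering percentage respectively to probe their redundancy, and Model 4
adds age to Model 2.

Each evaluation repeat runs full leave-one-out cross-validation (every
participant held out once), pools the held-out predictions into accuracy,
sensitivity and specificity (PD as the positive class), and repeats with
fresh forest randomness; reported metrics are means over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import config

MODEL_FEATURES: dict[int, list[str]] = {
    1: ["whis_RepF", "whis_MF", "SpErr_RedF", "RT_RedF", "RhyStrCons_NF"],
    2: ["whis_RepF", "SpErr_RedF", "RT_RedF", "RhyStrCons_NF"],
    3: ["whis_MF", "SpErr_RedF", "RT_RedF", "RhyStrCons_NF"],
    4: ["whis_RepF", "SpErr_RedF", "RT_RedF", "RhyStrCons_NF", "age"],
}


@dataclass(frozen=True)
class ModelSpec:
    """One feature set plus random-forest and evaluation settings."""

    model_id: int
    features: list[str] = field(default_factory=list)
    n_repeats: int = config.N_LOO_REPEATS
    n_estimators: int = config.RF_N_ESTIMATORS
    max_features: str | float | None = config.RF_MAX_FEATURES
    max_depth: int | None = None
    seed: int = 0

    def resolved_features(self) -> list[str]:
        if self.features:
            return list(self.features)
        if self.model_id not in MODEL_FEATURES:
            raise ValueError(f"unknown model_id {self.model_id}; supply features explicitly")
        return list(MODEL_FEATURES[self.model_id])


@dataclass(frozen=True)
class ClassifierReport:
    model_id: int
    features: list[str]
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float
    sensitivity_sd: float
    specificity_sd: float
    per_repeat: pd.DataFrame
    n_pd: int
    n_ctrl: int


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent; PD (=1) is positive.

    Sensitivity is the PD detection rate TP/(TP+FN) and specificity the
    control recognition rate TN/(TN+FP); both classes must appear in
    ``y_true`` for the metrics to be defined.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if np.unique(y_true).size < 2:
        raise ValueError("y_true must contain both classes")
    tp = np.count_nonzero((y_true == 1) & (y_pred == 1))
    tn = np.count_nonzero((y_true == 0) & (y_pred == 0))
    fn = np.count_nonzero((y_true == 1) & (y_pred == 0))
    fp = np.count_nonzero((y_true == 0) & (y_pred == 1))
    n = y_true.size
    return (
        100.0 * (tp + tn) / n,
        100.0 * tp / (tp + fn),
        100.0 * tn / (tn + fp),
    )


def _median_impute(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-median imputation with medians taken from the training fold only."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    train = np.where(np.isnan(train), med, train)
    test = np.where(np.isnan(test), med, test)
    return train, test


def loo_evaluate(table: pd.DataFrame, spec: ModelSpec) -> ClassifierReport:
    """Repeated leave-one-out evaluation of one random-forest model.

    For each repeat, every participant is predicted by a forest trained on
    all others (missing features median-imputed within the training fold),
    and the pooled predictions yield one accuracy/sensitivity/specificity
    triple; repeats differ only in the forest's internal randomness.
    Deterministic for a fixed ``spec.seed``.
    """
    features = spec.resolved_features()
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    y = (table["group"] == "PD").to_numpy(dtype=int)
    if np.unique(y).size < 2 or np.count_nonzero(y) < 2 or np.count_nonzero(1 - y) < 2:
        raise ValueError("need at least 2 participants per class")
    X = table[features].to_numpy(dtype=float)
    n = X.shape[0]

    ss = np.random.SeedSequence(spec.seed)
    repeat_seeds = ss.generate_state(spec.n_repeats)
    rows = []
    for rep, rep_seed in enumerate(repeat_seeds):
        rf_seed = int(rep_seed % (2**31 - 1))
        y_pred = np.empty(n, dtype=int)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_tr, X_te = _median_impute(X[mask], X[[i]])
            clf = RandomForestClassifier(
                n_estimators=spec.n_estimators,
                max_features=spec.max_features,
                max_depth=spec.max_depth,
                random_state=rf_seed,
                n_jobs=1,
            )
            clf.fit(X_tr, y[mask])
            y_pred[i] = clf.predict(X_te)[0]
        acc, sens, spc = confusion_metrics(y, y_pred)
        rows.append({"repeat": rep, "accuracy": acc, "sensitivity": sens, "specificity": spc})
    per_repeat = pd.DataFrame(rows)
    return ClassifierReport(
        model_id=spec.model_id,
        features=features,
        accuracy=float(per_repeat["accuracy"].mean()),
        sensitivity=float(per_repeat["sensitivity"].mean()),
        specificity=float(per_repeat["specificity"].mean()),
        accuracy_sd=float(per_repeat["accuracy"].std(ddof=0)),
        sensitivity_sd=float(per_repeat["sensitivity"].std(ddof=0)),
        specificity_sd=float(per_repeat["specificity"].std(ddof=0)),
        per_repeat=per_repeat,
        n_pd=int(np.count_nonzero(y)),
        n_ctrl=int(np.count_nonzero(1 - y)),
    )


def run_model_suite(
    table: pd.DataFrame, specs: Sequence[ModelSpec] | None = None
) -> tuple[list[ClassifierReport], pd.DataFrame]:
    """Evaluate a list of models (default: Models 1-4) and tabulate metrics."""
    if specs is None:
        specs = [ModelSpec(model_id=m, seed=m) for m in sorted(MODEL_FEATURES)]
    reports = [loo_evaluate(table, spec) for spec in specs]
    summary = pd.DataFrame(
        {
            "model": [r.model_id for r in reports],
            "features": [" + ".join(r.features) for r in reports],
            "accuracy": [round(r.accuracy, 1) for r in reports],
            "sensitivity": [round(r.sensitivity, 1) for r in reports],
            "specificity": [round(r.specificity, 1) for r in reports],
        }
    )
    return reports, summary
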