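"""Hierarchical classification metrics and cross-validation.

Predictions are leaf labels; evaluation can happen at any hierarchy level by
projecting both truth and prediction to their level-k dotted prefix, so a
prediction that misses the leaf but lands in the right subfamily is credited
at the subfamily level.

The per-class Matthews correlation coefficient (MCC) is the one-vs-rest
binary MCC, macro-averaged over classes; it is robust to the heavy class
imbalance typical of enzyme family data, where plain accuracy is not.  A
zero factor in the MCC denominator yields 0 by convention.  The generalized
multi-category MCC is available behind a flag (delegated to scikit-learn).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, matthews_corrcoef
from sklearn.model_selection import StratifiedKFold

from .hierarchy import LabelTree, project_to_level

__all__ = [
    "EvalReport",
    "accuracy",
    "mcc_binary",
    "confusion_table",
    "evaluate_at_level",
    "evaluate_labels",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Metrics at one hierarchy level, optionally with per-fold provenance."""

    level: int | None
    accuracy: float
    per_class_mcc: dict[str, float]
    macro_mcc: float
    macro_f1: float
    confusion: pd.DataFrame
    folds: list["EvalReport"] = field(default_factory=list)

    def summary(self) -> dict:
        out = {
            "level": self.level,
            "accuracy": self.accuracy,
            "macro_mcc": self.macro_mcc,
            "macro_f1": self.macro_f1,
            "per_class_mcc": dict(self.per_class_mcc),
        }
        if self.folds:
            for key in ("accuracy", "macro_mcc", "macro_f1"):
                vals = np.array([getattr(f, key) for f in self.folds])
                out[f"{key}_mean"] = float(vals.mean())
                out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out


def accuracy(truth: list[str], predictions: list[str]) -> float:
    """Fraction of exact matches."""
    if len(truth) != len(predictions):
        raise ValueError("truth and predictions differ in length")
    if not truth:
        raise ValueError("nothing to evaluate")
    return sum(t == p for t, p in zip(truth, predictions)) / len(truth)


def mcc_binary(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient of a 2x2 table:

        (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),

    with the 0-by-convention rule when any denominator factor vanishes.
    """
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    if tp + fp + fn + tn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("MCC denominator has a zero factor; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


def confusion_table(truth: list[str], predictions: list[str]) -> pd.DataFrame:
    """Square true-by-predicted count table over the union of observed labels."""
    labels = sorted(set(truth) | set(predictions))
    table = pd.crosstab(
        pd.Categorical(truth, categories=labels),
        pd.Categorical(predictions, categories=labels),
        dropna=False,
    )
    table.index.name = "true"
    table.columns.name = "predicted"
    return table


def evaluate_labels(
    truth: list[str],
    predictions: list[str],
    level: int | None = None,
    multiclass_mcc: bool = False,
) -> EvalReport:
    """Build an EvalReport from already-projected label lists."""
    conf = confusion_table(truth, predictions)
    total = conf.to_numpy().sum()
    acc = float(np.trace(conf.to_numpy())) / total
    per_class: dict[str, float] = {}
    for lab in conf.index:
        tp = int(conf.loc[lab, lab])
        fp = int(conf[lab].sum()) - tp
        fn = int(conf.loc[lab].sum()) - tp
        tn = int(total) - tp - fp - fn
        per_class[str(lab)] = mcc_binary(tp, fp, fn, tn)
    macro_mcc = (
        float(matthews_corrcoef(truth, predictions))
        if multiclass_mcc
        else float(np.mean(list(per_class.values())))
    )
    macro_f1 = float(
        f1_score(truth, predictions, labels=list(conf.index), average="macro",
                 zero_division=0)
    )
    return EvalReport(
        level=level,
        accuracy=acc,
        per_class_mcc=per_class,
        macro_mcc=macro_mcc,
        macro_f1=macro_f1,
        confusion=conf,
    )


def evaluate_at_level(
    truth_leaves: list[str],
    predicted_leaves: list[str],
    tree: LabelTree,
    level: int | None = None,
    multiclass_mcc: bool = False,
) -> EvalReport:
    """Project truth and prediction to a hierarchy level and score there.

    ``level=None`` evaluates at the leaf labels as given.
    """
    if len(truth_leaves) != len(predicted_leaves):
        raise ValueError("truth and predictions differ in length")
    if level is None:
        t, p = list(truth_leaves), list(predicted_leaves)
    else:
        t = [project_to_level(tree, lab, level) for lab in truth_leaves]
        p = [project_to_level(tree, lab, level) for lab in predicted_leaves]
    return evaluate_labels(t, p, level=level, multiclass_mcc=multiclass_mcc)


def cross_validate(
    X: np.ndarray,
    y: list[str],
    tree: LabelTree,
    trainer,
    folds: int = 10,
    seed: int = 0,
    level: int | None = None,
) -> EvalReport:
    """Stratified k-fold CV.  ``trainer(X_train, y_train) -> model`` where the
    model exposes ``predict(X) -> list[str]`` of leaf labels.

    Stratification is on leaf labels even when evaluating at a shallower
    level.  If the rarest class has fewer members than ``folds``, the fold
    count is reduced with a warning.  The aggregate report pools all
    out-of-fold predictions; per-fold reports (for the mean +/- sd
    presentation) ride along in ``.folds``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = list(y)
    min_class = int(min(np.unique(y, return_counts=True)[1]))
    eff = min(folds, min_class)
    if eff < folds:
        logger.warning(
            "smallest class has %d member(s); reducing to %d-fold CV", min_class, eff
        )
    if eff < 2:
        raise ValueError("cannot stratify: a class has a single member")
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    all_truth: list[str] = []
    all_pred: list[str] = []
    for tr, te in skf.split(X, y):
        model = trainer(X[tr], [y[i] for i in tr])
        pred = model.predict(X[te])
        t = [y[i] for i in te]
        fold_reports.append(evaluate_at_level(t, pred, tree, level=level))
        all_truth.extend(t)
        all_pred.extend(pred)
    report = evaluate_at_level(all_truth, all_pred, tree, level=level)
    report.folds = fold_reports
    return report
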