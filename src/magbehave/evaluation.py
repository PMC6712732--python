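"""Cross-validation schemes and confusion-matrix metrics.

Two evaluation protocols:

* STRAT — stratified ten-fold cross-validation, preserving the (skewed)
  behaviour proportions in every fold; fold confusion matrices are
  pooled before aggregate metrics are computed, which keeps rare-class
  metrics stable (running is ~1% of windows).  Per-fold reports are kept
  alongside.
* LOIO — leave-one-individual-out: all sessions of one individual are
  held out per fold, measuring robustness to inter-individual
  variability.  Sessions lacking any of the four behaviours are
  discarded first (they cannot train all three nodes); metrics are
  computed per held-out individual and summarised as mean ± SD (sample
  convention) across individuals.

Per-behaviour metrics are one-vs-rest: sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), specificity = TN/(TN+FP); overall accuracy is
the confusion-matrix trace over the total count.  Zero-denominator
ratios are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .classifier import HierarchyModel, predict, train_hierarchy
from .core import BEHAVIOURS, ValidationError

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "behaviour_metrics",
    "stratified_kfold_cv",
    "loio_cv",
]

logger = logging.getLogger(__name__)


def confusion_matrix(truth, pred, labels: tuple[str, ...] = BEHAVIOURS) -> np.ndarray:
    """Counts with rows = groundtruth class, columns = predicted class."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValidationError(
            f"truth/prediction length mismatch: {truth.shape} vs {pred.shape}")
    unknown = (set(truth.tolist()) | set(pred.tolist())) - set(labels)
    if unknown:
        raise ValidationError(f"labels outside the ethogram: {sorted(unknown)}")
    return _sk_confusion(truth, pred, labels=list(labels))


@dataclass
class EvalReport:
    """Confusion matrix, per-behaviour metrics and overall accuracy."""

    cm: np.ndarray  # (k, k) pooled counts
    labels: tuple[str, ...]
    per_class: pd.DataFrame  # index = behaviour; sensitivity/precision/specificity
    accuracy: float
    per_fold: list["EvalReport"] = field(default_factory=list)
    fold_names: list[str] = field(default_factory=list)
    discarded_sessions: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"overall accuracy: {self.accuracy:.4f}",
                 "confusion matrix (rows = truth):"]
        lines.append(pd.DataFrame(self.cm, index=self.labels,
                                  columns=self.labels).to_string())
        lines.append(self.per_class.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.fold_names:
            accs = [r.accuracy for r in self.per_fold]
            lines.append(f"folds ({len(accs)}): accuracy mean {np.mean(accs):.4f} "
                         f"± {np.std(accs, ddof=1):.4f}" if len(accs) > 1 else
                         f"folds: {accs}")
        if self.discarded_sessions:
            lines.append(f"discarded sessions: {self.discarded_sessions}")
        return "\n".join(lines)

    def fold_metric_stats(self) -> pd.DataFrame:
        """Mean ± SD of each metric across folds / held-out individuals."""
        if not self.per_fold:
            raise ValidationError("report has no per-fold breakdown")
        rows = {}
        for metric in ("sensitivity", "precision", "specificity"):
            vals = pd.concat([r.per_class[metric] for r in self.per_fold], axis=1)
            rows[(metric, "mean")] = vals.mean(axis=1)
            rows[(metric, "sd")] = vals.std(axis=1, ddof=1)
        out = pd.DataFrame(rows)
        accs = np.array([r.accuracy for r in self.per_fold])
        out.attrs["accuracy_mean"] = float(accs.mean())
        out.attrs["accuracy_sd"] = float(accs.std(ddof=1)) if len(accs) > 1 else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion_matrix": self.cm.tolist(),
            "accuracy": self.accuracy,
            "per_class": {m: self.per_class[m].to_dict()
                          for m in self.per_class.columns},
            "fold_names": list(self.fold_names),
            "fold_accuracies": [r.accuracy for r in self.per_fold],
            "discarded_sessions": list(self.discarded_sessions),
        }


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def behaviour_metrics(cm: np.ndarray,
                      labels: tuple[str, ...] = BEHAVIOURS) -> EvalReport:
    """One-vs-rest sensitivity/precision/specificity plus overall accuracy."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValidationError("confusion matrix is empty")
    rows = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[lab] = {
            "sensitivity": _ratio(tp, tp + fn, f"sensitivity({lab})"),
            "precision": _ratio(tp, tp + fp, f"precision({lab})"),
            "specificity": _ratio(tn, tn + fp, f"specificity({lab})"),
        }
    per_class = pd.DataFrame(rows).T
    return EvalReport(cm=cm, labels=tuple(labels), per_class=per_class,
                      accuracy=float(np.trace(cm) / total))


def _evaluate_split(train_fm: pd.DataFrame, test_fm: pd.DataFrame,
                    selected_features: dict[str, str], C: float) -> np.ndarray:
    model = train_hierarchy(train_fm, selected_features, C=C)
    return confusion_matrix(test_fm["label"].to_numpy(), predict(model, test_fm))


def stratified_kfold_cv(fm: pd.DataFrame, selected_features: dict[str, str],
                        k: int = 10, seed: int | None = 0,
                        C: float = 1.0) -> EvalReport:
    """Stratified k-fold cross-validation with the full per-fold refit.

    Every window is tested exactly once; node standardisation and SVM
    training are redone from scratch on each fold's training split.
    Class counts per fold differ by at most one (stratification).
    """
    labels = fm["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValidationError(
            f"classes with fewer than k={k} windows: {small.to_dict()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports, fold_names = [], []
    pooled = np.zeros((len(BEHAVIOURS), len(BEHAVIOURS)), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(fm)), labels.astype(str))):
        cm = _evaluate_split(fm.iloc[tr], fm.iloc[te], selected_features, C)
        pooled += cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fold_reports.append(behaviour_metrics(cm))
        fold_names.append(f"fold{fold}")
    report = behaviour_metrics(pooled)
    report.per_fold = fold_reports
    report.fold_names = fold_names
    return report


def loio_cv(fm: pd.DataFrame, selected_features: dict[str, str],
            C: float = 1.0) -> EvalReport:
    """Leave-one-individual-out cross-validation.

    Sessions missing any of the four behaviours are discarded (with a
    logged notice) because they cannot train the full hierarchy; all
    sessions of an individual are held out together.  The pooled report
    carries per-individual reports in ``per_fold`` (mean ± SD via
    :meth:`EvalReport.fold_metric_stats`).
    """
    usable_parts, discarded = [], []
    for session_id, part in fm.groupby("session_id", sort=True):
        if set(part["label"]) >= set(BEHAVIOURS):
            usable_parts.append(part)
        else:
            discarded.append(str(session_id))
    if discarded:
        logger.info("LOIO: discarding sessions without all four behaviours: %s",
                    discarded)
    if len(usable_parts) < 2:
        raise ValidationError(
            f"need >= 2 usable sessions for LOIO, have {len(usable_parts)} "
            f"(discarded: {discarded})")
    usable = pd.concat(usable_parts, ignore_index=True)
    individuals = sorted(usable["individual_id"].unique().tolist())
    if len(individuals) < 2:
        raise ValidationError("need >= 2 individuals for LOIO")

    fold_reports, fold_names = [], []
    pooled = np.zeros((len(BEHAVIOURS), len(BEHAVIOURS)), dtype=int)
    for indiv in individuals:
        held = usable["individual_id"] == indiv
        cm = _evaluate_split(usable.loc[~held], usable.loc[held],
                             selected_features, C)
        pooled += cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fold_reports.append(behaviour_metrics(cm))
        fold_names.append(str(indiv))
    report = behaviour_metrics(pooled)
    report.per_fold = fold_reports
    report.fold_names = fold_names
    report.discarded_sessions = discarded
    return report
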