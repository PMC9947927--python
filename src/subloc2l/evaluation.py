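"""Multiclass evaluation metrics and the stringent CV harness.

Metrics: overall accuracy, macro-averaged one-vs-rest precision /
recall / F1, the multiclass Matthews correlation (Gorodkin's R_K over
the confusion matrix), and per-class one-vs-rest ROC AUC and PR AUPR
with their mean and population standard deviation over classes.

The cross-validation harness is "stringent": feature selection, scaler
fitting and all SAE training are re-run from scratch inside every fold,
so no held-out row ever influences the model evaluated on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from subloc2l.features.base import LabeledFeatureSet
from subloc2l.two_level import TwoLevelConfig, train_two_level, predict_two_level


@dataclass
class MetricsReport:
    """All evaluation indices for one set of predictions."""

    oa: float
    rec_macro: float
    prec_macro: float
    f1_macro: float
    mcc: float
    per_class_auc: np.ndarray
    per_class_aupr: np.ndarray
    mean_auc: float
    std_auc: float
    mean_aupr: float
    std_aupr: float
    confusion: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "rec_macro": self.rec_macro,
            "prec_macro": self.prec_macro,
            "f1_macro": self.f1_macro,
            "mcc": self.mcc,
            "per_class_auc": np.asarray(self.per_class_auc).tolist(),
            "per_class_aupr": np.asarray(self.per_class_aupr).tolist(),
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "mean_aupr": self.mean_aupr,
            "std_aupr": self.std_aupr,
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": np.asarray(self.classes).tolist(),
        }


def compute_metrics(y_true, y_pred, probs, classes=None) -> MetricsReport:
    """Compute every evaluation index from labels, predictions, probabilities.

    ``probs`` columns follow ``classes`` (default: sorted union of the
    true labels).  A class absent from ``y_true`` has undefined AUC/AUPR
    and is excluded from their mean/std with a warning.  std over classes
    is the population standard deviation (a descriptive spread over the
    fixed class set).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    probs = np.asarray(probs, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    C = classes.size
    if probs.shape != (y_true.size, C):
        raise ValueError(f"probs must be {y_true.size} x {C}, got {probs.shape}")

    conf = confusion_matrix(y_true, y_pred, labels=classes)
    oa = float(np.trace(conf) / y_true.size)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    mcc = float(matthews_corrcoef(y_true, y_pred))

    auc = np.full(C, np.nan)
    aupr = np.full(C, np.nan)
    for k, cls in enumerate(classes):
        pos = (y_true == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == pos.size:
            warnings.warn(f"class {cls} absent (or exhaustive) in y_true; AUC/AUPR undefined")
            continue
        auc[k] = roc_auc_score(pos, probs[:, k])
        aupr[k] = average_precision_score(pos, probs[:, k])

    ok_auc = auc[~np.isnan(auc)]
    ok_aupr = aupr[~np.isnan(aupr)]
    return MetricsReport(
        oa=oa,
        rec_macro=float(rec),
        prec_macro=float(prec),
        f1_macro=float(f1),
        mcc=mcc,
        per_class_auc=auc,
        per_class_aupr=aupr,
        mean_auc=float(ok_auc.mean()) if ok_auc.size else float("nan"),
        std_auc=float(ok_auc.std()) if ok_auc.size else float("nan"),
        mean_aupr=float(ok_aupr.mean()) if ok_aupr.size else float("nan"),
        std_aupr=float(ok_aupr.std()) if ok_aupr.size else float("nan"),
        confusion=conf,
        classes=classes,
    )


def stratified_kfold_cv(
    raw_sets,
    k: int = 10,
    cfg: TwoLevelConfig | None = None,
    seed: int = 0,
    audit: list | None = None,
):
    """Stringent stratified k-fold CV of the two-level ensemble.

    For every fold the *entire* training procedure — per-set SDA
    selection, feature scaling, SAE pretraining and fine-tuning, stacking
    and the second-level model — runs on the k-1 training folds only;
    the held-out fold is predicted once.  Returns
    ``(per_fold_reports, pooled_report)`` where the pooled report scores
    the concatenated held-out predictions of all folds.
    """
    if cfg is None:
        cfg = TwoLevelConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(raw_sets[0].labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} samples "
            f"(smallest has {counts.min()})"
        )
    N = labels.size
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    fold_reports = []
    pooled_true = np.empty(N, dtype=labels.dtype)
    pooled_pred = np.empty(N, dtype=labels.dtype)
    pooled_probs = np.zeros((N, classes.size))
    for fold, (tr, te) in enumerate(skf.split(np.zeros(N), labels)):
        train_sets = [
            LabeledFeatureSet(
                name=fs.name, matrix=fs.matrix[tr], labels=fs.labels[tr],
                feature_ids=list(fs.feature_ids),
            )
            for fs in raw_sets
        ]
        fold_audit = [] if audit is not None else None
        fold_cfg = TwoLevelConfig(
            f_enter=cfg.f_enter, f_remove=cfg.f_remove,
            max_features=cfg.max_features, first_level=cfg.first_level,
            second_level=cfg.second_level, stacking_folds=cfg.stacking_folds,
            seed=cfg.seed + fold,
        )
        model = train_two_level(train_sets, fold_cfg, audit=fold_audit)
        if audit is not None:
            # Translate row indices local to the training subset back to
            # absolute dataset rows so leakage is auditable end to end.
            for rec in fold_audit:
                rec["train_rows"] = tr[rec["train_rows"]]
                if "test_rows" in rec:
                    rec["test_rows"] = tr[rec["test_rows"]]
                rec["cv_fold"] = fold
                rec["held_out_rows"] = np.sort(te)
            audit.extend(fold_audit)
        pred, decision = predict_two_level(
            model, {fs.name: fs.matrix[te] for fs in raw_sets}
        )
        pooled_true[te] = labels[te]
        pooled_pred[te] = pred
        pooled_probs[te] = decision.probs
        fold_reports.append(
            compute_metrics(labels[te], pred, decision.probs, classes=classes)
        )
    pooled = compute_metrics(pooled_true, pooled_pred, pooled_probs, classes=classes)
    return fold_reports, pooled
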