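"""Two-level SAE-SM stacking ensemble over heterogeneous feature sets.

First level: one SDA selection + SAE-SM per feature set.  The per-set
class-probability outputs ("intermediate decision" sets p_t) are fused
by their element-wise arithmetic mean, F_ME = (1/T) sum_t p_t, the
"intermediate feature" set.  Second level: another SAE-SM trained on
F_ME.

Second-level training inputs are produced by out-of-fold stacking so
that every F_ME row fed to the second level comes from first-level
models that never saw that row: the training rows are split into
stratified folds, and fold-specific selection + SAE-SM models predict
only their held-out fold.  SDA is re-run inside each stacking fold,
matching the per-fold selection discipline of the evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from subloc2l.sae import SAEConfig, SAEModel, fit_sae
from subloc2l.selection import SelectionResult, sda_select
from subloc2l.features.base import LabeledFeatureSet


@dataclass
class DecisionSet:
    """N x C class-probability matrix emitted by one classifier."""

    probs: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D")
        if np.any(self.probs < 0) or np.any(
            np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("rows must lie on the probability simplex")


@dataclass(frozen=True)
class TwoLevelConfig:
    """Configuration of the full two-level model."""

    f_enter: float = 3.84
    f_remove: float = 2.71
    max_features: int | None = 15
    first_level: SAEConfig = field(default_factory=SAEConfig)
    second_level: SAEConfig = field(
        default_factory=lambda: SAEConfig(hidden1=7, hidden2=7)
    )
    stacking_folds: int = 5
    seed: int = 0


@dataclass
class TwoLevelModel:
    """T fitted first-level (selection, SAE-SM) pairs + second-level SAE-SM."""

    first_level: list  # (set_name, SelectionResult, SAEModel)
    second_level: SAEModel
    config: TwoLevelConfig
    classes_: np.ndarray

    @property
    def n_sets(self) -> int:
        return len(self.first_level)


def mean_ensemble(decisions) -> np.ndarray:
    """Element-wise arithmetic mean of T decision matrices, (1/T) sum_t p_t.

    The mean of simplex rows stays on the simplex.
    """
    if len(decisions) == 0:
        raise ValueError("need at least one decision set")
    mats = [d.probs if isinstance(d, DecisionSet) else np.asarray(d, float) for d in decisions]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    return np.mean(mats, axis=0)


def _child_seeds(seed: int, n: int) -> list:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _fit_one(
    fs: LabeledFeatureSet,
    rows: np.ndarray,
    cfg: TwoLevelConfig,
    sae_cfg: SAEConfig,
    audit: list | None,
    stage: str,
):
    """SDA + SAE-SM on the given absolute row indices of one feature set."""
    sub = LabeledFeatureSet(
        name=fs.name, matrix=fs.matrix[rows], labels=fs.labels[rows],
        feature_ids=list(fs.feature_ids),
    )
    sel = sda_select(sub, cfg.f_enter, cfg.f_remove, cfg.max_features)
    model = fit_sae(sel.transform(fs.matrix[rows]), fs.labels[rows], sae_cfg)
    if audit is not None:
        audit.append({"stage": stage, "set": fs.name, "train_rows": np.sort(rows)})
    return sel, model


def train_two_level(
    raw_sets, cfg: TwoLevelConfig | None = None, audit: list | None = None
) -> TwoLevelModel:
    """Train the full two-level ensemble on T raw labeled feature sets.

    ``raw_sets`` is a list of :class:`LabeledFeatureSet` sharing sample
    order and labels.  ``audit``, if given, collects the absolute row
    indices used by every internal fit (for leakage auditing).
    """
    if cfg is None:
        cfg = TwoLevelConfig()
    if len(raw_sets) == 0:
        raise ValueError("need at least one feature set")
    labels = np.asarray(raw_sets[0].labels)
    for fs in raw_sets:
        if not np.array_equal(fs.labels, labels):
            raise ValueError("all feature sets must share sample order and labels")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < cfg.stacking_folds:
        small = classes[counts < cfg.stacking_folds]
        raise ValueError(
            f"classes {small.tolist()} have fewer samples than "
            f"stacking_folds={cfg.stacking_folds}; reduce stacking_folds or add samples"
        )

    T = len(raw_sets)
    N, C = labels.size, classes.size
    seeds = _child_seeds(cfg.seed, 2 * T + 2)

    # (b) out-of-fold intermediate decisions, one matrix per set.
    skf = StratifiedKFold(cfg.stacking_folds, shuffle=True, random_state=seeds[-1])
    oof = [np.zeros((N, C)) for _ in range(T)]
    for fold, (tr, te) in enumerate(skf.split(np.zeros(N), labels)):
        for t, fs in enumerate(raw_sets):
            fold_cfg = replace(cfg.first_level, seed=seeds[t] + fold + 1)
            sel, model = _fit_one(
                fs, tr, cfg, fold_cfg, audit, f"stack_fold{fold}"
            )
            oof[t][te] = model.predict_proba(sel.transform(fs.matrix[te]))
            if audit is not None:
                audit[-1]["test_rows"] = np.sort(te)

    # (c) mean ensemble of the out-of-fold decisions.
    F_ME = mean_ensemble(oof)

    # (d) second-level SAE-SM on (F_ME, y).
    second_cfg = replace(cfg.second_level, seed=seeds[-2])
    second = fit_sae(F_ME, labels, second_cfg)
    if audit is not None:
        audit.append({"stage": "second_level", "set": "ensemble",
                      "train_rows": np.arange(N)})

    # (a)/(e) deployment first-level models refit on all training rows.
    first = []
    for t, fs in enumerate(raw_sets):
        final_cfg = replace(cfg.first_level, seed=seeds[T + t])
        sel, model = _fit_one(fs, np.arange(N), cfg, final_cfg, audit, "final")
        first.append((fs.name, sel, model))

    return TwoLevelModel(
        first_level=first, second_level=second, config=cfg, classes_=classes
    )


def predict_two_level(model: TwoLevelModel, raw_vectors: dict):
    """Predict labels and second-level probabilities for new images.

    ``raw_vectors`` maps set name -> M x d_t raw feature matrix.  Each
    matrix is projected onto its stored selected columns (with the stored
    training scaler), passed through its first-level SAE-SM, the T
    decision matrices are mean-ensembled, and the second-level SAE-SM
    produces the final probabilities; labels are the row-wise argmax
    (ties break toward the lowest class index).
    """
    decisions = []
    for name, sel, sae in model.first_level:
        if name not in raw_vectors:
            raise KeyError(f"missing feature matrix for set {name!r}")
        X = np.asarray(raw_vectors[name], dtype=float)
        if X.ndim != 2 or X.shape[1] != sel.means.size:
            raise ValueError(
                f"set {name!r}: expected M x {sel.means.size} matrix, got {X.shape}"
            )
        decisions.append(sae.predict_proba(sel.transform(X)))
    fme = mean_ensemble(decisions)
    probs = model.second_level.predict_proba(fme)
    labels = model.classes_[np.argmax(probs, axis=1)]
    return labels, DecisionSet(probs=probs, source="ensemble")
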