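"""Stepwise discriminant analysis (SDA) feature selection.

Classical forward selection with backward elimination driven by Wilks'
lambda, the ratio det(W)/det(T) of within-group to total scatter
determinants on the candidate subset.  At each step the unselected
feature with the largest partial-F statistic enters if it exceeds
``f_enter``; selected features whose partial-F falls below ``f_remove``
are then removed.  The selected subset is a plain column subset of the
input matrix: no transformation is applied beyond the training-row
z-scoring recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_RIDGE = 1e-8


@dataclass
class SelectionResult:
    """Outcome of SDA on one feature set."""

    selected: list
    lambda_trace: list
    f_enter: float
    f_remove: float
    steps_log: list = field(default_factory=list)
    means: np.ndarray | None = None
    stds: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the stored training z-scoring, then select the columns."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.means) / self.stds
        return Z[:, self.selected]


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    """Within-group (W) and total (T) scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cls in np.unique(y):
        G = X[y == cls]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        warnings.warn("singular scatter matrix; applying ridge stabilization")
        sign, ld = np.linalg.slogdet(M + _RIDGE * np.trace(M) * np.eye(M.shape[0]))
        if sign <= 0:
            sign, ld = np.linalg.slogdet(M + _RIDGE * np.eye(M.shape[0]))
    return ld


def wilks_lambda(X: np.ndarray, y: np.ndarray, subset) -> float:
    """Wilks' lambda det(W)/det(T) restricted to the feature subset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    W, T = _scatter_matrices(X[:, subset], y)
    lam = float(np.exp(_logdet(W) - _logdet(T)))
    return min(lam, 1.0)


def _schur_complements(M: np.ndarray, sel: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """diag Schur complements M_qq - M_qs M_s^-1 M_sq for all candidates."""
    diag = M[cand, cand]
    if sel.size == 0:
        return diag
    Ms = M[np.ix_(sel, sel)]
    Msq = M[np.ix_(sel, cand)]
    try:
        sol = np.linalg.solve(Ms, Msq)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(Ms + _RIDGE * np.eye(sel.size), Msq)
    return diag - np.sum(Msq * sol, axis=0)


def sda_select(
    S,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_features: int | None = None,
) -> SelectionResult:
    """Run stepwise discriminant analysis on a labeled feature set.

    Features are z-scored on the provided rows before scatter
    accumulation; the scaling is stored in the result so held-out rows
    are transformed identically.  Ties in partial-F break toward the
    lowest feature index; if no feature passes ``f_enter`` at the first
    step the single best feature is returned with a warning.
    """
    if f_enter < f_remove or f_remove <= 0:
        raise ValueError("require f_enter >= f_remove > 0")
    X = np.asarray(S.matrix, dtype=float)
    y = np.asarray(S.labels)
    classes = np.unique(y)
    N, d = X.shape
    C = classes.size
    if C < 2:
        raise ValueError("need at least 2 classes for selection")
    if N <= C:
        raise ValueError("need more samples than classes")
    if max_features is None:
        max_features = min(d, N - C - 1)
    max_features = max(1, min(max_features, d))

    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0
    Z = (X - means) / stds
    W, T = _scatter_matrices(Z, y)

    selected: list = []
    lambda_trace: list = []
    steps_log: list = []
    lam = 1.0

    def partial_f_enter(sel, lam_now):
        """(candidate indices, their partial-F, their new lambdas)."""
        cand = np.array([j for j in range(d) if j not in sel], dtype=int)
        sel_a = np.array(sel, dtype=int)
        sw = _schur_complements(W, sel_a, cand)
        st = _schur_complements(T, sel_a, cand)
        ratio = np.full(cand.size, 1.0)
        ok = st > 1e-10  # exclude features collinear with the subset
        ratio[ok] = np.clip(sw[ok], 1e-300, None) / st[ok]
        ratio = np.clip(ratio, 1e-12, 1.0)
        lam_new = lam_now * ratio
        F = (N - C - len(sel)) / (C - 1) * (lam_now / lam_new - 1.0)
        F[~ok] = 0.0
        return cand, F, lam_new

    for _ in range(4 * max_features):  # hard cap against pathological cycling
        if len(selected) >= max_features:
            break
        cand, F, lam_new = partial_f_enter(selected, lam)
        if cand.size == 0:
            break
        best = int(np.argmax(F))  # argmax takes the lowest index on ties
        if F[best] < f_enter or lam_new[best] >= lam:
            break
        selected.append(int(cand[best]))
        lam = float(lam_new[best])
        lambda_trace.append(lam)
        steps_log.append(("enter", int(cand[best]), float(F[best])))

        # Backward pass: drop any selected feature whose partial-F fell
        # below f_remove (the just-entered feature's removal F equals its
        # entry F, so it cannot leave immediately).
        changed = True
        while changed and len(selected) > 1:
            changed = False
            k = len(selected)
            for j in list(selected):
                rest = [i for i in selected if i != j]
                lam_rest = wilks_lambda(Z, y, rest)
                F_rem = (N - C - (k - 1)) / (C - 1) * (lam_rest / lam - 1.0)
                if F_rem < f_remove:
                    selected.remove(j)
                    lam = lam_rest
                    lambda_trace.append(lam)
                    steps_log.append(("remove", j, float(F_rem)))
                    changed = True
                    break

    if not selected:
        warnings.warn("no feature passed f_enter; returning the single best feature")
        cand, F, lam_new = partial_f_enter([], 1.0)
        best = int(np.argmax(F))
        selected = [int(cand[best])]
        lam = float(lam_new[best])
        lambda_trace = [lam]
        steps_log.append(("enter", int(cand[best]), float(F[best])))

    return SelectionResult(
        selected=selected,
        lambda_trace=lambda_trace,
        f_enter=f_enter,
        f_remove=f_remove,
        steps_log=steps_log,
        means=means,
        stds=stds,
    )
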