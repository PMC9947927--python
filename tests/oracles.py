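"""Independent from-definition oracles used by the test suite.

Everything here is deliberately written as plain nested loops / direct
formula evaluation, independent of the vectorized implementations under
test.
"""

import numpy as np


# -- imaging ---------------------------------------------------------------

def od_scalar(pixel, i0):
    """Per-channel scalar optical density."""
    return [max(0.0, -np.log((p + 1.0) / (i0 + 1.0))) for p in pixel]


def normal_equations_2x2(A, b):
    """Solve the 3x2 least-squares system via explicit normal equations."""
    AtA = [[sum(A[i][r] * A[i][c] for i in range(3)) for c in range(2)] for r in range(2)]
    Atb = [sum(A[i][r] * b[i] for i in range(3)) for r in range(2)]
    det = AtA[0][0] * AtA[1][1] - AtA[0][1] * AtA[1][0]
    x0 = (Atb[0] * AtA[1][1] - AtA[0][1] * Atb[1]) / det
    x1 = (AtA[0][0] * Atb[1] - Atb[0] * AtA[1][0]) / det
    return x0, x1


# -- LBP family ------------------------------------------------------------

_OFF8 = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_codes_loop(img, radius=1):
    """Nested-loop raw LBP codes on interior pixels."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h - 2 * radius, w - 2 * radius), dtype=int)
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            code = 0
            for bit, (dy, dx) in enumerate(_OFF8):
                if img[y + dy * radius, x + dx * radius] >= img[y, x]:
                    code |= 1 << bit
            out[y - radius, x - radius] = code
    return out


def clbp_sm_loop(img, radius=1):
    """Nested-loop CLBP sign and magnitude raw codes (before riu2 mapping).

    The magnitude threshold is the image-wide mean of |neighbor - center|
    over all interior pixels, matching the implementation's convention.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    mags = []
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            for dy, dx in _OFF8:
                mags.append(abs(img[y + dy * radius, x + dx * radius] - img[y, x]))
    thr = float(np.mean(mags))
    hh, ww = h - 2 * radius, w - 2 * radius
    s = np.zeros((hh, ww), dtype=int)
    m = np.zeros((hh, ww), dtype=int)
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            sc = mc = 0
            for bit, (dy, dx) in enumerate(_OFF8):
                d = img[y + dy * radius, x + dx * radius] - img[y, x]
                if d >= 0:
                    sc |= 1 << bit
                if abs(d) >= thr:
                    mc |= 1 << bit
            s[y - radius, x - radius] = sc
            m[y - radius, x - radius] = mc
    return s, m


def rot4(c, k):
    k = k % 4
    return ((c << k) | (c >> (4 - k))) & 0xF


def riclbp_hist_loop(img, radius, disp):
    """Pair-enumeration RICLBP histogram for one scale (136 bins)."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    off4 = [(0, 1), (-1, 0), (0, -1), (1, 0)]
    codes = np.full((h, w), -1, dtype=int)
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            c = 0
            for bit, (dy, dx) in enumerate(off4):
                if img[y + dy * radius, x + dx * radius] >= img[y, x]:
                    c |= 1 << bit
            codes[y, x] = c
    canon = {}
    table = {}
    for a in range(16):
        for b in range(16):
            key = min((a, b), (rot4(b, 2), rot4(a, 2)))
            if key not in canon:
                canon[key] = len(canon)
            table[(a, b)] = canon[key]
    hist = np.zeros(136)
    for dy, dx, rot in ((0, disp, 0), (-disp, disp, 0), (-disp, 0, 1), (-disp, -disp, 1)):
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if not (0 <= y2 < h and 0 <= x2 < w):
                    continue
                a, b = codes[y, x], codes[y2, x2]
                if a < 0 or b < 0:
                    continue
                hist[table[(rot4(a, -rot), rot4(b, -rot))]] += 1
    return hist / hist.sum()


# -- GLCM ------------------------------------------------------------------

def glcm_loop(q, dy, dx, levels):
    """Symmetric normalized co-occurrence matrix for one displacement."""
    h, w = q.shape
    P = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                P[q[y, x], q[y2, x2]] += 1
                P[q[y2, x2], q[y, x]] += 1
    return P / P.sum()


# -- Wilks' lambda / stepwise ----------------------------------------------

def wilks_loop(X, y, subset):
    """Wilks' lambda via explicitly accumulated scatter matrices."""
    X = np.asarray(X, dtype=float)[:, list(subset)]
    y = np.asarray(y)
    n, d = X.shape
    grand = X.mean(axis=0)
    T = np.zeros((d, d))
    W = np.zeros((d, d))
    for i in range(n):
        dev = X[i] - grand
        T += np.outer(dev, dev)
    for cls in np.unique(y):
        G = X[y == cls]
        mu = G.mean(axis=0)
        for row in G:
            dev = row - mu
            W += np.outer(dev, dev)
    return np.linalg.det(W) / np.linalg.det(T)


def stepwise_loop(X, y, f_enter, f_remove, max_features):
    """Textbook stepwise discriminant selection, brute-force lambdas.

    Operates on z-scored columns (matching the implementation's stated
    convention) and evaluates every candidate subset by direct
    determinant ratio.  Returns the ordered selected indices.
    """
    X = np.asarray(X, dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    y = np.asarray(y)
    N, d = X.shape
    C = np.unique(y).size
    sel = []
    lam = 1.0
    while len(sel) < max_features:
        best_j, best_f, best_lam = None, -np.inf, None
        for j in range(d):
            if j in sel:
                continue
            lj = wilks_loop(X, y, sel + [j])
            if not np.isfinite(lj) or lj <= 0:
                continue
            f = (N - C - len(sel)) / (C - 1) * (lam / lj - 1.0)
            if f > best_f + 1e-9:
                best_j, best_f, best_lam = j, f, lj
        if best_j is None or best_f < f_enter or best_lam >= lam:
            break
        sel.append(best_j)
        lam = best_lam
        removed = True
        while removed and len(sel) > 1:
            removed = False
            k = len(sel)
            for j in list(sel):
                rest = [i for i in sel if i != j]
                lr = wilks_loop(X, y, rest)
                f = (N - C - (k - 1)) / (C - 1) * (lr / lam - 1.0)
                if f < f_remove:
                    sel.remove(j)
                    lam = lr
                    removed = True
                    break
    return sel


# -- metrics ---------------------------------------------------------------

def metrics_loop(y_true, y_pred, probs, classes):
    """All evaluation indices from explicit TP/FP/FN loops and direct
    threshold sweeps (trapezoidal ROC AUC, step-interpolated AUPR)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = list(classes)
    C = len(classes)
    n = y_true.size

    conf = np.zeros((C, C), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[classes.index(t), classes.index(p)] += 1
    oa = np.trace(conf) / n

    precs, recs, f1s = [], [], []
    for k in range(C):
        tp = conf[k, k]
        fp = conf[:, k].sum() - tp
        fn = conf[k, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)

    # Gorodkin R_K from the confusion matrix.
    t_k = conf.sum(axis=1).astype(float)
    p_k = conf.sum(axis=0).astype(float)
    c = np.trace(conf)
    s = conf.sum()
    num = c * s - t_k @ p_k
    den = np.sqrt(s**2 - p_k @ p_k) * np.sqrt(s**2 - t_k @ t_k)
    mcc = num / den if den else 0.0

    aucs, auprs = [], []
    for k, cls in enumerate(classes):
        pos = (y_true == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == n:
            aucs.append(np.nan)
            auprs.append(np.nan)
            continue
        score = probs[:, k]
        thresholds = np.unique(score)[::-1]
        tprs, fprs = [0.0], [0.0]
        rec_prec = []
        P = pos.sum()
        Nn = n - P
        for thr in thresholds:
            pred_pos = score >= thr
            tp = int(np.sum(pred_pos & (pos == 1)))
            fp = int(np.sum(pred_pos & (pos == 0)))
            tprs.append(tp / P)
            fprs.append(fp / Nn)
            rec_prec.append((tp / P, tp / (tp + fp) if tp + fp else 1.0))
        tprs.append(1.0)
        fprs.append(1.0)
        auc = 0.0
        for i in range(1, len(tprs)):
            auc += (fprs[i] - fprs[i - 1]) * (tprs[i] + tprs[i - 1]) / 2
        aucs.append(auc)
        # step-wise interpolation: sum over recall increments of precision
        aupr = 0.0
        prev_r = 0.0
        for r, p in rec_prec:
            aupr += (r - prev_r) * p
            prev_r = r
        auprs.append(aupr)

    ok_auc = [a for a in aucs if not np.isnan(a)]
    ok_aupr = [a for a in auprs if not np.isnan(a)]
    return {
        "oa": oa,
        "prec_macro": float(np.mean(precs)),
        "rec_macro": float(np.mean(recs)),
        "f1_macro": float(np.mean(f1s)),
        "mcc": float(mcc),
        "per_class_auc": aucs,
        "per_class_aupr": auprs,
        "mean_auc": float(np.mean(ok_auc)),
        "std_auc": float(np.std(ok_auc)),
        "mean_aupr": float(np.mean(ok_aupr)),
        "std_aupr": float(np.std(ok_aupr)),
        "confusion": conf,
    }


# -- finite differences ----------------------------------------------------

def finite_diff_grads(loss_fn, params, eps=1e-6):
    """Central finite-difference gradients of a scalar loss."""
    grads = []
    for idx, p in enumerate(params):
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        while not it.finished:
            mi = it.multi_index
            orig = p[mi]
            p[mi] = orig + eps
            hi = loss_fn(tuple(params))
            p[mi] = orig - eps
            lo = loss_fn(tuple(params))
            p[mi] = orig
            g[mi] = (hi - lo) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads
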