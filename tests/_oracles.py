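"""Independent brute-force reference implementations.

Pure-Python loop versions of the kernel-regression machinery, kept free of
the package's vectorized code paths so agreement is a genuine cross-check.
"""

import math

import numpy as np


def gauss_weight(row_t, row_o, tolerances, categorical=()):
    w = 1.0
    for name, sigma in tolerances.items():
        w *= math.exp(-0.5 * ((row_t[name] - row_o[name]) / sigma) ** 2)
    for name in categorical:
        if row_t[name] != row_o[name]:
            w = 0.0
    return w


def loo_table(table, tolerances, y_col="y", categorical=(), n_min_fraction=0.25):
    """Per-row LOO estimate and neighborhood size with the one-pass n_min rule."""
    rows = []
    for i in range(len(table)):
        r = table.iloc[i]
        if any(not np.isfinite(r[name]) for name in tolerances) or \
                not np.isfinite(r[y_col]):
            continue
        rows.append(i)
    nstar, wsum_y = [], []
    for i in rows:
        ri = table.iloc[i]
        s, sy = 0.0, 0.0
        for j in rows:
            if j == i:
                continue
            rj = table.iloc[j]
            w = gauss_weight(ri, rj, tolerances, categorical)
            s += w
            sy += w * rj[y_col]
        nstar.append(s)
        wsum_y.append(sy)
    n_min = n_min_fraction * (sum(nstar) / len(nstar))
    est = []
    for s, sy in zip(nstar, wsum_y):
        est.append(sy / s if s >= max(n_min, 1e-300) else float("nan"))
    return rows, np.array(est), np.array(nstar), n_min


def logB(y, yhat, p_bar=None):
    y = np.asarray(y, dtype=float)
    p = np.asarray(yhat, dtype=float)
    su = y.size
    eps = 1.0 / (2.0 * su)
    pb = float(y.mean()) if p_bar is None else p_bar
    pb = min(max(pb, eps), 1 - eps)
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, eps), 1 - eps)
        li = pi if yi == 1 else 1 - pi
        ni = pb if yi == 1 else 1 - pb
        total += math.log10(li) - math.log10(ni)
    return total


def auc_pairwise(y, est):
    """All-pairs concordance with ties counted one half."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(est, dtype=float)
    pos = e[y == 1]
    neg = e[y == 0]
    total, conc = 0, 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1.0
            elif p == n:
                conc += 0.5
    return conc / total


def predict_rows(fit_tolerances, building, new_rows, y_col="y", categorical=(),
                 n_min_fraction=0.25):
    """Non-LOO weighted-mean prediction with n_min recomputed on new rows."""
    b_ok = [i for i in range(len(building))
            if all(np.isfinite(building.iloc[i][n]) for n in fit_tolerances)
            and np.isfinite(building.iloc[i][y_col])]
    nstar, est_raw = [], []
    for i in range(len(new_rows)):
        ri = new_rows.iloc[i]
        s, sy = 0.0, 0.0
        for j in b_ok:
            rj = building.iloc[j]
            w = gauss_weight(ri, rj, fit_tolerances, categorical)
            s += w
            sy += w * rj[y_col]
        nstar.append(s)
        est_raw.append(sy / s if s > 0 else float("nan"))
    n_min = n_min_fraction * (sum(nstar) / len(nstar))
    est = [e if s >= max(n_min, 1e-300) else float("nan")
           for e, s in zip(est_raw, nstar)]
    return np.array(est), np.array(nstar), n_min


def sensitivity_q(table, tolerances, predictor, pred_range, base_est, n_min,
                  y_col="y", nudge=0.05):
    """Nudged re-estimation sensitivity, mirroring the LOO convention."""
    rows = [i for i in range(len(table))
            if all(np.isfinite(table.iloc[i][n]) for n in tolerances)
            and np.isfinite(table.iloc[i][y_col])]
    delta = nudge * pred_range
    diffs = []
    for sign in (1.0, -1.0):
        for k, i in enumerate(rows):
            if not np.isfinite(base_est[k]):
                continue
            ri = dict(table.iloc[i])
            ri[predictor] = ri[predictor] + sign * delta
            s, sy = 0.0, 0.0
            for j in rows:
                if j == i:
                    continue
                rj = table.iloc[j]
                w = gauss_weight(ri, rj, tolerances)
                s += w
                sy += w * rj[y_col]
            if s >= n_min:
                diffs.append(abs(sy / s - base_est[k]))
    return (sum(diffs) / len(diffs)) / nudge
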