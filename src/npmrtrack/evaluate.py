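"""Binary conversion and evaluation of continuous ARS-likelihood estimates.

The continuous estimate is converted to presence/absence at the cutoff that
maximizes the true skill statistic (TSS = TPR + TNR - 1); the resulting
confusion matrix feeds a suite of threshold metrics (prevalence, accuracy,
precision, the rates) and the threshold-free scores (AUC, RMSE, Brier).
Rows with missing estimates are excluded from every denominator and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cells ordered by observation then prediction: tn, fp, fn, tp."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("negative confusion cell")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def cells(self) -> tuple[int, int, int, int]:
        return (self.tn, self.fp, self.fn, self.tp)


@dataclass
class ClassificationReport:
    cutoff: float | None = None
    tss: float | None = None
    tpr: float | None = None
    tnr: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    observed_prevalence: float | None = None
    predicted_prevalence: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    auc: float | None = None
    rmse: float | None = None
    brier: float | None = None
    n_excluded_missing: int = 0
    confusion: tuple | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _clean(y, estimates):
    y = np.asarray(y, dtype=float)
    e = np.asarray(estimates, dtype=float)
    ok = np.isfinite(e) & np.isfinite(y)
    return y[ok], e[ok], int((~ok).sum())


def scan_cutoffs(estimates, y):
    """TSS over all candidate cutoffs; returns (cutoff*, TSS_max, curve).

    Candidates are the unique estimate values plus 0 and 1; a location is
    predicted present iff its estimate >= cutoff.  Ties in maximal TSS go
    to the lowest cutoff.  Requires both classes present.
    """
    yv, ev, _ = _clean(y, estimates)
    pos = yv == 1.0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to scan cutoffs")
    cuts = np.unique(np.concatenate([ev, [0.0, 1.0]]))
    pred = ev[None, :] >= cuts[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    tpr = tp / n_pos
    tnr = 1.0 - fp / n_neg
    tss = tpr + tnr - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (lowest) maximizer
    curve = pd.DataFrame({"cutoff": cuts, "tpr": tpr, "tnr": tnr, "tss": tss})
    return float(cuts[best]), float(tss[best]), curve


def confusion(y, estimates, cutoff: float) -> ConfusionMatrix:
    """Confusion cells under the presence-iff-estimate>=cutoff rule."""
    yv, ev, _ = _clean(y, estimates)
    pred = ev >= cutoff
    pos = yv == 1.0
    return ConfusionMatrix(
        tn=int((~pos & ~pred).sum()), fp=int((~pos & pred).sum()),
        fn=int((pos & ~pred).sum()), tp=int((pos & pred).sum()))


def metrics(cm: ConfusionMatrix, cutoff: float | None = None) -> ClassificationReport:
    """Threshold metrics from confusion cells; zero denominators give None."""
    tn, fp, fn, tp = cm.cells()
    total = cm.total

    def ratio(a, b):
        return a / b if b > 0 else None

    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    return ClassificationReport(
        cutoff=cutoff,
        tpr=tpr, tnr=tnr,
        fpr=None if tnr is None else 1.0 - tnr,
        fnr=None if tpr is None else 1.0 - tpr,
        tss=None if tpr is None or tnr is None else tpr + tnr - 1.0,
        observed_prevalence=(tp + fn) / total,
        predicted_prevalence=(tp + fp) / total,
        accuracy=(tp + tn) / total,
        precision=ratio(tp, tp + fp),
        confusion=cm.cells(),
    )


def score_metrics(y, estimates) -> dict:
    """Threshold-free scores: AUC (ties count 1/2), RMSE, Brier (= RMSE^2)."""
    yv, ev, _ = _clean(y, estimates)
    if yv.size == 0:
        raise ValueError("no scored rows")
    sq = float(np.mean((yv - ev) ** 2))
    pos = yv == 1.0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos and n_neg:
        ranks = rankdata(ev)  # midranks handle ties as half-concordant
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    else:
        auc = None
    return {"auc": None if auc is None else float(auc),
            "rmse": float(np.sqrt(sq)), "brier": sq}


def evaluate(y, estimates) -> ClassificationReport:
    """Full evaluation at the TSS-maximizing cutoff."""
    yv, ev, n_missing = _clean(y, estimates)
    cutoff, _, _ = scan_cutoffs(ev, yv)
    report = metrics(confusion(yv, ev, cutoff), cutoff=cutoff)
    report.n_excluded_missing = n_missing
    scores = score_metrics(yv, ev)
    report.auc, report.rmse, report.brier = (
        scores["auc"], scores["rmse"], scores["brier"])
    return report
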