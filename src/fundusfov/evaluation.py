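"""Accuracy and ROC evaluation for the binary DR classifier.

Accuracy is reported as mean +/- std over repeated seeded stratified
sub-samples of the test set (overall, per-class No DR, per-class DR).

ROC analysis follows the convention that the *positive* class is No DR:
TPR is the probability of detecting a No DR image as No DR (sensitivity),
FPR the probability of calling a No DR image DR-free when it is not...
i.e. the rates are computed from the No DR score unless ``positive_label``
says otherwise.  The curve is swept over all distinct scores (ties grouped)
with +/- infinity sentinels, AUC is the trapezoidal integral (equivalent to
the Mann-Whitney statistic with half credit for ties), and the equal error
rate (EER) — the operating point where FPR equals the false negative rate —
is found by linear interpolation between adjacent sweep points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "AccuracyReport",
    "RocCurve",
    "accuracy_report",
    "roc_curve",
    "equal_error_rate",
]


@dataclass
class AccuracyReport:
    """Mean/std accuracies over repeated stratified sub-samples."""

    overall: tuple[float, float]
    no_dr: tuple[float, float]
    dr: tuple[float, float]
    n_repeats: int
    subsample_fraction: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "overall": {"mean": self.overall[0], "std": self.overall[1]},
            "no_dr": {"mean": self.no_dr[0], "std": self.no_dr[1]},
            "dr": {"mean": self.dr[0], "std": self.dr[1]},
            "n_repeats": self.n_repeats,
            "subsample_fraction": self.subsample_fraction,
            "seed": self.seed,
        }


@dataclass
class RocCurve:
    """Threshold-swept ROC with AUC and equal error rate.

    ``points`` is ordered by increasing threshold, so FPR and TPR are
    non-increasing along the list; the ends anchor (1,1) and (0,0).
    """

    points: list[tuple[float, float, float]]  # (threshold, fpr, tpr)
    auc: float
    eer: float
    eer_threshold: float
    positive_label: int = 0

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


def accuracy_report(scores: np.ndarray, labels, n_repeats: int = 20,
                    subsample_fraction: float = 0.8, seed: int = 0,
                    max_retries: int = 100) -> AccuracyReport:
    """Accuracy (overall / No DR / DR) over repeated stratified sub-samples.

    ``scores`` is an (n, 2) matrix of class probabilities (column 0 No DR);
    the decision rule is argmax.  Each repeat draws, per class, a seeded
    uniform sub-sample of ``subsample_fraction`` of that class (at least 1),
    computes per-class and overall accuracy, and the mean and (population)
    std across repeats are returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[1] != 2 or len(scores) != len(labels):
        raise ValueError("scores must be (n, 2) aligned with labels")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    pred = scores.argmax(axis=1)
    correct = pred == labels
    idx_by_class = {c: np.flatnonzero(labels == c) for c in (0, 1)}
    if any(len(v) == 0 for v in idx_by_class.values()):
        raise ValueError("both classes must be present in the test set")
    rng = np.random.default_rng(seed)
    acc = {"overall": [], "no_dr": [], "dr": []}
    for _ in range(n_repeats):
        for _attempt in range(max_retries):
            take = []
            for c, idx in idx_by_class.items():
                k = max(1, int(round(subsample_fraction * len(idx))))
                take.append(rng.choice(idx, size=k, replace=False))
            sub = np.concatenate(take)
            sub_labels = labels[sub]
            if (sub_labels == 0).any() and (sub_labels == 1).any():
                break
        else:
            raise RuntimeError("could not draw a sub-sample with both classes")
        c = correct[sub]
        acc["overall"].append(c.mean())
        acc["no_dr"].append(c[sub_labels == 0].mean())
        acc["dr"].append(c[sub_labels == 1].mean())

    def _ms(v):
        a = np.asarray(v)
        return float(a.mean()), float(a.std())

    return AccuracyReport(overall=_ms(acc["overall"]), no_dr=_ms(acc["no_dr"]),
                          dr=_ms(acc["dr"]), n_repeats=n_repeats,
                          subsample_fraction=subsample_fraction, seed=seed)


def roc_curve(scores, labels, positive_label: int = 0) -> RocCurve:
    """ROC over all distinct score thresholds, with AUC and EER.

    ``scores`` is the probability of the positive class (default: No DR,
    label 0) per item; ``labels`` are 0/1 class labels.  The sweep groups
    tied scores at a single threshold and carries -inf/+inf sentinels so the
    curve is anchored at (1,1) and (0,0).  AUC is the trapezoidal integral
    of TPR over FPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    y = (labels == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _skm.roc_curve(y, scores, drop_intermediate=False)
    # sklearn orders by decreasing threshold with a +inf sentinel first;
    # reverse to increasing threshold and append a -inf anchor at (1,1)
    thr, fpr, tpr = thr[::-1], fpr[::-1], tpr[::-1]
    thr = np.concatenate([[-np.inf], thr])
    fpr = np.concatenate([[1.0], fpr])
    tpr = np.concatenate([[1.0], tpr])
    auc = float(-np.trapezoid(tpr, fpr))  # fpr decreasing along the sweep
    eer, eer_thr = _interp_eer(thr, fpr, tpr)
    points = [(float(t), float(f), float(s)) for t, f, s in zip(thr, fpr, tpr)]
    return RocCurve(points=points, auc=auc, eer=eer, eer_threshold=eer_thr,
                    positive_label=positive_label)


def _interp_eer(thr: np.ndarray, fpr: np.ndarray,
                tpr: np.ndarray) -> tuple[float, float]:
    """EER by linear interpolation on the sweep polyline.

    Along increasing threshold, d = FPR - FNR runs from +1 to -1; the
    crossing segment is interpolated linearly in (FPR, FNR); the threshold
    is interpolated on the same segment (clamped to the finite endpoint when
    the segment touches a sentinel).
    """
    fnr = 1.0 - tpr
    d = fpr - fnr
    # first index where d <= 0 (d is non-increasing along the sweep)
    k = int(np.argmax(d <= 0))
    if d[k] == 0:
        return float(fpr[k]), _finite(thr, k)
    i = k - 1  # d[i] > 0 >= d[k]
    u = d[i] / (d[i] - d[k])
    eer = float(fpr[i] + u * (fpr[k] - fpr[i]))
    t0, t1 = thr[i], thr[k]
    if not np.isfinite(t0):
        t = _finite(thr, k)
    elif not np.isfinite(t1):
        t = _finite(thr, i)
    else:
        t = float(t0 + u * (t1 - t0))
    return eer, t


def _finite(thr: np.ndarray, k: int) -> float:
    """Nearest finite threshold to index k (sentinel fallback)."""
    if np.isfinite(thr[k]):
        return float(thr[k])
    finite = thr[np.isfinite(thr)]
    if len(finite) == 0:
        return 0.5
    return float(finite[0] if k == 0 else finite[-1])


def equal_error_rate(curve: RocCurve) -> tuple[float, float]:
    """(EER, threshold) of a fitted ROC curve."""
    return curve.eer, curve.eer_threshold
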