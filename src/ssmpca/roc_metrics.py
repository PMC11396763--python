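"""ROC analysis on cross-validated scores, Youden thresholding, predictive
values, strict-threshold classification, and two-modality concordance.

AUC is computed by the rank/pair-counting formula (ties count one half), which
equals the trapezoidal area under the threshold-swept ROC curve. The Youden
threshold maximises J = sensitivity + specificity − 1; ties are broken toward
higher specificity, then higher threshold — certainty for a target call is
preferred over catching every target. Classification is strict: a score must
exceed the threshold to be called target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_formats import GROUP_REFERENCE, GROUP_TARGET


@dataclass
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocReport:
    points: list[RocPoint]
    auc: float
    youden_threshold: float | None = None
    sensitivity: float | None = None  # percent, at the chosen cut
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    confusion: tuple[int, int, int, int] | None = None  # TP, FP, TN, FN
    degenerate: bool = False  # all scores identical: no informative cut


@dataclass
class ConcordanceReport:
    concordant_ids: list[int]
    concordance_percent: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    confusion: tuple[int, int, int, int] | None
    empty_subset: bool = False


def _as_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "bif":
        return labels.astype(bool)
    return labels == GROUP_TARGET


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocReport:
    """Sweep thresholds over the unique scores; AUC by pair counting with ½ ties."""
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"both classes must be present, got {n_neg} reference / {n_pos} target")

    ranks = rankdata(scores)  # midranks: ties contribute 1/2 automatically
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    points = []
    for t in [-np.inf, *np.unique(scores)]:
        pred = scores > t
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        points.append(
            RocPoint(threshold=float(t), sensitivity=tp / n_pos, specificity=tn / n_neg)
        )
    return RocReport(points=points, auc=float(auc))


def youden_threshold(
    roc: RocReport, return_all: bool = False
) -> tuple[float, float, float] | list[tuple[float, float, float]]:
    """Operating point(s) maximising Youden's J = sensitivity + specificity − 1.

    Ties go to higher specificity, then higher threshold. With
    ``return_all=True`` every co-optimal (threshold, sensitivity, specificity)
    is returned, highest-specificity first.
    """
    if not roc.points:
        raise ValueError("ROC report has no points")
    j = np.array([p.sensitivity + p.specificity - 1.0 for p in roc.points])
    best = j.max()
    co_optimal = [p for p, v in zip(roc.points, j) if math.isclose(v, best, abs_tol=1e-12)]
    co_optimal.sort(key=lambda p: (p.specificity, p.threshold), reverse=True)
    out = [(p.threshold, p.sensitivity, p.specificity) for p in co_optimal]
    return out if return_all else out[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def predictive_values(tp: int, fp: int, tn: int, fn: int) -> tuple[int | None, int | None]:
    """PPV and NPV as integer percentages (half-up); None when the denominator
    is empty — an undefined value is never reported as 0."""
    for name, v in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if v < 0:
            raise ValueError(f"negative count {name} = {v}")
    ppv = _round_half_up(100.0 * tp / (tp + fp)) if tp + fp > 0 else None
    npv = _round_half_up(100.0 * tn / (tn + fn)) if tn + fn > 0 else None
    return ppv, npv


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Strictly-greater rule: score > threshold ⇒ target, else reference."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    scores = np.asarray(scores, dtype=np.float64)
    return np.where(scores > threshold, GROUP_TARGET, GROUP_REFERENCE)


def confusion_counts(predicted: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    pred = _as_binary(predicted)
    y = _as_binary(labels)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return tp, fp, tn, fn


def roc_report(scores: np.ndarray, labels: np.ndarray) -> RocReport:
    """Full ROC analysis: curve, AUC, Youden cut, confusion and derived metrics."""
    scores = np.asarray(scores, dtype=np.float64)
    roc = roc_curve(scores, labels)
    threshold, sens, spec = youden_threshold(roc)
    roc.degenerate = bool(np.all(scores == scores[0]))
    if not np.isfinite(threshold):
        # -inf cut (call everything target) — replace with just-below-minimum
        threshold = float(np.min(scores)) - 1.0
    roc.youden_threshold = float(threshold)
    predicted = classify(scores, threshold)
    tp, fp, tn, fn = confusion_counts(predicted, labels)
    roc.confusion = (tp, fp, tn, fn)
    roc.sensitivity = 100.0 * tp / (tp + fn)
    roc.specificity = 100.0 * tn / (tn + fp)
    roc.ppv, roc.npv = predictive_values(tp, fp, tn, fn)
    return roc


def concordance_combine(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    true_labels: np.ndarray,
) -> ConcordanceReport:
    """Two-modality agreement: metrics are computed only where both modalities
    predict the same phenotype; discordant subjects are 'no call'."""
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    y = np.asarray(true_labels)
    if not (len(a) == len(b) == len(y)):
        raise ValueError(f"length mismatch: {len(a)}, {len(b)}, {len(y)}")
    agree = _as_binary(a) == _as_binary(b)
    ids = [int(i) for i in np.flatnonzero(agree)]
    percent = 100.0 * len(ids) / len(a) if len(a) else 0.0
    if not ids:
        return ConcordanceReport(
            concordant_ids=[],
            concordance_percent=percent,
            sensitivity=None,
            specificity=None,
            ppv=None,
            npv=None,
            confusion=None,
            empty_subset=True,
        )
    tp, fp, tn, fn = confusion_counts(a[agree], y[agree])
    ppv, npv = predictive_values(tp, fp, tn, fn)
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    return ConcordanceReport(
        concordant_ids=ids,
        concordance_percent=percent,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        confusion=(tp, fp, tn, fn),
    )
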