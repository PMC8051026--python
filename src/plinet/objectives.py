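"""Loss functions and evaluation metrics.

Classification is trained with mean binary cross-entropy and evaluated with
confusion-matrix metrics (accuracy, precision, recall, specificity, MCC,
F1, balanced accuracy) plus ROC AUC.  Regression is trained with mean
squared error plus an L2 penalty ``lambda * ||w||^2`` on the regression
head's dense weights, and evaluated with RMSE, Pearson's R and SD — the
standard deviation of the residuals of the least-squares fit of the true
values on the predictions (the CASF convention), so a pure affine shift of
the predictions gives SD = 0.

Zero-denominator metrics (undefined R at zero variance, MCC/precision with
an empty margin, AUC with a single class) are reported as NaN with a
warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .encoding import EncodedPair

__all__ = [
    "BCE_EPSILON",
    "LabeledBatch",
    "MetricReport",
    "bce_loss",
    "mse_l2_loss",
    "regression_metrics",
    "classification_metrics",
    "roc_auc",
]

BCE_EPSILON = 1e-7  # probability clamp


@dataclass
class LabeledBatch:
    """A homogeneous batch of encoded pairs with labels.

    ``y`` holds {0,1} labels for classification or real pK values for
    regression; ``Xp``/``Xl`` are stacked one-hot matrices.
    """

    Xp: np.ndarray
    Xl: np.ndarray
    y: np.ndarray
    task: str
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (len(self.Xp) == len(self.Xl) == len(self.y)):
            raise ValueError("Xp, Xl and y must have equal length")
        if len(self.y) < 1:
            raise ValueError("a labeled batch needs at least one sample")
        if self.task == "classification" and not np.isin(self.y, (0, 1)).all():
            raise ValueError("classification labels must be 0/1")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_pairs(cls, pairs: Sequence[EncodedPair], ids: list | None = None) -> "LabeledBatch":
        tasks = {p.task for p in pairs}
        if len(tasks) != 1:
            raise ValueError(f"batch mixes tasks: {tasks}")
        return cls(
            Xp=np.stack([p.protein.matrix for p in pairs]),
            Xl=np.stack([p.ligand.matrix for p in pairs]),
            y=np.array([p.label for p in pairs], dtype=float),
            task=tasks.pop(),
            ids=ids or [],
        )

    def subset(self, idx: np.ndarray) -> "LabeledBatch":
        ids = [self.ids[i] for i in idx] if self.ids else []
        return LabeledBatch(self.Xp[idx], self.Xl[idx], self.y[idx], self.task, ids)


@dataclass
class MetricReport:
    """Flat container for evaluation metrics; serializes to a dict/JSON."""

    rmse: float = np.nan
    r: float = np.nan
    sd: float = np.nan
    accuracy: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    specificity: float = np.nan
    mcc: float = np.nan
    f1: float = np.nan
    balanced_accuracy: float = np.nan
    auc: float = np.nan
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _check_lengths(a, b, what: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"{what}: inputs must be equal-length 1-D arrays")
    if a.size == 0:
        raise ValueError(f"{what}: inputs must be non-empty")
    return a, b


def bce_loss(probs, labels, eps: float = BCE_EPSILON) -> float:
    """Mean binary cross-entropy, probabilities clamped to ``[eps, 1-eps]``."""
    probs, labels = _check_lengths(probs, labels, "bce_loss")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("bce_loss labels must be 0/1")
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def mse_l2_loss(preds, values, weights=None, lam: float = 0.0) -> float:
    """Mean squared error plus ``lam * ||w||^2``.

    ``weights`` may be a precomputed squared norm (scalar) or an iterable of
    weight arrays whose squared norms are summed.
    """
    preds, values = _check_lengths(preds, values, "mse_l2_loss")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    mse = float(np.mean((preds - values) ** 2))
    if weights is None or lam == 0.0:
        sqnorm = 0.0
    elif np.isscalar(weights):
        sqnorm = float(weights)
    else:
        sqnorm = float(sum(np.sum(np.asarray(w) ** 2) for w in weights))
    return mse + lam * sqnorm


def regression_metrics(preds, values) -> MetricReport:
    """RMSE, Pearson's R and residual SD of true values vs predictions.

    ``values`` are the experimental affinities (y), ``preds`` the model
    outputs (y-hat).  SD uses the least-squares fit ``y ~ a*y_hat + b`` and
    an ``N - 1`` denominator.  R and SD need >= 2 points with nonzero
    variance on both sides; otherwise they are NaN with a warning.
    """
    preds, values = _check_lengths(preds, values, "regression_metrics")
    rmse = float(np.sqrt(np.mean((values - preds) ** 2)))
    r = np.nan
    sd = np.nan
    n = values.size
    if n >= 2 and np.var(values) > 0 and np.var(preds) > 0:
        vc = values - values.mean()
        pc = preds - preds.mean()
        r = float(np.sum(vc * pc) / np.sqrt(np.sum(vc ** 2) * np.sum(pc ** 2)))
        a = float(np.sum(vc * pc) / np.sum(pc ** 2))
        b = float(values.mean() - a * preds.mean())
        resid = values - (a * preds + b)
        sd = float(np.sqrt(np.sum(resid ** 2) / (n - 1)))
    else:
        warnings.warn("regression_metrics: zero variance or n < 2; R and SD undefined (NaN)")
    return MetricReport(rmse=rmse, r=r, sd=sd)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoid over score-ranked thresholds).

    Computed via tie-aware midranks, which equals the trapezoidal area
    exactly.  NaN (with a warning) when only one class is present.
    """
    scores, labels = _check_lengths(scores, labels, "roc_auc")
    pos = labels == 1
    npos, nneg = int(pos.sum()), int((~pos).sum())
    if npos == 0 or nneg == 0:
        warnings.warn("roc_auc: need both classes; returning NaN")
        return np.nan
    ranks = rankdata(scores)  # average ranks for ties
    return float((ranks[pos].sum() - npos * (npos + 1) / 2.0) / (npos * nneg))


def classification_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics at ``threshold`` plus threshold-free AUC.

    A sample is called positive when its score is strictly above the
    threshold.  Balanced accuracy is (recall + specificity) / 2 — the
    formula is a reconstruction, no canonical definition is imposed by the
    confusion counts alone.
    """
    scores, labels = _check_lengths(scores, labels, "classification_metrics")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("classification labels must be 0/1")
    calls = scores > threshold
    pos = labels == 1
    tp = int(np.sum(calls & pos))
    tn = int(np.sum(~calls & ~pos))
    fp = int(np.sum(calls & ~pos))
    fn = int(np.sum(~calls & pos))

    def _safe(num: float, den: float) -> float:
        if den == 0:
            return np.nan
        return num / den

    accuracy = _safe(tp + tn, tp + tn + fp + fn)
    precision = _safe(tp, tp + fp)
    recall = _safe(tp, tp + fn)
    specificity = _safe(tn, fp + tn)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe(tp * tn - fp * fn, mcc_den)
    f1 = np.nan
    if not np.isnan(precision) and not np.isnan(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    balanced = np.nan
    if not np.isnan(recall) and not np.isnan(specificity):
        balanced = (recall + specificity) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc = roc_auc(scores, labels)
    return MetricReport(
        accuracy=accuracy, precision=precision, recall=recall,
        specificity=specificity, mcc=mcc, f1=f1, balanced_accuracy=balanced,
        auc=auc, tp=tp, tn=tn, fp=fp, fn=fn,
    )
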