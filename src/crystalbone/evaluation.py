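"""Threshold-free and thresholded classifier metrics, plus the
primary/subsequent fracture stratification.

AUROC is computed as the Mann-Whitney concordance (probability that a
random positive outranks a random negative, ties counted half) via
midranks; AUPRC uses the average-precision formulation (step-wise
integration over recall), not trapezoidal interpolation — the two differ
at small n, so the choice is fixed and documented here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .windows import Window


def _as_arrays(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and the same length")
    return s, y


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(tie)."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision (step-wise PR integration)."""
    s, y = _as_arrays(scores, labels)
    if y.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(y, s))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the flag rule ``score >= threshold``."""
    s, y = _as_arrays(scores, labels)
    flag = s >= threshold
    return ConfusionCounts(
        tp=int((flag & (y == 1)).sum()),
        fp=int((flag & (y == 0)).sum()),
        tn=int((~flag & (y == 0)).sum()),
        fn=int((~flag & (y == 1)).sum()),
    )


@dataclass
class EvaluationReport:
    """Threshold metrics in the shape of the published comparison table."""

    stratum: str
    n_windows: int
    auroc: float | None
    auprc: float | None
    recall: float | None
    specificity: float | None
    precision: float | None
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def build(cls, scores, labels, threshold: float, stratum: str = "overall") -> "EvaluationReport":
        s, y = _as_arrays(scores, labels)
        cm = confusion_at_threshold(s, y, threshold)
        n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp

        def ratio(a, b):
            return a / b if b else None

        return cls(
            stratum=stratum,
            n_windows=cm.n,
            auroc=auroc(s, y) if n_pos and n_neg else None,
            auprc=auprc(s, y) if n_pos else None,
            recall=ratio(cm.tp, n_pos),
            specificity=ratio(cm.tn, n_neg),
            precision=ratio(cm.tp, cm.tp + cm.fp),
            threshold=threshold,
            tp=cm.tp,
            fp=cm.fp,
            tn=cm.tn,
            fn=cm.fn,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(scores, labels, threshold: float = 0.5, stratum: str = "overall") -> EvaluationReport:
    if len(np.asarray(labels)) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    return EvaluationReport.build(scores, labels, threshold, stratum)


def evaluate_stratified(
    windows: list[Window],
    scores,
    threshold: float = 0.5,
) -> dict[str, EvaluationReport]:
    """Overall report plus per-stratum reports for primary vs subsequent
    fracture windows.

    A positive window joins the stratum of its anchor fracture's
    ``is_subsequent`` flag; negative windows have no fracture type, so they
    join both strata's negatives.  Empty strata are absent, not fatal.
    """
    s = np.asarray(scores, dtype=float)
    y = np.array([w.label for w in windows], dtype=int)
    if len(s) != len(windows):
        raise ValueError("scores and windows must align")
    reports = {"overall": EvaluationReport.build(s, y, threshold, "overall")}
    is_sub = np.array(
        [
            bool(w.anchor.fracture.is_subsequent)
            if (w.label and w.anchor.fracture is not None)
            else False
            for w in windows
        ]
    )
    for name, pos_mask in (
        ("primary", (y == 1) & ~is_sub),
        ("subsequent", (y == 1) & is_sub),
    ):
        mask = pos_mask | (y == 0)
        if pos_mask.sum() == 0:
            continue
        reports[name] = EvaluationReport.build(s[mask], y[mask], threshold, name)
    return reports
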