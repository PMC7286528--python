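"""ROC analysis and marker positivity cutoffs.

Continuous methylation measurements (qMSP score or pyrosequencing percent)
of cancer vs normal samples are reduced to a per-marker cutoff: the ROC
curve is computed over all distinct score values, AUC by the trapezoid rule
(equivalently the normalized Mann-Whitney U), and the operating cutoff is
chosen by Youden's J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

#: Published per-gene positivity cutoffs for the five-marker panel.
#: ADAMTS2/PCDH10/SEMA5A/SPSB4 are qMSP scores, HOXA1 is pyrosequencing %.
DEFAULT_PANEL_CUTOFFS: dict[str, float] = {
    "ADAMTS2": 0.90,
    "PCDH10": 0.70,
    "SEMA5A": 0.24,
    "SPSB4": 0.20,
    "HOXA1": 17.64,
}

DEFAULT_MEASUREMENT_KIND: dict[str, str] = {
    "ADAMTS2": "qmsp",
    "PCDH10": "qmsp",
    "SEMA5A": "qmsp",
    "SPSB4": "qmsp",
    "HOXA1": "pyrosequencing_percent",
}


@dataclass
class MarkerPanel:
    """Marker name -> positivity cutoff, with the measurement kind per marker."""

    cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_CUTOFFS)
    )
    measurement_kind: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_KIND)
    )

    def __post_init__(self) -> None:
        bad = [m for m, c in self.cutoffs.items() if c <= 0]
        if bad:
            raise ValueError(f"cutoffs must be positive: {bad}")


@dataclass
class RocResult:
    """ROC curve with the underlying scores retained for cutoff selection."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # true-positive rate per threshold
    fpr: np.ndarray  # 1 - specificity per threshold
    auc: float
    scores: np.ndarray
    labels: np.ndarray
    chosen_cutoff: float | None = None


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires at least one positive and one negative")
    return scores, labels


def roc_curve(scores, labels) -> RocResult:
    """ROC over all distinct score values; AUC by the trapezoid rule."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        fpr=fpr,
        auc=float(roc_auc_score(labels, scores)),
        scores=scores,
        labels=labels,
    )


def best_threshold(roc: RocResult, criterion: str = "youden") -> float:
    """Operating cutoff for a strict ``measurement > cutoff`` positivity rule.

    Candidate cutoffs are the midpoints between consecutive distinct score
    values plus one sentinel below the minimum and the maximum itself, so the
    returned cutoff sits inside a separating gap rather than on a data point.
    ``criterion`` is ``"youden"`` (maximize sensitivity + specificity - 1) or
    ``"closest_topleft"`` (minimize distance to the (0, 1) ROC corner).  Ties
    break toward higher specificity, then toward the lower cutoff.  Sets and
    returns ``roc.chosen_cutoff``.
    """
    if criterion not in ("youden", "closest_topleft"):
        raise ValueError(f"unknown criterion {criterion!r}")
    uniq = np.unique(roc.scores)
    if len(uniq) == 1:
        logger.warning("all scores identical; Youden J = 0 at that value")
        roc.chosen_cutoff = float(uniq[0])
        return roc.chosen_cutoff
    candidates = np.concatenate(
        [[uniq[0] - (uniq[1] - uniq[0])], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]]
    )
    pos = roc.labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best: tuple[float, float, float] | None = None  # (objective, spec, -cutoff)
    best_cut = candidates[0]
    for cut in candidates:
        called = roc.scores > cut
        sens = (called & pos).sum() / n_pos
        spec = (~called & ~pos).sum() / n_neg
        if criterion == "youden":
            obj = sens + spec - 1.0
        else:
            obj = -float(np.hypot(1.0 - spec, 1.0 - sens))
        key = (obj, spec, -cut)
        if best is None or key > best:
            best, best_cut = key, cut
    roc.chosen_cutoff = float(best_cut)
    return roc.chosen_cutoff


def binarize(measurement: float, panel: MarkerPanel, marker: str) -> bool:
    """Positive iff the measurement strictly exceeds the marker's cutoff."""
    if marker not in panel.cutoffs:
        raise KeyError(f"marker {marker!r} not in panel")
    return float(measurement) > panel.cutoffs[marker]
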