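"""Operating-point selection, the slide-level IC score and evaluation
metrics.

The slide score is

    S_IC = sum(P for P > P0) / N

with P the patch scores, P0 the patch threshold and N the number of
scored epithelial patches. Both the patch and slide decisions use a
strict ``>`` comparison; threshold ties are broken toward the smallest
maximizer; IC is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, NoEpitheliumError

_LEVELS = ("patch", "slide")


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map {IC, Rest} / {1, 0} labels to int {1, 0}."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "IC").astype(int)
    return (arr > 0).astype(int)


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdFit:
    threshold: float
    f1: float
    candidates: tuple[float, ...]
    level: str


def _f1(scores: np.ndarray, y: np.ndarray, threshold: float) -> float:
    pred = scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(scores: Sequence[float], labels: Sequence, level: str = "patch") -> ThresholdFit:
    """Exhaustive F1 maximization over the sorted unique scores plus
    {0, 1}; returns the smallest threshold attaining the maximum
    (predicted-positive means score strictly above the threshold)."""
    if level not in _LEVELS:
        raise DataError(f"level must be one of {_LEVELS}")
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    if len(scores) != len(y):
        raise DataError(f"{len(scores)} scores vs {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise DataError("threshold selection needs both classes present")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best_t, best_f1 = None, -1.0
    for t in candidates:  # ascending: first maximizer is the smallest
        f1 = _f1(scores, y, float(t))
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return ThresholdFit(
        threshold=best_t, f1=best_f1, candidates=tuple(candidates.tolist()), level=level
    )


# ---------------------------------------------------------------------------
# Slide score
# ---------------------------------------------------------------------------


def slide_score(patch_scores: Sequence[float], p0: float) -> float:
    """S_IC = sum of scores strictly above P0, divided by the number of
    scored patches. An empty score list is a no-epithelium condition,
    signalled as :class:`NoEpitheliumError`, never as 0.0."""
    scores = np.asarray(patch_scores, dtype=np.float64)
    if scores.size == 0:
        raise NoEpitheliumError("no epithelial patches on this slide")
    return float(scores[scores > p0].sum() / scores.size)


def classify_slide(s_ic: float, slide_threshold: float) -> str:
    """IC iff the slide score is strictly above the slide threshold."""
    return "IC" if s_ic > slide_threshold else "Rest"


@dataclass
class SlideScoreReport:
    """Per-slide scoring outcome; JSON-serializable via ``to_dict``."""

    slide_id: str
    patch_centers: list[tuple[int, int]]
    patch_scores: list[float]
    p0: float
    slide_threshold: float
    s_ic: float | None  # None on a no-epithelium slide
    slide_call: str  # "IC" | "Rest" | "no_epithelium"
    n_patches: int
    filter_report: dict | None = None
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "p0": self.p0,
            "slide_threshold": self.slide_threshold,
            "s_ic": self.s_ic,
            "slide_call": self.slide_call,
            "n_patches": self.n_patches,
            "patches": [
                {"center_xy": list(c), "score": s}
                for c, s in zip(self.patch_centers, self.patch_scores)
            ],
            "filter_report": self.filter_report,
            "timings_s": self.timings_s,
        }


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalMetrics:
    level: str
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float | None  # None when TP+FP == 0
    recall: float | None  # None when TP+FN == 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
        }


def evaluate(predictions: Sequence, truths: Sequence, level: str = "patch") -> EvalMetrics:
    """Confusion counts and accuracy / precision / recall with IC as the
    positive class. Ratios with a zero denominator are reported as absent
    (None), never as 0."""
    if level not in _LEVELS:
        raise DataError(f"level must be one of {_LEVELS}")
    pred = _as_binary(predictions)
    true = _as_binary(truths)
    if len(pred) != len(true) or len(pred) == 0:
        raise DataError(f"predictions ({len(pred)}) and truths ({len(true)}) mismatch or empty")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    return EvalMetrics(
        level=level,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / (tp + fp + fn + tn),
        precision=tp / (tp + fp) if (tp + fp) else None,
        recall=tp / (tp + fn) if (tp + fn) else None,
    )
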