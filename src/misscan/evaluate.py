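"""Validation machinery: one-vs-rest residue confusion counts, precision /
recall / F1, region-length-stratified per-residue metrics, and the
modeled-ratio prioritisation screen.

Region-stratified counting segments hard-missing runs independently in the
prediction and in the truth: a position is "predicted short" iff it lies in a
run tagged short by the prediction's own segmentation (and likewise for truth),
so a long truth region fragmented by the predictor shows up as short-region
false positives.

Undefined metrics (zero denominators) are reported as missing (None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HARD_MISSING,
    LABEL_NAMES,
    MODELED,
    ResidueLabels,
    ScoreTracks,
    as_label_array,
)
from .classify import segment_regions
from .feature_stats import PLDDT_THRESHOLD

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "residue_confusion",
    "precision_recall_f1",
    "region_membership",
    "region_stratified_confusion",
    "evaluate_predictions",
    "ScreenResult",
    "screen_sequences",
]

_CLASS_CODES = {name: code for code, name in enumerate(LABEL_NAMES)}


@dataclass
class ConfusionCounts:
    """One-vs-rest per-residue confusion counts for one target."""

    target: str
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.target != other.target:
            raise ValueError("cannot add confusion counts for different targets")
        return ConfusionCounts(
            self.target, self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricsRow:
    """Precision / recall / F1 for one target; None where undefined."""

    target: str
    precision: float | None
    recall: float | None
    f1: float | None
    counts: ConfusionCounts


def _as_vec(labels) -> np.ndarray:
    return as_label_array(labels)


def residue_confusion(pred, truth, target_class: str | int) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``target_class`` over all positions."""
    p = _as_vec(pred)
    t = _as_vec(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal lengths")
    code = _CLASS_CODES[target_class] if isinstance(target_class, str) else int(target_class)
    name = LABEL_NAMES[code]
    pp = p == code
    tt = t == code
    return ConfusionCounts(
        target=name,
        tp=int((pp & tt).sum()),
        tn=int((~pp & ~tt).sum()),
        fp=int((pp & ~tt).sum()),
        fn=int((~pp & tt).sum()),
    )


def precision_recall_f1(counts: ConfusionCounts) -> MetricsRow:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean;
    a metric with a zero denominator is missing (None), and F1 is missing
    whenever either component is missing or precision+recall is zero."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsRow(counts.target, precision, recall, f1, counts)


def region_membership(labels, length_class: str) -> np.ndarray:
    """Boolean vector: position lies in a hard-missing run of the given length
    class under this labelling's own segmentation."""
    if length_class not in ("short", "long"):
        raise ValueError("length_class must be 'short' or 'long'")
    vec = _as_vec(labels)
    member = np.zeros(vec.size, dtype=bool)
    for region in segment_regions(vec):
        if region.length_class == length_class:
            member[region.start - 1 : region.end] = True
    return member


def region_stratified_confusion(pred, truth, length_class: str) -> ConfusionCounts:
    """Per-residue confusion for membership in short (or long) regions.

    Membership is evaluated independently under the prediction's and the
    truth's own run segmentation.
    """
    p = _as_vec(pred)
    t = _as_vec(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal lengths")
    pm = region_membership(p, length_class)
    tm = region_membership(t, length_class)
    return ConfusionCounts(
        target=length_class,
        tp=int((pm & tm).sum()),
        tn=int((~pm & ~tm).sum()),
        fp=int((pm & ~tm).sum()),
        fn=int((~pm & tm).sum()),
    )


def evaluate_predictions(
    preds: Sequence[np.ndarray | ResidueLabels],
    truths: Sequence[np.ndarray | ResidueLabels],
    targets: Sequence[str] = ("modeled", "hard_missing", "soft_missing", "short", "long"),
) -> pd.DataFrame:
    """Corpus-level metrics report: counts pooled over proteins, one row per
    target (classes one-vs-rest; short/long by region membership)."""
    if len(preds) != len(truths):
        raise ValueError("need one prediction per truth")
    rows = []
    for target in targets:
        pooled = ConfusionCounts(target)
        for p, t in zip(preds, truths):
            if target in ("short", "long"):
                pooled = pooled + region_stratified_confusion(p, t, target)
            else:
                pooled = pooled + residue_confusion(p, t, target)
        row = precision_recall_f1(pooled)
        rows.append(
            {
                "target": target,
                "tp": pooled.tp, "tn": pooled.tn, "fp": pooled.fp, "fn": pooled.fn,
                "precision": row.precision, "recall": row.recall, "f1": row.f1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Prioritisation verdict for one sequence."""

    sequence_id: str
    seq_length: int
    plddt_high_ratio: float
    predicted_modeled_ratio: float
    selected: bool


def screen_sequences(
    entries: Sequence[tuple[str, ScoreTracks, np.ndarray]],
    ratio_threshold: float = 0.8,
    min_length: int = 200,
) -> list[ScreenResult]:
    """Prioritise structurally tractable sequences.

    Each entry is ``(sequence_id, tracks, predicted_labels)``. A sequence is
    selected iff its high-confidence pLDDT ratio (fraction >= 70) and its
    predicted-modeled ratio are both >= ``ratio_threshold`` and its length is
    strictly greater than ``min_length``.
    """
    results = []
    for seq_id, tracks, pred in entries:
        pred = _as_vec(pred)
        if len(pred) != len(tracks):
            raise ValueError(f"{seq_id}: tracks and predictions must be aligned")
        n = len(pred)
        high_ratio = float((tracks.plddt >= PLDDT_THRESHOLD).mean()) if n else 0.0
        modeled_ratio = float((pred == MODELED).mean()) if n else 0.0
        selected = (
            high_ratio >= ratio_threshold
            and modeled_ratio >= ratio_threshold
            and n > min_length
        )
        results.append(ScreenResult(seq_id, n, high_ratio, modeled_ratio, selected))
    return results
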