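"""Descriptive analyses: correlations of class counts with feature counts,
quadrant analysis at the pLDDT 70 / IUPred 0.5 thresholds, and per-class
amino-acid composition.

Correlations are computed across proteins on raw counts (not length-normalised
and not per-residue); the thresholds treat pLDDT exactly 70 as high confidence
and IUPred exactly 0.5 as disordered, consistently with the baselines.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ALPHABET,
    HARD_MISSING,
    LABEL_NAMES,
    MODELED,
    SOFT_MISSING,
    ResidueLabels,
    ScoreTracks,
    as_label_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PLDDT_THRESHOLD",
    "IUPRED_THRESHOLD",
    "pearson_r",
    "class_count_table",
    "feature_count_table",
    "correlate_classes_vs_features",
    "assign_quadrant",
    "assign_quadrants",
    "quadrant_occupancy",
    "composition_profile",
]

PLDDT_THRESHOLD = 70.0
IUPRED_THRESHOLD = 0.5

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (with a warning) when either input has
    zero variance, where r is undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson_r undefined for zero-variance input; reporting NaN")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def class_count_table(labels_per_protein: Sequence[ResidueLabels | np.ndarray]) -> pd.DataFrame:
    """Per-protein residue counts of the three classes."""
    rows = []
    for labels in labels_per_protein:
        vec = as_label_array(labels)
        rows.append({name: int((vec == code).sum()) for code, name in enumerate(LABEL_NAMES)})
    return pd.DataFrame(rows)


def feature_count_table(
    sequences: Sequence[str],
    tracks_per_protein: Sequence[ScoreTracks],
    ss_tracks: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-protein feature counts: residues above/below the pLDDT and IUPred
    thresholds, one count per amino-acid letter, and (optionally) counts per
    secondary-structure element type from an annotation track."""
    rows = []
    for i, (seq, tracks) in enumerate(zip(sequences, tracks_per_protein)):
        if len(seq) != len(tracks):
            raise ValueError(f"protein {i}: sequence and tracks disagree in length")
        row: dict[str, int] = {
            "plddt_high": int((tracks.plddt >= PLDDT_THRESHOLD).sum()),
            "plddt_low": int((tracks.plddt < PLDDT_THRESHOLD).sum()),
            "iupred_ordered": int((tracks.iupred < IUPRED_THRESHOLD).sum()),
            "iupred_disordered": int((tracks.iupred >= IUPRED_THRESHOLD).sum()),
        }
        for aa in ALPHABET:
            row[f"aa_{aa}"] = seq.count(aa)
        if ss_tracks is not None:
            ss = list(ss_tracks[i])
            for element in ("helix", "strand", "turn"):
                row[f"ss_{element}"] = sum(1 for s in ss if s == element)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_classes_vs_features(
    class_counts: pd.DataFrame, feature_counts: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r for every (class, feature) pair across proteins.

    Rows are classes, columns features; undefined correlations (zero variance)
    appear as NaN.
    """
    if len(class_counts) != len(feature_counts):
        raise ValueError("class and feature tables must cover the same proteins")
    if len(class_counts) < 3:
        raise ValueError("need at least three proteins for a correlation table")
    table = pd.DataFrame(
        index=list(class_counts.columns), columns=list(feature_counts.columns), dtype=float
    )
    for cls in class_counts.columns:
        for feat in feature_counts.columns:
            table.loc[cls, feat] = pearson_r(
                class_counts[cls].to_numpy(), feature_counts[feat].to_numpy()
            )
    return table


def assign_quadrant(plddt: float, iupred: float) -> str:
    """Quadrant of one residue in the joint (pLDDT, IUPred) plane:
    Q1 confident/ordered, Q2 confident/disordered, Q3 low-confidence/ordered,
    Q4 low-confidence/disordered."""
    if not (0.0 <= plddt <= 100.0):
        raise ValueError(f"pLDDT {plddt} outside [0, 100]")
    if not (0.0 <= iupred <= 1.0):
        raise ValueError(f"IUPred {iupred} outside [0, 1]")
    high = plddt >= PLDDT_THRESHOLD
    disordered = iupred >= IUPRED_THRESHOLD
    if high:
        return "Q2" if disordered else "Q1"
    return "Q4" if disordered else "Q3"


def assign_quadrants(tracks: ScoreTracks) -> np.ndarray:
    """Vectorised quadrant labels ('Q1'..'Q4') for a whole protein."""
    high = tracks.plddt >= PLDDT_THRESHOLD
    disordered = tracks.iupred >= IUPRED_THRESHOLD
    out = np.where(high, np.where(disordered, "Q2", "Q1"), np.where(disordered, "Q4", "Q3"))
    return out.astype("<U2")


def quadrant_occupancy(
    labels: ResidueLabels | Sequence[ResidueLabels],
    tracks: ScoreTracks | Sequence[ScoreTracks],
) -> pd.DataFrame:
    """Fraction of each class's residues falling in each quadrant.

    Accepts a single protein or a corpus (sequences of aligned labels/tracks);
    fractions per class sum to 1; a class with no residues is all-NaN.
    """
    if isinstance(labels, ResidueLabels):
        labels = [labels]
        tracks = [tracks]  # type: ignore[list-item]
    counts = pd.DataFrame(0, index=list(LABEL_NAMES), columns=list(QUADRANTS), dtype=float)
    for lab, trk in zip(labels, tracks):
        vec = as_label_array(lab)
        if len(vec) != len(trk):
            raise ValueError("labels and tracks must be aligned")
        quads = assign_quadrants(trk)
        for code, name in enumerate(LABEL_NAMES):
            sel = vec == code
            if sel.any():
                q, n = np.unique(quads[sel], return_counts=True)
                counts.loc[name, q] += n
    totals = counts.sum(axis=1)
    occupancy = counts.div(totals, axis=0)
    occupancy[totals == 0] = np.nan
    return occupancy


def composition_profile(
    labels: ResidueLabels | Sequence[ResidueLabels],
    sequence: str | Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class amino-acid frequencies and enrichment relative to modeled.

    Returns ``(frequencies, enrichment)``: frequencies are rows per class over
    the 21-letter alphabet summing to 1; enrichment is frequency(class) /
    frequency(modeled) per letter (NaN where modeled frequency is zero or the
    class is empty).
    """
    if isinstance(labels, ResidueLabels):
        labels = [labels]
        sequence = [sequence]  # type: ignore[list-item]
    counts = pd.DataFrame(0.0, index=list(LABEL_NAMES), columns=list(ALPHABET))
    for lab, seq in zip(labels, sequence):
        vec = as_label_array(lab)
        if len(vec) != len(seq):
            raise ValueError("labels and sequence must be aligned")
        arr = np.array(list(seq))
        for code, name in enumerate(LABEL_NAMES):
            sel = vec == code
            if sel.any():
                letters, n = np.unique(arr[sel], return_counts=True)
                for letter, cnt in zip(letters, n):
                    if letter in counts.columns:
                        counts.loc[name, letter] += cnt
    totals = counts.sum(axis=1)
    freqs = counts.div(totals, axis=0)
    freqs[totals == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = freqs.div(freqs.loc["modeled"], axis=1)
    return freqs, enrichment
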