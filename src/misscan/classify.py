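"""Residue taxonomy, region segmentation, and solved/unsolved labelling.

The taxonomy compares Cα presence across all structure entries grouped under
one protein: present everywhere -> modeled, absent everywhere -> hard missing,
mixed -> soft missing. Maximal hard-missing runs are tagged short (<= 30
residues) or long (> 30).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    HARD_MISSING,
    MODELED,
    SOFT_MISSING,
    CoverageAnnotation,
    Region,
    RegionSet,
    ResidueLabels,
    StructureObservation,
)

logger = logging.getLogger(__name__)

__all__ = ["classify_residues", "segment_regions", "label_solved_unsolved"]


def _classify_mask_matrix(masks: np.ndarray) -> np.ndarray:
    """Vectorised taxonomy kernel over an (entries x positions) presence matrix.

    Also accepts a batch (n x entries x positions); classification is applied
    along the entries axis.
    """
    masks = np.asarray(masks, dtype=bool)
    axis = masks.ndim - 2
    return np.where(
        masks.all(axis=axis),
        MODELED,
        np.where(~masks.any(axis=axis), HARD_MISSING, SOFT_MISSING),
    ).astype(np.int8)


def classify_residues(observations: list[StructureObservation]) -> ResidueLabels:
    """Classify every position of a protein from its grouped entries.

    A position never covered by any entry's construct is indistinguishable
    from an unresolved one under the Cα rule and is labelled hard_missing.
    """
    if not observations:
        raise ValueError("at least one structure observation is required")
    lengths = {obs.n_positions for obs in observations}
    if len(lengths) != 1:
        raise ValueError(f"observations have unequal mask lengths: {sorted(lengths)}")
    if len(observations) == 1:
        logger.warning(
            "single structure entry: soft_missing cannot be detected; "
            "labels are modeled/hard_missing only"
        )
    masks = np.vstack([obs.presence for obs in observations])
    return ResidueLabels(_classify_mask_matrix(masks), n_entries_used=len(observations))


def segment_regions(labels: ResidueLabels | np.ndarray) -> RegionSet:
    """Maximal runs of consecutive hard-missing positions, tagged short/long.

    The union of the returned regions is exactly the hard-missing position
    set; no hard-missing residues yields an empty set.
    """
    vec = labels.labels if isinstance(labels, ResidueLabels) else np.asarray(labels, dtype=np.int8)
    hard = np.concatenate(([False], vec == HARD_MISSING, [False]))
    edges = np.flatnonzero(np.diff(hard.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return RegionSet([Region(int(s) + 1, int(e)) for s, e in zip(starts, ends)])


def label_solved_unsolved(annotation: CoverageAnnotation) -> np.ndarray:
    """Boolean per-position vector: True where the residue lies inside any
    solved range (overlaps merged), False elsewhere. A protein with no ranges
    is entirely unsolved (the fully undetermined case)."""
    solved = np.zeros(annotation.seq_length, dtype=bool)
    for start, end in annotation.solved_ranges:
        solved[start - 1 : end] = True
    return solved
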