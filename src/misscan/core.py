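"""Core containers shared across the pipeline.

Residue classes follow the three-way taxonomy used throughout the package:

* ``modeled`` — the Cα atom is present in every structure entry of the protein;
* ``hard_missing`` — the Cα is absent in every entry (the operational proxy for
  intrinsic disorder);
* ``soft_missing`` — the Cα is present in some entries and absent in others.

All residue coordinates are 1-based inclusive, matching UniProt/PDB usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MODELED: int = 0
HARD_MISSING: int = 1
SOFT_MISSING: int = 2

LABEL_NAMES: tuple[str, str, str] = ("modeled", "hard_missing", "soft_missing")

#: Maximal run of hard-missing residues still called a "short" region.
SHORT_REGION_MAX: int = 30

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE: str = "X"
ALPHABET: str = AMINO_ACIDS + UNKNOWN_RESIDUE


class MisscanError(Exception):
    """Base class for package errors."""


class ConfigurationError(MisscanError, ValueError):
    """Invalid generator or training configuration."""


class FormatError(MisscanError, ValueError):
    """An input file violates its expected format."""


def label_name(code: int) -> str:
    return LABEL_NAMES[int(code)]


@dataclass
class StructureObservation:
    """Per-position Cα presence of one structure entry, aligned to the
    full-length sequence (index 0 is residue 1)."""

    entry_id: str
    chain_id: str
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 1:
            raise ValueError("presence mask must be one-dimensional")

    @property
    def n_positions(self) -> int:
        return int(self.presence.size)


@dataclass
class ResidueLabels:
    """Per-position class vector over the three-way taxonomy."""

    labels: np.ndarray
    n_entries_used: int = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and not np.isin(self.labels, (MODELED, HARD_MISSING, SOFT_MISSING)).all():
            raise ValueError("labels must be in {modeled, hard_missing, soft_missing}")
        if self.n_entries_used == 1 and (self.labels == SOFT_MISSING).any():
            raise ValueError("soft_missing is impossible with a single structure entry")

    def __len__(self) -> int:
        return int(self.labels.size)

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for code, name in enumerate(LABEL_NAMES)}

    def names(self) -> list[str]:
        return [LABEL_NAMES[c] for c in self.labels]


@dataclass(frozen=True)
class Region:
    """Maximal run of hard-missing residues, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_class(self) -> str:
        return "short" if self.length <= SHORT_REGION_MAX else "long"


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def total_residues(self) -> int:
        return sum(r.length for r in self.regions)

    def by_length_class(self, length_class: str) -> list[Region]:
        return [r for r in self.regions if r.length_class == length_class]


@dataclass
class ScoreTracks:
    """Aligned per-residue pLDDT (0-100) and IUPred (0-1) tracks."""

    plddt: np.ndarray
    iupred: np.ndarray

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.iupred = np.asarray(self.iupred, dtype=float)
        if self.plddt.shape != self.iupred.shape or self.plddt.ndim != 1:
            raise ValueError("pLDDT and IUPred tracks must be 1-D and equally long")
        if self.plddt.size:
            if self.plddt.min() < 0 or self.plddt.max() > 100:
                raise ValueError("pLDDT values must lie in [0, 100]")
            if self.iupred.min() < 0 or self.iupred.max() > 1:
                raise ValueError("IUPred values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.plddt.size)


@dataclass
class CoverageAnnotation:
    """Solved residue ranges of one protein (UniProt-style PDB coverage)."""

    accession: str
    seq_length: int
    solved_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        for start, end in self.solved_ranges:
            if not (1 <= start <= end <= self.seq_length):
                raise ValueError(
                    f"{self.accession}: range {start}-{end} outside 1..{self.seq_length}"
                )


@dataclass
class ProteinRecord:
    """One protein with whatever evidence has been attached to it."""

    protein_id: str
    sequence: str
    group: str = "xray"
    observations: list[StructureObservation] = field(default_factory=list)
    tracks: ScoreTracks | None = None
    labels: ResidueLabels | None = None
    regions: RegionSet | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def as_label_array(labels: ResidueLabels | Sequence[int] | np.ndarray) -> np.ndarray:
    """Accept either a ResidueLabels or a raw label vector."""
    if isinstance(labels, ResidueLabels):
        return labels.labels
    return np.asarray(labels, dtype=np.int8)
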