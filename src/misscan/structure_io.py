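"""Readers and writers for every external format the pipeline touches.

Structure files (PDB or mmCIF) are read with gemmi for Cα presence and for
pLDDT stored in the B-factor column of predicted models; IUPred tables,
coverage annotations and FASTA round out the inputs. Input structures must be
numbered on the full-length sequence (1-based); author-numbering remapping is
out of scope, so ``seq_length`` is always an explicit argument.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import CoverageAnnotation, FormatError, StructureObservation

logger = logging.getLogger(__name__)

__all__ = [
    "read_calpha_presence",
    "read_plddt_track",
    "read_iupred_output",
    "default_short_sequence_scores",
    "read_coverage_annotations",
    "read_fasta",
    "write_report",
]

#: IUPred3 cannot score sequences shorter than this; they get an all-zero track.
IUPRED_MIN_LENGTH = 16


def _read_structure(path: str | Path) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure file ({exc})") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: structure contains no models")
    return st


def _check_seqid(path, res) -> int | None:
    """Validate one residue's sequence id; returns its 1-based number or None
    to skip. Insertion codes and negative numbers are rejected outright."""
    if res.seqid.icode not in (" ", ""):
        raise FormatError(
            f"{path}: residue {res.seqid.num}{res.seqid.icode} has an insertion code; "
            "inputs must be numbered on the full-length sequence"
        )
    if res.seqid.num < 0:
        raise FormatError(f"{path}: negative residue number {res.seqid.num}")
    return res.seqid.num


def read_calpha_presence(
    structure_file: str | Path, chain_id: str, seq_length: int
) -> StructureObservation:
    """Per-position Cα presence of one chain, aligned to residues 1..seq_length.

    ``presence[i]`` is True iff an atom named CA exists for residue number
    ``i+1`` in the chosen chain; alternate locations count once. Residue
    numbers outside 1..seq_length are ignored with a warning.
    """
    path = Path(structure_file)
    st = _read_structure(path)
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        if len(model) == 0:
            # an entry whose construct resolved no residues at all: a legal
            # (fully absent) observation rather than a wrong chain id
            logger.warning("%s: structure contains no atoms; all positions absent", path)
            return StructureObservation(
                entry_id=path.stem, chain_id=chain_id, presence=np.zeros(seq_length, dtype=bool)
            )
        available = ", ".join(ch.name for ch in model)
        raise ValueError(f"{path}: chain {chain_id!r} not found (available: {available})")
    presence = np.zeros(seq_length, dtype=bool)
    for res in chain:
        num = _check_seqid(path, res)
        if num < 1 or num > seq_length:
            logger.warning("%s: residue number %d outside 1..%d ignored", path, num, seq_length)
            continue
        if any(atom.name == "CA" for atom in res):
            presence[num - 1] = True
    return StructureObservation(entry_id=path.stem, chain_id=chain_id, presence=presence)


def read_plddt_track(model_file: str | Path, seq_length: int) -> np.ndarray:
    """Per-residue pLDDT from a predicted-model file (B-factor column).

    Every atom of a residue must carry the same value (to 1e-6). The file must
    cover residues 1..seq_length exactly and use the 0-100 scale; files on a
    0-1 scale are rejected rather than rescaled. Values are returned at the
    2-decimal precision the B-factor column carries.
    """
    path = Path(model_file)
    st = _read_structure(path)
    values: dict[int, float] = {}
    for chain in st[0]:
        for res in chain:
            num = _check_seqid(path, res)
            bvals = [atom.b_iso for atom in res]
            if not bvals:
                continue
            if max(bvals) - min(bvals) > 1e-6:
                raise FormatError(
                    f"{path}: residue {num} has disagreeing per-atom confidence values"
                )
            if num in values and abs(values[num] - bvals[0]) > 1e-6:
                raise FormatError(f"{path}: residue number {num} appears twice with different values")
            values[num] = float(bvals[0])
    if sorted(values) != list(range(1, seq_length + 1)):
        raise FormatError(
            f"{path}: model covers {len(values)} residues, expected exactly 1..{seq_length}"
        )
    track = np.array([values[i] for i in range(1, seq_length + 1)], dtype=float)
    if track.min() < 0 or track.max() > 100:
        raise FormatError(f"{path}: pLDDT values outside [0, 100]")
    if seq_length > 0 and track.max() <= 1.0:
        raise FormatError(
            f"{path}: confidence values all <= 1; expected the 0-100 pLDDT scale"
        )
    return np.round(track, 2)


def read_iupred_output(table_file: str | Path, sequence: str) -> np.ndarray:
    """Parse an IUPred3 long-mode output table (``# POS RES IUPRED`` dialect).

    Rows are validated against ``sequence``: positions must be 1..len(sequence)
    in order and the residue letters must match.
    """
    path = Path(table_file)
    scores = np.full(len(sequence), np.nan)
    expected_pos = 1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            pos = int(parts[0])
            score = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
        if pos != expected_pos:
            raise FormatError(f"{path}:{lineno}: non-monotone position {pos}, expected {expected_pos}")
        if pos > len(sequence):
            raise FormatError(f"{path}:{lineno}: position {pos} beyond sequence length {len(sequence)}")
        if parts[1] != sequence[pos - 1]:
            raise FormatError(
                f"{path}:{lineno}: residue letter {parts[1]!r} at position {pos} "
                f"does not match sequence ({sequence[pos - 1]!r})"
            )
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"{path}:{lineno}: IUPred score {score} outside [0, 1]")
        scores[pos - 1] = score
        expected_pos += 1
    if expected_pos != len(sequence) + 1:
        raise FormatError(f"{path}: table covers {expected_pos - 1} positions, expected {len(sequence)}")
    return scores


def default_short_sequence_scores(sequence: str) -> np.ndarray | None:
    """IUPred cannot process sequences shorter than 16 residues; those get an
    all-zero disorder track (negligible disorder content assumed). Returns
    None for sequences of 16+ residues, signalling that a real score table is
    required."""
    if len(sequence) < IUPRED_MIN_LENGTH:
        return np.zeros(len(sequence), dtype=float)
    return None


def read_coverage_annotations(table_file: str | Path) -> list[CoverageAnnotation]:
    """Parse a coverage table: accession, seq_length, semicolon-separated
    start-end ranges (the ranges field may be empty -> fully unsolved)."""
    path = Path(table_file)
    annotations: list[CoverageAnnotation] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, skipinitialspace=True)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected accession, seq_length[, ranges]")
            accession = row[0].strip()
            try:
                seq_length = int(row[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad seq_length {row[1]!r}") from exc
            ranges: list[tuple[int, int]] = []
            field = row[2].strip() if len(row) > 2 else ""
            if field:
                for token in field.split(";"):
                    token = token.strip()
                    if not token:
                        continue
                    try:
                        start_s, end_s = token.split("-")
                        start, end = int(start_s), int(end_s)
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: malformed range {token!r}") from exc
                    ranges.append((start, end))
            try:
                annotations.append(CoverageAnnotation(accession, seq_length, ranges))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return annotations


def read_fasta(fasta_file: str | Path) -> dict[str, str]:
    """All records of a FASTA file as {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_file), "fasta")}


def write_report(report: pd.DataFrame, path: str | Path, summary: dict | None = None) -> None:
    """Write a report table as TSV plus a JSON summary side-car."""
    path = Path(path)
    report.to_csv(path, sep="\t", index=False)
    side = path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path
    if summary is not None:
        side.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float) + "\n")
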