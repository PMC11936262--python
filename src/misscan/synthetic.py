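"""Synthetic corpus generator.

Emulates the statistical structure of a grouped-structure corpus so every
downstream stage (classification, feature statistics, baselines, the recurrent
labeler, the prioritisation screen) can be exercised offline:

* each protein carries a planted three-way truth labelling in which
  hard-missing residues form contiguous regions with a controllable short/long
  length mix, separated by at least one modeled residue;
* several structure entries per protein realise the truth as Cα presence
  masks — modeled positions present everywhere, hard-missing absent
  everywhere, soft-missing variably present;
* pLDDT and IUPred tracks are drawn from class-conditional distributions
  centred on the X-ray class medians (pLDDT 97.1 / 84.4 / 55.5; IUPred
  0.2 / 0.29 / 0.38 for modeled / soft / hard) and smoothed along the
  sequence to mimic the autocorrelation of real confidence tracks;
* hard-missing sequence stretches are enriched in polar/charged residues
  (K, E, S, P) and depleted in hydrophobics (W, Y, F, L, I, V), the
  composition signature of disordered regions.

Fixture sets written by :func:`write_fixture_set` round-trip bit-exactly
through :mod:`misscan.structure_io`; simulated scores are therefore quantised
to the precision the file formats carry (two decimals for pLDDT stored in the
B-factor column, four for IUPred tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ALPHABET,
    AMINO_ACIDS,
    HARD_MISSING,
    MODELED,
    SOFT_MISSING,
    ConfigurationError,
    ProteinRecord,
    RegionSet,
    ResidueLabels,
    StructureObservation,
)
from .classify import classify_residues, segment_regions

__all__ = [
    "GeneratorConfig",
    "generate_truth",
    "simulate_observations",
    "simulate_scores",
    "generate_corpus",
    "write_fixture_set",
    "DEFAULT_SCORE_PARAMS",
    "DEFAULT_ENRICHMENT",
]

#: Class-conditional (location, scale) pairs. Locations are the X-ray class
#: medians; scales keep the classes separable but overlapping.
DEFAULT_SCORE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "plddt": {"modeled": (97.1, 3.0), "soft_missing": (84.4, 8.0), "hard_missing": (55.5, 12.0)},
    "iupred": {"modeled": (0.2, 0.08), "soft_missing": (0.29, 0.12), "hard_missing": (0.38, 0.15)},
}

_KESP = "KESP"
_HYDROPHOBIC = "WYFLIV"


def _class_weights_table() -> dict[str, dict[str, float]]:
    base = {aa: 1.0 for aa in AMINO_ACIDS}
    hard = dict(base)
    soft = dict(base)
    for aa in _KESP:
        hard[aa] = 3.0
        soft[aa] = 1.8
    for aa in _HYDROPHOBIC:
        hard[aa] = 0.35
        soft[aa] = 0.65
    return {"modeled": base, "hard_missing": hard, "soft_missing": soft}


DEFAULT_ENRICHMENT = _class_weights_table()


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a plausible X-ray-like group: mostly modeled residues,
    hard-missing regions biased toward short runs, a handful of entries per
    protein, and class-conditional score distributions centred on the X-ray
    class medians.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (300, 800)
    class_weights: tuple[float, float, float] = (0.70, 0.20, 0.10)
    short_long_mix: float = 0.7
    n_entries_range: tuple[int, int] = (2, 6)
    soft_visibility: float = 0.5
    score_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCORE_PARAMS.items()})
    smoothing_window: int = 5
    enrichment: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENRICHMENT.items()})
    unknown_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_weights must be three non-negative values summing to 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("length_range must satisfy 1 <= min <= max")
        if not (0.0 < self.soft_visibility < 1.0):
            raise ConfigurationError("soft_visibility must lie strictly inside (0, 1)")
        elo, ehi = self.n_entries_range
        if elo < 1 or ehi < elo:
            raise ConfigurationError("n_entries_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.short_long_mix <= 1.0):
            raise ConfigurationError("short_long_mix must be a probability")
        if self.smoothing_window < 1:
            raise ConfigurationError("smoothing_window must be >= 1")
        if not (0.0 <= self.unknown_rate < 1.0):
            raise ConfigurationError("unknown_rate must lie in [0, 1)")
        for track in ("plddt", "iupred"):
            params = self.score_params.get(track, {})
            for cls in ("modeled", "soft_missing", "hard_missing"):
                if cls not in params:
                    raise ConfigurationError(f"score_params[{track!r}] missing class {cls!r}")


def _segment_plan(rng: np.random.Generator, length: int, config: GeneratorConfig) -> np.ndarray:
    """Lay out the label vector as alternating class segments.

    Hard/soft segments are separated by a forced 1-residue modeled spacer so
    maximal-run segmentation is unambiguous.
    """
    labels = np.empty(length, dtype=np.int8)
    pos = 0
    prev_nonmodeled = False
    classes = np.array([MODELED, HARD_MISSING, SOFT_MISSING])
    weights = np.asarray(config.class_weights, dtype=float)
    while pos < length:
        cls = int(rng.choice(classes, p=weights))
        if cls != MODELED and prev_nonmodeled:
            labels[pos] = MODELED
            pos += 1
            prev_nonmodeled = False
            continue
        if cls == MODELED:
            seg = int(rng.integers(10, 61))
        elif cls == HARD_MISSING:
            if rng.random() < config.short_long_mix:
                seg = int(rng.integers(1, 31))
            else:
                seg = int(rng.integers(31, 91))
        else:
            seg = int(rng.integers(2, 21))
        seg = min(seg, length - pos)
        labels[pos : pos + seg] = cls
        pos += seg
        prev_nonmodeled = cls != MODELED
    return labels


def _draw_sequence(rng: np.random.Generator, labels: np.ndarray, config: GeneratorConfig) -> str:
    letters = np.array(list(ALPHABET))
    seq = np.empty(labels.size, dtype="<U1")
    for code, cls in ((MODELED, "modeled"), (HARD_MISSING, "hard_missing"), (SOFT_MISSING, "soft_missing")):
        idx = np.flatnonzero(labels == code)
        if idx.size == 0:
            continue
        table = config.enrichment[cls]
        w = np.array([table.get(aa, 0.0) for aa in AMINO_ACIDS] + [0.0], dtype=float)
        w = w / w.sum() * (1.0 - config.unknown_rate)
        w[-1] = config.unknown_rate
        seq[idx] = rng.choice(letters, size=idx.size, p=w)
    return "".join(seq)


def generate_truth(config: GeneratorConfig) -> list[tuple[str, ResidueLabels, RegionSet]]:
    """Generate ``n_proteins`` planted truths: sequence, labels, hard regions.

    Reproducible given ``config.seed``; region short/long tags are derived
    from the realised run lengths (a drawn region clipped at the sequence end
    keeps its actual-length tag).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = []
    lo, hi = config.length_range
    for _ in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        label_vec = _segment_plan(rng, length, config)
        sequence = _draw_sequence(rng, label_vec, config)
        # n_entries is decided at observation time; truth labels are entry-free
        labels = ResidueLabels(label_vec, n_entries_used=2)
        out.append((sequence, labels, segment_regions(labels)))
    return out


def simulate_observations(
    truth: ResidueLabels,
    n_entries: int,
    soft_visibility: float,
    seed: int,
    require_recoverable: bool = True,
    entry_prefix: str = "entry",
) -> list[StructureObservation]:
    """Realise the truth as ``n_entries`` Cα presence masks.

    Modeled positions are present in every entry and hard-missing positions in
    none; soft-missing positions are present per entry with probability
    ``soft_visibility``. With ``require_recoverable`` (the default) each
    soft-missing column is re-sampled until it is neither all-present nor
    all-absent, so classification recovers the planted truth exactly.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    labels = truth.labels
    has_soft = bool((labels == SOFT_MISSING).any())
    if n_entries == 1 and has_soft and require_recoverable:
        raise ValueError(
            "soft_missing truth cannot be recovered from a single entry; "
            "use n_entries >= 2 or require_recoverable=False"
        )
    rng = np.random.default_rng(seed)
    n = labels.size
    masks = np.zeros((n_entries, n), dtype=bool)
    masks[:, labels == MODELED] = True
    soft_idx = np.flatnonzero(labels == SOFT_MISSING)
    if soft_idx.size:
        cols = rng.random((n_entries, soft_idx.size)) < soft_visibility
        if require_recoverable and n_entries >= 2:
            for _ in range(10_000):
                bad = np.flatnonzero(cols.all(axis=0) | ~cols.any(axis=0))
                if bad.size == 0:
                    break
                cols[:, bad] = rng.random((n_entries, bad.size)) < soft_visibility
            else:  # pragma: no cover - astronomically unlikely for visibility in (0,1)
                raise RuntimeError("could not realise recoverable soft-missing columns")
        masks[:, soft_idx] = cols
    return [
        StructureObservation(entry_id=f"{entry_prefix}{k + 1}", chain_id="A", presence=masks[k])
        for k in range(n_entries)
    ]


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def simulate_scores(
    truth: ResidueLabels,
    score_params: dict | None = None,
    smoothing_window: int = 5,
    seed: int = 0,
):
    """Draw class-conditional pLDDT/IUPred tracks for one protein.

    Per-position normal draws centred on the class location are moving-average
    smoothed over ``smoothing_window`` residues (along-sequence
    autocorrelation), clipped to the legal range, and quantised to file
    precision (2 decimals pLDDT, 4 decimals IUPred).
    """
    from .core import ScoreTracks

    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    params = score_params or DEFAULT_SCORE_PARAMS
    for track in ("plddt", "iupred"):
        for cls in ("modeled", "soft_missing", "hard_missing"):
            if cls not in params[track]:
                raise ConfigurationError(f"score_params[{track!r}] missing class {cls!r}")
    rng = np.random.default_rng(seed)
    labels = truth.labels
    n = labels.size
    loc = {t: np.empty(n) for t in ("plddt", "iupred")}
    scale = {t: np.empty(n) for t in ("plddt", "iupred")}
    for code, cls in ((MODELED, "modeled"), (HARD_MISSING, "hard_missing"), (SOFT_MISSING, "soft_missing")):
        sel = labels == code
        for t in ("plddt", "iupred"):
            loc[t][sel], scale[t][sel] = params[t][cls]
    plddt = loc["plddt"] + rng.standard_normal(n) * scale["plddt"]
    iupred = loc["iupred"] + rng.standard_normal(n) * scale["iupred"]
    plddt = np.clip(_moving_average(plddt, smoothing_window), 0.0, 100.0)
    iupred = np.clip(_moving_average(iupred, smoothing_window), 0.0, 1.0)
    return ScoreTracks(plddt=np.round(plddt, 2), iupred=np.round(iupred, 4))


def generate_corpus(config: GeneratorConfig, group: str = "xray") -> list[ProteinRecord]:
    """Full synthetic corpus: truth + observations + score tracks per protein."""
    config.validate()
    truths = generate_truth(config)
    rng = np.random.default_rng(config.seed + 1)
    elo, ehi = config.n_entries_range
    records: list[ProteinRecord] = []
    for i, (sequence, labels, regions) in enumerate(truths):
        n_entries = int(rng.integers(max(elo, 2) if (labels.labels == SOFT_MISSING).any() else elo, ehi + 1))
        obs_seed = int(rng.integers(0, 2**31 - 1))
        score_seed = int(rng.integers(0, 2**31 - 1))
        observations = simulate_observations(labels, n_entries, config.soft_visibility, obs_seed)
        tracks = simulate_scores(labels, config.score_params, config.smoothing_window, score_seed)
        recovered = classify_residues(observations)
        records.append(
            ProteinRecord(
                protein_id=f"SYN{i + 1:04d}",
                sequence=sequence,
                group=group,
                observations=observations,
                tracks=tracks,
                labels=ResidueLabels(labels.labels, n_entries_used=n_entries),
                regions=regions,
            )
        )
        assert (recovered.labels == labels.labels).all()
    return records


# --- fixture writing ---------------------------------------------------------

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _write_ca_pdb(path: Path, sequence: str, present: np.ndarray, bfactors: np.ndarray | None = None) -> None:
    """Minimal PDB: one CA ATOM record per present residue, chain A.

    Coordinates are a straight line (3.8 Å Cα spacing); only presence and the
    B-factor column carry information.
    """
    lines = []
    serial = 0
    for i, aa in enumerate(sequence):
        if not present[i]:
            continue
        serial += 1
        b = 0.0 if bfactors is None else float(bfactors[i])
        lines.append(
            f"ATOM  {serial:5d}  CA  {_THREE_LETTER[aa]:<3s} A{i + 1:4d}    "
            f"{(i + 1) * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}          "
            f" C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_fixture_set(proteins: list[ProteinRecord], out_dir: str | Path) -> dict:
    """Write per-protein FASTA, entry PDBs, a pLDDT model file, and an IUPred
    table, plus a JSON manifest with file names and truth labels.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"proteins": []}
    for rec in proteins:
        pid = rec.protein_id
        fasta = out / f"{pid}.fasta"
        fasta.write_text(f">{pid}\n{rec.sequence}\n")
        entry_files = []
        for obs in rec.observations:
            pdb = out / f"{pid}_{obs.entry_id}.pdb"
            _write_ca_pdb(pdb, rec.sequence, obs.presence)
            entry_files.append(pdb.name)
        model_file = None
        iupred_file = None
        if rec.tracks is not None:
            model = out / f"{pid}_model.pdb"
            _write_ca_pdb(model, rec.sequence, np.ones(rec.length, bool), rec.tracks.plddt)
            model_file = model.name
            iup = out / f"{pid}.iupred"
            rows = ["# POS\tRES\tIUPRED"]
            rows += [
                f"{i + 1}\t{aa}\t{rec.tracks.iupred[i]:.4f}" for i, aa in enumerate(rec.sequence)
            ]
            iup.write_text("\n".join(rows) + "\n")
            iupred_file = iup.name
        manifest["proteins"].append(
            {
                "id": pid,
                "group": rec.group,
                "length": rec.length,
                "fasta": fasta.name,
                "entries": entry_files,
                "model": model_file,
                "iupred": iupred_file,
                "truth_labels": rec.labels.names() if rec.labels is not None else None,
                "n_entries": len(rec.observations),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
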