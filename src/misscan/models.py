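"""The three per-residue classifiers.

Two threshold baselines — pLDDT (< 70 -> hard missing) and IUPred (>= 0.5 ->
hard missing) — and a recurrent three-class labeler. Neither baseline ever
emits soft_missing.

The recurrent labeler follows a statsmodels-style Model/Results split:
:class:`RecurrentLabeler` is built from encoded proteins and a
:class:`TrainConfig`; its :meth:`~RecurrentLabeler.fit` returns a
:class:`RecurrentLabelerResults` carrying the trained weights, the per-epoch
training log, prediction methods and a ``summary()`` table.

Encoding: each position is a 23-dimensional row — a one-active token over the
20 standard amino acids plus an unknown token, then pLDDT rescaled to [0, 1],
then the IUPred score. Sequences are zero-padded (mask off) to the
standardized length, or truncated to it with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._lstm import LSTMSequenceClassifier
from .core import (
    AMINO_ACIDS,
    HARD_MISSING,
    MODELED,
    ConfigurationError,
    ProteinRecord,
    ResidueLabels,
    ScoreTracks,
    as_label_array,
)
from .feature_stats import IUPRED_THRESHOLD, PLDDT_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = [
    "plddt_baseline",
    "iupred_baseline",
    "TrainConfig",
    "PRESETS",
    "EncodedProtein",
    "encode",
    "filter_training_entries",
    "RecurrentLabeler",
    "RecurrentLabelerResults",
]

N_TOKEN_DIMS = 21  # 20 amino acids + unknown
N_FEATURES = N_TOKEN_DIMS + 2  # + pLDDT + IUPred
N_CLASSES = 3

_TOKEN_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNKNOWN_TOKEN = 20


def plddt_baseline(track: np.ndarray) -> np.ndarray:
    """pLDDT threshold baseline: under 70 -> hard_missing, else modeled."""
    track = np.asarray(track, dtype=float)
    if track.size and (track.min() < 0 or track.max() > 100):
        raise ValueError("pLDDT values must lie in [0, 100]")
    return np.where(track < PLDDT_THRESHOLD, HARD_MISSING, MODELED).astype(np.int8)


def iupred_baseline(track: np.ndarray) -> np.ndarray:
    """IUPred threshold baseline: >= 0.5 -> hard_missing, else modeled."""
    track = np.asarray(track, dtype=float)
    if track.size and (track.min() < 0 or track.max() > 1):
        raise ValueError("IUPred values must lie in [0, 1]")
    return np.where(track >= IUPRED_THRESHOLD, HARD_MISSING, MODELED).astype(np.int8)


@dataclass
class TrainConfig:
    """Training conditions for the recurrent labeler.

    The X-ray preset standardizes sequences to 1,500 positions with 256 hidden
    units; the SPA preset to 2,500 with 300. Proteins with fewer than
    ``min_hard_missing`` hard-missing residues are discarded before training
    to avoid a bias toward the modeled class.
    """

    standardized_length: int = 1500
    hidden_units: int = 256
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    min_hard_missing: int = 5
    bidirectional: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.standardized_length < 1:
            raise ConfigurationError("standardized_length must be >= 1")
        if self.min_hard_missing < 0:
            raise ConfigurationError("min_hard_missing must be >= 0")
        if self.hidden_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("hidden_units, epochs and batch_size must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must lie in [0, 1)")


PRESETS: dict[str, TrainConfig] = {
    "xray": TrainConfig(standardized_length=1500, hidden_units=256),
    "spa": TrainConfig(standardized_length=2500, hidden_units=300),
}


@dataclass
class EncodedProtein:
    """One protein in model space: (standardized_length x 23) features, a mask
    over real positions, and optional per-position integer targets."""

    protein_id: str
    x: np.ndarray
    mask: np.ndarray
    y: np.ndarray | None = None

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())


def encode(
    sequence: str,
    tracks: ScoreTracks,
    labels: ResidueLabels | np.ndarray | None,
    config: TrainConfig,
    protein_id: str = "",
) -> EncodedProtein:
    """Encode one protein to the fixed-length model representation.

    Rows beyond the sequence are all-zero with the mask off; sequences longer
    than the standardized length are truncated (tail excluded, with a warning).
    """
    if len(sequence) != len(tracks):
        raise ValueError("sequence and score tracks must be aligned")
    L = config.standardized_length
    n = len(sequence)
    if n > L:
        logger.warning(
            "%s: sequence length %d exceeds standardized length %d; tail truncated",
            protein_id or "<protein>", n, L,
        )
        n = L
    x = np.zeros((L, N_FEATURES), dtype=np.float32)
    mask = np.zeros(L, dtype=bool)
    mask[:n] = True
    for i in range(n):
        x[i, _TOKEN_INDEX.get(sequence[i], UNKNOWN_TOKEN)] = 1.0
    x[:n, N_TOKEN_DIMS] = tracks.plddt[:n] / 100.0
    x[:n, N_TOKEN_DIMS + 1] = tracks.iupred[:n]
    y = None
    if labels is not None:
        vec = as_label_array(labels)
        if vec.size != len(sequence):
            raise ValueError("labels must be aligned with the sequence")
        y = np.zeros(L, dtype=np.int8)
        y[:n] = vec[:n]
    return EncodedProtein(protein_id=protein_id, x=x, mask=mask, y=y)


def encode_record(record: ProteinRecord, config: TrainConfig) -> EncodedProtein:
    if record.tracks is None:
        raise ValueError(f"{record.protein_id}: no score tracks attached")
    return encode(record.sequence, record.tracks, record.labels, config, record.protein_id)


def filter_training_entries(
    dataset: Sequence[ProteinRecord], min_hard_missing: int = 5
) -> list[ProteinRecord]:
    """Discard proteins with fewer than ``min_hard_missing`` hard-missing
    residues (bias control toward the modeled class)."""
    kept = [
        rec
        for rec in dataset
        if rec.labels is not None
        and int((rec.labels.labels == HARD_MISSING).sum()) >= min_hard_missing
    ]
    if not kept:
        raise ValueError(
            "no proteins remain after the hard-missing filter; "
            "a larger or more disordered corpus is required"
        )
    return kept


class RecurrentLabeler:
    """Three-class recurrent sequence labeler (model object).

    Built from encoded proteins; ``fit()`` trains the LSTM and returns a
    :class:`RecurrentLabelerResults`.
    """

    def __init__(self, encoded: Sequence[EncodedProtein], config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.config.validate()
        encoded = list(encoded)
        if len(encoded) < 2:
            raise ValueError("need at least two encoded proteins to train")
        for ep in encoded:
            if ep.y is None:
                raise ValueError(f"{ep.protein_id}: encoded protein has no targets")
            if ep.x.shape != (self.config.standardized_length, N_FEATURES):
                raise ValueError(
                    f"{ep.protein_id}: encoding shape {ep.x.shape} does not match config"
                )
        self.encoded = encoded

    @classmethod
    def from_records(
        cls, records: Sequence[ProteinRecord], config: TrainConfig | None = None
    ) -> "RecurrentLabeler":
        """Filter (< min_hard_missing discarded), encode, and build the model."""
        config = config or TrainConfig()
        config.validate()
        kept = filter_training_entries(records, config.min_hard_missing)
        return cls([encode_record(rec, config) for rec in kept], config)

    def fit(self) -> "RecurrentLabelerResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = LSTMSequenceClassifier(
            N_FEATURES, cfg.hidden_units, N_CLASSES, seed=cfg.seed, bidirectional=cfg.bidirectional
        )
        n = len(self.encoded)
        order = rng.permutation(n)
        n_val = int(round(cfg.validation_fraction * n))
        val_idx = order[:n_val]
        train_idx = order[n_val:]
        if train_idx.size == 0:
            raise ValueError("validation_fraction leaves no training proteins")
        X = np.stack([self.encoded[i].x for i in train_idx])
        Y = np.stack([self.encoded[i].y for i in train_idx]).astype(np.int64)
        mask = np.stack([self.encoded[i].mask for i in train_idx])
        history = net.fit(
            X, Y, mask,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            rng=rng,
        )
        return RecurrentLabelerResults(
            model=self,
            net=net,
            history=history,
            train_ids=[self.encoded[i].protein_id for i in train_idx],
            validation_ids=[self.encoded[i].protein_id for i in val_idx],
        )


class RecurrentLabelerResults:
    """Fitted recurrent labeler: weights, training log, prediction, summary."""

    def __init__(
        self,
        model: RecurrentLabeler,
        net: LSTMSequenceClassifier,
        history: list[float],
        train_ids: list[str],
        validation_ids: list[str],
    ):
        self.model = model
        self.net = net
        self.history = history
        self.train_ids = train_ids
        self.validation_ids = validation_ids

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    def _check_encoded(self, encoded: EncodedProtein) -> None:
        if encoded.x.shape != (self.config.standardized_length, N_FEATURES):
            raise ValueError(
                f"encoded shape {encoded.x.shape} does not match the model's "
                f"standardized length {self.config.standardized_length}"
            )

    def predict_proba(self, encoded: EncodedProtein) -> np.ndarray:
        """Class probabilities over the real (unpadded) positions, (n_real, 3)."""
        self._check_encoded(encoded)
        n = encoded.n_real
        if n == 0:
            return np.zeros((0, N_CLASSES), dtype=np.float32)
        probs = self.net.predict_proba(encoded.x[None, :n, :])[0]
        return probs[encoded.mask[:n]]

    def predict(self, encoded: EncodedProtein) -> np.ndarray:
        """Arg-max class per real position; padded positions are excluded."""
        probs = self.predict_proba(encoded)
        return probs.argmax(axis=1).astype(np.int8)

    def predict_record(self, record: ProteinRecord) -> np.ndarray:
        return self.predict(encode_record(record, self.config))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Recurrent per-residue labeler (LSTM -> dense softmax)",
            "=" * 56,
            f"classes:              modeled / hard_missing / soft_missing",
            f"standardized length:  {cfg.standardized_length}",
            f"hidden units:         {cfg.hidden_units}"
            + (" (bidirectional)" if cfg.bidirectional else ""),
            f"optimizer:            Adam (lr={cfg.learning_rate})",
            f"loss:                 masked categorical cross-entropy",
            f"training proteins:    {len(self.train_ids)}",
            f"validation proteins:  {len(self.validation_ids)}",
            f"epochs:               {len(self.history)}",
            f"first/final loss:     {self.history[0]:.4f} / {self.history[-1]:.4f}",
            f"seed:                 {cfg.seed}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize weights plus the TrainConfig (npz with a JSON header)."""
        with open(Path(path), "wb") as fh:
            np.savez(
                fh,
                __config__=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
                **self.net.get_weights(),
            )

    @classmethod
    def load(cls, path: str | Path) -> "RecurrentLabelerResults":
        data = np.load(Path(path))
        config = TrainConfig(**json.loads(bytes(data["__config__"]).decode()))
        net = LSTMSequenceClassifier(
            N_FEATURES, config.hidden_units, N_CLASSES,
            seed=config.seed, bidirectional=config.bidirectional,
        )
        net.set_weights({k: data[k] for k in data.files if k != "__config__"})
        dummy = RecurrentLabeler.__new__(RecurrentLabeler)
        dummy.config = config
        dummy.encoded = []
        return cls(model=dummy, net=net, history=[float("nan")], train_ids=[], validation_ids=[])
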