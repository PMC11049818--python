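"""Pluggable protein-language-model embedder and fine-tuning harness.

The embedder contract: given a protein record, produce per-residue
representations (L x D, special tokens excluded), a pooled sequence
embedding (the arithmetic mean over residue rows, D = 320 by default),
and a symmetric residue-residue contact map in [0, 1].

Two backends satisfy the contract:

* ``stub`` — a deterministic, download-free backend used throughout the
  test suite.  Each residue's representation row is drawn from a fixed
  random codebook keyed by residue identity and seed, so the pooled
  embedding is a randomized linear image of the sequence's amino-acid
  composition: sequences whose compositions differ are separable, which
  is exactly the property the synthetic benchmarks exercise.
* ``esm2_t6_8M`` — the 6-layer ESM-2 model (layer-6 representations,
  320-D).  Loading it requires the optional ``esm`` package and
  pretrained weights; it is never touched by the tests.

The fine-tuning harness appends a fully connected layer and a 1-unit
sigmoid classification head on top of the pooled backbone representation
and trains everything (backbone included) with binary cross-entropy on
length-sorted batches of two.  Downstream 320-D embeddings are read
from the activations entering the fully connected layer — i.e. the
pooled backbone representation after fine-tuning.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sequence_io import (
    DEFAULT_ALPHABET,
    Alphabet,
    ProteinRecord,
    TokenizedSequence,
    ValidationError,
    pad_batch,
    tokenize,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EmbedderConfig:
    backend: str = "stub"
    repr_layer: int = 6
    output_dim: int = 320
    contact_head_width: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim <= 0:
            raise ConfigError("output_dim must be positive")
        if self.repr_layer < 1:
            raise ConfigError("repr_layer must be >= 1")


@dataclass(frozen=True)
class ResidueRepresentations:
    sequence_id: str
    matrix: np.ndarray  # L x D, special-token rows excluded


@dataclass(frozen=True)
class PooledEmbedding:
    sequence_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValidationError(f"non-finite embedding for {self.sequence_id!r}")


@dataclass(frozen=True)
class ContactMap:
    sequence_id: str
    matrix: np.ndarray  # L x L, symmetric, values in [0, 1]


@dataclass(frozen=True)
class FineTuneConfig:
    batch_size: int = 2
    epochs: int = 50
    learning_rate: float = 1e-3
    hidden_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


def _stable_seed(*parts) -> int:
    """Derive a < 2^31 substream seed by hashing the parts."""
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _residue_codebook(cfg: EmbedderConfig, alphabet: Alphabet) -> np.ndarray:
    """Fixed random table: one D-vector per alphabet symbol, keyed by seed."""
    rng = np.random.default_rng(_stable_seed("stub-codebook", cfg.seed, cfg.output_dim))
    return rng.normal(0.0, 1.0, size=(len(alphabet), cfg.output_dim))


class StubEmbedder:
    """Deterministic codebook embedder implementing the backend contract."""

    backend = "stub"

    def __init__(self, cfg: EmbedderConfig, alphabet: Alphabet = DEFAULT_ALPHABET,
                 codebook: Optional[np.ndarray] = None):
        self.cfg = cfg
        self.alphabet = alphabet
        self.codebook = _residue_codebook(cfg, alphabet) if codebook is None else codebook

    def embed(self, record: ProteinRecord) -> tuple[ResidueRepresentations, PooledEmbedding]:
        ids = [self.alphabet.encode_residue(aa) for aa in record.sequence.upper()]
        matrix = self.codebook[np.asarray(ids, dtype=np.int64)]
        pooled = matrix.mean(axis=0)
        return (
            ResidueRepresentations(sequence_id=record.id, matrix=matrix),
            PooledEmbedding(sequence_id=record.id, vector=pooled),
        )

    def predict_contacts(self, record: ProteinRecord) -> ContactMap:
        L = len(record.sequence)
        rng = np.random.default_rng(
            _stable_seed("stub-contacts", self.cfg.seed, record.sequence)
        )
        raw = rng.uniform(0.0, 1.0, size=(L, L))
        sym = np.clip((raw + raw.T) / 2.0, 0.0, 1.0)
        return ContactMap(sequence_id=record.id, matrix=sym)


def get_embedder(cfg: EmbedderConfig, alphabet: Alphabet = DEFAULT_ALPHABET):
    if cfg.backend == "stub":
        return StubEmbedder(cfg, alphabet)
    if cfg.backend == "esm2_t6_8M":
        try:
            import esm  # noqa: F401  (optional, never installed in CI)
        except ImportError as exc:
            raise ConfigError(
                "backend 'esm2_t6_8M' needs the optional 'esm' package and "
                "pretrained weights; install fair-esm or use backend='stub'"
            ) from exc
        raise ConfigError("esm2_t6_8M backend wiring requires downloaded weights")
    raise ConfigError(f"unknown embedder backend {cfg.backend!r}")


def embed(record: ProteinRecord, cfg: EmbedderConfig) -> tuple[ResidueRepresentations, PooledEmbedding]:
    return get_embedder(cfg).embed(record)


def predict_contacts(record: ProteinRecord, cfg: EmbedderConfig) -> ContactMap:
    return get_embedder(cfg).predict_contacts(record)


def embedding_table(records: Sequence[ProteinRecord], embedder) -> "np.ndarray":
    """Stack pooled embeddings into an (n, D) matrix, preserving record order."""
    return np.stack([embedder.embed(r)[1].vector for r in records])


# -- length-sorted batching --------------------------------------------------

@dataclass(frozen=True)
class PaddedBatch:
    records: tuple[ProteinRecord, ...]
    tokens: np.ndarray
    mask: np.ndarray


def make_length_batches(
    records: Sequence[ProteinRecord],
    batch_size: int,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> list[PaddedBatch]:
    """Sort by sequence length (ties by id), group consecutively, pad per batch.

    Sorting before batching keeps within-batch length spread minimal, so
    padding waste is bounded by the per-batch maxima; no global padding
    width is ever imposed.
    """
    if not records:
        raise ValidationError("make_length_batches requires records")
    if batch_size < 1:
        raise ConfigError("batch_size must be >= 1")
    ordered = sorted(records, key=lambda r: (len(r.sequence), r.id))
    batches = []
    for start in range(0, len(ordered), batch_size):
        group = ordered[start : start + batch_size]
        toks = [tokenize(r, alphabet) for r in group]
        tokens, mask = pad_batch(toks, alphabet)
        batches.append(PaddedBatch(records=tuple(group), tokens=tokens, mask=mask))
    return batches


# -- fine-tuning harness -----------------------------------------------------

@dataclass
class TrainingLog:
    epoch_losses: list[float] = field(default_factory=list)


class FineTunedStubEmbedder:
    """Stub backbone + fully connected layer + sigmoid classification head.

    The backbone is the residue codebook itself, promoted to a trainable
    parameter; the pooled representation feeding the fully connected
    layer is what :meth:`embed` returns after fine-tuning.  A reduced
    contact head (default input width 24) maps a fixed projection of
    pairwise representation products to contact probabilities.
    """

    backend = "stub-finetuned"

    def __init__(self, base: StubEmbedder, cfg: FineTuneConfig):
        self.alphabet = base.alphabet
        self.cfg = cfg
        self.embed_cfg = base.cfg
        D, H = base.cfg.output_dim, cfg.hidden_dim
        rng = np.random.default_rng(_stable_seed("finetune-init", cfg.seed, D, H))
        self.table = Tensor(base.codebook.copy(), requires_grad=True)
        self.W_fc = ad.Tensor(rng.normal(0, 1.0 / np.sqrt(D), size=(D, H)), requires_grad=True)
        self.b_fc = ad.init_zeros(H)
        self.W_out = ad.Tensor(rng.normal(0, 1.0 / np.sqrt(H), size=(H, 1)), requires_grad=True)
        self.b_out = ad.init_zeros(1)
        # reduced contact head: fixed down-projection + trainable logistic map
        W = base.cfg.contact_head_width
        self.contact_proj = rng.normal(0, 1.0 / np.sqrt(D), size=(D, W))
        self.contact_w = ad.init_zeros(W)
        self.contact_b = ad.init_zeros(1)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.table, self.W_fc, self.b_fc, self.W_out, self.b_out,
                self.contact_w, self.contact_b]

    def _pooled(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean over residue rows (cls/eos/pad excluded) for a padded batch."""
        residue_mask = mask.astype(float).copy()
        # strip cls (column 0) and each row's eos (last real token)
        residue_mask[:, 0] = 0.0
        lengths = mask.sum(axis=1)
        residue_mask[np.arange(len(lengths)), lengths - 1] = 0.0
        reps = ad.embedding_lookup(self.table, tokens)  # B x T x D
        weights = residue_mask / residue_mask.sum(axis=1, keepdims=True)
        return (reps * Tensor(weights[:, :, None])).sum(axis=1)

    def _forward_proba(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        pooled = self._pooled(tokens, mask)
        hidden = (pooled @ self.W_fc + self.b_fc).relu()
        return (hidden @ self.W_out + self.b_out).sigmoid().reshape(-1)

    def embed(self, record: ProteinRecord) -> tuple[ResidueRepresentations, PooledEmbedding]:
        ids = [self.alphabet.encode_residue(aa) for aa in record.sequence.upper()]
        matrix = self.table.data[np.asarray(ids, dtype=np.int64)]
        return (
            ResidueRepresentations(sequence_id=record.id, matrix=matrix),
            PooledEmbedding(sequence_id=record.id, vector=matrix.mean(axis=0)),
        )

    def predict_proba(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        batches = make_length_batches(records, self.cfg.batch_size, self.alphabet)
        out = {}
        for b in batches:
            probs = self._forward_proba(b.tokens, b.mask).data
            for r, p in zip(b.records, probs):
                out[r.id] = float(p)
        return np.array([out[r.id] for r in records])

    def predict_contacts(self, record: ProteinRecord) -> ContactMap:
        reps = self.embed(record)[0].matrix @ self.contact_proj  # L x width
        pair = reps[:, None, :] * reps[None, :, :]
        logits = pair @ self.contact_w.data + self.contact_b.data[0]
        probs = 1.0 / (1.0 + np.exp(-logits))
        sym = np.clip((probs + probs.T) / 2.0, 0.0, 1.0)
        return ContactMap(sequence_id=record.id, matrix=sym)


def finetune(
    train: Sequence[ProteinRecord],
    cfg: FineTuneConfig,
    embedder: StubEmbedder,
) -> tuple[FineTunedStubEmbedder, TrainingLog]:
    """Fine-tune the backbone + heads with BCE on length-sorted batches.

    Requires binary labels with both classes present.  Every backbone
    weight stays trainable; the training log records the mean per-epoch
    BCE.
    """
    labels = [r.label for r in train]
    if any(l is None for l in labels):
        raise ValidationError("fine-tuning requires labeled records")
    if len(set(labels)) < 2:
        raise ValidationError("fine-tuning requires both classes present")
    model = FineTunedStubEmbedder(embedder, cfg)
    opt = ad.Adam(model.parameters, lr=cfg.learning_rate)
    batches = make_length_batches(train, cfg.batch_size, embedder.alphabet)
    log = TrainingLog()
    for _ in range(cfg.epochs):
        losses = []
        for b in batches:
            y = np.array([r.label for r in b.records], dtype=float)
            opt.zero_grad()
            probs = model._forward_proba(b.tokens, b.mask)
            loss = ad.bce_loss(probs, y)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.epoch_losses.append(float(np.mean(losses)))
    return model, log
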