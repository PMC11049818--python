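"""Decoder-transformer protein classifier trained from random init.

A reduced GPT-2-style architecture maps a tokenized protein sequence
directly to two class probabilities (druggable / undruggable), with no
feature extraction step and no pretrained weights: the vocabulary is the
33-token protein alphabet, the final embedding is the sum of token and
learned position embeddings, a stack of causal self-attention +
feed-forward blocks transforms it, and a softmax head over two logits
reads the representation of the last non-pad token (which, under causal
attention, has seen the whole sequence).

Padding positions are masked out of attention, so appending pad tokens
never changes the output.  Sequences longer than the block size are
C-terminally truncated with a logged warning.
"""

from __future__ import annotations

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


@dataclass(frozen=True)
class GPTConfig:
    vocab_size: int = 33
    block_size: int = 512
    n_layer: int = 4
    n_head: int = 4
    embed_dim: int = 128
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_head:
            raise ValidationError("embed_dim must be divisible by n_head")
        if self.block_size < 3:
            raise ValidationError("block_size must be >= 3")
        if self.vocab_size < 1:
            raise ValidationError("vocab_size must be positive")


@dataclass(frozen=True)
class ClassifierOutput:
    logits: np.ndarray  # (n, 2)
    probs: np.ndarray   # (n, 2), rows sum to 1


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_accuracies: list[float] = field(default_factory=list)


def expected_parameter_count(cfg: GPTConfig) -> int:
    """Closed-form trainable-parameter count for a config."""
    D, V, T, L = cfg.embed_dim, cfg.vocab_size, cfg.block_size, cfg.n_layer
    per_block = (
        2 * D                    # ln1
        + D * 3 * D + 3 * D      # fused qkv
        + D * D + D              # attention projection
        + 2 * D                  # ln2
        + D * 4 * D + 4 * D      # mlp expand
        + 4 * D * D + D          # mlp contract
    )
    return V * D + T * D + L * per_block + 2 * D + (D * 2 + 2)


class _Block:
    """Pre-norm transformer block: causal self-attention + 4x MLP."""

    def __init__(self, cfg: GPTConfig, rng: np.random.Generator):
        D = cfg.embed_dim
        s = 0.02
        self.cfg = cfg
        self.ln1_g = Tensor(np.ones(D), requires_grad=True)
        self.ln1_b = ad.init_zeros(D)
        self.W_qkv = ad.Tensor(rng.normal(0, s, size=(D, 3 * D)), requires_grad=True)
        self.b_qkv = ad.init_zeros(3 * D)
        self.W_proj = ad.Tensor(rng.normal(0, s, size=(D, D)), requires_grad=True)
        self.b_proj = ad.init_zeros(D)
        self.ln2_g = Tensor(np.ones(D), requires_grad=True)
        self.ln2_b = ad.init_zeros(D)
        self.W_mlp1 = ad.Tensor(rng.normal(0, s, size=(D, 4 * D)), requires_grad=True)
        self.b_mlp1 = ad.init_zeros(4 * D)
        self.W_mlp2 = ad.Tensor(rng.normal(0, s, size=(4 * D, D)), requires_grad=True)
        self.b_mlp2 = ad.init_zeros(D)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.ln1_g, self.ln1_b, self.W_qkv, self.b_qkv, self.W_proj,
                self.b_proj, self.ln2_g, self.ln2_b, self.W_mlp1, self.b_mlp1,
                self.W_mlp2, self.b_mlp2]

    def __call__(self, x: Tensor, attn_mask: np.ndarray) -> Tensor:
        cfg = self.cfg
        B, T, D = x.shape
        H = cfg.n_head
        hd = D // H
        h = ad.layer_norm(x, self.ln1_g, self.ln1_b)
        qkv = h @ self.W_qkv + self.b_qkv  # B x T x 3D
        q = qkv[:, :, :D].reshape(B, T, H, hd).transpose(0, 2, 1, 3)
        k = qkv[:, :, D : 2 * D].reshape(B, T, H, hd).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * D :].reshape(B, T, H, hd).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        att = ad.softmax(scores, axis=-1, mask=attn_mask)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = x + ctx @ self.W_proj + self.b_proj
        h2 = ad.layer_norm(x, self.ln2_g, self.ln2_b)
        mlp = ((h2 @ self.W_mlp1 + self.b_mlp1).relu()) @ self.W_mlp2 + self.b_mlp2
        return x + mlp


class GPTClassifier:
    """From-scratch decoder transformer with a 2-class softmax head."""

    def __init__(self, cfg: GPTConfig = GPTConfig(), alphabet: Alphabet = DEFAULT_ALPHABET):
        self.cfg = cfg
        self.alphabet = alphabet
        rng = np.random.default_rng(cfg.seed)
        D = cfg.embed_dim
        self.tok_emb = ad.Tensor(rng.normal(0, 0.02, size=(cfg.vocab_size, D)),
                                 requires_grad=True)
        self.pos_emb = ad.Tensor(rng.normal(0, 0.02, size=(cfg.block_size, D)),
                                 requires_grad=True)
        self.blocks = [_Block(cfg, rng) for _ in range(cfg.n_layer)]
        self.ln_f_g = Tensor(np.ones(D), requires_grad=True)
        self.ln_f_b = ad.init_zeros(D)
        self.W_head = ad.Tensor(rng.normal(0, 0.02, size=(D, 2)), requires_grad=True)
        self.b_head = ad.init_zeros(2)
        self.fitted = False

    @property
    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.pos_emb]
        for blk in self.blocks:
            params.extend(blk.parameters)
        params.extend([self.ln_f_g, self.ln_f_b, self.W_head, self.b_head])
        return params

    @property
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters))

    # -- forward -----------------------------------------------------------
    def embed_tokens(self, seq: TokenizedSequence) -> Tensor:
        """Position-aware embedding: row t = token_emb[id_t] + pos_emb[t].

        Encodings longer than the block size are truncated from the end
        (the leading cls token is kept).
        """
        ids = seq.ids[: seq.length]
        if len(ids) > self.cfg.block_size:
            ids = ids[: self.cfg.block_size]
        if ids.size and ids.max() >= self.cfg.vocab_size:
            raise ValidationError(f"token id {int(ids.max())} >= vocab_size {self.cfg.vocab_size}")
        tok = ad.embedding_lookup(self.tok_emb, ids)
        pos = self.pos_emb[np.arange(len(ids))]
        return tok + pos

    def _hidden(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        B, T = tokens.shape
        if T > self.cfg.block_size:
            raise ValidationError(f"batch width {T} exceeds block_size {self.cfg.block_size}")
        x = ad.embedding_lookup(self.tok_emb, tokens) + self.pos_emb[np.arange(T)]
        causal = np.tril(np.ones((T, T), dtype=bool))
        attn_mask = causal[None, None, :, :] & mask.astype(bool)[:, None, None, :]
        for blk in self.blocks:
            x = blk(x, attn_mask)
        return ad.layer_norm(x, self.ln_f_g, self.ln_f_b)

    def forward_classify(self, tokens: np.ndarray, mask: np.ndarray) -> ClassifierOutput:
        """Classify padded batches; reads the last non-pad position per row."""
        logits = self._logits(tokens, mask).data
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=-1, keepdims=True)
        return ClassifierOutput(logits=logits, probs=probs)

    def _logits(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        if tokens.size == 0 or mask.sum() == 0:
            raise ValidationError("empty sequence batch")
        hidden = self._hidden(tokens, mask)
        last = mask.astype(int).sum(axis=1) - 1
        read = hidden[np.arange(tokens.shape[0]), last]  # B x D
        return read @ self.W_head + self.b_head

    # -- training ----------------------------------------------------------
    def _encode_batch(self, records: Sequence[ProteinRecord]) -> tuple[np.ndarray, np.ndarray]:
        toks = []
        for r in records:
            if len(r.sequence) > self.cfg.block_size - 2:
                logger.warning("truncating %s (%d residues) to block size %d",
                               r.id, len(r.sequence), self.cfg.block_size)
            toks.append(tokenize(r, self.alphabet, max_len=self.cfg.block_size))
        return pad_batch(toks, self.alphabet)

    def fit(self, train: Sequence[ProteinRecord], epochs: int = 100,
            learning_rate: float = 1e-3, batch_size: int = 8,
            seed: Optional[int] = None) -> TrainLog:
        """End-to-end training with 2-class cross-entropy; deterministic per seed."""
        labels = [r.label for r in train]
        if any(l is None for l in labels):
            raise ValidationError("training requires labeled records")
        if len(set(labels)) < 2:
            raise ValidationError("training requires both classes present")
        y_all = np.array(labels, dtype=np.int64)
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        opt = ad.Adam(self.parameters, lr=learning_rate)
        log = TrainLog()
        n = len(train)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                tokens, mask = self._encode_batch([train[i] for i in idx])
                opt.zero_grad()
                logits = self._logits(tokens, mask)
                loss = ad.cross_entropy_from_logits(logits, y_all[idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                correct += int((logits.data.argmax(axis=1) == y_all[idx]).sum())
            log.epoch_losses.append(float(np.mean(losses)))
            log.epoch_accuracies.append(correct / n)
        self.fitted = True
        return log

    def predict(self, records: Sequence[ProteinRecord], batch_size: int = 8) -> ClassifierOutput:
        outs_logits, outs_probs = [], []
        for start in range(0, len(records), batch_size):
            tokens, mask = self._encode_batch(records[start : start + batch_size])
            out = self.forward_classify(tokens, mask)
            outs_logits.append(out.logits)
            outs_probs.append(out.probs)
        return ClassifierOutput(logits=np.vstack(outs_logits), probs=np.vstack(outs_probs))

    def predict_proba(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        """Per-record druggable (class 1) probability."""
        return self.predict(records).probs[:, 1]


def train_end_to_end(train: Sequence[ProteinRecord], cfg: GPTConfig,
                     epochs: int = 100, seed: int = 0, **kwargs) -> tuple[GPTClassifier, TrainLog]:
    import dataclasses

    model = GPTClassifier(dataclasses.replace(cfg, seed=seed))
    log = model.fit(train, epochs=epochs, seed=seed, **kwargs)
    return model, log
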