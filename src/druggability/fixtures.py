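"""Deterministic synthetic benchmarks: labeled sequences + matching profiles.

The generator emulates a two-class druggability dataset with two
independent, tunable signal channels:

* a **sequence channel** — positives carry a planted amino-acid motif
  and a shifted background composition, so embedding- and
  transformer-based paths can separate the classes from raw sequence;
* a **profile channel** — each record gets a synthetic PSSM whose row k
  scores the true residue at ``pssm_signal`` and everything else with
  bounded integer noise, so the PSSM encoders inherit the same
  composition/motif signal through the profile route.

Setting ``motif=None`` and using identical class compositions removes
all signal, which downstream tests use to verify that classifiers fall
back to chance (a leakage guard).

Determinism: a single integer seed drives everything; per-record
substreams are derived by hashing ``(purpose, seed, record id)`` so a
record's sequence and profile never depend on generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pssm import PSIBLAST_AA_ORDER, PSSMatrix, write_ascii_pssm
from .sequence_io import (
    STANDARD_AA,
    ProteinRecord,
    ValidationError,
    write_fasta,
    write_labels,
)

def _substream(*parts) -> np.random.Generator:
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "big"))


def _norm_weights(weights: dict[str, float]) -> np.ndarray:
    w = np.array([weights.get(aa, 1.0) for aa in STANDARD_AA], dtype=float)
    return w / w.sum()


@dataclass(frozen=True)
class FixtureSpec:
    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 150)
    motif: Optional[str] = "WWWWW"
    #: per-class composition weights (relative, unnormalized; 1.0 elsewhere)
    background_pos: dict[str, float] = field(default_factory=lambda: {"K": 4.0, "R": 4.0})
    background_neg: dict[str, float] = field(default_factory=dict)
    pssm_signal: int = 5
    #: score at motif positions in positive profiles (conserved-motif emphasis)
    motif_pssm_signal: int = 10
    pssm_noise: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid length_range")
        if self.motif is not None:
            if not set(self.motif) <= set(STANDARD_AA):
                raise ValidationError("motif must use standard amino acids")
            if len(self.motif) >= lo:
                raise ValidationError("motif must be shorter than the minimum length")
        if self.pssm_noise < 0:
            raise ValidationError("pssm_noise must be >= 0")


def _draw_sequence(rng: np.random.Generator, length: int, weights: np.ndarray,
                   motif: Optional[str]) -> str:
    aas = np.array(list(STANDARD_AA))
    seq = list(rng.choice(aas, size=length, p=weights))
    if motif:
        start = int(rng.integers(0, length - len(motif) + 1))
        seq[start : start + len(motif)] = list(motif)
    return "".join(seq)


def generate_records(spec: FixtureSpec) -> list[ProteinRecord]:
    """Labeled two-class records, deterministic per seed and order-independent."""
    lo, hi = spec.length_range
    w_pos = _norm_weights(spec.background_pos)
    w_neg = _norm_weights(spec.background_neg)
    records = []
    for i in range(spec.n_pos):
        rid = f"pos_{i:04d}"
        rng = _substream("seq", spec.seed, rid)
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(
            id=rid, sequence=_draw_sequence(rng, length, w_pos, spec.motif), label=1))
    for i in range(spec.n_neg):
        rid = f"neg_{i:04d}"
        rng = _substream("seq", spec.seed, rid)
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(
            id=rid, sequence=_draw_sequence(rng, length, w_neg, None), label=0))
    return records


def generate_synthetic_pssm(
    record: ProteinRecord, spec: FixtureSpec, path: Optional[str | Path] = None
) -> PSSMatrix:
    """Profile whose row k scores residue r_k at ``pssm_signal``, noise elsewhere.

    Noise is integer-uniform in [-pssm_noise, pssm_noise], derived from
    the record's own substream.  In positive records the planted motif's
    positions score ``motif_pssm_signal`` instead — the profile-channel
    analogue of a conserved functional motif, which keeps the encoder
    route separable independently of sequence length.  When ``path`` is
    given the profile is also written in the ASCII dialect the parser
    reads.
    """
    rng = _substream("pssm", spec.seed, record.id)
    L = len(record.sequence)
    if spec.pssm_noise > 0:
        scores = rng.integers(-spec.pssm_noise, spec.pssm_noise + 1, size=(L, 20))
    else:
        scores = np.zeros((L, 20), dtype=np.int64)
    col = {aa: j for j, aa in enumerate(PSIBLAST_AA_ORDER)}
    for k, aa in enumerate(record.sequence):
        if aa in col:
            scores[k, col[aa]] = spec.pssm_signal
    if spec.motif and record.label == 1:
        start = record.sequence.find(spec.motif)
        if start >= 0:
            for k in range(start, start + len(spec.motif)):
                scores[k, col[record.sequence[k]]] = spec.motif_pssm_signal
    m = PSSMatrix(residues=record.sequence, scores=scores.astype(np.int64),
                  aa_order=PSIBLAST_AA_ORDER)
    if path is not None:
        write_ascii_pssm(m, path)
    return m


def make_benchmark(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Emit a self-contained benchmark directory.

    Layout: ``data.fasta`` (all records), ``labels.tsv``, ``pssm/<id>.pssm``
    per record, and ``split.json`` holding seeded train/val/test id lists.
    """
    from .evaluation import stratified_three_way_split

    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    records = generate_records(spec)
    write_fasta(records, out / "data.fasta")
    write_labels(records, out / "labels.tsv")
    for r in records:
        generate_synthetic_pssm(r, spec, out / "pssm" / f"{r.id}.pssm")
    split = stratified_three_way_split(records, seed=spec.seed)
    split_ids = {
        "train": [records[i].id for i in split.train_idx],
        "val": [records[i].id for i in split.val_idx],
        "test": [records[i].id for i in split.test_idx],
        "seed": spec.seed,
    }
    (out / "split.json").write_text(json.dumps(split_ids, indent=1))
    return {
        "fasta": str(out / "data.fasta"),
        "labels": str(out / "labels.tsv"),
        "pssm_dir": str(out / "pssm"),
        "split": str(out / "split.json"),
    }


def null_spec(seed: int = 7, n_pos: int = 100, n_neg: int = 100,
              length_range: tuple[int, int] = (50, 150)) -> FixtureSpec:
    """A spec with zero class signal: no motif, identical compositions."""
    return FixtureSpec(n_pos=n_pos, n_neg=n_neg, length_range=length_range,
                       motif=None, background_pos={}, background_neg={}, seed=seed)
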