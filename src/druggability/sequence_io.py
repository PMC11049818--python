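"""FASTA input/output, the 33-token protein alphabet, and tokenization.

The alphabet mirrors the ESM-2 convention: four leading special tokens
(``<cls>``, ``<pad>``, ``<eos>``, ``<unk>``), the twenty standard amino
acids plus extended residue codes (X, B, U, Z, O) and gap-like symbols,
and a trailing ``<mask>`` token — 33 symbols in total.  Tokenized
sequences are framed as ``[cls] residues... [eos]`` and padded on the
right, which is the framing both the embedder and the decoder-transformer
classifier consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Frozen 33-symbol vocabulary (version 1): specials first, then residue
#: symbols in the canonical ESM ordering, then <mask>.
ESM_ALPHABET_V1: tuple[str, ...] = (
    "<cls>", "<pad>", "<eos>", "<unk>",
    "L", "A", "G", "V", "S", "E", "R", "T", "I", "D", "P", "K",
    "Q", "N", "F", "Y", "M", "H", "W", "C", "X", "B", "U", "Z", "O",
    ".", "-", "<null_1>",
    "<mask>",
)


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the format."""


class ValidationError(ValueError):
    """Raised when a record or argument violates a contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional binary label.

    ``label`` is 1 for druggable, 0 for undruggable, ``None`` when
    unlabeled (prediction-only inputs).
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    @staticmethod
    def normalized(id: str, sequence: str, label: Optional[int] = None) -> "ProteinRecord":
        return ProteinRecord(id=id, sequence=sequence.upper(), label=label)


@dataclass(frozen=True)
class Alphabet:
    """Ordered token vocabulary with symbol <-> id maps."""

    tokens: tuple[str, ...] = ESM_ALPHABET_V1
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tokens) != 33:
            raise ValidationError(f"alphabet must have 33 tokens, got {len(self.tokens)}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("alphabet tokens must be unique")
        for special in ("<cls>", "<pad>", "<eos>", "<unk>"):
            if special not in self.tokens:
                raise ValidationError(f"alphabet missing special token {special}")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    @property
    def cls_id(self) -> int:
        return self.index["<cls>"]

    @property
    def pad_id(self) -> int:
        return self.index["<pad>"]

    @property
    def eos_id(self) -> int:
        return self.index["<eos>"]

    @property
    def unk_id(self) -> int:
        return self.index["<unk>"]

    @property
    def mask_id(self) -> int:
        return self.index["<mask>"]

    def __len__(self) -> int:
        return len(self.tokens)

    def encode_residue(self, aa: str) -> int:
        """Map one residue character to its id; unknown symbols -> unk."""
        return self.index.get(aa, self.unk_id)


DEFAULT_ALPHABET = Alphabet()


@dataclass(frozen=True)
class TokenizedSequence:
    """Integer encoding of one protein: [cls] + residues + [eos]."""

    ids: np.ndarray
    length: int  # count of non-pad tokens

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))


@dataclass(frozen=True)
class DatasetSummary:
    longest: int
    shortest: int
    mean: int
    median: int
    std: int


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased; record order is preserved.  A body line
    appearing before any ``>`` header is a parse error; an empty sequence
    under a header is a validation error naming the record.
    """
    path = Path(path)
    text = path.read_text()
    # Pre-validate framing Biopython silently tolerates.
    stripped_lines = [l for l in text.splitlines() if l.strip()]
    if stripped_lines and not stripped_lines[0].startswith(">"):
        lineno = next(
            i for i, l in enumerate(text.splitlines(), start=1) if l.strip()
        )
        raise FastaParseError(
            f"{path}: line {lineno}: sequence data before any '>' header"
        )
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (id, 0/1); a header line is skipped if present."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FastaParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        rid, val = parts[0].strip(), parts[1].strip()
        if lineno == 1 and val not in ("0", "1"):
            continue  # header
        if val not in ("0", "1"):
            raise ValidationError(f"{path}: line {lineno}: label must be 0 or 1, got {val!r}")
        labels[rid] = int(val)
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in records:
            if r.label is None:
                raise ValidationError(f"record {r.id!r} has no label")
            fh.write(f"{r.id}\t{r.label}\n")


def attach_labels(records: Sequence[ProteinRecord], labels: dict[str, int]) -> list[ProteinRecord]:
    out = []
    for r in records:
        if r.id not in labels:
            raise ValidationError(f"no label for record {r.id!r}")
        out.append(ProteinRecord(id=r.id, sequence=r.sequence, label=labels[r.id]))
    return out


def tokenize(
    record: ProteinRecord,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_len: Optional[int] = None,
) -> TokenizedSequence:
    """Encode a record as [cls] + residue ids + [eos].

    When ``max_len`` is given the encoding is truncated to at most
    ``max_len`` tokens by dropping C-terminal residues (the cls/eos frame
    is kept).  Residues outside the alphabet map to unk.
    """
    if max_len is not None and max_len < 3:
        raise ValidationError(f"max_len must be >= 3, got {max_len}")
    seq = record.sequence.upper()
    residues = [alphabet.encode_residue(aa) for aa in seq]
    if max_len is not None and len(residues) > max_len - 2:
        residues = residues[: max_len - 2]
    ids = np.array([alphabet.cls_id, *residues, alphabet.eos_id], dtype=np.int64)
    return TokenizedSequence(ids=ids, length=len(ids))


def detokenize(tokens: TokenizedSequence, alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Inverse of :func:`tokenize` up to unk replacement ('X' placeholder)."""
    out = []
    for tid in tokens.ids[: tokens.length]:
        sym = alphabet.tokens[int(tid)]
        if sym in ("<cls>", "<eos>", "<pad>"):
            continue
        out.append("X" if sym == "<unk>" else sym)
    return "".join(out)


def pad_batch(
    seqs: Sequence[TokenizedSequence], alphabet: Alphabet = DEFAULT_ALPHABET
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a batch to its longest member.

    Returns ``(tokens, mask)`` where ``mask`` is 1 on real tokens and 0 on
    padding; mask row sums therefore equal the original lengths.
    """
    if not seqs:
        raise ValidationError("pad_batch requires a non-empty batch")
    width = max(s.length for s in seqs)
    tokens = np.full((len(seqs), width), alphabet.pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), width), dtype=np.int64)
    for i, s in enumerate(seqs):
        tokens[i, : s.length] = s.ids[: s.length]
        mask[i, : s.length] = 1
    return tokens, mask


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def summarize_lengths(records: Sequence[ProteinRecord]) -> DatasetSummary:
    """Length summary with mean/median/population-sd rounded half-away-from-zero."""
    if not records:
        raise ValidationError("summarize_lengths requires a non-empty record list")
    lengths = np.array([len(r.sequence) for r in records], dtype=float)
    return DatasetSummary(
        longest=int(lengths.max()),
        shortest=int(lengths.min()),
        mean=_round_half_away(float(lengths.mean())),
        median=_round_half_away(float(np.median(lengths))),
        std=_round_half_away(float(lengths.std(ddof=0))),
    )
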