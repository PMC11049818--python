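"""PSI-BLAST ASCII PSSM parsing and evolutionary feature encoders.

A position-specific scoring matrix (PSSM) is the L x 20 integer log-odds
profile PSI-BLAST emits (``-out_ascii_pssm``); row k scores substituting
position k with each of the 20 standard amino acids.  Three 400-D
encoders condense a profile into fixed-length descriptors:

* **DPC-PSSM** — dipeptide composition generalized to profile space:
  ``y[i,j] = (1/(L-1)) * sum_k p[k,i] * p[k+1,j]``.
* **KSB-PSSM** — k-separated bigrams pairing positions k apart
  (default k = 3), unnormalized: ``y[i,j] = sum_t p[t,i] * p[t+k,j]``.
* **S-FPSSM** — per-residue-type column sums over the negative-filtered
  profile: ``Y_j(i) = sum_k max(p[k,j], 0) * [r_k == a_i]``.

Their concatenation (DPC, KSB, S-F) is the 1200-D feature vector fed to
the downstream classifiers.  Scores enter the formulas raw by default; a
sigmoid-normalization flag exists for users who want profile values
squashed to (0, 1) first.

Generating real profiles is an external step::

    psiblast -query protein.fasta -db swissprot -num_iterations 3 \\
             -evalue 0.001 -out_ascii_pssm protein.pssm

The parser only consumes the resulting ASCII files; it never runs
PSI-BLAST itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import STANDARD_AA, ValidationError

logger = logging.getLogger(__name__)

BLOCK_NAMES = ("DPC-PSSM", "KSB-PSSM", "S-FPSSM")

#: Column ordering PSI-BLAST prints in ASCII profiles.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Raised when an ASCII profile file deviates from the expected layout."""


@dataclass(frozen=True)
class PSSMatrix:
    """L x 20 integer log-odds profile aligned to a residue string."""

    residues: str
    scores: np.ndarray
    aa_order: str = PSIBLAST_AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(f"scores must be L x 20, got shape {scores.shape}")
        if scores.shape[0] != len(self.residues):
            raise ValidationError(
                f"{scores.shape[0]} score rows for {len(self.residues)} residues"
            )
        if sorted(self.aa_order) != sorted(STANDARD_AA):
            raise ValidationError("aa_order must be a permutation of the 20 standard amino acids")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureBlock:
    """One 400-value encoder output, flattened row-major over (i, j)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in BLOCK_NAMES:
            raise ValidationError(f"unknown block name {self.name!r}")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (400,):
            raise ValidationError(f"block {self.name}: expected 400 values, got {values.shape}")

    def flat_position(self, i: int, j: int) -> int:
        """Flat index of y[i, j] for 1-based i, j in 1..20."""
        if not (1 <= i <= 20 and 1 <= j <= 20):
            raise ValidationError("i and j must be in 1..20")
        return 20 * (i - 1) + (j - 1)


@dataclass(frozen=True)
class PSSMFeatureVector:
    """1200-D concatenation DPC-PSSM | KSB-PSSM | S-FPSSM."""

    values: np.ndarray
    group_tags: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (1200,):
            raise ValidationError(f"expected 1200 values, got {values.shape}")
        if len(self.group_tags) != 1200:
            raise ValidationError("group_tags must cover all 1200 positions")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _profile_scores(m: PSSMatrix, normalize: bool) -> np.ndarray:
    p = m.scores.astype(float)
    return _sigmoid(p) if normalize else p


def parse_ascii_pssm(path: str | Path) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The log-odds scores come from the FIRST 20 numeric columns; the
    trailing 20 weighted-percentage columns and the two per-row floats
    are ignored.  The amino-acid column order is read from the header
    label line (first 20 labels).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    aa_order = None
    header_idx = None
    for idx, line in enumerate(lines):
        fields = line.split()
        if len(fields) == 40 and all(f in STANDARD_AA and len(f) == 1 for f in fields):
            aa_order = "".join(fields[:20])
            header_idx = idx
            break
    if aa_order is None:
        raise PSSMParseError(f"{path}: no 40-label amino-acid header line found")

    residues: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for lineno0, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            break  # blank line ends the matrix block
        fields = line.split()
        if not fields[0].isdigit():
            break  # footer (K/Lambda statistics)
        if len(fields) != 44:
            raise PSSMParseError(
                f"{path}: line {lineno0}: expected 44 fields "
                f"(position, residue, 40 scores, 2 stats), got {len(fields)}"
            )
        pos = int(fields[0])
        if pos != expected_pos:
            raise PSSMParseError(
                f"{path}: line {lineno0}: position {pos}, expected {expected_pos}"
            )
        expected_pos += 1
        residues.append(fields[1])
        try:
            rows.append([int(v) for v in fields[2:22]])
        except ValueError as exc:
            raise PSSMParseError(f"{path}: line {lineno0}: non-integer score: {exc}") from None
    if not rows:
        raise PSSMParseError(f"{path}: no data rows found")
    return PSSMatrix(
        residues="".join(residues),
        scores=np.array(rows, dtype=np.int64),
        aa_order=aa_order,
    )


def write_ascii_pssm(m: PSSMatrix, path: str | Path) -> None:
    """Write a profile in the ASCII layout :func:`parse_ascii_pssm` reads.

    The weighted-percentage block is filled with zeros and the two
    per-row statistics with 0.00 — sufficient for round-tripping the
    log-odds scores.
    """
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted observed "
                 "percentages rounded down, information per position, and relative "
                 "weight of gapless real matches to pseudocounts\n")
        labels = "  ".join(m.aa_order)
        fh.write(f"            {labels}   {labels}\n")
        for k, (aa, row) in enumerate(zip(m.residues, m.scores), start=1):
            scores = " ".join(f"{int(v):3d}" for v in row)
            pcts = " ".join("  0" for _ in range(20))
            fh.write(f"{k:5d} {aa}  {scores}  {pcts}  0.00 0.00\n")
        fh.write("\n")


def zero_profile(sequence: str, aa_order: str = PSIBLAST_AA_ORDER) -> PSSMatrix:
    """All-zero profile used when PSI-BLAST found no hits for a sequence."""
    logger.warning("emitting all-zero PSSM for a %d-residue sequence (no profile)", len(sequence))
    return PSSMatrix(residues=sequence, scores=np.zeros((len(sequence), 20), dtype=np.int64),
                     aa_order=aa_order)


def dpc_pssm(m: PSSMatrix, normalize: bool = False) -> FeatureBlock:
    """Dipeptide-composition encoder: adjacent-row column products, length-normalized."""
    L = m.length
    if L < 2:
        raise ValidationError(f"DPC-PSSM requires L >= 2, got L = {L}")
    p = _profile_scores(m, normalize)
    # y[i,j] = (1/(L-1)) sum_k p[k,i] p[k+1,j]
    y = p[:-1].T @ p[1:] / (L - 1)
    return FeatureBlock(name="DPC-PSSM", values=y.ravel())


def ksb_pssm(m: PSSMatrix, k: int = 3, normalize: bool = False) -> FeatureBlock:
    """K-separated-bigram encoder pairing positions k apart (unnormalized sum)."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    p = _profile_scores(m, normalize)
    if m.length <= k:
        warnings.warn(
            f"KSB-PSSM: sequence length {m.length} <= k = {k}; empty sum, all-zero block",
            stacklevel=2,
        )
        return FeatureBlock(name="KSB-PSSM", values=np.zeros(400))
    y = p[:-k].T @ p[k:]
    return FeatureBlock(name="KSB-PSSM", values=y.ravel())


def s_fpssm(m: PSSMatrix) -> FeatureBlock:
    """Negative-filtered per-residue-type column sums.

    Row i of the 20 x 20 layout collects, over positions k whose residue
    equals the i-th amino acid of the profile's column order, the
    negative-filtered scores fp[k, j].  Residues outside the 20 standard
    symbols (e.g. X) match no row and contribute nothing.
    """
    fp = np.maximum(m.scores.astype(float), 0.0)
    y = np.zeros((20, 20))
    aa_index = {aa: i for i, aa in enumerate(m.aa_order)}
    for k, r in enumerate(m.residues):
        i = aa_index.get(r)
        if i is not None:
            y[i] += fp[k]
    return FeatureBlock(name="S-FPSSM", values=y.ravel())


def concat_features(blocks: Iterable[FeatureBlock]) -> PSSMFeatureVector:
    """Concatenate the three encoder blocks in the fixed DPC, KSB, S-F order."""
    by_name: dict[str, FeatureBlock] = {}
    for b in blocks:
        if b.name in by_name:
            raise ValidationError(f"duplicate block {b.name!r}")
        by_name[b.name] = b
    missing = [n for n in BLOCK_NAMES if n not in by_name]
    if missing:
        raise ValidationError(f"missing blocks: {missing}")
    values = np.concatenate([by_name[n].values for n in BLOCK_NAMES])
    tags = tuple(n for n in BLOCK_NAMES for _ in range(400))
    return PSSMFeatureVector(values=values, group_tags=tags)


def encode_profile(m: PSSMatrix, k: int = 3, normalize: bool = False) -> PSSMFeatureVector:
    """Full 1200-D encoding of one profile."""
    return concat_features([
        dpc_pssm(m, normalize=normalize),
        ksb_pssm(m, k=k, normalize=normalize),
        s_fpssm(m),
    ])


def feature_names() -> list[str]:
    """Column names ``block.i.j`` for persisted 1200-D feature tables."""
    return [f"{n}.{i}.{j}" for n in BLOCK_NAMES for i in range(1, 21) for j in range(1, 21)]


def feature_table(
    vectors: Sequence[PSSMFeatureVector], ids: Sequence[str]
):
    """Assemble encoded profiles into a pandas DataFrame indexed by id."""
    import pandas as pd

    if len(vectors) != len(ids):
        raise ValidationError("one id per vector required")
    return pd.DataFrame(
        np.stack([v.values for v in vectors]), index=list(ids), columns=feature_names()
    )
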