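"""Sequence, label and profile data types; window extraction and file I/O.

Residues are stored as integer indices into an :class:`Alphabet`.  Unknown
residues (``X``, ``B``, ``Z``, ``U``, ``O`` for the protein alphabet, or any
character outside the alphabet) are stored as index ``-1`` and, under the
default ``zero`` policy, encode as an all-zero block in context vectors.

Coordinates are 0-based internally; every report/output uses 1-based closed
intervals and says so in its header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids in the fixed order used throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

UNKNOWN = -1


class SequenceFormatError(ValueError):
    """Raised for malformed sequence, label or profile files."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    symbols:
        Residue characters in fixed order; ``index`` is a bijection onto
        ``0..len(symbols)-1``.
    unknown_policy:
        ``"zero"``  — characters outside the alphabet are kept with index -1
        and encode as an all-zero block;
        ``"error"`` — such characters raise :class:`SequenceFormatError`.
    """

    symbols: str = AMINO_ACIDS
    unknown_policy: str = "zero"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.unknown_policy not in ("zero", "error"):
            raise ValueError(f"unknown_policy {self.unknown_policy!r}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, ch: str) -> int:
        """Index of ``ch``, or -1 for an unknown character under ``zero`` policy."""
        i = self.symbols.find(ch.upper())
        if i < 0 and self.unknown_policy == "error":
            raise SequenceFormatError(f"character {ch!r} not in alphabet")
        return i

    def encode(self, s: str) -> np.ndarray:
        return np.array([self.index(c) for c in s], dtype=np.int64)

    def decode(self, idx: Iterable[int]) -> str:
        return "".join(self.symbols[i] if i >= 0 else "X" for i in idx)


@dataclass
class LabeledSequence:
    """A residue sequence with an optional per-residue label string."""

    id: str
    residues: np.ndarray
    labels: Optional[str] = None
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.int64)
        if len(self.residues) == 0:
            raise SequenceFormatError(f"record {self.id!r} has zero length")
        if self.labels is not None and len(self.labels) != len(self.residues):
            raise SequenceFormatError(
                f"record {self.id!r}: {len(self.residues)} residues but "
                f"{len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def unknown_positions(self) -> np.ndarray:
        """0-based positions holding a residue outside the alphabet."""
        return np.flatnonzero(self.residues < 0)

    @property
    def sequence(self) -> str:
        return self.alphabet.decode(self.residues)


@dataclass
class Profile:
    """Per-position residue profile (PSSM-style) for one sequence.

    ``matrix`` has one row per residue and one column per alphabet symbol.
    In ``frequency`` mode rows are nonnegative and sum to 1.
    """

    id: str
    matrix: np.ndarray
    mode: str = "frequency"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SequenceFormatError("profile matrix must be 2-D")
        if self.mode not in ("frequency", "score"):
            raise ValueError(f"profile mode {self.mode!r}")
        if self.mode == "frequency":
            if (self.matrix < 0).any():
                raise SequenceFormatError(f"profile {self.id!r}: negative frequency")
            sums = self.matrix.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise SequenceFormatError(
                    f"profile {self.id!r}: row {bad + 1} sums to {sums[bad]:.6f}"
                )
            self.matrix = self.matrix / sums[:, None]

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Context window of ``left`` residues before and ``right`` after the center."""

    left: int = 3
    right: int = 3

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValueError("window extents must be nonnegative")

    @property
    def K(self) -> int:
        return self.left + self.right + 1

    @property
    def symmetric(self) -> bool:
        return self.left == self.right


# ---------------------------------------------------------------------------
# window encoding
# ---------------------------------------------------------------------------

def encode_windows(
    seq: LabeledSequence,
    spec: WindowSpec,
    profile: Optional[Profile] = None,
) -> np.ndarray:
    """Encode every position of ``seq`` as a stacked context matrix.

    Returns an ``(L, A*K)`` array where ``A`` is the alphabet size.  Block
    ``j`` of row ``i`` encodes sequence position ``i - left + j``; blocks that
    fall outside ``[0, L)`` are all-zero (zero padding), as are blocks over
    unknown residues under the ``zero`` policy.  In profile mode the one-hot
    block is replaced by the profile row of that position.
    """
    A = seq.alphabet.size
    L = len(seq)
    K = spec.K
    if profile is not None and len(profile) != L:
        raise SequenceFormatError(
            f"profile {profile.id!r} has {len(profile)} rows for sequence "
            f"{seq.id!r} of length {L}"
        )
    out = np.zeros((L, A * K), dtype=float)
    for j in range(K):
        # source position for block j at center i is i - left + j
        shift = j - spec.left
        lo = max(0, -shift)
        hi = min(L, L - shift)
        if lo >= hi:
            continue
        src = np.arange(lo, hi) + shift
        if profile is not None:
            out[lo:hi, j * A : (j + 1) * A] = profile.matrix[src]
        else:
            res = seq.residues[src]
            known = res >= 0
            rows = np.arange(lo, hi)[known]
            out[rows, j * A + res[known]] = 1.0
    return out


def encode_window(
    seq: LabeledSequence,
    i: int,
    spec: WindowSpec,
    profile: Optional[Profile] = None,
) -> np.ndarray:
    """Context vector of dimension ``A*K`` for 0-based position ``i``."""
    if not 0 <= i < len(seq):
        raise IndexError(f"position {i} out of range for length {len(seq)}")
    return encode_windows(seq, spec, profile)[i]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: Optional[Alphabet] = None) -> list[LabeledSequence]:
    """Read an (unlabeled) FASTA file into :class:`LabeledSequence` records."""
    alphabet = alphabet or Alphabet()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        s = str(rec.seq)
        if not s:
            raise SequenceFormatError(f"{path}: record {rec.id!r} is empty")
        out.append(LabeledSequence(rec.id, alphabet.encode(s), None, alphabet))
    return out


def write_fasta(seqs: Sequence[LabeledSequence], path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# 3-line label format
# ---------------------------------------------------------------------------
# A record is a header line (">id") followed by sequence line(s) then label
# line(s).  All non-header lines of a record are concatenated and split in
# half: first half residues, second half labels.  This makes the format
# wrap-agnostic; the total character count per record must be even.

def read_labels(
    path,
    alphabet: Optional[Alphabet] = None,
    label_set: Optional[Iterable[str]] = None,
) -> list[LabeledSequence]:
    """Read a 3-line label file into labeled sequences."""
    alphabet = alphabet or Alphabet()
    labels_ok = set(label_set) if label_set is not None else None
    text = Path(path).read_text()
    out: list[LabeledSequence] = []
    header: Optional[str] = None
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        blob = "".join(body)
        if not blob:
            raise SequenceFormatError(f"{path}: record {header!r} is empty")
        if len(blob) % 2 != 0:
            raise SequenceFormatError(
                f"{path}: record {header!r}: sequence/label halves do not match "
                f"(total {len(blob)} characters is odd)"
            )
        half = len(blob) // 2
        seq_part, lab_part = blob[:half], blob[half:]
        if labels_ok is not None:
            bad = set(lab_part) - labels_ok
            if bad:
                raise SequenceFormatError(
                    f"{path}: record {header!r}: labels {sorted(bad)} not in "
                    f"declared label set {sorted(labels_ok)}"
                )
        out.append(LabeledSequence(header, alphabet.encode(seq_part), lab_part, alphabet))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0]
            body = []
        else:
            if header is None:
                raise SequenceFormatError(f"{path}: data before first header")
            body.append(line)
    flush()
    if not out:
        raise SequenceFormatError(f"{path}: no records found")
    return out


def write_labels(seqs: Sequence[LabeledSequence], path, width: int = 60) -> None:
    """Write labeled sequences in the 3-line label format."""
    with open(path, "w") as fh:
        for s in seqs:
            if s.labels is None:
                raise ValueError(f"record {s.id!r} has no labels")
            fh.write(f">{s.id}\n")
            seq = s.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            for i in range(0, len(s.labels), width):
                fh.write(s.labels[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# profile TSV
# ---------------------------------------------------------------------------

def read_profile(
    path,
    alphabet: Optional[Alphabet] = None,
    mode: str = "frequency",
) -> Profile:
    """Read a profile TSV whose header row is the alphabet in order.

    Frequency-mode rows within 1e-3 of summing to 1 are renormalized; larger
    deviations, a wrong column count or negative frequencies are errors.
    """
    alphabet = alphabet or Alphabet()
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.strip()]
    if len(cols) != alphabet.size:
        raise SequenceFormatError(
            f"{path}: expected {alphabet.size} columns, found {len(cols)}"
        )
    if "".join(cols) != alphabet.symbols:
        raise SequenceFormatError(
            f"{path}: header order {''.join(cols)!r} does not match alphabet "
            f"{alphabet.symbols!r}"
        )
    return Profile(Path(path).stem, df[cols].to_numpy(dtype=float), mode)


def write_profile(profile: Profile, path, alphabet: Optional[Alphabet] = None) -> None:
    alphabet = alphabet or Alphabet()
    df = pd.DataFrame(profile.matrix, columns=list(alphabet.symbols))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
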