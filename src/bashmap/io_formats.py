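"""Reference sequences, per-read misincorporation bitvectors, and mutation-type tables.

Every downstream stage consumes the containers defined here.  Coordinates are
1-based inclusive throughout: a read covering the whole of a length-L RNA has
``start == 1`` and ``end == L``, matching the residue numbering used in the
structural biology literature (G1638, G26-G42, ...).

The per-read bitvector dialect (the ".simple" file) is a tab-separated text
format with one read per line::

    read_id <TAB> start <TAB> end <TAB> bitstring

where the bitstring holds one character per covered position, ``0`` meaning
the base matched the reference and ``1`` meaning a misincorporation was
observed there.  Lines starting with ``#`` are comments.  Deletions are not
represented: within runs of identical bases they cannot be assigned to a
specific position, so only substitution-style misincorporations appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "BitVector",
    "ReadSet",
    "MutationTypeTable",
    "read_fasta",
    "write_fasta",
    "read_simple",
    "write_simple",
    "filter_full_length",
    "collapse_close_misincorporations",
    "signature_summary",
]

_RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA reference sequence with per-position case flags.

    ``seq`` is stored uppercase over {A, C, G, U}; DNA input (T) is mapped to
    U.  ``lowercase`` marks positions that were lowercase in the source FASTA,
    the convention used to annotate tertiary-constrained G's.
    """

    id: str
    seq: str
    lowercase: np.ndarray = field(default=None)  # bool, length L

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )
        lc = self.lowercase
        if lc is None:
            lc = np.zeros(len(self.seq), dtype=bool)
        lc = np.asarray(lc, dtype=bool)
        if lc.shape != (len(self.seq),):
            raise ValueError("lowercase mask length does not match sequence")
        object.__setattr__(self, "lowercase", lc)

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.seq[position - 1]

    def positions_of(self, base: str) -> np.ndarray:
        """1-based positions carrying ``base``."""
        arr = np.frombuffer(self.seq.encode(), dtype="S1")
        return np.flatnonzero(arr == base.encode()) + 1

    def lowercase_positions(self) -> set[int]:
        return set((np.flatnonzero(self.lowercase) + 1).tolist())

    def with_lowercase(self, positions: Iterable[int]) -> "SequenceRecord":
        """Copy of this record with exactly ``positions`` flagged lowercase."""
        lc = np.zeros(len(self.seq), dtype=bool)
        for p in positions:
            lc[p - 1] = True
        return SequenceRecord(self.id, self.seq, lc)


@dataclass
class BitVector:
    """One sequencing read: a 0/1 vector over a 1-based reference interval."""

    read_id: str
    start: int
    end: int
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"read {self.read_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.bits.ndim != 1 or len(self.bits) != self.end - self.start + 1:
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bits)} bits for "
                f"{self.end - self.start + 1}-position interval"
            )
        if self.bits.size and self.bits.max() > 1:
            raise ValueError(f"read {self.read_id!r}: bits must be 0/1")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def bit_at(self, position: int) -> int:
        """Bit at a 1-based reference position (must be covered)."""
        return int(self.bits[position - self.start])

    def one_positions(self) -> np.ndarray:
        """1-based reference positions with a misincorporation."""
        return np.flatnonzero(self.bits) + self.start


@dataclass
class ReadSet:
    """A reference sequence plus a collection of per-molecule bitvectors."""

    reference: SequenceRecord
    reads: list[BitVector]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        L = len(self.reference)
        for r in self.reads:
            if r.start < 1 or r.end > L:
                raise ValueError(
                    f"read {r.read_id!r} interval [{r.start}, {r.end}] outside [1, {L}]"
                )

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def L(self) -> int:
        return len(self.reference)

    def all_full_length(self) -> bool:
        L = self.L
        return all(r.start == 1 and r.end == L for r in self.reads)

    def to_matrix(self) -> np.ndarray:
        """(n_reads, L) uint8 bit matrix; requires full-length reads."""
        if not self.all_full_length():
            raise ValueError("to_matrix requires full-length reads")
        if not self.reads:
            return np.zeros((0, self.L), dtype=np.uint8)
        return np.stack([r.bits for r in self.reads])

    def coverage_matrix(self) -> np.ndarray:
        """(n_reads, L) bool coverage indicator for arbitrary intervals."""
        cov = np.zeros((len(self.reads), self.L), dtype=bool)
        for k, r in enumerate(self.reads):
            cov[k, r.start - 1 : r.end] = True
        return cov

    def bits_matrix_padded(self) -> np.ndarray:
        """(n_reads, L) uint8 bits with zeros outside each read's interval."""
        out = np.zeros((len(self.reads), self.L), dtype=np.uint8)
        for k, r in enumerate(self.reads):
            out[k, r.start - 1 : r.end] = r.bits
        return out


def read_fasta(path, record: str | None = None) -> SequenceRecord:
    """Read a (multi-)FASTA file, preserving case flags.

    Returns the first record unless ``record`` names a specific one.  T is
    accepted and mapped to U; lowercase letters set the per-position case
    flag (used to mark tertiary-constrained G's).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record is not None:
        matches = [r for r in records if r.id == record]
        if not matches:
            raise ValueError(f"{path}: no record named {record!r}")
        rec = matches[0]
    else:
        rec = records[0]
    raw = str(rec.seq)
    lowercase = np.array([c.islower() for c in raw], dtype=bool)
    seq = raw.upper().replace("T", "U")
    return SequenceRecord(rec.id, seq, lowercase)


def write_fasta(record: SequenceRecord, path) -> None:
    chars = [
        c.lower() if record.lowercase[i] else c for i, c in enumerate(record.seq)
    ]
    Path(path).write_text(f">{record.id}\n{''.join(chars)}\n")


def read_simple(path, reference: SequenceRecord) -> ReadSet:
    """Parse a .simple bitvector file against ``reference``."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            read_id, start_s, end_s, bitstring = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer interval") from exc
            if set(bitstring) - {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: bitstring must be over 0/1")
            if len(bitstring) != end - start + 1:
                raise ValueError(
                    f"{path}:{lineno}: {len(bitstring)} bits for "
                    f"{end - start + 1}-position interval"
                )
            bits = np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0")
            reads.append(BitVector(read_id, start, end, bits))
    return ReadSet(reference, reads, metadata={"source": str(path)})


def write_simple(rs: ReadSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tstart\tend\tbits\n")
        for r in rs.reads:
            bitstring = "".join("1" if b else "0" for b in r.bits)
            fh.write(f"{r.read_id}\t{r.start}\t{r.end}\t{bitstring}\n")


def filter_full_length(rs: ReadSet) -> ReadSet:
    """Keep only reads spanning the entire reference, [1, L]."""
    L = rs.L
    kept = [r for r in rs.reads if r.start == 1 and r.end == L]
    meta = dict(rs.metadata)
    meta["full_length_filtered"] = True
    return ReadSet(rs.reference, kept, meta)


def _collapse_bits(bits: np.ndarray, min_sep: int) -> np.ndarray:
    """Within one read, keep only the 5'-most of any 1-bits closer than min_sep."""
    if min_sep <= 1:
        return bits
    out = bits.copy()
    ones = np.flatnonzero(bits)
    last_kept = None
    for p in ones:
        if last_kept is not None and p - last_kept < min_sep:
            out[p] = 0
        else:
            last_kept = p
    return out


def collapse_close_misincorporations(rs: ReadSet, min_sep: int) -> ReadSet:
    """Suppress misincorporations closer than ``min_sep`` positions.

    Abasic sites and Watson-Crick-face methylations can smear into complex
    misincorporations at the next one or two nucleotides, so events within
    ``min_sep`` of a retained event are treated as a single event and only
    the 5'-most is kept.  ``min_sep <= 1`` leaves the reads unchanged.
    """
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    reads = [
        BitVector(r.read_id, r.start, r.end, _collapse_bits(r.bits, min_sep))
        for r in rs.reads
    ]
    meta = dict(rs.metadata)
    meta["min_mutation_separation"] = min_sep
    return ReadSet(rs.reference, reads, meta)


@dataclass
class MutationTypeTable:
    """Per-position counts of misincorporation classes (G->T, G->A, ...).

    Backed by a long-format DataFrame with columns
    ``position, class, count, depth``.
    """

    table: pd.DataFrame

    REQUIRED = ("position", "class", "count", "depth")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        t = self.table
        if (t["count"] < 0).any() or (t["depth"] < 0).any():
            raise ValueError("counts and depths must be nonnegative")
        per_pos = t.groupby("position").agg(total=("count", "sum"), depth=("depth", "max"))
        over = per_pos[per_pos["total"] > per_pos["depth"]]
        if len(over):
            raise ValueError(
                f"class counts exceed depth at positions {over.index.tolist()}"
            )

    @classmethod
    def read_csv(cls, path) -> "MutationTypeTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def signature_summary(table: MutationTypeTable, positions: Sequence[int]) -> pd.Series:
    """Fraction of each misincorporation class, pooled over ``positions``.

    Pooling sums raw class counts across the selected positions, which equals
    the count-weighted mean of per-position class fractions.  Raises on zero
    total counts (no events to summarise).
    """
    t = table.table
    sel = t[t["position"].isin(set(positions))]
    pooled = sel.groupby("class")["count"].sum()
    total = pooled.sum()
    if total == 0:
        raise ValueError("no misincorporation events at the selected positions")
    return (pooled / total).sort_index()
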