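"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
this package; any 1-based input must be converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("enhancersens")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_VALID_CHARS = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def extend(self, w: int) -> "GenomicInterval":
        """Symmetric extension by ``w`` on each side (start clipped at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - w), self.end + w, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """In-memory genome: uppercase DNA over {A,C,G,T,N} keyed by chromosome."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise FormatError(f"non-IUPAC characters in {name}: {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} extends past chromosome end ({len(seq)})")
        return seq[iv.start : iv.end]

    def clip(self, iv: GenomicInterval) -> GenomicInterval:
        """Clip an interval to the chromosome; warn when clipping occurs."""
        n = len(self.sequences[iv.chrom])
        start, end = max(0, iv.start), min(n, iv.end)
        if (start, end) != (iv.start, iv.end):
            log.warning("clipped %s:%d-%d to [%d,%d)", iv.chrom, iv.start, iv.end, start, end)
        return GenomicInterval(iv.chrom, start, end, iv.strand)


@dataclass
class PWM:
    """Position probability matrix (rows A,C,G,T) with background and pseudocount.

    ``probs`` columns each sum to 1; log-odds scoring lives in
    :mod:`enhancersens.motif`.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.125

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise FormatError("PWM must have 4 rows (A,C,G,T)")
        if np.any(self.probs < 0):
            raise FormatError("PWM probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise FormatError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise FormatError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=0))

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.125,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Normalize a count matrix to probabilities.

        Each column receives ``pseudocount * column_total`` extra mass split
        according to the background, then is renormalized, so zero counts map
        to small positive probabilities whenever pseudocount > 0.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise FormatError("count matrix must have 4 rows (A,C,G,T)")
        if np.any(counts < 0):
            raise FormatError("negative count in PWM")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        colsum = counts.sum(axis=0)
        if np.any(colsum <= 0):
            raise FormatError("empty PWM column")
        padded = counts + pseudocount * colsum[None, :] * bg[:, None]
        probs = padded / padded.sum(axis=0, keepdims=True)
        return cls(name=name, probs=probs, background=bg, pseudocount=pseudocount)


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA genome; sequences are uppercased, wrapping removed."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty or invalid FASTA: {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA header: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    return Genome(sequences=sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals. Column 6, when present, is the strand."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: start >= end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6, sorted by (chrom, start)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def read_jaspar_pwm(path: str | Path, pseudocount: float = 0.125) -> PWM:
    """Read a JASPAR-format count matrix (4 labeled rows A/C/G/T).

    Accepts both the bracketed 2016+ layout ``A [ 1 2 3 ]`` and bare rows.
    """
    name = "pwm"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] or name
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if not parts or parts[0].upper() not in _BASE_INDEX:
                raise FormatError(f"unexpected JASPAR line: {line!r}")
            base = parts[0].upper()
            if base in rows:
                raise FormatError(f"duplicate row for base {base}")
            try:
                rows[base] = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"non-numeric count in row {base}") from exc
    if set(rows) != set(_BASES):
        raise FormatError(f"expected rows A,C,G,T; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError("unequal row lengths in JASPAR matrix")
    counts = np.array([rows[b] for b in _BASES])
    if np.any(counts < 0):
        raise FormatError("negative count in JASPAR matrix")
    return PWM.from_counts(name, counts, pseudocount=pseudocount)


def write_jaspar_pwm(name: str, counts: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(_BASES):
            vals = " ".join(f"{v:g}" for v in np.asarray(counts)[i])
            fh.write(f"{base} [ {vals} ]\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with a header row; ragged rows are a format error."""
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed TSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"missing fields in {path}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out
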