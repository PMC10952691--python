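"""Assembly-level sequence statistics: N50, GC content, GC skew.

Conventions: N50 is the length at which the cumulative sum of
descending-sorted contig lengths first reaches half the assembly size.
GC content is (G+C)/(A+C+G+T); IUPAC ambiguity codes and N are excluded
from numerator and denominator.  GC skew is (G-C)/(G+C) per window, the
classic replication-strand indicator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "AssemblyStats",
    "SkewTrack",
    "EmptyInput",
    "NoUnambiguousBases",
    "EmptyFasta",
    "NonpositiveReference",
    "n50",
    "gc_content",
    "gc_skew",
    "assembly_stats",
    "percent_reduction",
    "round_half_up",
]


class EmptyInput(ValueError):
    pass


class NoUnambiguousBases(ValueError):
    pass


class EmptyFasta(ValueError):
    pass


class NonpositiveReference(ValueError):
    pass


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50_bp: int
    gc_fraction: float
    contig_lengths: tuple[int, ...]

    def to_row(self, label: str = "assembly") -> str:
        gc_pct = round_half_up(self.gc_fraction * 100, 1)
        return (
            f"{label}\t{self.n_contigs}\t{self.total_bp}\t"
            f"{self.n50_bp}\t{gc_pct:.1f}"
        )


@dataclass(frozen=True)
class SkewTrack:
    window_bp: int
    step_bp: int
    #: one value per window; NaN marks windows without any G or C
    values: tuple[float, ...]

    def defined_values(self) -> list[float]:
        return [v for v in self.values if not math.isnan(v)]


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of contig lengths (permutation-invariant)."""
    if not lengths:
        raise EmptyInput("n50 of an empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def _gc_at(counts_g: int, counts_c: int, counts_at: int) -> float:
    denom = counts_g + counts_c + counts_at
    if denom == 0:
        raise NoUnambiguousBases("no unambiguous A/C/G/T bases")
    return (counts_g + counts_c) / denom


def gc_content(sequences: str | Iterable[str]) -> float:
    """GC fraction over one or many sequences, case-insensitive.

    Ambiguity codes (N, R, Y, ...) are excluded from both numerator and
    denominator.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    g = c = at = 0
    for seq in sequences:
        s = seq.upper()
        g += s.count("G")
        c += s.count("C")
        at += s.count("A") + s.count("T")
    return _gc_at(g, c, at)


def gc_skew(sequence: str, window_bp: int = 1000, step_bp: int | None = None) -> SkewTrack:
    """(G-C)/(G+C) in sliding windows; NaN where a window has no G or C.

    ``step_bp`` defaults to ``window_bp`` (non-overlapping windows).  A
    window larger than the sequence degrades to a single whole-sequence
    window with a warning.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    step = window_bp if step_bp is None else step_bp
    if step < 1:
        raise ValueError("step_bp must be >= 1")
    seq = sequence.upper()
    if window_bp > len(seq):
        warnings.warn(
            "window larger than sequence; using one whole-sequence window",
            stacklevel=2,
        )
        window_bp = len(seq)
        step = max(len(seq), 1)
    values: list[float] = []
    for start in range(0, max(len(seq) - window_bp, 0) + 1, step):
        win = seq[start : start + window_bp]
        g = win.count("G")
        c = win.count("C")
        values.append((g - c) / (g + c) if g + c else math.nan)
    return SkewTrack(window_bp=window_bp, step_bp=step, values=tuple(values))


def assembly_stats(assembly: str | Path | Iterable) -> AssemblyStats:
    """Compute contig count, total size, N50 and GC for a FASTA assembly.

    Accepts a FASTA path or an iterable of Bio.SeqRecord objects.
    Duplicate contig ids trigger a warning, not an error.
    """
    if isinstance(assembly, (str, Path)):
        records = list(SeqIO.parse(str(assembly), "fasta"))
    else:
        records = list(assembly)
    if not records:
        raise EmptyFasta("assembly contains no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate contig ids in assembly", stacklevel=2)
    seqs = [str(r.seq) for r in records]
    lengths = tuple(len(s) for s in seqs)
    return AssemblyStats(
        n_contigs=len(records),
        total_bp=sum(lengths),
        n50_bp=n50(lengths),
        gc_fraction=gc_content(seqs),
        contig_lengths=lengths,
    )


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (12.5 -> 13), as used in printed tables."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_reduction(a: float, b: float) -> tuple[float, int]:
    """How much smaller ``a`` is than reference ``b``, as a percentage.

    Returns ``(raw, rounded)`` where raw = (1 - a/b) * 100 and rounded is
    half-up to the nearest integer.
    """
    if b <= 0:
        raise NonpositiveReference("reference quantity must be positive")
    if a < 0:
        raise ValueError("quantity must be non-negative")
    raw = (1 - a / b) * 100
    return raw, int(round_half_up(raw, 0))
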