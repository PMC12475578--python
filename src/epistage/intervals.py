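"""Genomic interval primitives, BED I/O, and the overlap engine.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval covers positions ``start .. end-1`` and two intervals that
share only a boundary coordinate do not overlap.  Strand is carried for
anchored profiles but ignored by all overlap logic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "read_intervals",
    "write_intervals",
    "sort_intervals",
    "intersect_intervals",
]

_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name. Intervals on different chromosomes never compare.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    strand : str
        One of ``+``, ``-``, ``.`` (default ``.``).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coordinate sort: (chrom, start, end)."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_intervals(path) -> list[GenomicInterval]:
    """Read a BED3+ file. Column 6, when present, is taken as strand.

    Raises ``ValueError`` naming the offending line on malformed input
    (fewer than three columns, non-integer coordinates, end <= start).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write coordinate-sorted BED (BED6 if any interval is stranded)."""
    ivs = sort_intervals(intervals)
    stranded = any(iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two interval lists.

    Returns ``(index into a, index into b, overlap length)`` for every pair
    sharing >= 1 base, sorted by (a index, b index).  Content-symmetric under
    argument swap.  Empty input yields empty output.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for rows in by_chrom.values():
        rows.sort()
    pairs: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        rows = by_chrom.get(iv.chrom)
        if not rows:
            continue
        starts = [r[0] for r in rows]
        # candidates must start before iv.end; filter on their end afterwards
        hi = bisect.bisect_left(starts, iv.end)
        for start, end, j in rows[:hi]:
            if end > iv.start:
                pairs.append((i, j, min(iv.end, end) - max(iv.start, start)))
    pairs.sort()
    return pairs
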