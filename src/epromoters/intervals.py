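"""Deterministic genomic-interval primitives.

Half-open, 0-based intervals throughout.  The three operations mirror the
bedtools contracts the pipeline relies on: ``closest -d -io -t first`` for
nearest-TSS distances, ``intersect -c`` for overlap counting, and ``slop``
for symmetric extension.  They are implemented on per-chromosome sorted
numpy arrays (binary search), so behaviour is exactly reproducible and
O((n + m) log n).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "nearest_other_point",
    "count_overlaps",
    "extend",
    "read_bed",
    "normalize_chrom",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def nearest_other_point(
    points: Sequence[tuple[str, int, Hashable]],
) -> dict[Hashable, int]:
    """Distance from each point to the nearest point at a *different* coordinate.

    Implements the ignore-overlap nearest-feature contract for 1-bp features:
    for every (chrom, position, id) triple the result maps id to
    min |p - q| over other points on the same chromosome, skipping points at
    the identical coordinate.  Points whose chromosome carries no point at a
    different coordinate are absent from the result.
    """
    if not points:
        raise ValueError("at least one point is required")
    by_chrom: dict[str, list[tuple[int, Hashable]]] = {}
    for chrom, pos, pid in points:
        by_chrom.setdefault(chrom, []).append((int(pos), pid))

    out: dict[Hashable, int] = {}
    for entries in by_chrom.values():
        uniq = np.unique(np.array([p for p, _ in entries], dtype=np.int64))
        if uniq.size < 2:
            continue  # alone on the chromosome, or all co-located
        for pos, pid in entries:
            i = int(np.searchsorted(uniq, pos))
            candidates = []
            # uniq[i] == pos always holds (pos is one of the unique values)
            if i > 0:
                candidates.append(pos - int(uniq[i - 1]))
            if i + 1 < uniq.size:
                candidates.append(int(uniq[i + 1]) - pos)
            out[pid] = min(candidates)
    return out


class _ChromIndex:
    """Sorted start/end arrays for one chromosome's subject intervals."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        pairs = list(intervals)
        self.n = len(pairs)
        self.starts = np.sort(np.array([s for s, _ in pairs], dtype=np.int64))
        self.ends = np.sort(np.array([e for _, e in pairs], dtype=np.int64))

    def count(self, qstart: int, qend: int) -> int:
        # overlap <=> subject.start < qend and subject.end > qstart; the two
        # excluded sets (start >= qend, end <= qstart) are disjoint because
        # every subject has start < end.
        n_right = self.n - int(np.searchsorted(self.starts, qend, side="left"))
        n_left = int(np.searchsorted(self.ends, qstart, side="right"))
        return self.n - n_right - n_left


def count_overlaps(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-query count of subjects sharing >= 1 bp (half-open semantics)."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        grouped.setdefault(s.chrom, []).append((s.start, s.end))
    index = {chrom: _ChromIndex(pairs) for chrom, pairs in grouped.items()}

    counts = np.zeros(len(queries), dtype=np.int64)
    for i, q in enumerate(queries):
        idx = index.get(q.chrom)
        if idx is not None:
            counts[i] = idx.count(q.start, q.end)
    return counts


def extend(
    interval: GenomicInterval, pad: int, chrom_len: int | None = None
) -> GenomicInterval:
    """Pad both sides by ``pad`` bp, clamped at the origin and chromosome end."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    start = max(0, interval.start - pad)
    end = interval.end + pad
    if chrom_len is not None:
        end = min(end, chrom_len)
    return GenomicInterval(interval.chrom, start, end, interval.name)


def normalize_chrom(chrom: str, use_prefix: bool) -> str:
    """Map between the "chr1" and "1" chromosome naming styles."""
    has = chrom.startswith("chr")
    if use_prefix and not has:
        return "chr" + chrom
    if not use_prefix and has:
        return chrom[3:]
    return chrom


def read_bed(
    path: str | Path,
    chrom_prefix: bool | None = None,
) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, tolerating track/browser/comment lines.

    ``chrom_prefix`` optionally re-styles chromosome names: True forces
    "chr1"-style, False forces "1"-style, None keeps the file's own names.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: list[GenomicInterval] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            if chrom_prefix is not None:
                chrom = normalize_chrom(chrom, chrom_prefix)
            name = fields[3] if len(fields) > 3 else None
            out.append(GenomicInterval(chrom, int(fields[1]), int(fields[2]), name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
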