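"""UCSC refGene annotation parsing and gene-model collapsing.

The pipeline works at gene level: all transcripts sharing a symbol (refGene
``name2``) are collapsed into one :class:`Gene` carrying the set of
strand-aware TSSs of its transcripts.  Coordinates follow the UCSC
convention: txStart is 0-based, txEnd exclusive, so the TSS of a minus-strand
transcript is ``txEnd - 1``.  The canonical TSS is the 5'-most TSS in the
direction of transcription (minimum coordinate on +, maximum on -).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptRecord",
    "Gene",
    "PromoterWindow",
    "AnnotationError",
    "load_annotation",
    "collapse_genes",
    "promoter_windows",
    "write_gene_bed6",
]


class AnnotationError(ValueError):
    """Raised on malformed or empty annotation input."""


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    is_coding: bool

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise AnnotationError(
                f"{self.transcript_id}: txStart must precede txEnd"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class Gene:
    """A symbol-keyed gene model with canonical and alternative TSSs."""

    symbol: str
    chrom: str
    strand: str
    canonical_tss: int
    all_tss: tuple[int, ...]
    is_coding: bool = True

    def __post_init__(self) -> None:
        if not self.all_tss:
            raise AnnotationError(f"{self.symbol}: empty TSS set")
        if self.canonical_tss not in self.all_tss:
            raise AnnotationError(f"{self.symbol}: canonical TSS not in TSS set")


@dataclass(frozen=True)
class PromoterWindow:
    gene_symbol: str
    chrom: str
    start: int
    end: int
    anchor_tss: int

    def __post_init__(self) -> None:
        if self.start >= self.end or self.start < 0:
            raise AnnotationError(
                f"{self.gene_symbol}: bad promoter window [{self.start}, {self.end})"
            )

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_symbol)


# refGene column order: bin, name, chrom, strand, txStart, txEnd, cdsStart,
# cdsEnd, exonCount, exonStarts, exonEnds, score, name2, ...
_REFGENE_MIN_COLS = 13
_NONCODING_PREFIXES = ("NR_", "XR_")


def load_annotation(
    path: str | Path,
    dialect: str = "refGene",
    coding_only: bool = True,
) -> list[TranscriptRecord]:
    """Parse a UCSC refGene tab file (.txt or .txt.gz) into transcript records.

    Rows on unplaced/alternative contigs (chromosome names containing "_")
    are always dropped; with ``coding_only`` non-coding accessions
    ("NR_"/"XR_" prefixes) are dropped as well.
    """
    if dialect != "refGene":
        raise AnnotationError(f"unsupported annotation dialect: {dialect!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[TranscriptRecord] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _REFGENE_MIN_COLS:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected >= {_REFGENE_MIN_COLS} "
                    f"refGene columns, got {len(fields)}"
                )
            accession, chrom, strand = fields[1], fields[2], fields[3]
            if "_" in chrom:
                continue
            is_coding = not accession.startswith(_NONCODING_PREFIXES)
            if coding_only and not is_coding:
                continue
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer txStart/txEnd"
                ) from exc
            records.append(
                TranscriptRecord(
                    transcript_id=accession,
                    gene_symbol=fields[12],
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    is_coding=is_coding,
                )
            )
    if not records:
        raise AnnotationError(f"{path}: no transcripts left after filtering")
    return records


def collapse_genes(transcripts: Sequence[TranscriptRecord]) -> list[Gene]:
    """Collapse transcripts into one Gene per symbol.

    TSSs are the strand-aware transcript starts; the canonical TSS is the
    5'-most one.  If transcripts of a symbol disagree on chromosome or
    strand, the gene is emitted on the chromosome/strand of the longest
    transcript (conflicting transcripts are dropped and logged).
    """
    if not transcripts:
        raise AnnotationError("no transcripts to collapse")
    by_symbol: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_symbol.setdefault(t.gene_symbol, []).append(t)

    genes: list[Gene] = []
    for symbol in sorted(by_symbol):
        group = by_symbol[symbol]
        chroms = {t.chrom for t in group}
        strands = {t.strand for t in group}
        if len(chroms) > 1 or len(strands) > 1:
            anchor = max(group, key=lambda t: (t.length, t.transcript_id))
            kept = [
                t for t in group if t.chrom == anchor.chrom and t.strand == anchor.strand
            ]
            logger.warning(
                "gene %s has transcripts on multiple chrom/strand; keeping %d/%d "
                "on %s%s (longest transcript %s)",
                symbol, len(kept), len(group), anchor.chrom, anchor.strand,
                anchor.transcript_id,
            )
            group = kept
        strand = group[0].strand
        tss_set = tuple(sorted({t.tss for t in group}))
        canonical = tss_set[0] if strand == "+" else tss_set[-1]
        genes.append(
            Gene(
                symbol=symbol,
                chrom=group[0].chrom,
                strand=strand,
                canonical_tss=canonical,
                all_tss=tss_set,
                is_coding=any(t.is_coding for t in group),
            )
        )
    return genes


def promoter_windows(
    gene: Gene,
    upstream: int = 1000,
    downstream: int = 1000,
    per_tss: bool = True,
    strand_aware: bool = True,
) -> list[PromoterWindow]:
    """Half-open promoter windows around the gene's TSS(s).

    The window includes the TSS base plus ``upstream`` bp against and
    ``downstream`` bp along the direction of transcription, i.e.
    [TSS - upstream, TSS + downstream + 1) on +, mirrored on -.  With
    ``strand_aware=False`` upstream is always placed on the lower-coordinate
    side.  Windows are clamped at the chromosome origin.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    anchors = gene.all_tss if per_tss else (gene.canonical_tss,)
    flip = strand_aware and gene.strand == "-"
    left, right = (downstream, upstream) if flip else (upstream, downstream)
    windows = []
    for tss in anchors:
        windows.append(
            PromoterWindow(
                gene_symbol=gene.symbol,
                chrom=gene.chrom,
                start=max(0, tss - left),
                end=tss + right + 1,
                anchor_tss=tss,
            )
        )
    return sorted(windows, key=lambda w: w.start)


def write_gene_bed6(genes: Sequence[Gene], path: str | Path) -> None:
    """Write collapsed genes as BED6 (1-bp canonical-TSS features)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.canonical_tss, g.symbol)):
            fh.write(
                f"{g.chrom}\t{g.canonical_tss}\t{g.canonical_tss + 1}"
                f"\t{g.symbol}\t0\t{g.strand}\n"
            )
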