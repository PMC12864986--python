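"""Synthetic genomes, induced gene sets, peaks, TADs and motif tracks.

Every stage of the pipeline is testable against planted ground truth
generated here, without any external download.  The fixtures emulate the
structure of a processed stress dataset: a refGene-style annotation
universe, an induced subset (with fold changes) carrying planted proximity
structure, ChIP-seq-like peaks dropped on the planted Epromoters, TADs
spanning each planted cluster, and a motif-occurrence track.

All randomness flows from one explicit integer seed; regeneration with the
same parameters and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import Gene
from .intervals import GenomicInterval, write_bed

__all__ = [
    "SyntheticTruth",
    "make_genome",
    "plant_clusters",
    "simulate_proximity",
    "write_fixture",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """A planted dataset: universe, induced subset, and the expected calls."""

    genes: tuple[Gene, ...]
    induced_symbols: tuple[str, ...]
    fold_changes: dict[str, float]
    planted_clusters: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    singleton_symbols: tuple[str, ...]
    tads: tuple[GenomicInterval, ...]
    peaks: tuple[GenomicInterval, ...]
    motif_track: tuple[GenomicInterval, ...]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def induced_genes(self) -> list[Gene]:
        by_symbol = {g.symbol: g for g in self.genes}
        return [by_symbol[s] for s in self.induced_symbols]


def make_genome(
    n_chrom: int = 2,
    genes_per_chrom: int = 200,
    chrom_len: int = 10_000_000,
    min_gene_spacing: int = 10_000,
    seed: int = 0,
) -> list[Gene]:
    """Uniformly placed non-overlapping genes on a toy multi-chromosome genome.

    Canonical TSSs follow a uniform-with-exclusion process (pairwise spacing
    >= min_gene_spacing); strands are random and each gene carries 1-3 TSSs,
    the alternatives within 5 kb downstream of the canonical one (so the
    canonical TSS stays the 5'-most, as after transcript collapsing).
    """
    if genes_per_chrom * min_gene_spacing >= chrom_len:
        raise ValueError(
            f"cannot place {genes_per_chrom} genes with {min_gene_spacing} bp "
            f"spacing on a {chrom_len} bp chromosome"
        )
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        slack = chrom_len - (genes_per_chrom - 1) * min_gene_spacing
        y = np.sort(rng.uniform(0, slack, size=genes_per_chrom))
        tss = y.astype(np.int64) + np.arange(genes_per_chrom) * min_gene_spacing
        strands = rng.choice(["+", "-"], size=genes_per_chrom)
        for i in range(genes_per_chrom):
            canonical = int(tss[i])
            strand = str(strands[i])
            n_alt = int(rng.integers(0, 3))
            offsets = sorted(int(rng.integers(500, 5001)) for _ in range(n_alt))
            sign = 1 if strand == "+" else -1
            alt = [max(0, canonical + sign * o) for o in offsets]
            all_tss = tuple(sorted({canonical, *alt}))
            genes.append(
                Gene(
                    symbol=f"g{c}_{i:04d}",
                    chrom=chrom,
                    strand=strand,
                    canonical_tss=canonical,
                    all_tss=all_tss,
                    is_coding=True,
                )
            )
    return genes


def _shift_gene(gene: Gene, new_canonical: int) -> Gene:
    """Move a gene to a new canonical TSS, preserving its alternative-TSS offsets."""
    delta = new_canonical - gene.canonical_tss
    return Gene(
        symbol=gene.symbol,
        chrom=gene.chrom,
        strand=gene.strand,
        canonical_tss=new_canonical,
        all_tss=tuple(sorted(max(0, t + delta) for t in gene.all_tss)),
        is_coding=gene.is_coding,
    )


def plant_clusters(
    genome: Sequence[Gene],
    n_clusters: int,
    genes_per_cluster: int = 3,
    intra_gap_range: tuple[int, int] = (20_000, 80_000),
    n_singletons: int = 10,
    epromoters_per_cluster: int | str = 1,
    peak_width: int = 200,
    distal_peaks: bool = False,
    with_tads: bool = True,
    tad_margin: int = 150_000,
    motifs_per_epromoter: int = 0,
    chrom_len: int = 10_000_000,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant induced clusters with known Epromoters into a toy genome.

    Cluster members and induced singletons are existing genome genes whose
    TSSs are re-placed along their chromosome: blocks (clusters/singletons)
    are separated by 400-600 kb of clear space, intra-cluster gaps are drawn
    from ``intra_gap_range`` (strictly below the 100 kb clustering rule), and
    the remaining genes become background, trailing the last block.  A peak
    of ``peak_width`` bp is dropped on each planted Epromoter's canonical
    TSS (``epromoters_per_cluster`` may be "all" to bind every member);
    optional distal peaks sit mid-way inside the first intra-cluster gap,
    clear of every promoter window.  TADs span each planted cluster with a
    ``tad_margin`` that stays short of the neighbouring blocks.
    """
    lo, hi = intra_gap_range
    if not (0 < lo <= hi < 100_000):
        raise ValueError("intra_gap_range must lie strictly below 100 kb")
    if genes_per_cluster < 2:
        raise ValueError("a planted cluster needs at least 2 genes")
    if isinstance(epromoters_per_cluster, str) and epromoters_per_cluster != "all":
        raise ValueError("epromoters_per_cluster must be an int or 'all'")
    rng = np.random.default_rng(seed)

    by_chrom: dict[str, list[Gene]] = {}
    for g in genome:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(by_chrom)
    for chrom in chroms:
        by_chrom[chrom].sort(key=lambda g: g.canonical_tss)

    # round-robin block assignment: clusters first, then singletons
    blocks_per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    for k in range(n_clusters):
        blocks_per_chrom[chroms[k % len(chroms)]].append(("cluster", k))
    for k in range(n_singletons):
        blocks_per_chrom[chroms[k % len(chroms)]].append(("singleton", k))

    placed: list[Gene] = []
    planted: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    singletons: list[str] = []
    peaks: list[GenomicInterval] = []
    motif_track: list[GenomicInterval] = []
    tads: list[GenomicInterval] = []
    fold_changes: dict[str, float] = {}

    for chrom in chroms:
        pool = list(by_chrom[chrom])
        needed = sum(
            genes_per_cluster if kind == "cluster" else 1
            for kind, _ in blocks_per_chrom[chrom]
        )
        if needed > len(pool):
            raise ValueError(
                f"{chrom}: {needed} induced genes requested but only "
                f"{len(pool)} genes available"
            )
        cursor = int(rng.integers(50_000, 150_000))
        for kind, k in blocks_per_chrom[chrom]:
            if kind == "cluster":
                positions = [cursor]
                for _ in range(genes_per_cluster - 1):
                    positions.append(positions[-1] + int(rng.integers(lo, hi + 1)))
                if positions[-1] + tad_margin >= chrom_len:
                    raise ValueError(
                        f"cluster {k} does not fit on {chrom} "
                        f"(would end at {positions[-1]} of {chrom_len} bp)"
                    )
                members = [
                    _shift_gene(pool.pop(0), pos) for pos in positions
                ]
                placed.extend(members)
                symbols = tuple(m.symbol for m in members)
                if epromoters_per_cluster == "all":
                    bound = list(symbols)
                else:
                    idx = rng.choice(
                        genes_per_cluster,
                        size=min(int(epromoters_per_cluster), genes_per_cluster),
                        replace=False,
                    )
                    bound = [symbols[i] for i in sorted(idx)]
                planted[k] = (symbols, tuple(bound))
                for m in members:
                    fold_changes[m.symbol] = round(float(rng.uniform(2, 10)), 2)
                    if m.symbol in bound:
                        start = m.canonical_tss - peak_width // 2
                        peaks.append(
                            GenomicInterval(chrom, max(0, start), max(0, start) + peak_width)
                        )
                        for j in range(motifs_per_epromoter):
                            s = m.canonical_tss - 600 + 40 * j
                            motif_track.append(GenomicInterval(chrom, s, s + 10))
                if distal_peaks:
                    mid = (positions[0] + positions[1]) // 2
                    peaks.append(
                        GenomicInterval(chrom, mid - peak_width // 2,
                                        mid - peak_width // 2 + peak_width)
                    )
                if with_tads:
                    tads.append(
                        GenomicInterval(
                            chrom,
                            max(0, positions[0] - tad_margin),
                            positions[-1] + tad_margin,
                            name=f"tad_{k}",
                        )
                    )
                cursor = positions[-1] + int(rng.integers(400_000, 600_000))
            else:
                if cursor >= chrom_len:
                    raise ValueError(f"singleton {k} does not fit on {chrom}")
                g = _shift_gene(pool.pop(0), cursor)
                placed.append(g)
                singletons.append(g.symbol)
                fold_changes[g.symbol] = round(float(rng.uniform(2, 10)), 2)
                cursor += int(rng.integers(400_000, 600_000))
        # background genes fill the space after the last block, uniformly
        # with a spacing floor scaled to what fits
        if pool:
            n_bg = len(pool)
            space = chrom_len - cursor
            spacing = max(1, min(10_000, space // (2 * n_bg)))
            slack = space - (n_bg - 1) * spacing
            if slack <= 0:
                raise ValueError(
                    f"{chrom}: {n_bg} background genes do not fit in the "
                    f"remaining {space} bp"
                )
            y = np.sort(rng.uniform(0, slack, size=n_bg))
            for g, offset in zip(pool, y.astype(np.int64)
                                 + np.arange(n_bg) * spacing):
                placed.append(_shift_gene(g, cursor + int(offset)))

    induced = [s for k in sorted(planted) for s in planted[k][0]] + singletons
    return SyntheticTruth(
        genes=tuple(sorted(placed, key=lambda g: (g.chrom, g.canonical_tss, g.symbol))),
        induced_symbols=tuple(induced),
        fold_changes=fold_changes,
        planted_clusters=tuple(planted[k] for k in sorted(planted)),
        singleton_symbols=tuple(singletons),
        tads=tuple(tads),
        peaks=tuple(peaks),
        motif_track=tuple(motif_track),
        seed=seed,
        params={
            "n_clusters": n_clusters,
            "genes_per_cluster": genes_per_cluster,
            "intra_gap_range": list(intra_gap_range),
            "n_singletons": n_singletons,
            "epromoters_per_cluster": epromoters_per_cluster,
            "peak_width": peak_width,
            "distal_peaks": distal_peaks,
            "with_tads": with_tads,
            "tad_margin": tad_margin,
            "motifs_per_epromoter": motifs_per_epromoter,
            "chrom_len": chrom_len,
        },
    )


def simulate_proximity(
    universe: Sequence[Gene],
    n_induced: int,
    clump_size: int | None = None,
    clump_spread: int = 50_000,
    seed: int = 0,
) -> list[Gene]:
    """Draw an induced gene set, optionally planted in tight clumps.

    ``clump_size=None`` draws a uniform subsample.  Otherwise genes are
    drawn as groups: a random anchor gene plus up to ``clump_size - 1`` of
    its nearest same-chromosome neighbours within ``clump_spread`` bp.
    """
    if n_induced > len(universe):
        raise ValueError("n_induced exceeds the universe size")
    rng = np.random.default_rng(seed)
    if clump_size is None:
        idx = rng.choice(len(universe), size=n_induced, replace=False)
        return [universe[i] for i in idx]

    ordered = sorted(universe, key=lambda g: (g.chrom, g.canonical_tss, g.symbol))
    chosen: dict[str, Gene] = {}
    while len(chosen) < n_induced:
        anchor = ordered[int(rng.integers(len(ordered)))]
        if anchor.symbol in chosen:
            continue
        neighbours = [
            g
            for g in ordered
            if g.chrom == anchor.chrom
            and g.symbol not in chosen
            and abs(g.canonical_tss - anchor.canonical_tss) <= clump_spread
        ]
        neighbours.sort(key=lambda g: abs(g.canonical_tss - anchor.canonical_tss))
        for g in neighbours[:clump_size]:
            if len(chosen) < n_induced:
                chosen[g.symbol] = g
    return list(chosen.values())


def write_fixture(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write a truth object as the pipeline's on-disk input formats.

    Emits a refGene-format annotation (one transcript per TSS), the induced
    2-column TSV, peak/TAD/motif BED files and a JSON truth record.  Files
    are sorted deterministically so identical truths are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.refGene.txt",
        "induced": outdir / "induced.tsv",
        "peaks": outdir / "peaks.bed",
        "tads": outdir / "tads.bed",
        "motifs": outdir / "motifs.bed",
        "truth": outdir / "truth.json",
    }
    tx_len = 1000
    with open(paths["annotation"], "w") as fh:
        acc = 0
        for g in truth.genes:
            for tss in g.all_tss:
                if g.strand == "+":
                    tx_start, tx_end = tss, tss + tx_len
                else:
                    tx_start, tx_end = max(0, tss + 1 - tx_len), tss + 1
                fh.write(
                    "\t".join(
                        [
                            "0",
                            f"NM_{acc:06d}",
                            g.chrom,
                            g.strand,
                            str(tx_start),
                            str(tx_end),
                            str(tx_start),
                            str(tx_end),
                            "1",
                            f"{tx_start},",
                            f"{tx_end},",
                            "0",
                            g.symbol,
                            "cmpl",
                            "cmpl",
                            "0,",
                        ]
                    )
                    + "\n"
                )
                acc += 1
    with open(paths["induced"], "w") as fh:
        fh.write("symbol\tfold_change\n")
        for s in truth.induced_symbols:
            fh.write(f"{s}\t{truth.fold_changes[s]}\n")
    write_bed(truth.peaks, paths["peaks"])
    write_bed(truth.tads, paths["tads"])
    write_bed(truth.motif_track, paths["motifs"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "params": truth.params,
                "induced_symbols": list(truth.induced_symbols),
                "singleton_symbols": list(truth.singleton_symbols),
                "planted_clusters": [
                    {"members": list(m), "epromoters": list(e)}
                    for m, e in truth.planted_clusters
                ],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
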