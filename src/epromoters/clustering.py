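"""Clustering of co-induced genes by TSS proximity or TAD co-membership.

Two clustering methods are provided:

* distance — per chromosome, genes sorted by canonical TSS are chained
  whenever the gap to the previous gene is strictly below ``max_gap``
  (default 100 kb); maximal chains of two or more genes become clusters.
  On a line, this single-linkage chaining coincides with the connected
  components of the pairwise < max_gap graph.
* tad — each gene belongs to every TAD containing its canonical TSS
  (half-open containment); TADs holding two or more induced genes become
  clusters, with no distance limit inside the TAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotation import Gene
from .intervals import GenomicInterval

__all__ = [
    "GeneCluster",
    "MethodComparison",
    "cluster_by_distance",
    "cluster_by_tad",
    "unclustered_genes",
    "compare_methods",
]


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    method: str
    genes: tuple[Gene, ...]
    chrom: str
    span: GenomicInterval
    tad_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"{self.cluster_id}: a cluster needs more than 1 gene")
        if any(g.chrom != self.chrom for g in self.genes):
            raise ValueError(f"{self.cluster_id}: genes span multiple chromosomes")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MethodComparison:
    common: tuple[tuple[str, str], ...]
    distance_only: tuple[str, ...]
    tad_only: tuple[str, ...]

    @property
    def n_common(self) -> int:
        return len(self.common)


def _make_cluster(
    genes: list[Gene], method: str, dataset_id: str, index: int, tad_id: str | None = None
) -> GeneCluster:
    genes = sorted(genes, key=lambda g: (g.canonical_tss, g.symbol))
    chrom = genes[0].chrom
    tsss = [g.canonical_tss for g in genes]
    # span covers min..max canonical TSS; +1 keeps the interval non-empty
    span = GenomicInterval(chrom, min(tsss), max(tsss) + 1)
    return GeneCluster(
        cluster_id=f"{dataset_id}:{method}:{chrom}:{index}",
        method=method,
        genes=tuple(genes),
        chrom=chrom,
        span=span,
        tad_id=tad_id,
    )


def cluster_by_distance(
    induced: Sequence[Gene],
    max_gap: int = 100_000,
    dataset_id: str = "dataset",
) -> list[GeneCluster]:
    """Chain induced genes whose consecutive TSS gaps are strictly < max_gap.

    Output order (and cluster ids) are deterministic: chromosomes sorted
    lexicographically, clusters indexed by leftmost TSS.  Input order is
    irrelevant.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in induced:
        by_chrom.setdefault(g.chrom, []).append(g)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.canonical_tss, g.symbol))
        chain: list[Gene] = [genes[0]]
        index = 0
        for g in genes[1:]:
            if g.canonical_tss - chain[-1].canonical_tss < max_gap:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chain, "distance", dataset_id, index))
                    index += 1
                chain = [g]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain, "distance", dataset_id, index))
    return clusters


def cluster_by_tad(
    induced: Sequence[Gene],
    tads: Sequence[GenomicInterval],
    dataset_id: str = "dataset",
    smallest_only: bool = False,
) -> list[GeneCluster]:
    """Group induced genes by TAD co-membership (canonical-TSS containment).

    Overlapping or nested TADs are tolerated and may yield overlapping
    clusters; with ``smallest_only`` each gene is assigned only to the
    smallest TAD containing its TSS.
    """
    named = [
        (tad.name if tad.name else f"tad_{i}", tad) for i, tad in enumerate(tads)
    ]
    assignment: dict[str, list[Gene]] = {}
    for g in induced:
        containing = [
            (tid, tad)
            for tid, tad in named
            if tad.chrom == g.chrom and tad.start <= g.canonical_tss < tad.end
        ]
        if not containing:
            continue
        if smallest_only:
            containing = [min(containing, key=lambda x: (x[1].length, x[0]))]
        for tid, _ in containing:
            assignment.setdefault(tid, []).append(g)

    clusters: list[GeneCluster] = []
    counters: dict[str, int] = {}
    order = {tid: i for i, (tid, _) in enumerate(named)}
    for tid in sorted(assignment, key=lambda t: order[t]):
        members = assignment[tid]
        if len(members) < 2:
            continue
        chrom = members[0].chrom
        index = counters.get(chrom, 0)
        counters[chrom] = index + 1
        clusters.append(_make_cluster(members, "tad", dataset_id, index, tad_id=tid))
    return clusters


def unclustered_genes(
    induced: Sequence[Gene], clusters: Sequence[GeneCluster]
) -> list[Gene]:
    """Induced genes not assigned to any of the given clusters (singletons)."""
    clustered = {s for c in clusters for s in c.symbols}
    return [g for g in induced if g.symbol not in clustered]


def compare_methods(
    calls_distance: Sequence, calls_tad: Sequence
) -> MethodComparison:
    """Match distance-method and TAD-method cluster calls by shared genes.

    Greedy maximal one-to-one matching by descending gene-set intersection
    size (ties broken by cluster id); unmatched calls land in the
    method-specific buckets.  Accepts GeneClusters or ClusterCalls (anything
    with ``cluster_id``/``symbols`` or a ``cluster`` carrying them).
    """

    def unpack(obj) -> tuple[str, frozenset[str]]:
        cluster = getattr(obj, "cluster", obj)
        return cluster.cluster_id, frozenset(cluster.symbols)

    dist = dict(unpack(c) for c in calls_distance)
    tad = dict(unpack(c) for c in calls_tad)
    pairs = [
        (len(dist[d] & tad[t]), d, t)
        for d in dist
        for t in tad
        if dist[d] & tad[t]
    ]
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_d: set[str] = set()
    matched_t: set[str] = set()
    common: list[tuple[str, str]] = []
    for _, d, t in pairs:
        if d in matched_d or t in matched_t:
            continue
        common.append((d, t))
        matched_d.add(d)
        matched_t.add(t)
    return MethodComparison(
        common=tuple(common),
        distance_only=tuple(sorted(set(dist) - matched_d)),
        tad_only=tuple(sorted(set(tad) - matched_t)),
    )
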