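"""Epromoter classification of gene clusters.

A cluster gene's promoter is "bound" when any ChIP-seq peak of any of the
dataset's key TFs overlaps (>= 1 bp) the +/- 1 kb window around any of the
gene's TSSs, alternative TSSs included.  Clusters are then categorised:

* unbound — no gene bound;
* epromoter_regulated — at least one but fewer than all genes bound, the
  signature of a promoter recruiting the TF on behalf of its neighbours;
* all_bound — every gene bound;
* partial_multi — only under the stricter ``exactly_one`` criterion (the
  TAD-method default), clusters with two or more (but not all) bound genes.

Bound genes of an epromoter_regulated cluster are the candidate Epromoters;
its unbound genes are the co-induced genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import Gene, promoter_windows
from .clustering import GeneCluster
from .intervals import GenomicInterval, count_overlaps, extend

__all__ = [
    "ClusterCall",
    "DatasetSummary",
    "PeakLocationProfile",
    "CATEGORIES",
    "promoter_bound",
    "bound_genes",
    "classify_cluster",
    "classify_clusters",
    "summarize_dataset",
    "bubble_grid",
    "merge_nonredundant",
    "merge_symbol_groups",
    "peak_location_profile",
]

CATEGORIES = ("unbound", "epromoter_regulated", "all_bound", "partial_multi")


@dataclass(frozen=True)
class ClusterCall:
    cluster: GeneCluster
    bound_flags: Mapping[str, bool]              # symbol -> bound by any key TF
    per_tf_flags: Mapping[str, Mapping[str, bool]]  # tf -> symbol -> bound
    category: str
    epromoter_genes: tuple[str, ...]
    coinduced_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n, nb = self.n_genes, self.n_bound
        ok = {
            "unbound": nb == 0,
            "all_bound": nb == n,
            "epromoter_regulated": 1 <= nb < n,
            "partial_multi": 2 <= nb < n,
        }[self.category]
        if not ok:
            raise ValueError(
                f"{self.cluster.cluster_id}: category {self.category} inconsistent "
                f"with {nb}/{n} bound genes"
            )

    @property
    def n_genes(self) -> int:
        return self.cluster.n_genes

    @property
    def n_bound(self) -> int:
        return sum(bool(v) for v in self.bound_flags.values())


@dataclass(frozen=True)
class DatasetSummary:
    dataset_id: str
    n_induced_genes: int
    n_clusters: int
    n_genes_in_clusters: int
    n_epromoter_clusters: int
    n_all_bound_clusters: int
    n_unbound_clusters: int
    n_partial_multi_clusters: int
    freq_epromoter: float
    freq_all_bound: float
    one_bound_share: float
    fewer_bound_share: float

    def __post_init__(self) -> None:
        total = (
            self.n_epromoter_clusters
            + self.n_all_bound_clusters
            + self.n_unbound_clusters
            + self.n_partial_multi_clusters
        )
        if total != self.n_clusters:
            raise ValueError(
                f"{self.dataset_id}: cluster categories do not partition "
                f"({total} != {self.n_clusters})"
            )


@dataclass(frozen=True)
class PeakLocationProfile:
    cluster_id: str
    n_proximal_peaks: int
    n_distal_peaks: int
    location_class: str

    def __post_init__(self) -> None:
        expected = _location_class(self.n_proximal_peaks, self.n_distal_peaks)
        if self.location_class != expected:
            raise ValueError(f"{self.cluster_id}: inconsistent location class")


def _location_class(n_proximal: int, n_distal: int) -> str:
    if n_proximal and n_distal:
        return "proximal_and_distal"
    if n_proximal:
        return "proximal_only"
    if n_distal:
        return "distal_only"
    return "none"


def promoter_bound(
    gene: Gene, peaks: Sequence[GenomicInterval], flank: int = 1000
) -> bool:
    """True iff any peak overlaps the +/- flank window around any TSS of the gene."""
    windows = promoter_windows(gene, flank, flank, per_tss=True, strand_aware=False)
    counts = count_overlaps([w.as_interval() for w in windows], list(peaks))
    return bool(counts.sum() > 0)


def bound_genes(
    genes: Sequence[Gene], peaks: Sequence[GenomicInterval], flank: int = 1000
) -> dict[str, bool]:
    """Per-gene promoter-binding flags (vectorised over all TSS windows)."""
    windows: list[GenomicInterval] = []
    owners: list[str] = []
    for g in genes:
        for w in promoter_windows(g, flank, flank, per_tss=True, strand_aware=False):
            windows.append(w.as_interval())
            owners.append(g.symbol)
    counts = count_overlaps(windows, list(peaks))
    flags = {g.symbol: False for g in genes}
    for owner, c in zip(owners, counts):
        if c > 0:
            flags[owner] = True
    return flags


def classify_cluster(
    cluster: GeneCluster,
    peaks_by_tf: Mapping[str, Sequence[GenomicInterval]],
    criterion: str = "fewer_than_n",
    flank: int = 1000,
) -> ClusterCall:
    """Categorise one cluster from its genes' promoter-binding flags.

    Binding is OR-combined across the dataset's key TFs (e.g., HSF1 and HSF2
    for a heat-shock dataset).  ``criterion="fewer_than_n"`` calls a cluster
    epromoter_regulated whenever 1 <= n_bound < n_genes; ``"exactly_one"``
    (TAD-method default) demotes clusters with several-but-not-all bound
    genes to partial_multi.
    """
    if criterion not in ("fewer_than_n", "exactly_one"):
        raise ValueError(f"unknown criterion {criterion!r}")
    per_tf = {
        tf: bound_genes(cluster.genes, peaks, flank) for tf, peaks in peaks_by_tf.items()
    }
    flags = {
        g.symbol: any(per_tf[tf][g.symbol] for tf in per_tf) for g in cluster.genes
    }
    n, nb = cluster.n_genes, sum(flags.values())
    if nb == 0:
        category = "unbound"
    elif nb == n:
        category = "all_bound"
    elif criterion == "exactly_one" and nb > 1:
        category = "partial_multi"
    else:
        category = "epromoter_regulated"
    epromoters = tuple(
        g.symbol for g in cluster.genes if flags[g.symbol]
    ) if category == "epromoter_regulated" else ()
    coinduced = tuple(
        g.symbol for g in cluster.genes if not flags[g.symbol]
    ) if category == "epromoter_regulated" else ()
    return ClusterCall(
        cluster=cluster,
        bound_flags=flags,
        per_tf_flags=per_tf,
        category=category,
        epromoter_genes=epromoters,
        coinduced_genes=coinduced,
    )


def classify_clusters(
    clusters: Sequence[GeneCluster],
    peaks_by_tf: Mapping[str, Sequence[GenomicInterval]],
    criterion: str = "fewer_than_n",
    flank: int = 1000,
) -> list[ClusterCall]:
    return [classify_cluster(c, peaks_by_tf, criterion, flank) for c in clusters]


def summarize_dataset(
    calls: Sequence[ClusterCall],
    dataset_id: str,
    n_induced_genes: int | None = None,
) -> DatasetSummary:
    """Per-dataset cluster category counts and shares.

    ``one_bound_share`` and ``fewer_bound_share`` are computed among clusters
    with at least one bound gene: the share with exactly one bound gene and
    the share with fewer bound genes than members, respectively.  Fractions
    are NaN when their denominator is zero.
    """
    n = len(calls)
    cats = [c.category for c in calls]
    n_e = cats.count("epromoter_regulated")
    n_a = cats.count("all_bound")
    n_u = cats.count("unbound")
    n_p = cats.count("partial_multi")
    with_binding = [c for c in calls if c.n_bound >= 1]
    one_bound = sum(1 for c in with_binding if c.n_bound == 1)
    fewer_bound = sum(1 for c in with_binding if c.n_bound < c.n_genes)
    nan = float("nan")
    return DatasetSummary(
        dataset_id=dataset_id,
        n_induced_genes=n_induced_genes
        if n_induced_genes is not None
        else len({s for c in calls for s in c.cluster.symbols}),
        n_clusters=n,
        n_genes_in_clusters=sum(c.n_genes for c in calls),
        n_epromoter_clusters=n_e,
        n_all_bound_clusters=n_a,
        n_unbound_clusters=n_u,
        n_partial_multi_clusters=n_p,
        freq_epromoter=n_e / n if n else nan,
        freq_all_bound=n_a / n if n else nan,
        one_bound_share=one_bound / len(with_binding) if with_binding else nan,
        fewer_bound_share=fewer_bound / len(with_binding) if with_binding else nan,
    )


def bubble_grid(calls: Sequence[ClusterCall]) -> pd.DataFrame:
    """Occupancy grid: number of clusters per (n_genes, n_bound) cell."""
    rows: dict[tuple[int, int], int] = {}
    for c in calls:
        key = (c.n_genes, c.n_bound)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"n_genes": k[0], "n_bound": k[1], "n_clusters": v}
            for k, v in sorted(rows.items())
        ]
    )


def merge_symbol_groups(
    groups_by_build: Mapping[str, Sequence[tuple[str, Sequence[str]]]],
) -> tuple[int, pd.DataFrame]:
    """Merge (cluster_id, gene symbols) groups sharing >= 1 symbol, per build.

    Within each genome build, groups sharing at least one gene symbol are
    linked; connected components are the non-redundant clusters.  Builds are
    never merged with each other.  Returns the total component count and a
    table with one row per component.
    """
    total = 0
    rows = []
    for build in sorted(groups_by_build):
        groups = [(cid, tuple(symbols)) for cid, symbols in groups_by_build[build]]
        groups.sort(key=lambda g: g[0])
        parent = list(range(len(groups)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        symbol_first: dict[str, int] = {}
        for i, (_, symbols) in enumerate(groups):
            for s in symbols:
                if s in symbol_first:
                    ri, rj = find(i), find(symbol_first[s])
                    if ri != rj:
                        parent[ri] = rj
                else:
                    symbol_first[s] = i
        components: dict[int, list[int]] = {}
        for i in range(len(groups)):
            components.setdefault(find(i), []).append(i)
        total += len(components)
        for members in sorted(components.values(), key=lambda m: groups[m[0]][0]):
            symbols = sorted({s for i in members for s in groups[i][1]})
            rows.append(
                {
                    "genome_build": build,
                    "n_source_clusters": len(members),
                    "cluster_ids": ";".join(sorted(groups[i][0] for i in members)),
                    "gene_symbols": ";".join(symbols),
                }
            )
    return total, pd.DataFrame(rows)


def merge_nonredundant(
    calls_by_build: Mapping[str, Sequence[ClusterCall]],
) -> tuple[int, pd.DataFrame]:
    """Non-redundant Epromoter-regulated cluster count across datasets.

    Only epromoter_regulated calls participate; see
    :func:`merge_symbol_groups` for the merging rule.
    """
    groups = {
        build: [
            (c.cluster.cluster_id, c.cluster.symbols)
            for c in calls
            if c.category == "epromoter_regulated"
        ]
        for build, calls in calls_by_build.items()
    }
    return merge_symbol_groups(groups)


def peak_location_profile(
    call: ClusterCall,
    peaks: Sequence[GenomicInterval],
    all_genes: Sequence[Gene],
    pad: int = 100_000,
    flank: int = 1000,
) -> PeakLocationProfile:
    """Classify the peaks around a cluster as TSS-proximal or distal.

    The cluster span (leftmost to rightmost TSS) is extended by ``pad`` on
    both sides; peaks overlapping the extended span are proximal when they
    overlap the +/- flank window of any TSS of ANY annotated gene (induced
    or not), distal (intergenic) otherwise.
    """
    region = extend(call.cluster.span, pad)
    local = [
        p
        for p in peaks
        if p.chrom == region.chrom and p.start < region.end and p.end > region.start
    ]
    windows = [
        w.as_interval()
        for g in all_genes
        for w in promoter_windows(g, flank, flank, per_tss=True, strand_aware=False)
    ]
    n_prox = 0
    for p in local:
        if count_overlaps([p], windows)[0] > 0:
            n_prox += 1
    n_dist = len(local) - n_prox
    return PeakLocationProfile(
        cluster_id=call.cluster.cluster_id,
        n_proximal_peaks=n_prox,
        n_distal_peaks=n_dist,
        location_class=_location_class(n_prox, n_dist),
    )
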