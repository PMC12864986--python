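"""Motif-density analysis over promoter categories.

Induced-gene promoters are partitioned into four categories — predicted
Epromoters, co-induced promoters (clustered with an Epromoter), and the
remaining induced promoters split by whether they bind the key TF — plus a
seeded random control set drawn from non-induced genes.  Motif occurrences
(precomputed genome-wide BED tracks, e.g. JASPAR scans of the heat-shock
element) are counted inside an asymmetric promoter window (-1250/+750 bp
around the TSS by default) and binned as 0 / 1 / 2-3 / >3 motifs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, PromoterWindow, promoter_windows
from .calling import ClusterCall
from .intervals import GenomicInterval, count_overlaps

__all__ = [
    "MOTIF_BINS",
    "assign_categories",
    "category_windows",
    "count_motifs",
    "bin_table",
]

MOTIF_BINS = ("0", "1", "2-3", ">3")
_CATEGORIES = ("epromoter", "coinduced", "induced_tf_plus", "induced_tf_minus", "random")


def motif_bin(count: int) -> str:
    if count <= 0:
        return "0"
    if count == 1:
        return "1"
    if count <= 3:
        return "2-3"
    return ">3"


def assign_categories(
    calls: Sequence[ClusterCall],
    induced: Sequence[Gene],
    bound_flags: Mapping[str, bool],
    universe: Sequence[Gene],
    n_random: int,
    seed: int,
) -> dict[str, str]:
    """Map every induced gene (plus a random control set) to one category.

    Epromoter and co-induced labels come from the epromoter_regulated
    cluster calls; every other induced gene is induced_tf_plus or
    induced_tf_minus according to its own promoter-binding flag.  The random
    controls are sampled (seed-deterministic) from non-induced universe
    genes.  Categories are mutually exclusive by construction.
    """
    mapping: dict[str, str] = {}
    for call in calls:
        if call.category != "epromoter_regulated":
            continue
        for s in call.epromoter_genes:
            mapping[s] = "epromoter"
        for s in call.coinduced_genes:
            mapping[s] = "coinduced"
    induced_symbols = {g.symbol for g in induced}
    for g in induced:
        if g.symbol in mapping:
            continue
        mapping[g.symbol] = (
            "induced_tf_plus" if bound_flags.get(g.symbol, False) else "induced_tf_minus"
        )
    pool = sorted(
        (g.symbol for g in universe if g.symbol not in induced_symbols)
    )
    if n_random > len(pool):
        raise ValueError(
            f"cannot sample {n_random} random promoters from {len(pool)} non-induced genes"
        )
    rng = np.random.default_rng(seed)
    for s in rng.choice(pool, size=n_random, replace=False):
        mapping[str(s)] = "random"
    assert len(mapping) == len(induced_symbols) + n_random, "category overlap"
    return mapping


def category_windows(
    categories: Mapping[str, str],
    genes: Sequence[Gene],
    upstream: int = 1250,
    downstream: int = 750,
    strand_aware: bool = True,
) -> list[PromoterWindow]:
    """One canonical-TSS promoter window per categorised gene."""
    by_symbol = {g.symbol: g for g in genes}
    windows = []
    for symbol in sorted(categories):
        g = by_symbol[symbol]
        windows.extend(
            promoter_windows(
                g, upstream, downstream, per_tss=False, strand_aware=strand_aware
            )
        )
    return windows


def count_motifs(
    promoters: Sequence[PromoterWindow],
    motif_tracks: Sequence[GenomicInterval] | Sequence[Sequence[GenomicInterval]],
) -> pd.Series:
    """Per-promoter motif-occurrence count (summed over multiple tracks).

    ``motif_tracks`` may be one flat list of occurrences or a list of tracks
    (e.g. one per TF motif), in which case per-track counts are summed.
    """
    if motif_tracks and isinstance(motif_tracks[0], GenomicInterval):
        tracks: list[Sequence[GenomicInterval]] = [motif_tracks]  # type: ignore[list-item]
    else:
        tracks = list(motif_tracks)  # type: ignore[assignment]
    queries = [p.as_interval() for p in promoters]
    total = np.zeros(len(promoters), dtype=np.int64)
    for track in tracks:
        total += count_overlaps(queries, list(track))
    return pd.Series(total, index=[p.gene_symbol for p in promoters], name="motif_count")


def bin_table(
    counts: pd.Series, categories: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene motif bins plus per-category bin percentages.

    Returns (per_gene, per_category): per_gene has one row per promoter with
    its category, count and bin; per_category holds the percentage of
    promoters per bin within each category (rows sum to 100; NaN rows for
    empty categories).
    """
    per_gene = pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "category": [categories[s] for s in counts.index],
            "motif_count": counts.to_numpy(),
        }
    )
    per_gene["bin"] = per_gene["motif_count"].map(motif_bin)
    rows = []
    for cat in _CATEGORIES:
        sub = per_gene[per_gene["category"] == cat]
        row: dict[str, object] = {"category": cat, "n_promoters": len(sub)}
        for b in MOTIF_BINS:
            row[f"pct_{b}"] = (
                100.0 * (sub["bin"] == b).mean() if len(sub) else float("nan")
            )
        rows.append(row)
    return per_gene, pd.DataFrame(rows)
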