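"""Promoter binding, cluster categories, summaries and peak-location profiles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epromoters import (
    GenomicInterval,
    bubble_grid,
    classify_cluster,
    cluster_by_distance,
    merge_nonredundant,
    peak_location_profile,
    promoter_bound,
    summarize_dataset,
)
from epromoters.calling import ClusterCall, bound_genes

from conftest import gene


def peak(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def call_for(tss_list, bound_idx, peaks_extra=(), criterion="fewer_than_n"):
    """Build a cluster from TSS positions and bind the genes at bound_idx."""
    genes = [gene(f"g{i}", t) for i, t in enumerate(tss_list)]
    (cluster,) = [c for c in cluster_by_distance(genes)]
    peaks = [peak(tss_list[i] - 50, tss_list[i] + 50) for i in bound_idx]
    peaks += list(peaks_extra)
    return classify_cluster(cluster, {"TF": peaks}, criterion=criterion)


class TestPromoterBound:
    def test_peak_inside_window(self):
        assert promoter_bound(gene("g", 10_000), [peak(9_500, 9_600)])

    def test_window_end_is_exclusive(self):
        assert not promoter_bound(gene("g", 10_000), [peak(11_001, 12_000)])
        assert promoter_bound(gene("g", 10_000), [peak(11_000, 12_000)])

    def test_alternative_tss_counts(self):
        g = gene("g", 10_000, alt=(50_000,))
        assert promoter_bound(g, [peak(49_100, 49_300)])

    def test_vectorised_flags_match_single_gene_path(self):
        rng = np.random.default_rng(41)
        genes = [gene(f"g{i}", int(p), alt=(int(p) + 3_000,))
                 for i, p in enumerate(rng.choice(1_000_000, 30, replace=False))]
        peaks = [peak(int(s), int(s) + 400)
                 for s in rng.integers(0, 1_000_000, 50)]
        flags = bound_genes(genes, peaks)
        assert flags == {g.symbol: promoter_bound(g, peaks) for g in genes}


class TestClassifyCluster:
    def test_bidirectional_promoter_three_genes(self):
        """Three induced genes, two promoter regions, one (bidirectional)
        region bound: the cluster is Epromoter-regulated with one co-induced
        gene."""
        genes = [gene("left", 50_000, strand="-"), gene("right", 50_400),
                 gene("third", 120_000)]
        (cluster,) = cluster_by_distance(genes)
        # one peak on the shared bidirectional promoter binds both genes
        call = classify_cluster(cluster, {"TF": [peak(50_100, 50_300)]})
        assert call.category == "epromoter_regulated"
        assert set(call.epromoter_genes) == {"left", "right"}
        assert call.coinduced_genes == ("third",)

    def test_six_genes_one_bound_yields_five_coinduced(self):
        call = call_for([0, 30_000, 60_000, 90_000, 120_000, 150_000], [1])
        assert call.category == "epromoter_regulated"
        assert call.epromoter_genes == ("g1",)
        assert len(call.coinduced_genes) == 5

    def test_two_gene_one_bound_pairs(self):
        # the Cxcl1-Cxcl2 / Cd274-Jak2 configuration: 2 genes, 1 bound
        call = call_for([10_000, 80_000], [0])
        assert call.category == "epromoter_regulated"
        assert call.n_bound == 1

    def test_all_bound_and_unbound(self):
        assert call_for([0, 50_000], [0, 1]).category == "all_bound"
        assert call_for([0, 50_000, 99_000, 150_000], []).category == "unbound"

    def test_exactly_one_criterion_demotes_partial_multi(self):
        call = call_for([0, 50_000, 100_000], [0, 1], criterion="exactly_one")
        assert call.category == "partial_multi"
        one = call_for([0, 50_000, 100_000], [0], criterion="exactly_one")
        assert one.category == "epromoter_regulated"

    def test_or_combination_across_tfs(self):
        genes = [gene("a", 10_000), gene("b", 80_000)]
        (cluster,) = cluster_by_distance(genes)
        call = classify_cluster(cluster, {
            "HSF1": [peak(9_900, 10_100)],
            "HSF2": [peak(79_900, 80_100)],
        })
        assert call.category == "all_bound"

    def test_adding_a_peak_never_unbinds(self):
        base = call_for([0, 50_000], [0, 1])
        more = call_for([0, 50_000], [0, 1], peaks_extra=[peak(200_000, 200_100)])
        assert base.category == "all_bound" and more.category == "all_bound"


class TestSummarize:
    def test_hand_enumerated_counts_and_shares(self):
        calls = [
            call_for([0, 50_000], [0]),                      # E, 1 bound of 2
            call_for([0, 50_000, 100_000], [0, 1]),          # E, 2 bound of 3
            call_for([0, 50_000], [0, 1]),                   # all_bound
            call_for([0, 50_000], []),                       # unbound
        ]
        s = summarize_dataset(calls, "ds")
        assert (s.n_epromoter_clusters, s.n_all_bound_clusters,
                s.n_unbound_clusters) == (2, 1, 1)
        assert s.freq_epromoter == 0.5
        # clusters with >=1 bound: 3; exactly one bound: 1; fewer than n: 2
        assert s.one_bound_share == pytest.approx(1 / 3)
        assert s.fewer_bound_share == pytest.approx(2 / 3)
        grid = bubble_grid(calls)
        assert grid["n_clusters"].sum() == 4
        assert set(zip(grid["n_genes"], grid["n_bound"])) == {
            (2, 1), (3, 2), (2, 2), (2, 0)
        }

    def test_empty_call_list_yields_nan_fractions(self):
        s = summarize_dataset([], "empty")
        assert s.n_clusters == 0 and math.isnan(s.freq_epromoter)

    def test_category_partition_is_enforced(self):
        calls = [call_for([0, 50_000], [0]), call_for([0, 50_000], [])]
        s = summarize_dataset(calls, "ds")
        assert (s.n_epromoter_clusters + s.n_all_bound_clusters
                + s.n_unbound_clusters + s.n_partial_multi_clusters) == s.n_clusters


class TestMergeNonredundant:
    def test_same_cluster_in_two_datasets_merges(self):
        a = call_for([0, 50_000], [0])
        b = call_for([0, 50_000], [0])
        total, table = merge_nonredundant({"hg19": [a, b]})
        assert total == 1 and table.loc[0, "n_source_clusters"] == 2

    def test_shared_gene_links_but_disjoint_does_not(self):
        genes1 = [gene("a", 0), gene("b", 50_000)]
        genes2 = [gene("b", 50_000), gene("c", 99_000)]
        genes3 = [gene("x", 5_000_000), gene("y", 5_050_000)]

        def make(genes):
            (cl,) = cluster_by_distance(genes)
            return classify_cluster(
                cl, {"TF": [peak(genes[0].canonical_tss - 10,
                                 genes[0].canonical_tss + 10)]})

        total, _ = merge_nonredundant({"hg19": [make(genes1), make(genes2),
                                                make(genes3)]})
        assert total == 2

    def test_builds_never_merge_and_order_invariance(self):
        a = call_for([0, 50_000], [0])
        b = call_for([0, 50_000], [0])
        total, _ = merge_nonredundant({"hg19": [a], "mm10": [b]})
        assert total == 2
        t1, _ = merge_nonredundant({"hg19": [a, b]})
        t2, _ = merge_nonredundant({"hg19": [b, a]})
        assert t1 == t2

    def test_only_epromoter_calls_participate(self):
        total, _ = merge_nonredundant({"hg19": [call_for([0, 50_000], [0, 1])]})
        assert total == 0


class TestPeakLocation:
    def test_single_promoter_peak_is_proximal_only(self):
        call = call_for([100_000, 150_000], [0])
        genes = [gene("g0", 100_000), gene("g1", 150_000)]
        profile = peak_location_profile(call, [peak(99_950, 100_050)], genes)
        assert profile.location_class == "proximal_only"
        assert (profile.n_proximal_peaks, profile.n_distal_peaks) == (1, 0)

    def test_promoter_plus_faraway_peak(self):
        call = call_for([100_000, 150_000], [0])
        genes = [gene("g0", 100_000), gene("g1", 150_000)]
        peaks = [peak(99_950, 100_050), peak(125_000, 125_100)]
        profile = peak_location_profile(call, peaks, genes)
        assert profile.location_class == "proximal_and_distal"

    def test_partition_matches_brute_force_window_check(self):
        genes = [gene("g0", 200_000), gene("g1", 260_000), gene("bg", 400_000)]
        call = call_for([200_000, 260_000], [0])
        peaks = [peak(199_900, 200_100), peak(230_000, 230_200),
                 peak(399_500, 399_700), peak(900_000, 900_100)]
        profile = peak_location_profile(call, peaks, genes, pad=100_000)
        # region = [100000, 360001): only the first two peaks fall inside;
        # the first overlaps the g0 window [199000, 201001), the second is
        # >1 kb from every TSS
        assert (profile.n_proximal_peaks, profile.n_distal_peaks) == (1, 1)
        wide = peak_location_profile(call, peaks, genes, pad=150_000)
        # widening the region pulls in the 399500-399700 peak, which overlaps
        # the background gene's window [399000, 401001) and counts proximal
        assert (wide.n_proximal_peaks, wide.n_distal_peaks) == (2, 1)

    def test_distal_only_and_none(self):
        call = call_for([100_000, 150_000], [0])
        genes = [gene("g0", 100_000), gene("g1", 150_000)]
        distal = peak_location_profile(call, [peak(125_000, 125_100)], genes)
        assert distal.location_class == "distal_only"
        empty = peak_location_profile(call, [], genes)
        assert empty.location_class == "none"
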