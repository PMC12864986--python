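"""Nearest-TSS distance statistics: K-S comparison, deviation score, summit."""

from __future__ import annotations

import numpy as np
import pytest

from epromoters import (
    deviation_score,
    distribution_summit,
    fraction_within,
    ks_compare,
    nn_distances,
    random_gene_null,
    simulate_proximity,
)
from epromoters.proximity import DistanceSample, proximity_report, read_induced_table

from conftest import gene


def sample(values, label="s"):
    values = np.asarray(values, dtype=float)
    return DistanceSample(label, values, len(values), 0)


class TestNnDistances:
    def test_three_genes_on_one_chromosome(self):
        genes = [gene("a", 0), gene("b", 60_000), gene("c", 200_000)]
        s = nn_distances(genes)
        assert sorted(s.distances.tolist()) == [60_000, 60_000, 140_000]
        assert s.n_excluded_singletons == 0

    def test_cross_chromosome_pairs_become_singletons(self):
        genes = [gene("a", 100, chrom="chr1"), gene("b", 100, chrom="chr2")]
        s = nn_distances(genes)
        assert len(s) == 0 and s.n_excluded_singletons == 2

    def test_order_invariance(self, toy_genome):
        fwd = nn_distances(toy_genome[:50])
        rev = nn_distances(toy_genome[:50][::-1])
        assert np.array_equal(np.sort(fwd.distances), np.sort(rev.distances))
        assert fwd.n_excluded_singletons == rev.n_excluded_singletons

    def test_fewer_than_two_genes_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            nn_distances([gene("a", 0)])


class TestRandomNull:
    def test_full_universe_returns_the_universe(self, toy_genome):
        drawn = random_gene_null(toy_genome, len(toy_genome), seed=1)
        assert set(g.symbol for g in drawn) == set(g.symbol for g in toy_genome)

    def test_seed_determinism(self, toy_genome):
        a = random_gene_null(toy_genome, 100, seed=1)
        b = random_gene_null(toy_genome, 100, seed=1)
        assert [g.symbol for g in a] == [g.symbol for g in b]

    def test_oversampling_is_an_error(self, toy_genome):
        with pytest.raises(ValueError):
            random_gene_null(toy_genome[:10], 11, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        universe = [gene(f"g{i}", 1000 * i) for i in range(1000)]
        hits = np.zeros(1000)
        n_draws = 2000
        for seed in range(n_draws):
            for g in random_gene_null(universe, 100, seed=seed):
                hits[int(g.symbol[1:])] += 1
        freq = hits / n_draws
        se = np.sqrt(0.1 * 0.9 / n_draws)
        assert np.all(np.abs(freq - 0.1) < 5 * se)


class TestKsCompare:
    def test_identical_samples(self):
        a = sample(np.arange(1, 101))
        stat, p = ks_compare(a, a)
        assert stat == 0.0 and p > 0.99

    def test_disjoint_supports(self):
        stat, _ = ks_compare(sample([0.5, 0.8, 1.0]), sample([2.0, 2.5, 3.0]))
        assert stat == 1.0

    def test_statistic_equals_manual_ecdf_sup(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1_000, 500_000, 200)
        shifted = base.copy()
        shifted[:100] += 40_000
        a, b = sample(base), sample(shifted)
        stat, _ = ks_compare(a, b)
        grid = np.concatenate([base, shifted])
        ecdf_a = np.searchsorted(np.sort(base), grid, side="right") / 200
        ecdf_b = np.searchsorted(np.sort(shifted), grid, side="right") / 200
        assert stat == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ks_compare(sample([]), sample([1.0]))


class TestDeviationScore:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(1)
        a = sample(rng.uniform(1, 1e6, 500))
        assert deviation_score(a, a) == 0.0

    def test_constant_shift_closed_form(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(50_000, 500_000, 400)
        c = 5_000.0
        induced, rand = sample(base - c), sample(base)
        k = 1000
        expected = -k * c / np.sqrt(2)
        got = deviation_score(induced, rand, n_quantiles=k, units="bp")
        assert got == pytest.approx(expected, rel=1e-9)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        a = sample(rng.uniform(1, 1e6, 300))
        b = sample(rng.lognormal(11, 1, 250))
        assert deviation_score(a, b) == pytest.approx(-deviation_score(b, a), abs=0.0)

    def test_mean_variant_is_sum_over_k(self):
        rng = np.random.default_rng(4)
        a = sample(rng.uniform(1, 1e6, 300))
        b = sample(rng.uniform(1, 1e6, 300))
        s = deviation_score(a, b, n_quantiles=200)
        m = deviation_score(a, b, n_quantiles=200, aggregate="mean")
        assert m == pytest.approx(s / 200, rel=1e-12)


class TestSummit:
    def test_degenerate_mode_recovered(self):
        rng = np.random.default_rng(5)
        vals = 50_000 + rng.choice([-1.0, 1.0], size=1000)
        assert distribution_summit(sample(vals)) == pytest.approx(50.0, rel=0.01)

    def test_lognormal_mode_within_ten_percent(self):
        rng = np.random.default_rng(6)
        vals = 10 ** rng.normal(5, 0.1, 5000)
        assert distribution_summit(sample(vals)) == pytest.approx(100.0, rel=0.10)

    def test_scaling_shifts_summit_by_one_decade(self):
        rng = np.random.default_rng(7)
        vals = 10 ** rng.normal(4.5, 0.2, 2000)
        s1 = distribution_summit(sample(vals))
        s10 = distribution_summit(sample(vals * 10))
        assert s10 == pytest.approx(10 * s1, rel=1e-9)

    def test_tiny_sample_is_an_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            distribution_summit(sample([1.0] * 9))


class TestFractionWithin:
    def test_all_below(self):
        assert fraction_within(sample([10_000] * 5)) == 1.0

    def test_threshold_is_inclusive(self):
        s = sample([50_000, 100_000, 150_000])
        assert fraction_within(s, 100_000) == pytest.approx(2 / 3)

    def test_zero_threshold(self):
        assert fraction_within(sample([1.0, 2.0]), 0) == 0.0


class TestSimulatedPower:
    def test_clumped_induced_genes_score_negative_and_ks_rejects(self, toy_genome):
        induced = simulate_proximity(toy_genome, 200, clump_size=3,
                                     clump_spread=50_000, seed=1)
        null = random_gene_null(toy_genome, 200, seed=2)
        d = deviation_score(nn_distances(induced), nn_distances(null))
        _, p = ks_compare(nn_distances(induced), nn_distances(null))
        assert d < 0 and p < 0.01

    def test_uniform_null_is_centred_at_zero(self, toy_genome):
        scores = []
        for seed in range(100):
            a = nn_distances(simulate_proximity(toy_genome, 150, seed=seed))
            b = nn_distances(random_gene_null(toy_genome, 150, seed=seed + 50_000))
            scores.append(deviation_score(a, b))
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * se


def test_proximity_report_fields_consistent(toy_genome):
    induced = simulate_proximity(toy_genome, 100, clump_size=3, seed=9)
    report, qq = proximity_report(induced, toy_genome, seed=9)
    assert 0 <= report.ks_statistic <= 1
    assert 0 <= report.frac_within_threshold_induced <= 1
    assert len(qq) == report.n_quantiles
    assert report.deviation_score == pytest.approx(
        qq["signed_offset_bp"].sum() / 1000
    )


def test_read_induced_table_requires_two_columns(tmp_path):
    p = tmp_path / "induced.tsv"
    p.write_text("symbol\tfold_change\nGENE1\t4.2\n")
    df = read_induced_table(p)
    assert df.loc[0, "symbol"] == "GENE1" and df.loc[0, "fold_change"] == 4.2
    bad = tmp_path / "bad.tsv"
    bad.write_text("symbol\nGENE1\n")
    with pytest.raises(ValueError):
        read_induced_table(bad)
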