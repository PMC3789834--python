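import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifnet import (
    PromoterSet,
    hypergeom_pvalue,
    parse_motif,
    position_zscore,
    score_all,
    score_gene,
    select_seeds,
)

from conftest import make_network
from oracles import exact_hypergeom_upper


class TestHypergeomPvalue:
    def test_worked_example(self):
        # 66/252 by enumerating all C(10,5) draws
        assert hypergeom_pvalue(3, 5, 4, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_pvalue(0, 5, 4, 10) == 1.0

    def test_forced_outcome_is_one(self):
        assert hypergeom_pvalue(5, 5, 10, 10) == 1.0

    @pytest.mark.parametrize(
        "m,M,k,K", [(-1, 5, 4, 10), (6, 5, 4, 10), (3, 5, 2, 10), (3, 11, 4, 10),
                    (3, 5, 11, 10)]
    )
    def test_bound_violations_rejected(self, m, M, k, K):
        with pytest.raises(ValueError):
            hypergeom_pvalue(m, M, k, K)

    @settings(max_examples=200, derandomize=True)
    @given(data=st.data())
    def test_matches_exact_enumeration(self, data):
        K = data.draw(st.integers(1, 40))
        k = data.draw(st.integers(0, K))
        M = data.draw(st.integers(1, K))
        m = data.draw(st.integers(0, min(k, M)))
        assert hypergeom_pvalue(m, M, k, K) == pytest.approx(
            exact_hypergeom_upper(m, M, k, K), abs=1e-12
        )

    def test_monotone_nonincreasing_in_m(self):
        ps = [hypergeom_pvalue(m, 20, 30, 100) for m in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPositionZscore:
    def test_mean_at_null_center_gives_zero(self):
        n, p_bar, z = position_zscore([-500.0] * 7, L=1000, l=6)
        assert (n, p_bar) == (7, -500.0)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_single_tss_proximal_hit_is_sqrt3(self):
        # ((L-l)/2) * sqrt(12)/(L-l) = sqrt(3), independent of L and l
        for L, l in [(1000, 6), (500, 8), (100, 3)]:
            _, _, z = position_zscore([-l / 2], L=L, l=l)
            assert z == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_worked_tss_biased_group(self):
        # nine hits averaging 50 bp upstream: z = 450*3*sqrt(12)/994
        n, p_bar, z = position_zscore([-50.0] * 9, L=1000, l=6)
        assert z == pytest.approx(450 * 3 * math.sqrt(12) / 994, abs=1e-12)
        assert z > 3

    def test_empty_positions_sentinel(self):
        n, p_bar, z = position_zscore([], L=1000, l=6)
        assert n == 0 and math.isnan(p_bar) and math.isnan(z)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            position_zscore([-1001.0], L=1000, l=6)
        with pytest.raises(ValueError):
            position_zscore([1.0], L=1000, l=6)

    def test_motif_not_shorter_than_promoter_rejected(self):
        with pytest.raises(ValueError):
            position_zscore([-5.0], L=10, l=10)

    def test_discrete_null_close_to_continuous_at_scale(self):
        _, _, zc = position_zscore([-100.0] * 4, L=1000, l=6)
        _, _, zd = position_zscore([-100.0] * 4, L=1000, l=6, discrete=True)
        assert zd == pytest.approx(zc, rel=2e-3)
        assert zd != zc

    @settings(max_examples=100, derandomize=True)
    @given(
        positions=st.lists(
            st.floats(min_value=-997.0, max_value=-3.0), min_size=1, max_size=30
        )
    )
    def test_appending_hit_at_null_mean_shrinks_z(self, positions):
        # |z| may grow at most by sqrt((n+1)/n); sign preserved while p_bar
        # stays on the same side of the null mean
        n, p_bar, z = position_zscore(positions, L=1000, l=6)
        n2, p_bar2, z2 = position_zscore(positions + [-500.0], L=1000, l=6)
        assert abs(z2) <= abs(z) * math.sqrt((n + 1) / n) + 1e-9
        if (p_bar + 500) * (p_bar2 + 500) > 0:
            assert z * z2 >= 0


class TestScoreGene:
    def test_star_composes_with_hypergeom(self, star_promoters, star_network):
        # 6-promoter group, motif in 4; pad the genome to K=100, k=20
        records = dict(star_promoters.records)
        for i in range(94):
            if i < 16:
                records[f"F{i}"] = "T" * 100 + "CACGTG" + "T" * 94
            else:
                records[f"F{i}"] = "T" * 200
        promoters = PromoterSet(records=records, nominal_length=200)
        motif = parse_motif("CACGTG")
        stat = score_gene(star_network, promoters, motif, "HUB")
        assert (stat.M, stat.m, stat.k, stat.K) == (6, 4, 20, 100)
        assert stat.pValue == pytest.approx(
            exact_hypergeom_upper(4, 6, 20, 100), abs=1e-12
        )

    def test_group_without_hits(self, star_network):
        promoters = PromoterSet(
            {g: "A" * 200 for g in ["HUB", "N1", "N2", "N3", "N4", "N5"]},
            nominal_length=200,
        )
        stat = score_gene(star_network, promoters, parse_motif("CACGTG"), "HUB")
        assert stat.m == 0 and stat.pValue == 1.0
        assert stat.n == 0 and math.isnan(stat.z)

    def test_gene_without_promoter_still_scored(self, star_promoters, star_network):
        records = dict(star_promoters.records)
        del records["HUB"]
        promoters = PromoterSet(records=records, nominal_length=200)
        stat = score_gene(star_network, promoters, parse_motif("CACGTG"), "HUB")
        assert stat.M == 5  # HUB excluded from the group count

    def test_no_promoters_in_group_is_error(self, star_network):
        promoters = PromoterSet({"OTHER": "A" * 50}, nominal_length=50)
        with pytest.raises(ValueError):
            score_gene(star_network, promoters, parse_motif("CACGTG"), "HUB")

    def test_tss_hits_give_large_z(self, star_promoters, star_network):
        # all hits abut the TSS in 200-bp promoters: strongly biased
        stat = score_gene(star_network, star_promoters, parse_motif("CACGTG"), "HUB")
        assert stat.z > 3


class TestScoreAll:
    def test_row_count_is_genes_times_motifs(self):
        net = make_network(
            [("A", "B", 0.1), ("B", "C", 0.1), ("C", "A", 0.1), ("C", "D", 0.1)]
        )
        promoters = PromoterSet({g: "ACGT" * 25 for g in "ABCD"}, nominal_length=100)
        motifs = [parse_motif("CACGTG"), parse_motif("TTGAC")]
        stats = score_all(net, promoters, motifs, min_degree=2)
        assert len(stats) == 3 * 2  # A, B, C qualify at degree >= 2
        stats0 = score_all(net, promoters, motifs, min_degree=0)
        assert len(stats0) == 4 * 2

    def test_identical_promoters_share_genome_counts(self):
        net = make_network([("A", "B", 0.1), ("B", "C", 0.1)])
        promoters = PromoterSet(
            {g: "T" * 40 + "CACGTG" + "T" * 10 for g in "ABC"}, nominal_length=56
        )
        stats = score_all(net, promoters, [parse_motif("CACGTG")], min_degree=0)
        assert set(stats["k"]) == {3} and set(stats["K"]) == {3}
        # symmetry: A and C have identical topology, hence identical stats
        a = stats[stats.gene == "A"].iloc[0]
        c = stats[stats.gene == "C"].iloc[0]
        assert (a.M, a.m, a.pValue, a.n, a.z) == (c.M, c.m, c.pValue, c.n, c.z)


class TestSelectSeeds:
    def make_stats(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "motif", "pValue", "z", "n"]
        )

    def test_pvalue_cutoff_inclusive(self):
        stats = self.make_stats(
            [("g1", "m", 0.0005, 1.0, 3), ("g2", "m", 0.001, 1.0, 3),
             ("g3", "m", 0.002, 1.0, 3)]
        )
        assert select_seeds(stats, "pvalue", 0.001) == ["g1", "g2"]

    def test_zscore_cutoff_inclusive(self):
        stats = self.make_stats(
            [("g1", "m", 1.0, 3.0, 3), ("g2", "m", 1.0, 2.99, 3)]
        )
        assert select_seeds(stats, "zscore", 3.0) == ["g1"]

    def test_instance_floor_in_intermediate_band(self):
        stats = self.make_stats(
            [("g1", "m", 1.0, 3.5, 2), ("g2", "m", 1.0, 2.5, 6),
             ("g3", "m", 1.0, 2.5, 3)]
        )
        got = select_seeds(stats, "zscore", 2.2, min_instances_rule=(2.2, 3.0, 5))
        assert got == ["g1", "g2"]

    def test_or_semantics_across_motif_variants(self):
        stats = self.make_stats(
            [("g1", "CCWACC", 0.5, 0.0, 1), ("g1", "ACCWACC", 0.005, 0.0, 1),
             ("g2", "CCWACC", 0.5, 0.0, 1), ("g2", "ACCWACC", 0.5, 0.0, 1)]
        )
        assert select_seeds(stats, "pvalue", 0.01) == ["g1"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            select_seeds(self.make_stats([]), "bayes", 0.5)


class TestNullCalibration:
    def test_pvalue_null_fraction_bounded(self):
        # neighborhood enrichment on shuffled-composition promoters should
        # not exceed twice the nominal level at any common cutoff
        from motifnet import SimulationConfig, generate

        pro, net, _ = generate(
            SimulationConfig(n_genes=600, module_sizes=(), p_background=0.008),
            seed=77,
        )
        stats = score_all(net, pro, [parse_motif("CACGTG")], min_degree=5)
        assert len(stats) > 100
        for alpha in (0.05, 0.01, 0.001):
            assert (stats["pValue"] <= alpha).mean() <= 2 * alpha
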