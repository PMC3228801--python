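"""Hotspot annotation: overlaps, enrichment, track densities, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from comphot.annotate import (compare_group_densities, compare_tracks,
                              expression_enrichment, length_stats,
                              overlap_stats, track_density)
from comphot.blindmap import AnalysisUnit
from comphot.detect import CandidateHotspot
from conftest import hypergeom_fisher_oracle


def hotspot(start, end, chrom="chr1", winner="HIV", hid="h_1", strand="+"):
    unit = AnalysisUnit(chrom, "p", strand, 0, max(end, 10_000_000))
    return CandidateHotspot(unit=unit, a=float(start), b=float(end),
                            winner=winner, start=start, end=end, id=hid)


def genes_df(intervals, chrom="chr1", flags=None):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["name"] = [f"g{i}" for i in range(len(df))]
    if flags is not None:
        df["flag"] = flags
    return df


class TestOverlapStats:
    def test_contained_genes_counted_with_density(self):
        h = hotspot(0, 1_000_000)
        genes = genes_df([(i * 10_000, i * 10_000 + 5_000) for i in range(50)])
        out = overlap_stats([h], genes)
        assert out.loc[0, "n_genes"] == 50
        assert out.loc[0, "gene_density"] == pytest.approx(5e-5)

    def test_boundary_straddling_gene_counts_once(self):
        h = hotspot(1000, 2000)
        genes = genes_df([(900, 1100)])
        assert overlap_stats([h], genes).loc[0, "n_genes"] == 1

    def test_strand_agnostic_counting(self):
        # gene on the opposite strand of the hotspot still counts
        h = hotspot(0, 1000, strand="+")
        genes = genes_df([(100, 200)])
        genes["strand"] = "-"
        assert overlap_stats([h], genes).loc[0, "n_genes"] == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 900_000, size=1000)
        genes = genes_df(np.column_stack(
            [starts, starts + rng.integers(1, 50_000, size=1000)]))
        h = hotspot(400_000, 600_000)
        brute = sum(1 for _, g in genes.iterrows()
                    if g["start"] < h.end and g["end"] > h.start)
        assert overlap_stats([h], genes).loc[0, "n_genes"] == brute


class TestExpressionEnrichment:
    def test_equal_frequencies_give_unit_or(self):
        h = hotspot(0, 100_000)
        inside = genes_df([(i * 100, i * 100 + 50) for i in range(40)],
                          flags=["present"] * 30 + ["absent"] * 10)
        outside = genes_df(
            [(200_000 + i * 100, 200_000 + i * 100 + 50) for i in range(4000)],
            flags=["present"] * 3000 + ["absent"] * 1000)
        outside["name"] = [f"o{i}" for i in range(len(outside))]
        out = expression_enrichment([h], pd.concat([inside, outside],
                                                   ignore_index=True))
        assert out.loc[0, "OR"] == pytest.approx(1.0)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_all_present_inside_matches_enumeration(self):
        h = hotspot(0, 100_000)
        inside = genes_df([(i * 100, i * 100 + 50) for i in range(40)],
                          flags=["present"] * 40)
        outside = genes_df(
            [(200_000 + i * 100, 200_000 + i * 100 + 50) for i in range(1000)],
            flags=["present"] * 500 + ["absent"] * 500)
        out = expression_enrichment([h], pd.concat([inside, outside],
                                                   ignore_index=True))
        assert np.isinf(out.loc[0, "OR"])
        assert out.loc[0, "p_raw"] == pytest.approx(
            hypergeom_fisher_oracle([[40, 0], [500, 500]]), rel=1e-9)

    def test_geneless_hotspot_reported_na_excluded_from_family(self):
        h1 = hotspot(0, 100_000, hid="h_1")
        h2 = hotspot(5_000_000, 5_100_000, hid="h_2")
        genes = genes_df([(1000, 2000)], flags=["present"])
        genes = pd.concat([genes, genes_df([(200_000 + i, 200_000 + i + 10)
                                            for i in range(0, 1000, 10)],
                                           flags=["present"] * 50
                                           + ["absent"] * 50)],
                          ignore_index=True)
        out = expression_enrichment([h1, h2], genes).set_index("id")
        assert np.isnan(out.loc["h_2", "p_raw"])
        assert np.isnan(out.loc["h_2", "p_adj"])
        # family size 1: adjusted equals raw for the gene-bearing hotspot
        assert out.loc["h_1", "p_adj"] == pytest.approx(out.loc["h_1", "p_raw"])

    def test_uniform_flags_rarely_flagged(self):
        """Under uniform expression flags, <= 5% of hotspots reach raw
        p <= 0.05 (Fisher is conservative on discrete tables)."""
        rng = np.random.default_rng(12)
        hotspots = [hotspot(i * 20_000, i * 20_000 + 10_000, hid=f"h_{i}")
                    for i in range(300)]
        starts = np.sort(rng.integers(0, 8_000_000, size=6000))
        genes = genes_df(np.column_stack([starts, starts + 500]),
                         flags=rng.choice(["present", "absent"], size=6000))
        out = expression_enrichment(hotspots, genes)
        rate = (out["p_raw"] <= 0.05).mean()
        assert rate <= 0.05


class TestTrackDensity:
    def test_density_magnitude(self):
        h = hotspot(0, 150_000)
        reads = pd.DataFrame({"chrom": "chr1",
                              "pos": np.linspace(0, 149_999, 300, dtype=int)})
        assert track_density(h, reads) == pytest.approx(0.002)

    def test_zero_and_shifted_reads(self):
        h = hotspot(0, 150_000)
        empty = pd.DataFrame({"chrom": [], "pos": []})
        assert track_density(h, empty) == 0.0
        outside = pd.DataFrame({"chrom": "chr1", "pos": [200_000, 300_000]})
        assert track_density(h, outside) == 0.0


class TestCompareGroupDensities:
    def test_exhaustive_mannwhitney_example(self):
        cmp = compare_group_densities([1, 2, 3], [4, 5, 6],
                                      statistic="mannwhitney", n_perm=1000)
        assert cmp.p_perm == pytest.approx(2 / 20)

    def test_identical_groups_p_one(self):
        cmp = compare_group_densities([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                      statistic="mannwhitney", n_perm=1000)
        assert cmp.p_perm == pytest.approx(1.0)

    def test_size_one_group_falls_back_to_mannwhitney(self, caplog):
        with caplog.at_level("WARNING", logger="comphot.annotate"):
            cmp = compare_group_densities([1.0], [2.0, 3.0, 4.0],
                                          statistic="welch", n_perm=1000)
        assert cmp.statistic == "mannwhitney"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_matches_exact_mannwhitney(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        cmp = compare_group_densities(a, b, statistic="mannwhitney",
                                      n_perm=1000)
        exact = mannwhitneyu(a, b, alternative="two-sided",
                             method="exact").pvalue
        assert cmp.p_perm == pytest.approx(exact, rel=1e-9)

    def test_monte_carlo_p_has_addone_resolution(self):
        rng = np.random.default_rng(3)
        a = rng.normal(3.0, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        cmp = compare_group_densities(a, b, statistic="welch", n_perm=1999,
                                      seed=0)
        assert cmp.p_perm == pytest.approx(1 / 2000)

    def test_shifted_normals_significant_after_holm(self):
        """One track shifted by 2 sigma among ten null tracks is detected
        (adjusted p < 0.01) in nearly every replicate."""
        wins = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            tracks = {f"t{i}": (rng.normal(0, 1, 40), rng.normal(0, 1, 40))
                      for i in range(9)}
            tracks["shifted"] = (rng.normal(2, 1, 40), rng.normal(0, 1, 40))
            out = compare_tracks(tracks, statistic="welch", n_perm=1999,
                                 seed=rep).set_index("track")
            wins += out.loc["shifted", "p_adj"] < 0.01
        assert wins / reps >= 0.95

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            compare_group_densities([1, 2], [3, 4], n_perm=10)


class TestLengthStats:
    def test_medians(self):
        hs = [hotspot(0, l, winner="HIV", hid=f"a{l}") for l in (2, 4, 6)] + \
             [hotspot(0, l, winner="MLV", hid=f"b{l}") for l in (1, 3, 5)]
        out = length_stats(hs, n_perm=1000)
        assert out["per_winner"]["HIV"]["median"] == 4
        assert out["per_winner"]["MLV"]["median"] == 3
        assert 0 <= out["p_perm"] <= 1

    def test_even_group_median_is_middle_pair_mean(self):
        hs = [hotspot(0, l, winner="HIV", hid=f"a{l}") for l in (2, 4, 6, 10)]
        out = length_stats(hs)
        assert out["per_winner"]["HIV"]["median"] == 5.0

    def test_single_group_p_na(self):
        hs = [hotspot(0, 5, winner="HIV")]
        out = length_stats(hs)
        assert np.isnan(out["p_perm"])
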