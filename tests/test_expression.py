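import numpy as np
import pandas as pd
import pytest

from zwscan.expression import (assign_regions, de_direction_shares,
                               estimate_chrom_sizes, flag_de, pearson_r,
                               round_half_up, summarize_region, truncate_pct)
from zwscan.regions import RegionCall


def gene_frame(n, n_expressed, n_de, region="PWR", chrom="chr13"):
    """n genes; the first n_expressed have count > 1; the first n_de of those
    are differentially expressed (padj 1e-4, LFC +2)."""
    rows = []
    for i in range(n):
        expressed = i < n_expressed
        de = i < n_de
        rows.append({
            "gene_id": f"g{i}", "chrom": chrom, "start": i * 100,
            "end": i * 100 + 50, "mean_count": 5.0 if expressed else 0.5,
            "lfc": 2.0 if de else 0.1, "padj": 1e-4 if de else 0.9,
            "region": region,
        })
    return pd.DataFrame(rows)


class TestFlagDE:
    @pytest.mark.parametrize("lfc,padj,expected", [
        (3.80, 1.40e-6, (True, True, False)),   # male-upregulated candidate
        (-1.67, 6.88e-1, (False, False, False)),  # high padj: not DE
        (0.5, 0.001, (True, False, False)),     # DE but below the LFC gates
        (-2.0, 0.01, (True, False, True)),      # boundary padj counts as DE
        (1.0, 0.009, (True, True, False)),      # boundary LFC counts as up
        (2.0, None, (False, False, False)),     # missing padj is never DE
    ])
    def test_threshold_rules(self, lfc, padj, expected):
        assert flag_de(lfc, padj) == expected

    def test_up_flags_partition_within_de(self):
        rng = np.random.default_rng(0)
        n_de = ups = 0
        for _ in range(500):
            lfc = rng.normal(0, 2)
            padj = rng.random()
            de, um, uf = flag_de(lfc, padj)
            assert not (um and uf)
            n_de += de
            ups += um + uf
        assert ups <= n_de


class TestAssignRegions:
    CALLS = [RegionCall("chr13", 0, 3000, "PWR", 0, 0.0),
             RegionCall("chr13", 3000, 20_000, "CHR", 0, 0.0),
             RegionCall("chr13", 20_000, 44_000, "PAR", 0, 0.0)]

    def test_midpoint_rule(self):
        genes = pd.DataFrame([
            {"gene_id": "a", "chrom": "chr13", "start": 1000, "end": 2000,
             "mean_count": 2.0, "lfc": 0.0, "padj": 1.0},
            # straddles the 3000 boundary, midpoint 2900 -> left region
            {"gene_id": "b", "chrom": "chr13", "start": 2500, "end": 3300,
             "mean_count": 2.0, "lfc": 0.0, "padj": 1.0},
            {"gene_id": "c", "chrom": "chr99", "start": 0, "end": 100,
             "mean_count": 2.0, "lfc": 0.0, "padj": 1.0},
        ])
        out = assign_regions(genes, self.CALLS)
        assert list(out["region"])[:2] == ["PWR", "PWR"]
        assert out["region"].iloc[2] is None

    def test_every_gene_on_called_chromosome_gets_one_label(self):
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 43_000, size=200)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)], "chrom": "chr13",
            "start": starts, "end": starts + rng.integers(1, 900, size=200),
            "mean_count": 2.0, "lfc": 0.0, "padj": 1.0,
        })
        out = assign_regions(genes, self.CALLS)
        assert out["region"].notna().all()
        assert set(out["region"]).issubset({"PWR", "CHR", "PAR"})

    def test_overlapping_calls_rejected(self):
        bad = [RegionCall("chr13", 0, 3000, "PWR", 0, 0.0),
               RegionCall("chr13", 2000, 5000, "CHR", 0, 0.0)]
        with pytest.raises(ValueError, match="overlap"):
            assign_regions(gene_frame(3, 3, 0), bad)


class TestSummarizeRegion:
    def test_counts_and_percentages(self):
        s = summarize_region(gene_frame(75, 50, 12))
        assert (s.n_genes, s.n_expressed, s.n_de) == (75, 50, 12)
        assert s.pct_expressed == 66.67
        assert s.pct_de_of_expressed == 24.00

    def test_no_expressed_genes_percentage_missing(self):
        s = summarize_region(gene_frame(10, 0, 0))
        assert s.pct_expressed == 0.0
        assert s.pct_de_of_expressed is None

    def test_de_counted_among_expressed_only(self):
        df = gene_frame(10, 5, 0)
        # one DE gene that is NOT expressed must not enter n_de
        df.loc[9, ["padj", "lfc"]] = [1e-5, 3.0]
        s = summarize_region(df)
        assert s.n_de == 0
        assert s.n_up_male == 1  # direction flags count over all genes

    def test_mixed_regions_rejected(self):
        df = pd.concat([gene_frame(2, 2, 0, region="PWR"),
                        gene_frame(2, 2, 0, region="PAR")])
        with pytest.raises(ValueError, match="multiple"):
            summarize_region(df)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(66.6667, 66.67), (12.2172, 12.22),
                                            (0.125, 0.13), (1.0655, 1.07)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    @pytest.mark.parametrize("x,expected", [(42.6672, 42.66), (57.3328, 57.33)])
    def test_truncation(self, x, expected):
        assert truncate_pct(x) == expected

    def test_direction_shares_never_exceed_hundred(self):
        m, f = de_direction_shares(2557, 1091, 1466)
        assert (m, f) == (42.66, 57.33)
        assert m + f <= 100.0


class TestKaryotype:
    def test_single_chromosome_share(self):
        df = pd.DataFrame({"chrom": ["c1", "c2"], "mean_um": [2.0, 18.0]})
        est = estimate_chrom_sizes(df, 100)
        assert est["c1"] == pytest.approx(10.0)

    def test_equal_measurements_split_evenly(self):
        df = pd.DataFrame({"chrom": [f"c{i}" for i in range(4)],
                           "mean_um": [3.0] * 4})
        est = estimate_chrom_sizes(df, 4_000_000_000)
        assert est.to_numpy() == pytest.approx(1_000_000_000)

    def test_estimates_conserve_genome_size(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"chrom": [f"c{i}" for i in range(27)],
                           "mean_um": rng.uniform(0.5, 6.0, 27)})
        est = estimate_chrom_sizes(df, 1_282_030_339)
        assert est.sum() == pytest.approx(1_282_030_339)

    def test_nonpositive_inputs_rejected(self):
        df = pd.DataFrame({"chrom": ["c1"], "mean_um": [1.0]})
        with pytest.raises(ValueError):
            estimate_chrom_sizes(df, 0)


class TestPearson:
    def test_perfect_linearity(self):
        x = [1, 2, 3, 4, 5]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([3.0, 3.5, 6.0, 6.5, 10.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
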