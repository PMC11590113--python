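import numpy as np
import pytest

from zwscan.simulate import (SimLayout, build_layout, demo_layout, segment,
                             simulate_gene_table, simulate_linkage_table,
                             simulate_pool_counts)
from zwscan.sites import SiteClass, classify_site, site_alleles


class TestLayout:
    def test_single_segment_identity(self):
        layout = build_layout({"segments": [{"label": "PAR", "length_bp": 100_000}],
                               "baseline_depth": 25})
        assert layout.total_length == 100_000
        assert layout.baseline_depth == 25

    def test_demo_layout_proportions(self):
        layout = demo_layout()
        truth = layout.region_truth()
        spans = {label: e - s for _, s, e, label in truth}
        # PWR:CHR:PAR = 3:17:24, the 1:1000 scale-down of the 44-Mb chromosome
        assert spans == {"PWR": 3000, "CHR": 17_000, "PAR": 24_000}
        pwr = layout.segments[0]
        assert (pwr.cov_mult_female, pwr.cov_mult_male) == (2.3, 0.6)

    @pytest.mark.parametrize("bad", [
        {"segments": [{"label": "PAR", "length_bp": 0}]},
        {"segments": [{"label": "PAR", "length_bp": 10, "divergence_per_bp": 1.5}]},
        {"segments": [{"length_bp": 10}]},
        {"segments": []},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_layout(bad)

    def test_region_truth_tiles_chromosome(self):
        layout = demo_layout()
        truth = layout.region_truth()
        assert truth[0][1] == 0
        assert truth[-1][2] == layout.total_length
        for a, b in zip(truth, truth[1:]):
            assert a[2] == b[1]

    def test_yaml_round_trip_identity(self, tmp_path):
        layout = demo_layout(seed=3)
        p = tmp_path / "layout.yaml"
        layout.to_yaml(p)
        assert SimLayout.from_yaml(p) == layout


class TestPoolCounts:
    def test_fixed_seed_reproduces_byte_identical_output(self):
        layout = demo_layout(seed=5)
        a, ta = simulate_pool_counts(layout)
        b, tb = simulate_pool_counts(layout)
        assert a == b
        assert ta.regions == tb.regions
        assert ta.sites.equals(tb.sites)

    def test_no_signal_layout_is_monomorphic_and_identical(self):
        layout = SimLayout(chrom_name="c", segments=(segment("PAR", 2000),),
                           baseline_depth=20.0, error_rate=0.0, seed=1)
        records, truth = simulate_pool_counts(layout)
        assert not truth.sites["is_divergent"].any()
        for rec in records:
            a = site_alleles(rec)
            assert (a.p_male or 0.0) == 0.0 and (a.p_female or 0.0) == 0.0
            assert classify_site(a) is SiteClass.UNINFORMATIVE

    def test_par_depth_converges_to_baseline(self):
        layout = SimLayout(chrom_name="c", segments=(segment("PAR", 50_000),),
                           baseline_depth=25.0, error_rate=0.0, seed=2)
        records, _ = simulate_pool_counts(layout)
        mean_m = np.mean([r.depth_male for r in records])
        assert abs(mean_m - 25.0) / 25.0 < 0.01  # within 1% at 50k sites

    def test_segment_depths_match_multipliers_within_3se(self, demo_sim):
        layout, records, _ = demo_sim
        depth_m = np.array([r.depth_male for r in records])
        depth_f = np.array([r.depth_female for r in records])
        pos = 0
        for seg in layout.segments:
            if seg.length_bp < 1000:
                continue
            sl = slice(pos, pos + seg.length_bp)
            for arr, mult in ((depth_m, seg.cov_mult_male),
                              (depth_f, seg.cov_mult_female)):
                mean = arr[sl].mean()
                expect = layout.baseline_depth * mult
                se = np.sqrt(max(expect, 1e-9) / seg.length_bp)
                assert abs(mean - expect) <= 3 * se + 1e-9
            pos += seg.length_bp

    def test_divergent_sites_have_half_frequency_in_females(self):
        layout = SimLayout(
            chrom_name="c",
            segments=(segment("ZW_DIVERGENT", 100_000, divergence_per_bp=0.01),),
            baseline_depth=30.0, error_rate=0.0, seed=6)
        records, truth = simulate_pool_counts(layout)
        div = truth.divergent_positions()
        # ~1,000 divergent sites at 0.01/bp over 100 kb (binomial 99% bounds)
        assert 900 <= len(div) <= 1100
        div_set = set(div)
        freqs = []
        for rec in records:
            if rec.pos in div_set and rec.depth_female > 0:
                a = site_alleles(rec)
                assert a.p_male == 0.0
                freqs.append(a.p_female)
        mean_f = np.mean(freqs)
        # mean of ~1000 binomial(depth~30, 0.5) frequencies
        assert abs(mean_f - 0.5) < 0.01

    def test_zero_coverage_positions_emitted(self):
        layout = SimLayout(
            chrom_name="c",
            segments=(segment("Z_ONLY", 300, cov_mult_female=0.0),),
            baseline_depth=10.0, error_rate=0.0, seed=3)
        records, _ = simulate_pool_counts(layout)
        assert len(records) == 300
        assert all(r.depth_female == 0 for r in records)


class TestLinkageTable:
    def test_row_count_conservation(self):
        df = simulate_linkage_table(n_lg=28, markers_per_lg=400, seed=0)
        assert len(df) == 11_200
        assert df["cm_female"].notna().all() and df["cm_male"].notna().all()

    def test_monotone_cm_along_bp(self):
        df = simulate_linkage_table(n_lg=4, markers_per_lg=100,
                                    suppression_span=0.3, sexlinked_lg="LG2", seed=1)
        for _, g in df.groupby("lg"):
            g = g.sort_values("pos_bp")
            assert (np.diff(g["cm_female"]) >= -1e-9).all()
            assert (np.diff(g["cm_male"]) >= -1e-9).all()

    def test_suppression_zero_no_forced_plateau(self):
        df = simulate_linkage_table(n_lg=2, markers_per_lg=200, seed=2,
                                    sexlinked_lg="LG1", suppression_span=0.0)
        lg = df[df["lg"] == "LG1"].sort_values("pos_bp")
        # no long run of identical female cM values
        runs = (lg["cm_female"].diff() == 0).rolling(10).sum().fillna(0)
        assert runs.max() < 10

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            simulate_linkage_table(suppression_span=1.5)


REGION_TRUTH = [("chr13", 0, 3000, "PWR"), ("chr13", 3000, 20_000, "CHR"),
                ("chr13", 20_000, 44_000, "PAR")]


class TestGeneTable:
    def test_no_de_means_all_padj_above_threshold(self):
        df = simulate_gene_table(REGION_TRUTH, {"PWR": 30, "CHR": 30, "PAR": 30},
                                 frac_expressed=1.0, frac_de_given_expressed=0.0,
                                 seed=0)
        assert (df["padj"] > 0.01).all()
        assert (df["mean_count"] > 1).all()

    def test_all_de_up_male_when_fraction_one(self):
        df = simulate_gene_table(REGION_TRUTH, {"PWR": 50}, frac_expressed=1.0,
                                 frac_de_given_expressed=1.0,
                                 frac_up_male_given_de=1.0, seed=1)
        assert (df["padj"] <= 0.01).all()
        assert (df["lfc"] >= 1.0).all()

    def test_genes_lie_inside_truth_regions(self):
        df = simulate_gene_table(REGION_TRUTH, {"PWR": 40, "CHR": 40, "PAR": 40},
                                 seed=3)
        bounds = {label: (s, e) for _, s, e, label in REGION_TRUTH}
        for row in df.itertuples(index=False):
            lo, hi = bounds[row.gene_id.split("_")[0]]
            assert lo <= row.start < row.end <= hi

    def test_exact_mode_realizes_fractions_to_the_gene(self):
        df = simulate_gene_table(REGION_TRUTH, {"PWR": 75},
                                 frac_expressed=50 / 75,
                                 frac_de_given_expressed=12 / 50,
                                 seed=4, exact=True)
        assert (df["mean_count"] > 1).sum() == 50
        assert ((df["padj"] <= 0.01) & (df["mean_count"] > 1)).sum() == 12

    def test_observed_fractions_within_binomial_bounds(self):
        from scipy import stats
        n = 400
        df = simulate_gene_table([("c", 0, 100_000, "PAR")], {"PAR": n},
                                 frac_expressed=0.8, seed=5)
        k = int((df["mean_count"] > 1).sum())
        lo, hi = stats.binom.interval(0.99, n, 0.8)
        assert lo <= k <= hi

    def test_negative_gene_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_table(REGION_TRUTH, {"PWR": -1}, seed=0)
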