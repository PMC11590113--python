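# zwscan

Pooled-sequencing sex-signal scan and ZW sex-chromosome region segmentation.

`zwscan` is for researchers characterizing a heteromorphic ZW (or, by
symmetry of its statistics, XY) sex chromosome from **pool-seq** data: one
sequencing pool of ZZ males and one of ZW females mapped to a single,
unphased reference. Starting from per-position nucleotide counts
(popoolation2 `sync` format), it computes per-site pooled F_ST, sex-specific
SNP calls and coverage, aggregates them in sliding windows (50 kb every
1 kb by default), and segments each chromosome into:

* **PWR** — putative W-specific region: male depth ≈ 0, elevated female depth;
* **CHR** — chimeric Z/W region under degeneration: alternating male-doubled
  coverage and dense female-specific SNPs (W alleles at ~0.5 frequency in
  the female pool);
* **PAR** — pseudoautosomal region: depth ratio ≈ 1, no sex-specific SNPs.

Companion modules summarize sex-specific linkage maps (heterochiasmy ratios,
zero-recombination clusters on the Marey map), region-wise gene-expression
tables, and karyotype-based chromosome-size validation. A built-in simulator
generates ZW pool-seq data with known truth so the whole pipeline is
testable without external data.

## The statistic at the core

At each site the counts are reduced to a pooled major/minor allele pair with
per-pool minor frequencies p_M, p_F at read depths n_M, n_F, and a
Hudson-type two-population F_ST with finite-depth correction is formed:

    F_ST = [ (p_M − p_F)² − p_M(1−p_M)/(n_M−1) − p_F(1−p_F)/(n_F−1) ]
           / [ p_M(1−p_F) + p_F(1−p_M) ]

Window F_ST is the ratio of sums (Σ numerators / Σ denominators) clamped to
[0, 1]. A site is called **female-specific** when p_F ∈ [0.4, 0.6] while the
male pool is monomorphic (p_M ≤ 0.05) at depth ≥ 10 in both pools — the
expected footprint of a W-restricted allele. See `docs/methods.md` for the
full model, thresholds and segmentation rules.

## Worked example

Simulate the demo chromosome — a 1:1000 scale-down of a 44-Mb ZW
chromosome (PWR 0–3 kb, CHR 3–20 kb, PAR 20–44 kb, pools at ~25×) — then
scan and segment it:

```sh
zwscan run-all --out demo --seed 1
cat demo.regions.bed
```

```
chrSim13	0	2050	PWR	0
chrSim13	2050	19350	CHR	261
chrSim13	19350	44000	PAR	8
```

Each BED line is a called region with its label and the mean window F_ST
scaled to [0, 1000]. The calls recover the simulated truth (0/3000/20000/
44000) to within one window: the boundaries sit ~1 kb early because windows
are anchored at their start coordinate. The CHR score 261 reflects the high
allele-frequency differentiation of the chimeric Z/W region (mean window
F_ST ≈ 0.26 at this scale), while the pseudoautosomal region sits at ≈ 0.
`demo.windows.tsv` holds the underlying per-window tracks (depths, relative
depths, M/F depth ratio, F_ST, sex-specific SNP counts) and
`demo.truth.bed` the simulated truth.

The stages are also available separately — `zwscan simulate`, `scan`,
`call-regions`, `linkage`, `summarize-expression`, `karyo` — and as library
functions (`zwscan.scan_sync`, `zwscan.call_regions`, ...). For example,
summarizing a linkage-marker table reports per-LG map lengths, the
genome-wide male/female length ratio and zero-recombination clusters;
summarizing a gene table against a regions BED reports per-region expressed
and differentially expressed percentages.

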