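# Methods

## Problem setting

In a ZW system females are the heterogametic sex (ZW) and males are ZZ.
When male and female DNA pools are sequenced and mapped to a single
(unphased) reference, the three characteristic region types of a
degenerating sex chromosome leave distinct, complementary footprints:

| region | coverage | sex-specific SNPs | F_ST |
|---|---|---|---|
| W-specific (PWR) | male depth ≈ 0; female depth elevated | few (reference is W) | can peak |
| chimeric Z/W (CHR) | alternating male-doubled and balanced | dense female-specific SNPs at ~0.5 frequency | elevated |
| pseudoautosomal (PAR) | ratio ≈ 1 | none | ≈ 0 |

The female pool carries one Z and one W per individual, so a W-restricted
allele at a site where W-derived reads still map is expected at frequency
0.5 in the female pool and 0 in the male pool. Where the W homolog has
diverged beyond mapping, females retain a single mapping (Z) copy and the
male/female depth ratio tends to 2. Where the reference itself is W-derived,
males lose coverage entirely. The pipeline turns these signatures into an
explicit, reproducible segmentation.

## Per-site statistics

Each sync position is reduced to a biallelic major/minor pair chosen from
the pooled (male + female) counts over A, C, G, T; ties resolve in fixed
base order A < C < G < T. N and deletion counts never enter depths. The
per-pool minor-allele frequencies p_M, p_F with read depths n_M, n_F feed a
Hudson-type two-population F_ST with a finite-depth correction:

    num = (p_M − p_F)² − p_M(1−p_M)/(n_M−1) − p_F(1−p_F)/(n_F−1)
    den = p_M(1−p_F) + p_F(1−p_M)

Read depths stand in for sample sizes, which is the natural choice for
pool-seq where individual genotypes are unobservable. Sites with depth < 2
in either pool contribute nothing; negative site values are retained
(clamping only happens at window level) so the window ratio-of-sums stays
unbiased.

Site classification (FEMALE_SPECIFIC / MALE_SPECIFIC / FIXED_DIFF /
SHARED_POLY / UNINFORMATIVE) uses three thresholds: heterozygous band
half-width h = 0.1 around 0.5, monomorphy tolerance f = 0.05, and a minimum
per-pool depth d = 10. FEMALE_SPECIFIC requires p_F ∈ [0.5−h, 0.5+h] with
the male pool monomorphic (p_M ≤ f); MALE_SPECIFIC is symmetric. h = 0.1 at
~25× depth accepts roughly two thirds of true W alleles per site while the
0.002 error rate essentially never promotes a monomorphic site into the
band, so the classifier is conservative per site and relies on density at
window scale.

## Window scan

Windows of 50 kb advanced every 1 kb (the full-scale convention; window and
step are configurable and scale together), anchored and reported at their
start coordinate. Window F_ST is the ratio of sums Σnum/Σden clamped to
[0, 1]; mean depths divide by the full window span so missing or zero-depth
positions dilute the mean rather than vanish. Relative depths divide by the
genome-wide pool means (computed over all parsed positions before
windowing); the depth ratio is absolute male mean over absolute female mean,
capped at 10 when the female mean is zero and undefined when both are.

## Region calling

Windows map to evidence states with precedence
LOW_COV > W_LIKE > W_DIVERGENT > Z_ELEVATED > BALANCED:

* W_LIKE: depth ratio ≤ 0.3 **and** relative female depth ≥ 1.5 — the
  observed W-region signature is elevated female coverage (≈2.3×), not
  merely absent male coverage.
* W_DIVERGENT: female-specific SNPs ≥ max(floor, 10 × genome median per
  window). The cutoff is data-adaptive because the absolute count scales
  with depth and window size; the floor is 25 for full-scale 50-kb windows
  and should be scaled with the window span (the bundled demo scale uses 10
  per 1-kb window, still far above its ~0 background).
* Z_ELEVATED: depth ratio ≥ 1.5 (males carry two mapping Z copies).
* LOW_COV: both relative depths < 0.25.
* BALANCED otherwise.

A majority filter (default width 51 windows; 11 at demo scale) suppresses
single-window noise; ties keep the original state. States then collapse to
region labels (W_LIKE → PWR; Z_ELEVATED and W_DIVERGENT → CHR, so the
alternating chimeric blocks form one region; BALANCED → PAR; LOW_COV →
UNCLASSIFIED) and maximal runs become regions. Runs spanning less than
min_region_span (2 × window) are absorbed into the longer flanking region,
smallest run first — dissolving thin transitional slivers before any larger
boundary decision — and adjacent same-label regions merge. Boundaries sit at
the midpoint between the last window start of one run and the first of the
next; output regions always tile the chromosome. An HMM was deliberately
avoided: every call is auditable against the thresholds that produced it.

Because windows are anchored at their start, called boundaries sit
systematically about half a window early; at demo scale this bias is
~500–950 bp, well inside the ±2 kb recovery tolerance the tests check.

## Simulator

The generator reproduces the observable signatures, not the assembly
mechanics that caused them. Segment types and default multipliers
(female, male): W_SPECIFIC (2.3, 0.6); Z_ONLY (0.5, 1.0); ZW_DIVERGENT
(1.0, 1.0) with divergence 0.05/bp; PAR (1.0, 1.0). The elevated female
multiplier in W_SPECIFIC mirrors the observed 2.3× signature (repeat-collapsed
W consensus attracting reads) rather than the naive hemizygous 0.5× — the
multiplier states the observation without asserting a mechanism. Depths are
Poisson(baseline × multiplier); base counts are multinomial from the pooled
allele frequency (exactly 0.5 for the W allele in females at divergent
mapped sites, 0 in males) with a symmetric error rate (default 0.002) spread
uniformly over the three other bases. Individual-level resampling across
pool members is not modeled: counts are drawn from the pooled expectation,
which is precisely what the downstream estimator can observe. Pool sizes
(default 20 + 20) are retained for bookkeeping. One seed drives everything,
so a fixed layout reproduces byte-identical output.

The default demo layout is a 1:1000 scale-down of a 44-Mb ZW chromosome:
W_SPECIFIC 0–3 kb, then 8 alternating Z_ONLY / ZW_DIVERGENT blocks of
2,125 bp to 20 kb, then PAR to 44 kb, at baseline depth 25. The matching
scan uses window 1,000 bp / step 100 bp (the same 50:1 proportion as the
full-scale 50 kb / 1 kb scan), smoothing width 11 and min_region_span
2 kb, so the whole simulate–scan–segment round trip runs in a few seconds.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: mapping artifacts and repeat-driven coverage
structure, GC or library bias, base-quality variation, indels, linked-read
correlation along fragments, and residual Z polymorphism within pools
(simulated males are strictly monomorphic). The recovery results on
simulation validate the statistical machinery, not robustness to alignment
pathology.

The linkage-map generator lays markers at sorted uniform bp positions and
builds monotone per-sex cM maps from exponential gaps rescaled to target
lengths (defaults echo a dense 28-LG fish map near 3,500/3,300 cM
male/female; the sex-linked LG defaults to the heterochiasmic 87.81/47.37 cM
pair). A suppression span s centers a plateau of identical female cM over a
fraction s of the LG's physical length. The gene-table generator emits mean
counts, LFC and padj realizing configured expressed/DE fractions per region;
`exact=True` forces realized counts to round(fraction × n) so published
percentages reproduce to the digit.

## Linkage and expression summaries

Map length per sex is the cM range (max − min) — identical to summed
adjacent gaps for monotone maps but robust to unsorted input. The
genome-wide heterochiasmy ratio is Σ male lengths / Σ female lengths.
Zero-recombination clusters are maximal bp-consecutive runs with identical
cM (tolerance 1e−6 cM), at least 5 markers and 100 kb span by default; the
size minima are this package's choice since such clusters are usually shown
graphically without numeric criteria.

Expression summaries take the upstream DE table as input: expressed means
mean count > 1; DE means padj ≤ 0.01; direction flags additionally require
|LFC| ≥ 1 (male-positive). The %DE denominator is the expressed-gene count.
Genes are assigned to the region containing their midpoint. Percentages in
region summaries round half-up at 2 decimals at presentation only; the
male/female direction shares of the DE total truncate at 2 decimals so the
two shares can never sum above 100.

Karyotype validation rescales mean measured chromosome sizes (µm) by
share of total karyotype length: estimate_i = µm_i × genome_bp / Σµm —
estimates conserve the genome total by construction — and Pearson-correlates
them with assembled sizes.

## Numerical and degenerate-input choices

Zero-depth pools yield undefined frequencies and UNINFORMATIVE sites;
monomorphic sites have undefined F_ST (denominator 0) and contribute nothing
to windows; a window with no informative site reports F_ST 0. Empty inputs
produce header-only tables. All coordinates are 0-based half-open internally
and in BED; sync and marker tables are 1-based at the I/O boundary only.
All randomness flows from explicit seeds; reruns are byte-identical.

## Known limitations

Only biallelic reduction (no multi-allelic or indel handling beyond the
sync `del` column); no genotype-likelihood model; no GC/mappability
correction of depth; the caller assumes one contiguous block per region
type at demo scale but permits disjoint CHR pieces in general; quality
filtering is assumed done upstream of the sync file.
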