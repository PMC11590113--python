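"""Synthetic ZW pool-seq data with known truth.

The generator emulates two sequencing pools — ZZ males and ZW females —
mapped to a single reference chromosome composed of segments:

* ``W_SPECIFIC``   — reference is W-derived sequence; males nearly absent.
                     Default coverage multipliers follow the observed
                     W-region signature: 2.3x the female average depth and
                     0.6x the male average (repeat collapse onto the W
                     consensus inflates female coverage; the multiplier models
                     the signature directly rather than the mechanism).
* ``ZW_DIVERGENT`` — Z/W consensus where W-derived reads still map; at a
                     configurable density of fixed Z-W differences the female
                     pool shows the W allele at expected frequency 0.5
                     (one Z + one W per female), males are monomorphic.
* ``Z_ONLY``       — Z sequence whose W homolog no longer maps: females keep
                     one mapping copy (0.5x) while males keep two (1.0x),
                     giving the male-doubled depth ratio.
* ``PAR``          — pseudoautosomal: both sexes at baseline, no divergence.

Counts are drawn per position: depth ~ Poisson(baseline x multiplier), base
composition multinomial from the pool allele frequency with a symmetric
sequencing error spread uniformly over the three other bases.  Individual
resampling across pool members is not modeled — counts come from the pooled
expected frequency, which is exactly what a pool-seq estimator can see; pool
sizes are kept for bookkeeping.  All randomness flows from one seed, so a
fixed layout reproduces byte-identical output.

The module also generates linkage-marker tables with an injected
zero-recombination plateau in the female map of a sex-linked linkage group,
and gene tables realizing configured expressed / differentially-expressed
fractions per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import PoolSiteCount

SEGMENT_LABELS = ("W_SPECIFIC", "ZW_DIVERGENT", "Z_ONLY", "PAR")

#: per-label defaults: (cov_mult_female, cov_mult_male, divergence_per_bp, w_maps)
_SEGMENT_DEFAULTS = {
    "W_SPECIFIC": (2.3, 0.6, 0.0, True),
    "ZW_DIVERGENT": (1.0, 1.0, 0.05, True),
    "Z_ONLY": (0.5, 1.0, 0.0, False),
    "PAR": (1.0, 1.0, 0.0, True),
}

_LABEL_TO_REGION = {
    "W_SPECIFIC": "PWR",
    "ZW_DIVERGENT": "CHR",
    "Z_ONLY": "CHR",
    "PAR": "PAR",
}


@dataclass(frozen=True)
class SegmentSpec:
    """One homogeneous stretch of the simulated chromosome."""

    label: str
    length_bp: int
    cov_mult_female: float
    cov_mult_male: float
    divergence_per_bp: float = 0.0
    w_maps: bool = True

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if not 0.0 <= self.divergence_per_bp <= 1.0:
            raise ValueError("divergence_per_bp must lie in [0, 1]")
        if self.cov_mult_female < 0 or self.cov_mult_male < 0:
            raise ValueError("coverage multipliers must be non-negative")
        if self.label not in ("W_SPECIFIC", "Z_ONLY"):
            if self.cov_mult_female == 0 or self.cov_mult_male == 0:
                raise ValueError(
                    f"{self.label} multipliers must be positive "
                    "(only W_SPECIFIC/Z_ONLY may zero one sex)"
                )


def segment(label: str, length_bp: int, **overrides) -> SegmentSpec:
    """Build a SegmentSpec with per-label default multipliers/divergence."""
    covf, covm, div, w_maps = _SEGMENT_DEFAULTS[label]
    params = dict(cov_mult_female=covf, cov_mult_male=covm,
                  divergence_per_bp=div, w_maps=w_maps)
    params.update(overrides)
    return SegmentSpec(label=label, length_bp=length_bp, **params)


@dataclass(frozen=True)
class SimLayout:
    """A full simulation design: segments plus global pool parameters."""

    chrom_name: str
    segments: tuple[SegmentSpec, ...]
    baseline_depth: float = 25.0
    pool_size_male: int = 20
    pool_size_female: int = 20
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("layout needs at least one segment")
        if self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be positive")
        if self.pool_size_male < 1 or self.pool_size_female < 1:
            raise ValueError("pool sizes must be positive integers")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")

    @property
    def total_length(self) -> int:
        return sum(s.length_bp for s in self.segments)

    def region_truth(self) -> list[tuple[str, int, int, str]]:
        """True region intervals (chrom, start, end, PWR/CHR/PAR), 0-based
        half-open, adjacent same-label segments merged; tiles the chromosome."""
        out: list[tuple[str, int, int, str]] = []
        pos = 0
        for seg in self.segments:
            label = _LABEL_TO_REGION[seg.label]
            if out and out[-1][3] == label:
                prev = out[-1]
                out[-1] = (prev[0], prev[1], pos + seg.length_bp, label)
            else:
                out.append((self.chrom_name, pos, pos + seg.length_bp, label))
            pos += seg.length_bp
        return out

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["segments"] = [asdict(s) for s in self.segments]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return build_layout(doc)


def build_layout(config: Mapping) -> SimLayout:
    """Validate a structured description (e.g. parsed YAML) into a SimLayout.

    ``config`` carries a ``segments`` list (each with at least label and
    length_bp; missing per-segment parameters take the label defaults) and
    optional global keys chrom_name, baseline_depth, pool sizes, error_rate,
    seed.
    """
    if "segments" not in config or not config["segments"]:
        raise ValueError("config must list at least one segment")
    segs = []
    for sdoc in config["segments"]:
        sdoc = dict(sdoc)
        label = sdoc.pop("label", None)
        if label is None:
            raise ValueError("segment missing label")
        length = sdoc.pop("length_bp", None)
        if length is None:
            raise ValueError("segment missing length_bp")
        segs.append(segment(label, int(length), **sdoc))
    return SimLayout(
        chrom_name=config.get("chrom_name", "chrSim"),
        segments=tuple(segs),
        baseline_depth=float(config.get("baseline_depth", 25.0)),
        pool_size_male=int(config.get("pool_size_male", 20)),
        pool_size_female=int(config.get("pool_size_female", 20)),
        error_rate=float(config.get("error_rate", 0.002)),
        seed=int(config.get("seed", 0)),
    )


def demo_layout(seed: int = 0, scale: float = 1.0) -> SimLayout:
    """The default demonstration chromosome: a 1:1000 scale-down of a 44-Mb
    ZW chromosome with PWR 0-3 kb, CHR 3-20 kb (alternating Z-only and Z/W
    divergent blocks), PAR 20-44 kb.  Pool depths 25x (male baseline; the
    female pool's 24x average emerges from the segment multipliers)."""

    def L(bp: int) -> int:
        return max(1, int(round(bp * scale)))

    segs = [segment("W_SPECIFIC", L(3_000))]
    # chimeric region: 8 alternating blocks of 2,125 bp
    for i in range(4):
        segs.append(segment("Z_ONLY", L(2_125)))
        segs.append(segment("ZW_DIVERGENT", L(2_125)))
    segs.append(segment("PAR", L(24_000)))
    return SimLayout(chrom_name="chrSim13", segments=tuple(segs), seed=seed)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth emitted alongside simulated counts."""

    regions: tuple[tuple[str, int, int, str], ...]
    sites: pd.DataFrame = field(repr=False)  # pos (1-based), z_allele, w_allele, is_divergent

    def divergent_positions(self) -> np.ndarray:
        return self.sites.loc[self.sites["is_divergent"], "pos"].to_numpy()


_BASES = np.array(["A", "C", "G", "T"])
# column order of a sync count field
_SYNC_ORDER = {"A": 0, "T": 1, "C": 2, "G": 3}


def _base_probs(freqs: np.ndarray, error_rate: float) -> np.ndarray:
    """Observed base probabilities given true base frequencies (rows: sites,
    cols: ACGT) and a symmetric error spread over the other three bases."""
    return freqs * (1.0 - error_rate) + (1.0 - freqs) * (error_rate / 3.0)


def simulate_pool_counts(layout: SimLayout) -> tuple[list[PoolSiteCount], TruthTable]:
    """Draw per-position pool counts for the whole layout.

    Depths are Poisson(baseline x segment multiplier) per pool; base counts
    are multinomial from the pooled allele frequency (0.5 for the W allele in
    females at divergent mapped sites, 0 in males) with symmetric sequencing
    error.  Zero-depth positions are emitted with all-zero counts.
    """
    rng = np.random.default_rng(layout.seed)
    n = layout.total_length
    ref_idx = rng.integers(0, 4, size=n)

    covf = np.empty(n)
    covm = np.empty(n)
    divergent = np.zeros(n, dtype=bool)
    pos0 = 0
    for seg in layout.segments:
        sl = slice(pos0, pos0 + seg.length_bp)
        covf[sl] = seg.cov_mult_female
        covm[sl] = seg.cov_mult_male
        if seg.divergence_per_bp > 0 and seg.w_maps:
            divergent[sl] = rng.random(seg.length_bp) < seg.divergence_per_bp
        pos0 += seg.length_bp

    # W allele: a random non-reference base at divergent sites
    w_idx = ref_idx.copy()
    if divergent.any():
        shift = rng.integers(1, 4, size=int(divergent.sum()))
        w_idx[divergent] = (ref_idx[divergent] + shift) % 4

    depth_m = rng.poisson(layout.baseline_depth * covm)
    depth_f = rng.poisson(layout.baseline_depth * covf)

    # true base frequencies per pool
    freq_m = np.zeros((n, 4))
    freq_m[np.arange(n), ref_idx] = 1.0
    freq_f = np.zeros((n, 4))
    freq_f[np.arange(n), ref_idx] += np.where(divergent, 0.5, 1.0)
    freq_f[np.arange(n), w_idx] += np.where(divergent, 0.5, 0.0)

    probs_m = _base_probs(freq_m, layout.error_rate)
    probs_f = _base_probs(freq_f, layout.error_rate)

    records: list[PoolSiteCount] = []
    zeros2 = (0, 0)
    for i in range(n):
        cm = rng.multinomial(depth_m[i], probs_m[i]) if depth_m[i] > 0 else np.zeros(4, dtype=int)
        cf = rng.multinomial(depth_f[i], probs_f[i]) if depth_f[i] > 0 else np.zeros(4, dtype=int)
        # ACGT -> sync order A:T:C:G, N and del always 0
        counts_m = (int(cm[0]), int(cm[3]), int(cm[1]), int(cm[2])) + zeros2
        counts_f = (int(cf[0]), int(cf[3]), int(cf[1]), int(cf[2])) + zeros2
        records.append(PoolSiteCount(
            chrom=layout.chrom_name,
            pos=i + 1,
            ref_base=str(_BASES[ref_idx[i]]),
            counts_male=counts_m,
            counts_female=counts_f,
        ))

    sites = pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "z_allele": _BASES[ref_idx],
        "w_allele": _BASES[w_idx],
        "is_divergent": divergent,
    })
    truth = TruthTable(regions=tuple(layout.region_truth()), sites=sites)
    return records, truth


def write_truth(truth: TruthTable, bed_path: str | Path, sites_path: str | Path) -> None:
    """Truth regions as BED (0-based half-open) and site truth as TSV."""
    with open(bed_path, "w") as fh:
        for chrom, start, end, label in truth.regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
    truth.sites.to_csv(sites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# linkage-map simulation


def simulate_linkage_table(n_lg: int = 28,
                           markers_per_lg: int = 400,
                           sexlinked_lg: str = "LG24",
                           suppression_span: float = 0.0,
                           seed: int = 0,
                           lg_length_bp: int = 30_000_000,
                           female_cm: float = 118.0,
                           male_cm: float = 126.0,
                           sexlinked_female_cm: float = 87.81,
                           sexlinked_male_cm: float = 47.37) -> pd.DataFrame:
    """Generate a marker table with per-sex cM positions.

    Each LG gets ``markers_per_lg`` markers at sorted uniform bp positions with
    monotone cM maps built from exponential gaps rescaled to the target map
    length.  On the sex-linked LG the female map contains a zero-recombination
    plateau: a run of consecutive markers sharing an identical female cM and
    spanning at least ``suppression_span`` of the LG's physical length.  The
    default map lengths echo a dense fish map (28 LGs, ~400 markers each,
    total near 3,500/3,300 cM male/female); the sex-linked defaults use the
    heterochiasmic LG lengths 87.81/47.37 cM.
    """
    if n_lg < 1:
        raise ValueError("n_lg must be >= 1")
    if markers_per_lg < 2:
        raise ValueError("markers_per_lg must be >= 2")
    if not 0.0 <= suppression_span <= 1.0:
        raise ValueError("suppression_span must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(1, n_lg + 1):
        lg = f"LG{g}"
        chrom = f"chr{g}"
        m = markers_per_lg
        pos = np.sort(rng.integers(1, lg_length_bp + 1, size=m))

        def monotone_map(total_cm: float, plateau: np.ndarray | None = None) -> np.ndarray:
            gaps = rng.exponential(1.0, size=m - 1)
            if plateau is not None:
                gaps[plateau] = 0.0
            if gaps.sum() == 0:
                return np.zeros(m)
            cm = np.concatenate([[0.0], np.cumsum(gaps)])
            return cm * (total_cm / cm[-1])

        if lg == sexlinked_lg:
            plateau = None
            if suppression_span > 0:
                span_bp = suppression_span * lg_length_bp
                lo = (lg_length_bp - span_bp) / 2.0
                inside = (pos >= lo) & (pos <= lo + span_bp)
                # zero the gaps between consecutive inside markers
                plateau = inside[:-1] & inside[1:]
            cmf = monotone_map(sexlinked_female_cm, plateau)
            cmm = monotone_map(sexlinked_male_cm)
        else:
            cmf = monotone_map(female_cm * float(rng.uniform(0.85, 1.15)))
            cmm = monotone_map(male_cm * float(rng.uniform(0.85, 1.15)))
        cmf = np.round(cmf, 3)
        cmm = np.round(cmm, 3)
        for k in range(m):
            rows.append((lg, f"{lg}_M{k + 1}", chrom, int(pos[k]),
                         float(cmf[k]), float(cmm[k])))
    return pd.DataFrame(rows, columns=["lg", "marker_id", "chrom", "pos_bp",
                                       "cm_female", "cm_male"])


# ---------------------------------------------------------------------------
# gene-table simulation


def simulate_gene_table(region_truth: Sequence[tuple[str, int, int, str]],
                        genes_per_region: Mapping[str, int],
                        frac_expressed: Mapping[str, float] | float = 0.8,
                        frac_de_given_expressed: Mapping[str, float] | float = 0.15,
                        frac_up_male_given_de: float = 0.5,
                        seed: int = 0,
                        exact: bool = False) -> pd.DataFrame:
    """Emit a gene table realizing the configured fractions per region.

    Expressed genes get mean normalized count > 1, others <= 1; DE genes (drawn
    among the expressed) get padj <= 0.01 and |LFC| >= 1 with the sign set
    male-positive with probability ``frac_up_male_given_de``.  With
    ``exact=True`` the realized counts are round(fraction x n) exactly
    (deterministic composition; positions and effect sizes still random), so a
    downstream summary reproduces the configured percentages to the digit.
    Gene intervals are 0-based half-open and lie inside their truth region.
    """

    def frac_for(table, label):
        v = table[label] if isinstance(table, Mapping) else table
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    if not region_truth:
        raise ValueError("region_truth must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, start, end, label in region_truth:
        n = int(genes_per_region.get(label, 0)) if isinstance(genes_per_region, Mapping) \
            else int(genes_per_region)
        if n < 0:
            raise ValueError("gene counts must be non-negative")
        if n == 0:
            continue
        fe = frac_for(frac_expressed, label)
        fd = frac_for(frac_de_given_expressed, label)
        if not 0.0 <= frac_up_male_given_de <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        if exact:
            n_exp = int(round(fe * n))
            n_de = int(round(fd * n_exp))
            n_up = int(round(frac_up_male_given_de * n_de))
            expressed = np.zeros(n, dtype=bool)
            expressed[:n_exp] = True
            de = np.zeros(n, dtype=bool)
            de[:n_de] = True
            up_male = np.zeros(n, dtype=bool)
            up_male[:n_up] = True
        else:
            expressed = rng.random(n) < fe
            de = expressed & (rng.random(n) < fd)
            up_male = de & (rng.random(n) < frac_up_male_given_de)

        span = max(end - start, 2)
        starts = start + np.sort(rng.integers(0, span - 1, size=n))
        ends = np.minimum(starts + rng.integers(500, 5000, size=n), end)
        ends = np.maximum(ends, starts + 1)
        mean_count = np.where(expressed,
                              1.0 + rng.lognormal(3.0, 1.0, size=n),
                              rng.uniform(0.0, 1.0, size=n))
        magnitude = 1.0 + rng.exponential(1.0, size=n)
        lfc = np.where(de, np.where(up_male, magnitude, -magnitude),
                       rng.normal(0.0, 0.4, size=n).clip(-0.99, 0.99))
        padj = np.where(de, 10.0 ** rng.uniform(-8.0, -2.0, size=n),
                        rng.uniform(0.02, 1.0, size=n))
        for k in range(n):
            rows.append((f"{label}_{chrom}_g{k + 1}", chrom, int(starts[k]),
                         int(ends[k]), float(mean_count[k]), float(lfc[k]),
                         float(padj[k])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "mean_count", "lfc", "padj"])
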