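"""Region-wise expression summaries and karyotype size validation.

The differential-expression model fit itself (a negative-binomial test on
transcript counts) happens upstream; this module consumes its output table
(mean normalized count, log fold change, adjusted p-value per gene) and
applies the study thresholds: a gene is *expressed* when its mean count
exceeds 1, *differentially expressed* (DE) at padj <= 0.01, and up-regulated
in males (females) at LFC >= 1 (<= -1) among DE genes — LFC is male-positive.

Percent conventions: region summaries round half-up to 2 decimals; the
male/female direction shares of the DE total are truncated to 2 decimals so
the two shares can never sum above 100.

Karyotype validation rescales measured chromosome sizes (µm) to base pairs by
their share of the total karyotype length and correlates them with assembled
sizes (Pearson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13 at 2 digits), used for all
    printed percentages in region summaries."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_pct(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals."""
    factor = 10 ** ndigits
    return math.trunc(x * factor) / factor


@dataclass(frozen=True)
class RegionExpressionSummary:
    region: str
    n_genes: int
    n_expressed: int
    pct_expressed: float | None  # half-up, 2 decimals; None when no genes
    n_de: int                    # DE among expressed genes
    pct_de_of_expressed: float | None
    n_up_male: int
    n_up_female: int


def flag_de(lfc: float, padj: float | None) -> tuple[bool, bool, bool]:
    """(DE?, up_male?, up_female?) under the study thresholds.

    DE iff padj is present and <= 0.01; direction flags additionally require
    |LFC| >= 1 (a DE gene with |LFC| < 1 carries neither flag); a missing padj
    is never DE.
    """
    de = padj is not None and not pd.isna(padj) and padj <= 0.01
    return de, de and lfc >= 1.0, de and lfc <= -1.0


def assign_regions(genes: pd.DataFrame, region_calls) -> pd.DataFrame:
    """Label each gene with the region containing its midpoint.

    Region calls must tile each called chromosome without overlap; genes on
    chromosomes without calls keep a missing region.  A gene straddling a
    boundary goes to the region holding its midpoint (integer division, so an
    exact-boundary midpoint belongs to the region starting there).
    """
    by_chrom: dict[str, list] = {}
    for r in region_calls:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, calls in by_chrom.items():
        calls.sort(key=lambda r: r.start)
        for a, b in zip(calls, calls[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping region calls on {chrom}")
    out = genes.copy()
    labels: list[str | None] = []
    for _, g in out.iterrows():
        mid = (int(g["start"]) + int(g["end"])) // 2
        label = None
        for r in by_chrom.get(g["chrom"], ()):
            if r.start <= mid < r.end:
                label = r.label
                break
        labels.append(label)
    out["region"] = labels
    return out


def summarize_region(genes: pd.DataFrame) -> RegionExpressionSummary:
    """Expression summary for the genes of one region.

    n_expressed counts mean_count > 1; n_de counts DE genes *among the
    expressed* (the %DE denominator is the expressed-gene count); the
    direction counts are over all genes of the region.  Percentages round
    half-up to 2 decimals; an empty denominator reports a missing percentage.
    """
    regions = [r for r in genes.get("region", pd.Series(dtype=object)).unique()
               if r is not None and not pd.isna(r)]
    if len(regions) > 1:
        raise ValueError(f"genes span multiple regions: {regions}")
    region = str(regions[0]) if regions else ""
    n = len(genes)
    expressed = genes["mean_count"] > 1
    n_expressed = int(expressed.sum())
    flags = [flag_de(l, p) for l, p in zip(genes["lfc"], genes["padj"])]
    de_all = pd.Series([f[0] for f in flags], index=genes.index, dtype=bool)
    n_de = int((de_all & expressed).sum())
    n_up_male = sum(f[1] for f in flags)
    n_up_female = sum(f[2] for f in flags)
    pct_expressed = round_half_up(100.0 * n_expressed / n) if n else None
    pct_de = round_half_up(100.0 * n_de / n_expressed) if n_expressed else None
    return RegionExpressionSummary(
        region=region,
        n_genes=n,
        n_expressed=n_expressed,
        pct_expressed=pct_expressed,
        n_de=n_de,
        pct_de_of_expressed=pct_de,
        n_up_male=int(n_up_male),
        n_up_female=int(n_up_female),
    )


def summarize_by_region(genes: pd.DataFrame) -> list[RegionExpressionSummary]:
    """Summaries for every assigned region, in PWR/CHR/PAR-first order."""
    order = {"PWR": 0, "CHR": 1, "PAR": 2}
    present = [r for r in genes["region"].dropna().unique()]
    present.sort(key=lambda r: (order.get(r, 99), r))
    return [summarize_region(genes[genes["region"] == r]) for r in present]


def de_direction_shares(n_de: int, n_up_male: int, n_up_female: int) -> tuple[float, float]:
    """Male- and female-upregulated percentages of the DE total, truncated to
    2 decimals (so shares never sum above 100)."""
    if n_de <= 0:
        raise ValueError("n_de must be positive")
    return (truncate_pct(100.0 * n_up_male / n_de),
            truncate_pct(100.0 * n_up_female / n_de))


def estimate_chrom_sizes(measures: pd.DataFrame, total_genome_bp: int) -> pd.Series:
    """Estimated chromosome sizes in bp from karyotype measurements:

        estimate_i = mean_um_i * total_genome_bp / sum(mean_um)

    The estimates sum to the genome size by construction.
    """
    if total_genome_bp <= 0:
        raise ValueError("total_genome_bp must be positive")
    um = measures["mean_um"]
    if (um <= 0).any():
        raise ValueError("mean_um must be positive")
    total_um = float(um.sum())
    est = um * (total_genome_bp / total_um)
    est.index = measures["chrom"].to_numpy()
    return est


def pearson_r(x, y) -> float:
    """Product-moment correlation of paired values (>= 3 pairs, both with
    nonzero variance)."""
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in input")
    return float(stats.pearsonr(x, y).statistic)
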