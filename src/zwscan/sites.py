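"""Per-site statistics for the two sex pools.

With pool sequencing only allele frequencies are observable, not genotypes.
At each position we reduce the counts to a biallelic major/minor pair (chosen
from the pooled male+female counts), estimate the minor-allele frequency in
each pool, compute a Hudson-type two-population F_ST with a finite-depth
correction, and classify the site.  In a ZW system a W-restricted allele is
expected near frequency 0.5 in the female pool (each ZW female carries one W)
and absent from the ZZ male pool, which is the FEMALE_SPECIFIC signature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io import PoolSiteCount

#: fixed base order used for major/minor tie-breaking
BASE_ORDER = ("A", "C", "G", "T")

# sync count order is A:T:C:G; map into A,C,G,T order
_SYNC_TO_ACGT = (0, 2, 3, 1)


class SiteClass(enum.Enum):
    UNINFORMATIVE = "UNINFORMATIVE"
    FEMALE_SPECIFIC = "FEMALE_SPECIFIC"
    MALE_SPECIFIC = "MALE_SPECIFIC"
    SHARED_POLY = "SHARED_POLY"
    FIXED_DIFF = "FIXED_DIFF"


@dataclass(frozen=True)
class SiteThresholds:
    """Classification thresholds.

    het_halfwidth
        Half-width h of the heterozygous band: the heterogametic pool must show
        the minor allele within [0.5 - h, 0.5 + h].
    hom_tolerance
        Maximum minor-allele frequency f still treated as monomorphic.
    min_depth
        Minimum per-pool depth d for a site to be informative.
    """

    het_halfwidth: float = 0.1
    hom_tolerance: float = 0.05
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.het_halfwidth < 0.5:
            raise ValueError("het_halfwidth must lie in (0, 0.5)")
        if not 0 < self.hom_tolerance < 0.5:
            raise ValueError("hom_tolerance must lie in (0, 0.5)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class SiteAlleles:
    """Major/minor reduction of one site; frequencies are of the minor base."""

    major_base: str
    minor_base: str
    p_male: float | None
    p_female: float | None
    n_male: int
    n_female: int


@dataclass(frozen=True)
class SiteFst:
    numerator: float
    denominator: float
    value: float | None


def site_alleles(site: PoolSiteCount) -> SiteAlleles:
    """Reduce a site to its pooled major/minor alleles and per-pool minor
    frequencies.

    The major base has the highest male+female pooled count, the minor base the
    second highest; ties resolve by the fixed order A < C < G < T.  A pool with
    zero depth gets an undefined (None) frequency.
    """
    male = [site.counts_male[i] for i in _SYNC_TO_ACGT]
    female = [site.counts_female[i] for i in _SYNC_TO_ACGT]
    pooled = [m + f for m, f in zip(male, female)]
    order = sorted(range(4), key=lambda i: (-pooled[i], i))
    major_i, minor_i = order[0], order[1]
    n_male, n_female = sum(male), sum(female)
    p_male = male[minor_i] / n_male if n_male > 0 else None
    p_female = female[minor_i] / n_female if n_female > 0 else None
    return SiteAlleles(
        major_base=BASE_ORDER[major_i],
        minor_base=BASE_ORDER[minor_i],
        p_male=p_male,
        p_female=p_female,
        n_male=n_male,
        n_female=n_female,
    )


def site_fst(a: SiteAlleles) -> SiteFst | None:
    """Hudson-type pooled F_ST components for one site.

    numerator   = (pM - pF)^2 - pM(1-pM)/(nM-1) - pF(1-pF)/(nF-1)
    denominator = pM(1-pF) + pF(1-pM)

    using read depths as sample sizes.  Returns None when either pool has
    depth < 2 (no F_ST contribution); the value itself is undefined when the
    denominator is zero (monomorphic site) and may be negative site-level.
    """
    if a.n_male < 2 or a.n_female < 2 or a.p_male is None or a.p_female is None:
        return None
    pm, pf = a.p_male, a.p_female
    num = (pm - pf) ** 2
    num -= pm * (1.0 - pm) / (a.n_male - 1)
    num -= pf * (1.0 - pf) / (a.n_female - 1)
    den = pm * (1.0 - pf) + pf * (1.0 - pm)
    value = num / den if den > 0 else None
    return SiteFst(numerator=num, denominator=den, value=value)


def classify_site(a: SiteAlleles, thresholds: SiteThresholds | None = None) -> SiteClass:
    """Assign exactly one class to a site.

    FEMALE_SPECIFIC: female minor frequency within the heterozygous band
    around 0.5 while the male pool is monomorphic (and both depths pass the
    gate); MALE_SPECIFIC symmetric; FIXED_DIFF when the pools are near-fixed
    for opposite alleles; SHARED_POLY when both pools are polymorphic; all
    remaining sites are UNINFORMATIVE.
    """
    t = thresholds or SiteThresholds()
    if a.n_male < t.min_depth or a.n_female < t.min_depth:
        return SiteClass.UNINFORMATIVE
    pm, pf = a.p_male, a.p_female
    if pm is None or pf is None:
        return SiteClass.UNINFORMATIVE
    h, f = t.het_halfwidth, t.hom_tolerance
    if 0.5 - h <= pf <= 0.5 + h and pm <= f:
        return SiteClass.FEMALE_SPECIFIC
    if 0.5 - h <= pm <= 0.5 + h and pf <= f:
        return SiteClass.MALE_SPECIFIC
    if (pm >= 1.0 - f and pf <= f) or (pf >= 1.0 - f and pm <= f):
        return SiteClass.FIXED_DIFF
    if min(pm, 1.0 - pm) > f and min(pf, 1.0 - pf) > f:
        return SiteClass.SHARED_POLY
    return SiteClass.UNINFORMATIVE
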