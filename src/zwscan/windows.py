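"""Sliding-window aggregation of per-site statistics.

The scan mirrors the pool-seq convention of a 50-kb window advanced every
1 kb, each window reported at its start coordinate.  Window F_ST is the
ratio of sums (sum of site numerators over sum of site denominators), the
standard variance-reduction for Hudson-type estimators, clamped to [0, 1].
Depths are normalized against the genome-wide mean of each pool so that the
W-region signature (elevated relative female depth, male/female depth ratio
near zero) and the Z signature (ratio near two) are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io import PoolSiteCount
from .sites import SiteClass, SiteFst, SiteThresholds, classify_site, site_alleles, site_fst

DEFAULT_WINDOW = 50_000
DEFAULT_STEP = 1_000
DEFAULT_RATIO_CAP = 10.0


@dataclass(frozen=True)
class WindowStats:
    """Aggregated statistics for one window [start, end), 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_sites: int
    n_informative: int
    mean_depth_male: float
    mean_depth_female: float
    fst: float
    n_fspec: int
    n_mspec: int
    rel_depth_male: float | None = None
    rel_depth_female: float | None = None
    depth_ratio: float | None = None

    @property
    def normalized(self) -> bool:
        return self.rel_depth_male is not None and self.rel_depth_female is not None


def make_windows(chrom_len: int, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> list[tuple[int, int]]:
    """Sliding windows [0, w), [step, step+w), ... truncated at chrom_len.

    Every position is covered by at least one window; the number of windows is
    floor((chrom_len - 1)/step) + 1.
    """
    if chrom_len < 1:
        raise ValueError("chrom_len must be >= 1")
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    return [(s, min(s + window, chrom_len)) for s in range(0, chrom_len, step)]


def aggregate_window(sites: Sequence[PoolSiteCount],
                     fsts: Sequence[SiteFst | None],
                     classes: Sequence[SiteClass],
                     interval: tuple[int, int],
                     chrom: str | None = None) -> WindowStats:
    """Aggregate per-site results falling in one window.

    Mean depths divide by the full interval length, so positions absent from
    the input (or with zero depth) dilute the window mean.  Window F_ST is
    max(0, sum(num)/sum(den)) over sites with defined components, 0 when none.
    """
    start, end = interval
    positions = [s.pos - 1 for s in sites]
    if any(not (start <= p < end) for p in positions):
        raise ValueError("sites outside the window interval")
    if positions != sorted(positions):
        raise ValueError("sites must be sorted by position")
    span = end - start
    num = den = 0.0
    n_informative = 0
    for f in fsts:
        if f is not None:
            num += f.numerator
            den += f.denominator
            n_informative += 1
    fst = max(0.0, num / den) if den > 0 else 0.0
    return WindowStats(
        chrom=chrom if chrom is not None else (sites[0].chrom if sites else ""),
        start=start,
        end=end,
        n_sites=len(sites),
        n_informative=n_informative,
        mean_depth_male=sum(s.depth_male for s in sites) / span,
        mean_depth_female=sum(s.depth_female for s in sites) / span,
        fst=min(fst, 1.0),
        n_fspec=sum(c is SiteClass.FEMALE_SPECIFIC for c in classes),
        n_mspec=sum(c is SiteClass.MALE_SPECIFIC for c in classes),
    )


def normalize_depths(windows: Sequence[WindowStats],
                     genome_mean_male: float,
                     genome_mean_female: float,
                     ratio_cap: float = DEFAULT_RATIO_CAP) -> list[WindowStats]:
    """Attach relative depths and the male/female depth ratio.

    rel_depth_sex = window mean / genome-wide pool mean.  The depth ratio uses
    absolute means; when the female mean is zero it is undefined (None) if the
    male mean is also zero, else capped at ``ratio_cap`` to stay plottable.
    """
    if genome_mean_male <= 0 or genome_mean_female <= 0:
        raise ValueError("genome-wide means must be positive")
    out = []
    for w in windows:
        if w.mean_depth_female > 0:
            ratio = min(w.mean_depth_male / w.mean_depth_female, ratio_cap)
        elif w.mean_depth_male > 0:
            ratio = ratio_cap
        else:
            ratio = None
        out.append(replace(
            w,
            rel_depth_male=w.mean_depth_male / genome_mean_male,
            rel_depth_female=w.mean_depth_female / genome_mean_female,
            depth_ratio=ratio,
        ))
    return out


def genome_depth_means(records: Iterable[PoolSiteCount]) -> tuple[float, float, int]:
    """Genome-wide mean depth per pool over all parsed positions (zero-depth
    positions included).  Returns (male_mean, female_mean, n_positions)."""
    tot_m = tot_f = n = 0
    for rec in records:
        tot_m += rec.depth_male
        tot_f += rec.depth_female
        n += 1
    if n == 0:
        return 0.0, 0.0, 0
    return tot_m / n, tot_f / n, n


def scan_sync(records: Iterable[PoolSiteCount],
              chrom_lengths: dict[str, int],
              window: int = DEFAULT_WINDOW,
              step: int = DEFAULT_STEP,
              thresholds: SiteThresholds | None = None,
              ratio_cap: float = DEFAULT_RATIO_CAP) -> list[WindowStats]:
    """Full scan: per-site statistics -> sliding windows -> normalized depths.

    ``records`` may be any iterable of PoolSiteCount grouped by chromosome
    (file order).  Windows for every chromosome in ``chrom_lengths`` are
    produced even where no site was observed.
    """
    t = thresholds or SiteThresholds()
    # accumulate per-chromosome prefix-summable arrays
    per_chrom: dict[str, dict[str, list]] = {}
    tot_m = tot_f = n_pos = 0
    for rec in records:
        if rec.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {rec.chrom} missing from lengths table")
        if rec.pos > chrom_lengths[rec.chrom]:
            raise ValueError(f"position {rec.pos} beyond {rec.chrom} length")
        a = site_alleles(rec)
        f = site_fst(a)
        c = classify_site(a, t)
        d = per_chrom.setdefault(rec.chrom, {
            "pos": [], "dm": [], "df": [], "num": [], "den": [],
            "inf": [], "fs": [], "ms": [],
        })
        d["pos"].append(rec.pos - 1)
        d["dm"].append(rec.depth_male)
        d["df"].append(rec.depth_female)
        d["num"].append(f.numerator if f is not None else 0.0)
        d["den"].append(f.denominator if f is not None else 0.0)
        d["inf"].append(1 if f is not None else 0)
        d["fs"].append(1 if c is SiteClass.FEMALE_SPECIFIC else 0)
        d["ms"].append(1 if c is SiteClass.MALE_SPECIFIC else 0)
        tot_m += rec.depth_male
        tot_f += rec.depth_female
        n_pos += 1

    windows: list[WindowStats] = []
    for chrom, length in chrom_lengths.items():
        intervals = make_windows(length, window, step)
        d = per_chrom.get(chrom)
        if d is None:
            arrays = {k: np.zeros(0) for k in ("pos", "dm", "df", "num", "den", "inf", "fs", "ms")}
        else:
            arrays = {k: np.asarray(v, dtype=float) for k, v in d.items()}
        pos = arrays["pos"]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cums = {k: np.concatenate([[0.0], np.cumsum(arrays[k][order])])
                for k in ("dm", "df", "num", "den", "inf", "fs", "ms")}
        n_cum = np.arange(len(pos) + 1, dtype=float)
        for start, end in intervals:
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            span = end - start
            num = cums["num"][hi] - cums["num"][lo]
            den = cums["den"][hi] - cums["den"][lo]
            fst = max(0.0, num / den) if den > 0 else 0.0
            windows.append(WindowStats(
                chrom=chrom,
                start=start,
                end=end,
                n_sites=int(n_cum[hi] - n_cum[lo]),
                n_informative=int(cums["inf"][hi] - cums["inf"][lo]),
                mean_depth_male=(cums["dm"][hi] - cums["dm"][lo]) / span,
                mean_depth_female=(cums["df"][hi] - cums["df"][lo]) / span,
                fst=min(fst, 1.0),
                n_fspec=int(cums["fs"][hi] - cums["fs"][lo]),
                n_mspec=int(cums["ms"][hi] - cums["ms"][lo]),
            ))
    if n_pos == 0 or tot_m == 0 or tot_f == 0:
        # nothing to normalize against; leave relative fields unset
        return windows
    return normalize_depths(windows, tot_m / n_pos, tot_f / n_pos, ratio_cap)
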