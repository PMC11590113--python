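"""Rule-based segmentation of a chromosome into sex-linked regions.

Each normalized window is assigned one evidence state from the coverage and
SNP signatures of a degenerating ZW pair:

* W_LIKE      — male/female depth ratio near zero with elevated relative
                female depth: W-specific sequence, hemizygous in males.
* Z_ELEVATED  — males at roughly double the female coverage: Z sequence whose
                W homolog no longer maps.
* W_DIVERGENT — an excess of female-specific SNPs: Z/W consensus sequence
                where W alleles appear at ~0.5 frequency in the female pool.
* BALANCED    — depth ratio near one, no sex-specific SNP excess:
                pseudoautosomal behaviour.
* LOW_COV     — both pools far below genome coverage; uninformative.

States are smoothed with a majority filter and merged into maximal runs:
W_LIKE runs become the putative W region (PWR), runs of Z_ELEVATED and/or
W_DIVERGENT become the chimeric Z/W region (CHR), BALANCED runs the
pseudoautosomal region (PAR).  Runs shorter than a minimum span are absorbed
into the longer flanking region, so the calls always tile the chromosome.
The segmentation is deliberately rule-based (not an HMM) so every boundary
is auditable against the thresholds that produced it.
"""

from __future__ import annotations

import enum
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .windows import WindowStats


class WindowState(enum.Enum):
    W_LIKE = "W_LIKE"
    Z_ELEVATED = "Z_ELEVATED"
    W_DIVERGENT = "W_DIVERGENT"
    BALANCED = "BALANCED"
    LOW_COV = "LOW_COV"


_STATE_TO_LABEL = {
    WindowState.W_LIKE: "PWR",
    WindowState.Z_ELEVATED: "CHR",
    WindowState.W_DIVERGENT: "CHR",
    WindowState.BALANCED: "PAR",
    WindowState.LOW_COV: "UNCLASSIFIED",
}

REGION_LABELS = ("PWR", "CHR", "PAR", "UNCLASSIFIED")


@dataclass(frozen=True)
class CallerThresholds:
    """All cutoffs of the region caller.

    ratio_w_max / rel_f_min_w
        W_LIKE gate: depth ratio at most ratio_w_max AND relative female depth
        at least rel_f_min_w (the W signature is elevated female coverage, not
        merely missing male coverage).
    ratio_z_min
        Z_ELEVATED gate on the depth ratio (males ~2x females).
    fspec_min
        Minimum female-specific SNPs per window for W_DIVERGENT.  None selects
        the data-adaptive default max(25, 10 x genome median per window).
    ratio_par_lo / ratio_par_hi
        BALANCED band on the depth ratio.
    low_cov_frac
        LOW_COV when both relative depths fall below this fraction.
    smoothing_width
        Odd width of the majority filter, in windows.
    min_region_span
        Minimum region span in bp; shorter runs merge into the longer flank.
    """

    ratio_w_max: float = 0.3
    rel_f_min_w: float = 1.5
    ratio_z_min: float = 1.5
    fspec_min: int | None = None
    fspec_floor: int = 25
    ratio_par_lo: float = 0.8
    ratio_par_hi: float = 1.2
    low_cov_frac: float = 0.25
    smoothing_width: int = 51
    min_region_span: int = 100_000

    def __post_init__(self) -> None:
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be an odd integer >= 1")
        if self.min_region_span < 1:
            raise ValueError("min_region_span must be positive")
        for name in ("ratio_w_max", "rel_f_min_w", "ratio_z_min",
                     "ratio_par_lo", "ratio_par_hi", "low_cov_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RegionCall:
    """A labeled interval [start, end), with its supporting window evidence."""

    chrom: str
    start: int
    end: int
    label: str
    n_windows: int
    mean_fst: float
    evidence: dict[str, int] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start


def adaptive_fspec_min(windows: Sequence[WindowStats], t: CallerThresholds) -> int:
    """Resolve the W_DIVERGENT SNP cutoff: the configured value, or
    max(floor, 10 x median per-window female-specific SNP count)."""
    if t.fspec_min is not None:
        return t.fspec_min
    if not windows:
        return t.fspec_floor
    med = statistics.median(w.n_fspec for w in windows)
    return max(t.fspec_floor, int(10 * med))


def classify_window(w: WindowStats, t: CallerThresholds,
                    fspec_min: int | None = None) -> WindowState:
    """Assign one evidence state; precedence LOW_COV > W_LIKE > W_DIVERGENT >
    Z_ELEVATED > BALANCED."""
    if not w.normalized:
        raise ValueError("window must be depth-normalized before classification")
    cut = fspec_min if fspec_min is not None else (t.fspec_min or t.fspec_floor)
    if w.rel_depth_male < t.low_cov_frac and w.rel_depth_female < t.low_cov_frac:
        return WindowState.LOW_COV
    ratio = w.depth_ratio
    if ratio is not None and ratio <= t.ratio_w_max and w.rel_depth_female >= t.rel_f_min_w:
        return WindowState.W_LIKE
    if w.n_fspec >= cut:
        return WindowState.W_DIVERGENT
    if ratio is not None and ratio >= t.ratio_z_min:
        return WindowState.Z_ELEVATED
    return WindowState.BALANCED


def smooth_states(states: Sequence[WindowState], width: int) -> list[WindowState]:
    """Majority filter: each state becomes the modal state of its centered
    width-window (truncated at the edges); ties keep the original state."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd integer >= 1")
    half = width // 2
    out = []
    for i, s in enumerate(states):
        neigh = states[max(0, i - half): i + half + 1]
        counts = Counter(neigh).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            out.append(s)
        else:
            out.append(counts[0][0])
    return out


def _runs(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Maximal runs as (first_index, last_index_inclusive, label)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - 1, labels[start]))
            start = i
    return runs


def segment_regions(states: Sequence[WindowState],
                    intervals: Sequence[tuple[int, int]],
                    t: CallerThresholds,
                    windows: Sequence[WindowStats] | None = None,
                    chrom: str = "") -> list[RegionCall]:
    """Merge window states into labeled regions tiling [0, chrom_end).

    Boundaries between adjacent runs sit at the midpoint between the last
    window start of one run and the first window start of the next.  Runs
    spanning less than ``min_region_span`` are absorbed into the longer
    flanking region (so small W patches inside the chimeric region do not
    fragment it); adjacent same-label regions merge.
    """
    if len(states) != len(intervals):
        raise ValueError("states and intervals must have the same length")
    if not states:
        return []
    if windows is not None and len(windows) != len(states):
        raise ValueError("windows and states must have the same length")
    if chrom == "" and windows:
        chrom = windows[0].chrom

    labels = [_STATE_TO_LABEL[s] for s in states]
    runs = _runs(labels)  # index runs

    def run_span(run: tuple[int, int, str]) -> int:
        i, j, _ = run
        end = intervals[j + 1][0] if j + 1 < len(intervals) else intervals[j][1]
        start = intervals[i][0]
        return end - start

    # absorb short runs into the longer flank, smallest run first, so thin
    # slivers between fragments dissolve before larger boundary decisions
    while len(runs) > 1:
        spans = [run_span(r) for r in runs]
        short = [k for k, s in enumerate(spans) if s < t.min_region_span]
        if not short:
            break
        k = min(short, key=lambda k: spans[k])
        left = runs[k - 1] if k > 0 else None
        right = runs[k + 1] if k + 1 < len(runs) else None
        if right is None or (left is not None and run_span(left) >= run_span(right)):
            target_label = left[2]
        else:
            target_label = right[2]
        runs[k] = (runs[k][0], runs[k][1], target_label)
        merged: list[tuple[int, int, str]] = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1] = (merged[-1][0], r[1], r[2])
            else:
                merged.append(r)
        runs = merged

    # convert index runs to bp regions with midpoint boundaries
    chrom_end = intervals[-1][1]
    calls: list[RegionCall] = []
    prev_end = 0
    for k, (i, j, label) in enumerate(runs):
        if k + 1 < len(runs):
            nxt = runs[k + 1][0]
            boundary = (intervals[j][0] + intervals[nxt][0]) // 2
        else:
            boundary = chrom_end
        evidence = Counter(states[i:j + 1])
        if windows is not None:
            mean_fst = sum(w.fst for w in windows[i:j + 1]) / (j - i + 1)
        else:
            mean_fst = 0.0
        calls.append(RegionCall(
            chrom=chrom,
            start=prev_end,
            end=boundary,
            label=label,
            n_windows=j - i + 1,
            mean_fst=mean_fst,
            evidence={s.value: c for s, c in sorted(evidence.items(), key=lambda x: x[0].value)},
        ))
        prev_end = boundary
    return calls


def call_regions(windows: Sequence[WindowStats],
                 t: CallerThresholds | None = None) -> list[RegionCall]:
    """Classify, smooth and segment per chromosome; windows must be sorted by
    (chrom, start) and depth-normalized."""
    t = t or CallerThresholds()
    calls: list[RegionCall] = []
    by_chrom: dict[str, list[WindowStats]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    fspec_cut = adaptive_fspec_min(windows, t)
    for chrom, ws in by_chrom.items():
        if [w.start for w in ws] != sorted(w.start for w in ws):
            raise ValueError(f"windows of {chrom} not sorted by start")
        states = [classify_window(w, t, fspec_min=fspec_cut) for w in ws]
        states = smooth_states(states, t.smoothing_width)
        intervals = [(w.start, w.end) for w in ws]
        calls.extend(segment_regions(states, intervals, t, windows=ws, chrom=chrom))
    return calls
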