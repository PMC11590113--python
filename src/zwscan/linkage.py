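"""Sex-specific linkage-map summaries.

Heterochiasmy — the sex difference in recombination rate — is summarized as
male/female genetic map-length ratios, per linkage group and genome-wide.
Recombination suppression shows up on a Marey map (bp versus cM) as
"zero-recombination clusters": runs of markers that advance along the
physical map while their genetic position stays put.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CM_TOL = 1e-6  # cM equality tolerance for cluster membership


@dataclass(frozen=True)
class LGSummary:
    lg: str
    n_markers: int
    length_female_cm: float
    length_male_cm: float
    length_avg_cm: float
    mf_ratio: float | None  # male / female; None when female length is 0
    mean_spacing_cm: float


@dataclass(frozen=True)
class ZeroRecombCluster:
    lg: str
    sex: str
    first_bp: int
    last_bp: int
    n_markers: int
    cm_value: float

    @property
    def span_bp(self) -> int:
        return self.last_bp - self.first_bp


def _sex_column(sex: str) -> str:
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    return f"cm_{sex}"


def summarize_lg(markers: pd.DataFrame) -> LGSummary:
    """Summarize one linkage group's markers.

    Map length per sex is the cM range (max - min), robust to input order and
    equal to the sum of adjacent gaps for a monotone map.  The male/female
    ratio is kept at full precision (round at presentation); mean spacing uses
    the sex-averaged length over n - 1 intervals.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to summarize an LG")
    lgs = markers["lg"].unique()
    if len(lgs) != 1:
        raise ValueError(f"expected a single LG, got {list(lgs)}")
    lf = float(markers["cm_female"].max() - markers["cm_female"].min())
    lm = float(markers["cm_male"].max() - markers["cm_male"].min())
    cm_avg = (markers["cm_female"] + markers["cm_male"]) / 2.0
    la = float(cm_avg.max() - cm_avg.min())
    return LGSummary(
        lg=str(lgs[0]),
        n_markers=len(markers),
        length_female_cm=lf,
        length_male_cm=lm,
        length_avg_cm=la,
        mf_ratio=(lm / lf) if lf > 0 else None,
        mean_spacing_cm=la / (len(markers) - 1),
    )


def summarize_map(markers: pd.DataFrame) -> list[LGSummary]:
    """Per-LG summaries for a whole marker table, in LG order of appearance."""
    return [summarize_lg(g) for _, g in markers.groupby("lg", sort=False)]


def genome_mf_ratio(summaries: list[LGSummary]) -> float:
    """Genome-wide male/female map-length ratio: sum of male lengths over sum
    of female lengths."""
    if not summaries:
        raise ValueError("need at least one LG summary")
    tot_m = sum(s.length_male_cm for s in summaries)
    tot_f = sum(s.length_female_cm for s in summaries)
    if tot_f == 0:
        raise ValueError("total female map length is zero")
    return tot_m / tot_f


def find_zero_recomb_clusters(markers: pd.DataFrame, sex: str,
                              min_markers: int = 5,
                              min_span_bp: int = 100_000) -> list[ZeroRecombCluster]:
    """Detect zero-recombination clusters in one LG for the chosen sex.

    A cluster is a maximal run of consecutive-by-bp markers whose cM in that
    sex agree within ``CM_TOL``, with at least ``min_markers`` members and a
    physical span of at least ``min_span_bp``.  Output is invariant to input
    order (markers are sorted by bp internally).
    """
    col = _sex_column(sex)
    if markers["pos_bp"].isna().any():
        bad = markers.loc[markers["pos_bp"].isna(), "marker_id"].tolist()
        raise ValueError(f"markers without bp positions: {bad}")
    df = markers.sort_values(["pos_bp", "marker_id"], kind="stable").reset_index(drop=True)
    lg = str(df["lg"].iloc[0])
    clusters: list[ZeroRecombCluster] = []
    i = 0
    n = len(df)
    cm = df[col].to_numpy(dtype=float)
    bp = df["pos_bp"].to_numpy(dtype=int)
    while i < n:
        j = i
        while j + 1 < n and abs(cm[j + 1] - cm[i]) <= CM_TOL:
            j += 1
        if j - i + 1 >= min_markers and bp[j] - bp[i] >= min_span_bp:
            clusters.append(ZeroRecombCluster(
                lg=lg, sex=sex, first_bp=int(bp[i]), last_bp=int(bp[j]),
                n_markers=j - i + 1, cm_value=float(cm[i]),
            ))
        i = j + 1
    return clusters


def collinearity_table(markers: pd.DataFrame,
                       region_calls=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Contingency counts of markers by (LG, chromosome), and by sex-region
    label when region calls are supplied.

    Markers without a chromosome tally under ``unplaced``; markers on called
    chromosomes but outside every region (or on chromosomes without calls)
    tally under ``outside``.  Totals conserve the input marker count.
    """
    df = markers.copy()
    df["chrom"] = df["chrom"].fillna("unplaced")
    lg_by_chrom = pd.crosstab(df["lg"], df["chrom"])
    if region_calls is None:
        return lg_by_chrom, None
    labels = []
    for _, row in df.iterrows():
        label = "outside"
        if row["chrom"] != "unplaced" and not pd.isna(row["pos_bp"]):
            p = int(row["pos_bp"]) - 1  # to 0-based
            for r in region_calls:
                if r.chrom == row["chrom"] and r.start <= p < r.end:
                    label = r.label
                    break
        elif row["chrom"] == "unplaced":
            label = "unplaced"
        labels.append(label)
    df["region"] = labels
    return lg_by_chrom, pd.crosstab(df["lg"], df["region"])
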