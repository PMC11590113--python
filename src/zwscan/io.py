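"""Readers and writers for the formats the pipeline touches.

The scan starts from a popoolation2-style sync file: one line per reference
position carrying the nucleotide composition of the male and the female pool.
Count fields are colon-separated integers in the order ``A:T:C:G:N:del``.
Sync files and marker tables are 1-based inclusive; every internal interval
type and all BED output are 0-based half-open.  Conversion happens only here,
at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: index order of the count fields in a sync count column
SYNC_BASES = ("A", "T", "C", "G", "N", "del")

WINDOW_TSV_COLUMNS = (
    "chrom", "start", "end", "n_sites", "depth_m", "depth_f",
    "rel_depth_m", "rel_depth_f", "depth_ratio", "fst", "n_fspec", "n_mspec",
)

MARKER_TSV_COLUMNS = ("lg", "marker_id", "chrom", "pos_bp", "cm_female", "cm_male")

GENE_TSV_COLUMNS = ("gene_id", "chrom", "start", "end", "mean_count", "lfc", "padj")


class SyncFormatError(ValueError):
    """A sync line that cannot be parsed; message carries the line number."""


@dataclass(frozen=True)
class PoolSiteCount:
    """Nucleotide counts of both pools at one reference position (1-based)."""

    chrom: str
    pos: int
    ref_base: str
    counts_male: tuple[int, int, int, int, int, int]
    counts_female: tuple[int, int, int, int, int, int]

    @property
    def depth_male(self) -> int:
        """Male read depth over the four real bases (N and del excluded)."""
        return sum(self.counts_male[:4])

    @property
    def depth_female(self) -> int:
        return sum(self.counts_female[:4])


def _parse_counts(field: str, lineno: int) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncFormatError(
            f"line {lineno}: count field {field!r} has {len(parts)} values, expected 6"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise SyncFormatError(f"line {lineno}: non-integer count in {field!r}") from exc
    if any(c < 0 for c in counts):
        raise SyncFormatError(f"line {lineno}: negative count in {field!r}")
    return counts


def read_sync(path: str | Path) -> Iterator[PoolSiteCount]:
    """Stream ``PoolSiteCount`` records from a sync file in file order.

    Only one record is held in memory at a time.  Unknown reference bases are
    downgraded to ``N`` with a warning; malformed lines raise
    :class:`SyncFormatError` naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SyncFormatError(
                    f"line {lineno}: expected >=5 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise SyncFormatError(f"line {lineno}: position {pos} < 1")
            if ref not in "ACGTN" or len(ref) != 1:
                logger.warning("line %d: unknown ref base %r downgraded to N", lineno, ref)
                ref = "N"
            yield PoolSiteCount(
                chrom=chrom,
                pos=pos,
                ref_base=ref,
                counts_male=_parse_counts(fields[3], lineno),
                counts_female=_parse_counts(fields[4], lineno),
            )


def write_sync(records: Iterable[PoolSiteCount], path: str | Path) -> None:
    """Write records as canonical sync lines (byte-stable for a fixed input)."""
    with open(path, "w") as fh:
        for rec in records:
            m = ":".join(str(c) for c in rec.counts_male)
            f = ":".join(str(c) for c in rec.counts_female)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref_base}\t{m}\t{f}\n")


def read_lengths(path: str | Path) -> dict[str, int]:
    """Read a chromosome-lengths table (first two whitespace-separated columns,
    as in a FASTA ``.fai`` index)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns")
            chrom, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValueError(f"line {lineno}: non-positive length for {chrom}")
            if chrom in lengths:
                raise ValueError(f"line {lineno}: duplicate chromosome {chrom}")
            lengths[chrom] = length
    return lengths


def write_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def _check_sorted(items: Sequence, what: str) -> None:
    keys = [(it.chrom, it.start) for it in items]
    if keys != sorted(keys):
        raise ValueError(f"{what} must be sorted by (chrom, start)")


def write_windows_tsv(windows: Sequence, path: str | Path) -> None:
    """Write window statistics as a TSV with a fixed header.

    ``depth_ratio`` and ``fst`` print as ``NA`` when undefined.  Input must be
    sorted by (chrom, start); empty input yields a header-only file.
    """
    _check_sorted(windows, "windows")
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_TSV_COLUMNS) + "\n")
        for w in windows:
            def fmt(v):
                return "NA" if v is None else f"{v:.6g}"
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t"
                f"{w.mean_depth_male:.6g}\t{w.mean_depth_female:.6g}\t"
                f"{fmt(w.rel_depth_male)}\t{fmt(w.rel_depth_female)}\t"
                f"{fmt(w.depth_ratio)}\t{w.fst:.6g}\t{w.n_fspec}\t{w.n_mspec}\n"
            )


def read_windows_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(WINDOW_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"windows TSV missing columns: {sorted(missing)}")
    return df


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write region calls as BED (0-based half-open), label in column 4 and a
    score column = mean window F_ST scaled to [0, 1000]."""
    _check_sorted(regions, "regions")
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(min(max(r.mean_fst, 0.0), 1.0) * 1000))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 4+ column BED into a frame with chrom/start/end/label columns."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError("expected >=4 BED columns (chrom start end name)")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def read_markers_tsv(path: str | Path) -> pd.DataFrame:
    """Read a linkage-marker table (lg, marker_id, chrom, pos_bp, cm_female,
    cm_male); pos_bp is 1-based, missing placements allowed."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    if (df["cm_female"].dropna() < 0).any() or (df["cm_male"].dropna() < 0).any():
        raise ValueError("cM positions must be non-negative")
    return df


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene table with expression columns; start/end are 1-based
    inclusive on disk and converted to 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj must lie in [0, 1]")
    return df


def read_karyotype_tsv(path: str | Path) -> pd.DataFrame:
    """Read karyotype measurements: chrom, mean_um (mean chromosome size in
    micrometres), optionally assembled_bp."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "mean_um" not in df.columns:
        raise ValueError("karyotype table needs chrom and mean_um columns")
    if (df["mean_um"] <= 0).any():
        raise ValueError("mean_um must be positive")
    return df
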