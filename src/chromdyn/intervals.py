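"""Genomic interval algebra, binning, and text-format readers/writers.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; TSS positions in annotation files are declared 0-based.  Chromosome
sizes come from a two-column TSV (name, length) so clamping and bin counts
never require a sequence parse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "DEFAULT_STAGES",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_gene_annotation",
    "read_bedgraph",
    "bin_bedgraph",
    "bedgraph_coverage",
    "promoter_window",
    "overlap_length",
]

#: Default differentiation axis: pluripotent stem cell -> vascular mesoderm
#: -> endothelial progenitor -> hematopoietic progenitor.
DEFAULT_STAGES: tuple = ("hPSC", "VME", "EPC", "HPC")


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SignalTrack:
    """Per-chromosome vectors of per-bin summed signal.

    ``data[chrom][i]`` is the sum of (value x overlapping bases) of all
    bedGraph records falling in bin ``[i*bin_size, (i+1)*bin_size)``.
    """

    data: Dict[str, np.ndarray]
    bin_size: int

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def concatenated(self, chroms: Sequence[str] | None = None) -> np.ndarray:
        chroms = list(self.data) if chroms is None else list(chroms)
        return np.concatenate([self.data[c] for c in chroms])


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6; columns beyond 6 are ignored, track/browser lines skipped."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: malformed coordinate"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: malformed score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)
            )
    return intervals


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path, bed6: bool = False) -> None:
    """Write intervals as BED; BED6 columns are emitted when any interval
    carries a name/score/strand or when ``bed6`` is forced."""
    intervals = list(intervals)
    need6 = bed6 or any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if need6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name or '.'}\t{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# small TSV readers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column TSV (name, length) -> ordered dict of chromosome sizes."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}: line {lineno}: need name and length")
            name, length = parts[0], int(parts[1])
            if length <= 0:
                raise BedParseError(f"{path}: line {lineno}: non-positive length")
            sizes[name] = length
    return sizes


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV with header: gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    if (df["tss"] < 0).any():
        raise ValueError(f"{path}: negative TSS")
    return df


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph -> DataFrame(chrom, start, end, value), track lines skipped."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    mask = df["chrom"].str.startswith(("track", "browser"))
    if mask.any():
        df = df[~mask].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        bad = df[(df["start"] >= df["end"]) | (df["start"] < 0)].index[0]
        raise BedParseError(f"{path}: record {bad}: invalid interval")
    return df


def bin_bedgraph(path, bin_size: int, chrom_sizes: Mapping[str, int]) -> SignalTrack:
    """Bin a bedGraph into per-``bin_size`` sums of (value x overlapping bases).

    Mass is conserved: the sum over all bins equals the sum over records of
    value x length.  Records extending past a chromosome end are an error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = path if isinstance(path, pd.DataFrame) else read_bedgraph(path)
    unknown = set(df["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"bedGraph chromosome(s) {sorted(unknown)} not in chrom sizes")
    data: Dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = math.ceil(size / bin_size)
        sub = df[df["chrom"] == chrom]
        if len(sub) and int(sub["end"].max()) > size:
            raise ValueError(f"record beyond end of {chrom} (size {size})")
        # per-base painting by difference array, then block sums per bin
        diff = np.zeros(size + 1)
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        np.add.at(diff, starts, vals)
        np.add.at(diff, ends, -vals)
        per_base = np.cumsum(diff[:-1])
        if bin_size == 1:
            data[chrom] = per_base
        else:
            edges = np.arange(0, size, bin_size)
            data[chrom] = (
                np.add.reduceat(per_base, edges) if size else np.zeros(n_bins)
            )
    return SignalTrack(data=data, bin_size=bin_size)


def bedgraph_coverage(
    records: pd.DataFrame, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Sum of (value x overlapping bases) of bedGraph records per interval.

    Intervals must be disjoint per chromosome.  Records are assumed short
    relative to the gaps between intervals (each record is matched against
    the interval containing its start and the next one), which holds for the
    binned and per-base tracks this package produces.
    """
    out = np.zeros(len(intervals))
    by_chrom: Dict[str, List[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx_arr = np.array(idx)
        starts = np.array([intervals[i].start for i in idx])
        ends = np.array([intervals[i].end for i in idx])
        order = np.argsort(starts)
        starts, ends, idx_arr = starts[order], ends[order], idx_arr[order]
        sub = records[records["chrom"] == chrom]
        if not len(sub):
            continue
        r_start = sub["start"].to_numpy()
        r_end = sub["end"].to_numpy()
        r_val = sub["value"].to_numpy()
        pos = np.searchsorted(starts, r_start, side="right") - 1
        for cand in (pos, pos + 1):
            ok = (cand >= 0) & (cand < len(starts))
            if not ok.any():
                continue
            ov = np.zeros(len(sub))
            ov[ok] = np.minimum(r_end[ok], ends[cand[ok]]) - np.maximum(
                r_start[ok], starts[cand[ok]]
            )
            ov = np.clip(ov, 0, None)
            np.add.at(out, idx_arr[np.clip(cand, 0, len(starts) - 1)], ov * r_val)
    return out


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def promoter_window(
    chrom: str,
    tss: int,
    chrom_sizes: Mapping[str, int],
    flank: int = 2500,
) -> GenomicInterval:
    """Promoter window ``[tss - flank, tss + flank)`` clamped to the
    chromosome; symmetric, so strand never changes the window."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if chrom not in chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    size = chrom_sizes[chrom]
    start = max(0, tss - flank)
    end = min(size, tss + flank)
    return GenomicInterval(chrom, start, end)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp of two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))
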