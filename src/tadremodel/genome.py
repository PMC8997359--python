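"""Genomic coordinate primitives: intervals, bin tables, and interval I/O.

All coordinates are 0-based, half-open internally. BED and bedGraph are
native; GFF3 (1-based, closed) is converted at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "BinTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_genes_bed12",
    "read_genes_gff3",
    "merge_intervals",
    "overlaps_any",
    "tss_positions",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BinTable:
    """An ordered, chromosome-tiling partition of the genome into bins.

    Bins within a chromosome are adjacent and sorted. ``kind`` is "uniform"
    (fixed ``resolution``, short last bin allowed) or "fragment"
    (restriction-fragment derived, variable widths).
    """

    def __init__(self, df: pd.DataFrame, kind: str = "uniform",
                 resolution: int | None = None):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"bin table needs columns {sorted(required)}")
        df = df[["chrom", "start", "end"]].reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df
        if kind not in ("uniform", "fragment"):
            raise ValueError(f"unknown bin table kind {kind!r}")
        self.kind = kind
        self.resolution = int(resolution) if resolution else None
        self._ranges: dict[str, tuple[int, int]] = {}
        lo = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0:
                raise ValueError(f"{chrom}: first bin must start at 0")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: bins must tile without gaps")
            self._ranges[chrom] = (lo, lo + len(sub))
            lo += len(sub)
        if lo != len(df):
            raise ValueError("bins of one chromosome must be contiguous rows")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_uniform(cls, chromsizes: dict[str, int], resolution: int) -> "BinTable":
        rows = []
        for chrom, size in chromsizes.items():
            edges = list(range(0, int(size), int(resolution))) + [int(size)]
            for s, e in zip(edges[:-1], edges[1:]):
                rows.append((str(chrom), s, e))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                   kind="uniform", resolution=resolution)

    # -- basic queries ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._ranges)

    @property
    def chromsizes(self) -> dict[str, int]:
        return {c: int(self.df["end"].iloc[hi - 1])
                for c, (lo, hi) in self._ranges.items()}

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        return self._ranges[str(chrom)]

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._ranges[str(chrom)]
        return slice(lo, hi)

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def median_width(self) -> float:
        return float(np.median(self.widths()))

    def interval(self, i: int) -> GenomicInterval:
        row = self.df.iloc[int(i)]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        lo, hi = self._ranges[str(chrom)]
        ends = self.df["end"].to_numpy()[lo:hi]
        i = int(np.searchsorted(ends, pos, side="right"))
        if i >= hi - lo:
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        return lo + i

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and len(self.df) == len(other.df)
            and (self.df.values == other.df.values).all()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"BinTable({self.n_bins} bins, {len(self.chroms)} chroms, "
                f"kind={self.kind!r})")


# ---------------------------------------------------------------------------
# interval table I/O (pandas-backed BED / bedGraph)
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    df.columns = _BED_COLS[: len(df.columns)] + list(df.columns[6:])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into a (chrom, start, end, value) DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str},
                     names=["chrom", "start", "end", "value"])
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False,
        float_format="%.6g")


def read_genes_bed12(path) -> pd.DataFrame:
    """Read gene models from BED12 (gene body = thick interval columns 1-2)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    genes = pd.DataFrame({
        "gene_id": df[3].astype(str),
        "chrom": df[0].astype(str),
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
        "strand": df[5].astype(str),
    })
    return genes


def read_genes_gff3(path) -> pd.DataFrame:
    """Extract gene records from a GFF3 file (1-based closed -> 0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


# ---------------------------------------------------------------------------
# interval algebra (sorted, per-chromosome, numpy searchsorted based)
# ---------------------------------------------------------------------------

def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cs, ce = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each query interval overlap any subject interval?

    ``subject`` is merged internally, so overlapping subjects are allowed.
    """
    hit = np.zeros(len(query), dtype=bool)
    if len(subject) == 0 or len(query) == 0:
        return hit
    subj = merge_intervals(subject)
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in subj.groupby("chrom", sort=False)}
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for chrom, (ss, se) in by_chrom.items():
        sel = np.flatnonzero(qc == chrom)
        if sel.size == 0:
            continue
        # rightmost subject starting before query end; overlap iff it ends
        # after query start (subjects are disjoint and sorted)
        idx = np.searchsorted(ss, qe[sel], side="left") - 1
        ok = idx >= 0
        ok[ok] &= se[idx[ok]] > qs[sel[ok]]
        hit[sel[ok]] = True
    return hit


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware transcription start positions for a gene table."""
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)
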