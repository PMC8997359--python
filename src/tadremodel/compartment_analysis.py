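"""A/B compartment calling, switch detection, saddle plots and strength.

Compartments are the leading eigenvector of the per-chromosome Pearson
correlation matrix of the observed/expected contact map, with the sign
oriented so that it correlates positively with GC content (A = positive,
B = negative). The saddle grid averages observed/expected contact
enrichment between eigenvector percentile groups; compartment strength is
the ratio of homotypic to heterotypic corner means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_matrix import ContactMatrix, aggregate, balance, expected_profile
from .genome import BinTable

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "compartment_eigenvector",
    "detect_switches",
    "saddle",
]

COMPARTMENT_RESOLUTION = 10_000
EXCLUDE_CHROMS = ("4", "Y", "chr4", "chrY")
MIN_BINS = 20
SADDLE_BINS = 30
SADDLE_TRIM = (0.025, 0.975)
CORNER = 10


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector, GC fraction, and A/B label."""

    bin_table: BinTable
    e1: np.ndarray       # NaN where masked
    gc: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        """Per-bin label "A" (e1 > 0), "B" (e1 < 0), or "" (masked)."""
        lab = np.where(self.e1 > 0, "A", np.where(self.e1 < 0, "B", ""))
        lab[~np.isfinite(self.e1)] = ""
        return lab

    def to_bedgraph_frame(self) -> pd.DataFrame:
        df = self.bin_table.df.copy()
        df["value"] = self.e1
        return df.dropna(subset=["value"])


@dataclass
class SaddleResult:
    matrix: np.ndarray   # n_bins x n_bins mean O/E grid, B-to-A order
    strength: float


def _oe_dense_chrom(m: ContactMatrix, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Dense O/E map and validity mask for one chromosome of a balanced matrix."""
    lo, hi = m.bin_table.chrom_range(chrom)
    n = hi - lo
    c = m.dense(chrom=chrom, balanced=True)
    prof = expected_profile(m).profiles[chrom]
    offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp = prof[offs]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, c / exp, np.nan)
    valid = m.mask()[lo:hi] & (c.sum(axis=1) > 0)
    return oe, valid


def compartment_eigenvector(m: ContactMatrix, gc: np.ndarray,
                            resolution: int = COMPARTMENT_RESOLUTION,
                            exclude: tuple[str, ...] = EXCLUDE_CHROMS,
                            ) -> CompartmentTrack:
    """Leading eigenvector of the O/E Pearson-correlation map, GC-oriented.

    ``gc`` is the per-bin GC fraction aligned to the matrix bins (after
    aggregation to ``resolution``). Chromosomes in ``exclude`` or with
    fewer than 20 unmasked bins are masked.
    """
    mm = m
    bt = m.bin_table
    if not (bt.kind == "uniform" and bt.resolution == resolution):
        mm = balance(aggregate(m, resolution))
    elif m.weights is None:
        mm = balance(m)
    bt = mm.bin_table
    gc = np.asarray(gc, dtype=float)
    if gc.size != bt.n_bins:
        raise ValueError("gc vector does not align with the bin table")
    e1 = np.full(bt.n_bins, np.nan)
    for chrom in bt.chroms:
        lo, hi = bt.chrom_range(chrom)
        if chrom in exclude:
            continue
        oe, valid = _oe_dense_chrom(mm, chrom)
        sub = oe[np.ix_(valid, valid)]
        sub = np.nan_to_num(sub, nan=1.0)
        # constant rows break Pearson correlation
        sd = sub.std(axis=1)
        good = sd > 0
        if good.sum() < MIN_BINS:
            warnings.warn(f"{chrom}: fewer than {MIN_BINS} usable bins; masked")
            continue
        idx = np.flatnonzero(valid)[good]
        corr = np.corrcoef(sub[np.ix_(good, good)])
        vals, vecs = np.linalg.eigh(corr)
        v = vecs[:, -1]
        v = v * np.sqrt(max(vals[-1], 0.0))
        gsub = gc[lo:hi][idx - lo]
        if np.std(gsub) > 0 and np.std(v) > 0:
            if np.corrcoef(gsub, v)[0, 1] < 0:
                v = -v
        e1[idx] = v
    return CompartmentTrack(bt, e1, gc)


def detect_switches(a: CompartmentTrack, b: CompartmentTrack
                    ) -> tuple[np.ndarray, float]:
    """Per-bin compartment switch labels and the genome-wide switch fraction."""
    if a.bin_table != b.bin_table:
        raise ValueError("compartment tracks are on different bin tables")
    la, lb = a.labels, b.labels
    both = (la != "") & (lb != "")
    lab = np.full(la.size, "masked", dtype=object)
    lab[both] = [f"{x}→{y}" for x, y in zip(la[both], lb[both])]
    switched = both & (la != lb)
    frac = float(switched.sum() / both.sum()) if both.any() else 0.0
    return lab, frac


def saddle(m: ContactMatrix, t: CompartmentTrack, n_bins: int = SADDLE_BINS,
           trim: tuple[float, float] = SADDLE_TRIM,
           corner: int = CORNER) -> SaddleResult:
    """Saddle grid of mean O/E between eigenvector percentile groups.

    Bins are ranked by e1 (after trimming to the ``trim`` quantile
    interval) into ``n_bins`` percentile groups, B-most first. Cell (p, q)
    is the mean intra-chromosomal O/E between groups p and q. Strength is
    mean(AA corner, BB corner) / mean(AB, BA corners) over ``corner``-sized
    corner blocks of the nonnormalized grid.
    """
    mm = m
    bt = m.bin_table
    if not (bt.kind == "uniform" and bt.resolution == t.bin_table.resolution):
        mm = balance(aggregate(m, t.bin_table.resolution))
    elif m.weights is None:
        mm = balance(m)
    if mm.bin_table != t.bin_table:
        raise ValueError("matrix and compartment track bin tables differ")
    finite = np.isfinite(t.e1)
    if finite.sum() < n_bins:
        raise ValueError("fewer unmasked bins than saddle groups")
    lo_q, hi_q = np.quantile(t.e1[finite], trim)
    keep = finite & (t.e1 >= lo_q) & (t.e1 <= hi_q)
    ranks = np.full(t.e1.size, -1)
    kept_vals = t.e1[keep]
    order = np.argsort(kept_vals, kind="stable")
    group = np.empty(order.size, dtype=np.int64)
    group[order] = np.minimum((np.arange(order.size) * n_bins) // order.size,
                              n_bins - 1)
    ranks[np.flatnonzero(keep)] = group
    num = np.zeros((n_bins, n_bins))
    den = np.zeros((n_bins, n_bins))
    for chrom in mm.bin_table.chroms:
        lo, hi = mm.bin_table.chrom_range(chrom)
        r = ranks[lo:hi]
        sel = r >= 0
        if sel.sum() < 2:
            continue
        oe, valid = _oe_dense_chrom(mm, chrom)
        sel &= valid
        if sel.sum() < 2:
            continue
        sub = oe[np.ix_(sel, sel)]
        g = r[sel]
        okmat = np.isfinite(sub)
        sub = np.nan_to_num(sub)
        for p in range(n_bins):
            rows = g == p
            if not rows.any():
                continue
            num[p] += np.bincount(g, weights=sub[rows].sum(axis=0),
                                  minlength=n_bins)
            den[p] += np.bincount(g, weights=okmat[rows].sum(axis=0),
                                  minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    c = min(corner, n_bins // 2)
    bb = np.nanmean(grid[:c, :c])
    aa = np.nanmean(grid[-c:, -c:])
    ab = np.nanmean(grid[:c, -c:])
    ba = np.nanmean(grid[-c:, :c])
    strength = float(np.mean([aa, bb]) / np.mean([ab, ba]))
    return SaddleResult(grid, strength)
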