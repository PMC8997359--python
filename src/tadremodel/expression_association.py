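"""TAD reorganization versus differential gene expression.

Splits the genome into segments by the union of WT and knockdown borders,
classifies each segment by how far the borders of its containing WT TAD
moved, tests enrichment of differentially expressed genes in reorganized
TADs by region permutation, and flags housekeeping genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, merge_intervals
from .tad_analysis import Border, FUZZY_TOL

__all__ = [
    "TadRegionClass",
    "PermutationResult",
    "apply_deg_thresholds",
    "classify_tad_regions",
    "permutation_overlap_test",
    "call_housekeeping",
    "deg_border_span_check",
]

DEG_PADJ = 0.05
DEG_LOG2FC = 2.0
N_PERM = 1000
HK_PERCENTILE = 40


@dataclass
class TadRegionClass:
    region: GenomicInterval
    region_class: str  # conserved_two | conserved_one | kd_specific | fuzzy | unassigned


@dataclass
class PermutationResult:
    observed: int
    null_draws: np.ndarray
    pvalue: float
    z: float

    @property
    def n_perm(self) -> int:
        return len(self.null_draws)


def apply_deg_thresholds(deg: pd.DataFrame, padj: float = DEG_PADJ,
                         log2fc: float = DEG_LOG2FC) -> pd.DataFrame:
    """(Re)derive the up/down/not-DE status column from padj and log2FC."""
    out = deg.copy()
    up = (out["padj"] <= padj) & (out["log2fc"] >= log2fc)
    down = (out["padj"] <= padj) & (out["log2fc"] <= -log2fc)
    out["status"] = np.where(up, "up", np.where(down, "down", "not-DE"))
    return out


# ---------------------------------------------------------------------------
# TAD-relative region classes
# ---------------------------------------------------------------------------

def _border_positions(borders: list[Border], chrom: str) -> np.ndarray:
    return np.sort(np.array([b.midpoint for b in borders if b.chrom == chrom],
                            dtype=np.int64))


def classify_tad_regions(wt_borders: list[Border], kd_borders: list[Border],
                         chromsizes: dict[str, int],
                         fuzzy_tol: int = FUZZY_TOL,
                         same_tol: int = 600) -> list[TadRegionClass]:
    """Class of every genome segment by the movement of its WT TAD borders.

    The genome is split at the union of WT and knockdown border positions.
    Each segment inherits the displacement of the two borders of the WT TAD
    containing it: both within ``same_tol`` -> conserved_two; exactly one
    moved beyond ``fuzzy_tol`` -> conserved_one; both beyond -> kd_specific;
    both moved but within ``fuzzy_tol`` -> fuzzy. Segments outside any WT
    TAD (chromosome ends) are "unassigned". Because called positions are
    quantized to bins, displacements are compared against
    max(fuzzy_tol, same_tol), never finer than one bin.
    """
    out: list[TadRegionClass] = []
    big_tol = max(fuzzy_tol, same_tol)
    for chrom, size in chromsizes.items():
        wt_pos = _border_positions(wt_borders, chrom)
        kd_pos = _border_positions(kd_borders, chrom)
        cuts = np.unique(np.concatenate([[0], wt_pos, kd_pos, [size]]))
        if wt_pos.size < 2:
            for s, e in zip(cuts[:-1], cuts[1:]):
                out.append(TadRegionClass(GenomicInterval(chrom, int(s), int(e)),
                                          "unassigned"))
            continue

        def displacement(pos: int) -> float:
            if kd_pos.size == 0:
                return np.inf
            return float(np.min(np.abs(kd_pos - pos)))

        disp = {int(p): displacement(int(p)) for p in wt_pos}
        for s, e in zip(cuts[:-1], cuts[1:]):
            mid = (s + e) // 2
            i = np.searchsorted(wt_pos, mid)
            if i == 0 or i == wt_pos.size:
                out.append(TadRegionClass(GenomicInterval(chrom, int(s), int(e)),
                                          "unassigned"))
                continue
            d1, d2 = disp[int(wt_pos[i - 1])], disp[int(wt_pos[i])]
            big1, big2 = d1 > big_tol, d2 > big_tol
            moved1, moved2 = d1 > same_tol, d2 > same_tol
            if big1 and big2:
                cls = "kd_specific"
            elif big1 or big2:
                cls = "conserved_one"
            elif not moved1 and not moved2:
                cls = "conserved_two"
            else:
                cls = "fuzzy"
            out.append(TadRegionClass(GenomicInterval(chrom, int(s), int(e)), cls))
    return out


def regions_frame(classes: list[TadRegionClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.region.chrom, c.region.start, c.region.end, c.region_class)
         for c in classes],
        columns=["chrom", "start", "end", "class"])


# ---------------------------------------------------------------------------
# permutation overlap test (regioneR-style randomizeRegions analogue)
# ---------------------------------------------------------------------------

def permutation_overlap_test(deg_regions: pd.DataFrame,
                             target_regions: pd.DataFrame,
                             universe: pd.DataFrame,
                             n_perm: int = N_PERM,
                             seed: int = 0,
                             alternative: str = "greater") -> PermutationResult:
    """Permutation test of region-set overlap.

    ``observed`` is the number of ``deg_regions`` overlapping any target.
    Each permutation redraws every region's start uniformly within its
    chromosome's universe span, preserving width and chromosome. p-value is
    (1 + #{null >= observed}) / (1 + n_perm) (upper tail; set
    ``alternative="less"`` for depletion).
    """
    rng = np.random.default_rng(seed)
    targets = merge_intervals(target_regions) if len(target_regions) else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    uni = {r["chrom"]: (int(r["start"]), int(r["end"]))
           for _, r in merge_intervals(universe).iterrows()}
    tgt = {c: (g["start"].to_numpy(), g["end"].to_numpy())
           for c, g in targets.groupby("chrom", sort=False)}

    def count_overlaps(chroms, starts, ends) -> np.ndarray:
        """Per-row boolean overlap against the (disjoint, sorted) targets."""
        hit = np.zeros(starts.shape, dtype=bool)
        for c, (ts, te) in tgt.items():
            sel = chroms == c
            if not sel.any():
                continue
            idx = np.searchsorted(ts, ends[sel], side="left") - 1
            ok = idx >= 0
            ok &= np.where(ok, te[np.maximum(idx, 0)] > starts[sel], False)
            h = np.zeros(sel.sum(), dtype=bool)
            h[ok] = True
            hit[sel] = h
        return hit

    chroms = deg_regions["chrom"].to_numpy()
    starts = deg_regions["start"].to_numpy(dtype=np.int64)
    ends = deg_regions["end"].to_numpy(dtype=np.int64)
    widths = ends - starts
    for c, s, e in zip(chroms, starts, ends):
        if c not in uni or s < uni[c][0] or e > uni[c][1]:
            raise ValueError(f"region {c}:{s}-{e} outside the universe")
        if e - s > uni[c][1] - uni[c][0]:
            raise ValueError(f"region wider than its chromosome universe: {c}")
    observed = int(count_overlaps(chroms, starts, ends).sum())

    n = len(deg_regions)
    lo = np.array([uni[c][0] for c in chroms], dtype=np.int64)
    span = np.array([uni[c][1] - uni[c][0] for c in chroms], dtype=np.int64)
    max_start = span - widths
    null = np.empty(n_perm, dtype=np.int64)
    # vectorized across regions; loop over permutations (cheap per draw)
    chrom_tiled = chroms
    for k in range(int(n_perm)):
        s = lo + (rng.random(n) * (max_start + 1)).astype(np.int64)
        null[k] = count_overlaps(chrom_tiled, s, s + widths).sum()
    if alternative == "greater":
        tail = int((null >= observed).sum())
    else:
        tail = int((null <= observed).sum())
    pvalue = (1 + tail) / (1 + n_perm)
    sd = null.std()
    z = float((observed - null.mean()) / sd) if sd > 0 else 0.0
    return PermutationResult(observed, null, float(pvalue), z)


# ---------------------------------------------------------------------------
# housekeeping genes and border-spanning DEGs
# ---------------------------------------------------------------------------

def call_housekeeping(expr: pd.DataFrame, percentile: float = HK_PERCENTILE
                      ) -> set[str]:
    """Genes whose expression is in the top ``percentile`` % in every sample.

    ``expr`` is a genes x samples table indexed by gene identifier. Genes
    with a missing value in any sample are excluded (with a warning).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    missing = expr.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes with missing values excluded")
    x = expr.loc[~missing]
    if x.empty:
        return set()
    # top `percentile`% per sample: rank fraction >= 1 - percentile/100
    frac = x.rank(axis=0, pct=True, method="max")
    keep = (frac >= 1 - percentile / 100).all(axis=1)
    return set(x.index[keep].astype(str))


def deg_border_span_check(deg: pd.DataFrame, genes: pd.DataFrame,
                          borders: list[Border]) -> pd.DataFrame:
    """Differentially expressed genes whose body straddles a TAD border."""
    de_ids = set(deg.loc[deg["status"].isin(["up", "down"]),
                         "gene_id"].astype(str))
    sub = genes[genes["gene_id"].astype(str).isin(de_ids)]
    if sub.empty:
        return sub
    hits = []
    for _, g in sub.iterrows():
        for b in borders:
            if b.chrom == g["chrom"] and g["start"] < b.midpoint < g["end"] - 1:
                hits.append(g)
                break
    return pd.DataFrame(hits, columns=genes.columns)
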