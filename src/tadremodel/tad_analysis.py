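"""TAD-separation (insulation) scoring and border analysis.

The TAD-separation score of a bin is the mean corrected contact count in
the diamond window spanning the bins immediately upstream and downstream,
z-scored per chromosome and averaged across window sizes. Local minima of
the score are border candidates; a two-tier delta threshold (0.04 weak /
0.08 strong by default) and a BH-corrected rank-sum test of inter-domain
versus intra-domain contacts decide which candidates become borders.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contact_matrix import ContactMatrix
from .genome import BinTable, GenomicInterval

__all__ = [
    "InsulationTrack",
    "Border",
    "BorderComparison",
    "DirectnessCall",
    "insulation_score",
    "call_borders",
    "robust_borders",
    "classify_borders",
    "intersect_status",
    "annotate_direct",
    "proportion_test",
    "borders_to_bed",
]

DELTA_WEAK = 0.04
DELTA_STRONG = 0.08
BORDER_PVALUE = 0.01
MIN_TAD = 5000
FUZZY_TOL = 2000
DEFAULT_WINDOWS = (10_000, 20_000, 30_000)


@dataclass
class InsulationTrack:
    """Per-bin TAD-separation score (z-scored, averaged over windows)."""

    bin_table: BinTable
    score: np.ndarray  # NaN where undefined
    window_sizes: tuple[int, ...]
    raw: dict[int, np.ndarray] = field(default_factory=dict)  # diamond means

    def to_bedgraph_frame(self) -> pd.DataFrame:
        df = self.bin_table.df.copy()
        df["value"] = self.score
        return df.dropna(subset=["value"])


@dataclass
class Border:
    """A called TAD border (one bin) with its separation statistics."""

    position: GenomicInterval
    bin: int  # global bin index
    score: float
    delta: float
    pvalue: float
    strength: str  # "strong" | "weak"

    @property
    def midpoint(self) -> int:
        return self.position.midpoint

    @property
    def chrom(self) -> str:
        return self.position.chrom


@dataclass
class BorderComparison:
    """Cross-condition status of a WT border (or a knockdown-only border)."""

    wt_border: Border | None
    kd_border: Border | None
    status: str  # maintained | weakened | fuzzy | lost | new
    shift: int | None = None


@dataclass
class DirectnessCall:
    """Whether a border has direct architectural-protein binding."""

    border: Border
    bound_proteins: tuple[str, ...]

    @property
    def direct(self) -> bool:
        return len(self.bound_proteins) > 0


# ---------------------------------------------------------------------------
# insulation score
# ---------------------------------------------------------------------------

def _window_bins(window_bp: int, bin_width: float) -> int:
    return max(2, int(round(window_bp / bin_width)))


def diamond_means(a: np.ndarray, valid: np.ndarray, w: int) -> np.ndarray:
    """Mean contact count in the w x w diamond at each bin of one chromosome.

    The diamond at bin i covers rows i-w..i-1 (upstream) by columns
    i+1..i+w (downstream). NaN where the window does not fit or no valid
    cells remain.
    """
    n = a.shape[0]
    out = np.full(n, np.nan)
    if n < 2 * w + 1:
        return out
    az = np.where(np.outer(valid, valid), a, 0.0)
    vz = np.outer(valid, valid).astype(np.float64)
    # summed-area tables with zero padding
    sa = np.zeros((n + 1, n + 1))
    sv = np.zeros((n + 1, n + 1))
    sa[1:, 1:] = az.cumsum(0).cumsum(1)
    sv[1:, 1:] = vz.cumsum(0).cumsum(1)

    def rect_sum(tab, r0, r1, c0, c1):  # rows [r0,r1), cols [c0,c1)
        return tab[r1, c1] - tab[r0, c1] - tab[r1, c0] + tab[r0, c0]

    idx = np.arange(w, n - w)
    r0, r1 = idx - w, idx
    c0, c1 = idx + 1, idx + 1 + w
    ssum = rect_sum(sa, r0, r1, c0, c1)
    scount = rect_sum(sv, r0, r1, c0, c1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[idx] = np.where(scount > 0, ssum / np.maximum(scount, 1), np.nan)
    return out


def insulation_score(m: ContactMatrix,
                     window_sizes=DEFAULT_WINDOWS) -> InsulationTrack:
    """Multi-window TAD-separation score of a (balanced) contact matrix."""
    bt = m.bin_table
    score = np.full(bt.n_bins, np.nan)
    raw: dict[int, np.ndarray] = {int(w): np.full(bt.n_bins, np.nan)
                                  for w in window_sizes}
    valid_all = m.mask()
    for chrom in bt.chroms:
        lo, hi = bt.chrom_range(chrom)
        a = m.dense(chrom=chrom, balanced=True)
        valid = valid_all[lo:hi]
        width = float(np.median(bt.widths()[lo:hi]))
        ztracks = []
        for wbp in window_sizes:
            w = _window_bins(int(wbp), width)
            dm = diamond_means(a, valid, w)
            raw[int(wbp)][lo:hi] = dm
            ok = np.isfinite(dm)
            z = np.full_like(dm, np.nan)
            sd = dm[ok].std() if ok.sum() >= 2 else 0.0
            # a numerically constant track carries no separation signal
            if sd > 1e-9 * max(1.0, abs(dm[ok].mean())) if ok.any() else False:
                z[ok] = (dm[ok] - dm[ok].mean()) / sd
            elif ok.any():
                z[ok] = 0.0
            ztracks.append(z)
        zs = np.vstack(ztracks)
        any_ok = np.isfinite(zs).any(axis=0)
        with np.errstate(invalid="ignore"):
            score[lo:hi][any_ok] = np.nanmean(zs[:, any_ok], axis=0)
    return InsulationTrack(bt, score, tuple(int(w) for w in window_sizes), raw)


# ---------------------------------------------------------------------------
# border calling
# ---------------------------------------------------------------------------

def _candidate_minima(y: np.ndarray, delta_min: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Local minima of the score with topographic prominence >= delta_min.

    Prominence (depth of a minimum below the lowest crest separating it
    from a deeper minimum) distinguishes one broad insulation valley from
    ripple inside it: secondary dips within a valley have only noise-scale
    prominence. NaN stretches split the track into independent runs.
    """
    from scipy.signal import find_peaks

    mins: list[int] = []
    deltas: list[float] = []
    n = y.size
    finite = np.isfinite(y)
    i = 0
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j < n and finite[j]:
            j += 1
        seg = y[i:j]
        peaks, props = find_peaks(-seg, prominence=delta_min)
        mins.extend(int(p) + i for p in peaks)
        deltas.extend(float(p) for p in props["prominences"])
        i = j
    return np.asarray(mins, dtype=np.int64), np.asarray(deltas)


def _separation_pvalue(a: np.ndarray, valid: np.ndarray, i: int, w: int) -> float:
    """Rank-sum p for contact depletion across candidate border bin i.

    Compares the inter-domain diamond (upstream x downstream) against the
    pooled intra-domain triangles of the two flanks, one-sided (less).
    ``a`` must be distance-normalized (observed/expected), otherwise the
    comparison is confounded by decay: diamond and triangle cells sit at
    different diagonal offsets.
    """
    n = a.shape[0]
    w = min(w, i, n - 1 - i)
    if w < 2:
        return 1.0
    rows = np.arange(i - w, i)
    cols = np.arange(i + 1, i + 1 + w)
    vr, vc = valid[rows], valid[cols]
    inter = a[np.ix_(rows, cols)][np.outer(vr, vc)]
    tri = []
    for block in (rows, cols):
        sub = a[np.ix_(block, block)]
        vv = np.outer(valid[block], valid[block])
        iu = np.triu_indices(len(block), k=1)
        keep = vv[iu]
        tri.append(sub[iu][keep])
    intra = np.concatenate(tri) if tri else np.array([])
    if inter.size < 3 or intra.size < 3:
        return 1.0
    if np.all(inter == inter[0]) and np.all(intra == inter[0]):
        return 1.0
    return float(stats.mannwhitneyu(inter, intra, alternative="less").pvalue)


def call_borders(t: InsulationTrack, m: ContactMatrix,
                 delta_weak: float = DELTA_WEAK,
                 delta_strong: float = DELTA_STRONG,
                 pvalue: float = BORDER_PVALUE,
                 min_tad: int = MIN_TAD) -> list[Border]:
    """Two-tier TAD border calling from an insulation track.

    Candidates are local minima of the score with prominence (score drop
    to the flanking crests) >= ``delta_weak``; delta is that prominence.
    Candidates also need a BH-adjusted rank-sum p <= ``pvalue``; borders
    closer than ``min_tad`` are resolved by keeping the larger delta.
    Strength is "strong" iff delta >= ``delta_strong``.
    """
    from .contact_matrix import expected_profile

    bt = t.bin_table
    valid_all = m.mask()
    prof = expected_profile(m)
    candidates: list[tuple[int, str, float, float, float]] = []
    pvals: list[float] = []
    for chrom in bt.chroms:
        lo, hi = bt.chrom_range(chrom)
        y = t.score[lo:hi]
        minima, prominences = _candidate_minima(y, delta_weak)
        if minima.size == 0:
            continue
        a = m.dense(chrom=chrom, balanced=True)
        n = hi - lo
        pvec = prof.profiles[chrom]
        offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(pvec[offs] > 0, a / pvec[offs], 0.0)
        width = float(np.median(bt.widths()[lo:hi]))
        w = _window_bins(max(t.window_sizes), width)
        valid = valid_all[lo:hi]
        for i, delta in zip(minima, prominences):
            p = _separation_pvalue(a, valid, int(i), w)
            candidates.append((lo + int(i), chrom, float(y[i]), float(delta), p))
            pvals.append(p)
    if not candidates:
        return []
    padj = multipletests(pvals, method="fdr_bh")[1]
    kept = [(g, chrom, s, d, q) for (g, chrom, s, d, _), q
            in zip(candidates, padj) if q <= pvalue]
    # enforce minimum TAD width: among borders closer than min_tad keep the
    # larger delta
    kept.sort(key=lambda r: r[0])
    borders: list[Border] = []
    mids = bt.midpoints()
    for g, chrom, s, d, q in kept:
        if borders and borders[-1].chrom == chrom \
                and mids[g] - mids[borders[-1].bin] < min_tad:
            if d > borders[-1].delta:
                borders.pop()
            else:
                continue
        strength = "strong" if d >= delta_strong else "weak"
        borders.append(Border(bt.interval(g), g, s, d, q, strength))
    # recheck strength after merges
    return borders


# ---------------------------------------------------------------------------
# robustness and cross-condition classification
# ---------------------------------------------------------------------------

def _nearest(border: Border, pool: list[Border]) -> tuple[Border | None, int]:
    """Nearest border on the same chromosome (ties to the leftmost)."""
    best, bd = None, np.iinfo(np.int64).max
    for b in pool:
        if b.chrom != border.chrom:
            continue
        d = abs(b.midpoint - border.midpoint)
        if d < bd or (d == bd and best is not None
                      and b.midpoint < best.midpoint):
            best, bd = b, d
    return best, bd


def robust_borders(full: list[Border], downsampled: list[Border],
                   match_tol: int = FUZZY_TOL) -> list[Border]:
    """Full-data borders recovered at the same strength after down-sampling."""
    out = []
    for b in full:
        same_class = [d for d in downsampled if d.strength == b.strength]
        near, dist = _nearest(b, same_class)
        if near is not None and dist <= match_tol:
            out.append(b)
    return out


def classify_borders(wt: list[Border], kd: list[Border],
                     fuzzy_tol: int = FUZZY_TOL,
                     same_tol: int | None = None) -> list[BorderComparison]:
    """Classify WT strong borders as maintained/weakened/fuzzy/lost and
    detect knockdown-specific (new) strong borders.

    ``wt`` should be the robust strong borders; ``kd`` may contain strong
    and weak borders. Matching is greedy by distance; each knockdown border
    is consumed by at most one WT border. ``same_tol`` defaults to one
    median bin width (minimum 600 bp, mirroring fragment-scale bins).
    """
    for name, lst in (("wt", wt), ("kd", kd)):
        seen = {}
        for b in lst:
            key = (b.chrom, b.bin)
            if key in seen:
                raise ValueError(f"overlapping borders in {name} input at "
                                 f"{b.chrom}:{b.position.start}")
            seen[key] = b
    if same_tol is None:
        widths = [b.position.width for b in wt + kd] or [600]
        same_tol = max(600, int(np.median(widths)))
    wt_strong = [b for b in wt if b.strength == "strong"]
    # matching radius: positional identity can never be finer than one bin,
    # so on coarse grids same_tol may exceed the fuzzy tolerance
    radius = max(fuzzy_tol, same_tol)
    # greedy by distance over all (wt, kd) pairs
    pairs = []
    for iw, w in enumerate(wt_strong):
        for ik, k in enumerate(kd):
            if w.chrom != k.chrom:
                continue
            d = abs(w.midpoint - k.midpoint)
            if d <= radius:
                pairs.append((d, k.midpoint, iw, ik))
    pairs.sort()
    wt_match: dict[int, int] = {}
    kd_used: set[int] = set()
    for d, _, iw, ik in pairs:
        if iw in wt_match or ik in kd_used:
            continue
        wt_match[iw] = ik
        kd_used.add(ik)
    out: list[BorderComparison] = []
    for iw, w in enumerate(wt_strong):
        if iw not in wt_match:
            out.append(BorderComparison(w, None, "lost"))
            continue
        k = kd[wt_match[iw]]
        shift = abs(w.midpoint - k.midpoint)
        if shift <= same_tol and k.strength == "strong":
            out.append(BorderComparison(w, k, "maintained", shift))
        elif shift <= same_tol:
            out.append(BorderComparison(w, k, "weakened", shift))
        else:
            out.append(BorderComparison(w, k, "fuzzy", shift))
    # knockdown-specific strong borders: no WT strong border within radius
    for k in kd:
        if k.strength != "strong":
            continue
        near, dist = _nearest(k, wt_strong)
        if near is None or dist > radius:
            out.append(BorderComparison(None, k, "new"))
    return out


def status_counts(comparisons: list[BorderComparison]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in comparisons:
        counts[c.status] = counts.get(c.status, 0) + 1
    return counts


def intersect_status(a: list[BorderComparison], b: list[BorderComparison],
                     match_tol: int = FUZZY_TOL) -> dict[str, list]:
    """Borders sharing a status in two knockdowns versus the same WT.

    Returns common maintained / lost (keyed by the WT border), common new
    (a's new borders with a matching new border of b within ``match_tol``),
    and the status-discordant WT borders.
    """
    def key(c):
        return (c.wt_border.chrom, c.wt_border.bin)

    b_status = {key(c): c.status for c in b if c.wt_border is not None}
    common = {"maintained": [], "lost": [], "new": [], "discordant": []}
    for c in a:
        if c.wt_border is None:
            continue
        other = b_status.get(key(c))
        if other is None:
            continue
        if c.status == other and c.status in ("maintained", "lost"):
            common[c.status].append(c.wt_border)
        elif c.status != other:
            common["discordant"].append(c.wt_border)
    b_new = [c.kd_border for c in b if c.status == "new"]
    for c in a:
        if c.status != "new":
            continue
        near, dist = _nearest(c.kd_border, b_new)
        if near is not None and dist <= match_tol:
            common["new"].append(c.kd_border)
    return common


# ---------------------------------------------------------------------------
# direct binding and group tests
# ---------------------------------------------------------------------------

KNOWN_PROTEINS = ("BEAF-32", "Cp190", "Chro")


def annotate_direct(borders: list[Border], peaks: dict[str, pd.DataFrame],
                    vicinity: int = 5000,
                    known: tuple[str, ...] | None = None) -> list[DirectnessCall]:
    """Flag borders with >= 1 ChIP peak within ``vicinity``/2 of the border.

    ``peaks`` maps protein name -> BED-like DataFrame (chrom, start, end).
    """
    if known is None:
        known = KNOWN_PROTEINS
    for prot in peaks:
        if prot not in known:
            raise ValueError(f"unknown protein key {prot!r}; expected {known}")
    calls = []
    half = vicinity // 2
    for b in borders:
        bound = []
        for prot, df in peaks.items():
            sub = df[df["chrom"] == b.chrom]
            lo, hi = b.midpoint - half, b.midpoint + half
            if ((sub["start"] < hi) & (sub["end"] > lo)).any():
                bound.append(prot)
        calls.append(DirectnessCall(b, tuple(bound)))
    return calls


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for proportions k1/n1 versus k2/n2."""
    for v in (k1, n1, k2, n2):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if k1 > n1 or k2 > n2:
        raise ValueError("k must not exceed n")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def borders_to_bed(borders: list[Border]) -> pd.DataFrame:
    rows = [(b.chrom, b.position.start, b.position.end, b.strength,
             int(round(b.delta * 1000))) for b in borders]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
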