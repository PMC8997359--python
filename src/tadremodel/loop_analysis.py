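"""Focal chromatin-loop detection and cross-condition comparison.

Loops are called at a fixed resolution (2 kb by default) by comparing each
pixel's corrected count against four local expectation filters (donut,
horizontal, vertical, lower-left), with per-filter Poisson upper-tail
p-values, BH correction, enrichment-factor thresholds, and merging of
nearby significant pixels — the donut-filter scheme of HiCCUPS, with
direct Poisson tails in place of lambda-chunking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, special, stats
from statsmodels.stats.multitest import multipletests

from .contact_matrix import ContactMatrix, aggregate, balance, expected_profile
from .genome import GenomicInterval, overlaps_any, tss_positions

__all__ = [
    "Loop",
    "LoopComparison",
    "LoopAnnotation",
    "call_loops",
    "compare_loops",
    "apa",
    "annotate_loops",
    "deg_at_loops",
    "loops_to_bedpe",
]

LOOP_RESOLUTION = 2000
LOOP_FDR = 0.05
LOOP_WINDOW = 10     # donut outer radius, bins
LOOP_PEAK = 5        # peak (excluded) radius, bins
MERGE_DIST = 20_000  # bp
# HiCCUPS-style threshold vector 0.02, 1.5, 1.75, 2
SINGLETON_QVAL = 0.02
ENRICH_HV = 1.5
ENRICH_DONUT = 1.75
ENRICH_SINGLETON = 2.0


@dataclass
class Loop:
    """A pair of same-chromosome anchors with local enrichment statistics."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    observed: float
    expected_donut: float
    expected_horizontal: float
    expected_vertical: float
    expected_lowerleft: float
    fdr: float

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchor1 must be upstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def size(self) -> int:
        return self.anchor2.midpoint - self.anchor1.midpoint


@dataclass
class LoopComparison:
    wt_loop: Loop
    status: str  # maintained | partial | lost
    kd_loop: Loop | None = None


@dataclass
class LoopAnnotation:
    loop: Loop
    end1_class: str  # P | E | G | O
    end2_class: str

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.end1_class, self.end2_class)))


# ---------------------------------------------------------------------------
# filter kernels
# ---------------------------------------------------------------------------

def _kernels(w: int, p: int) -> dict[str, np.ndarray]:
    """Boolean footprint of each local-expectation filter (center at w, w)."""
    size = 2 * w + 1
    ii, jj = np.mgrid[-w:w + 1, -w:w + 1]
    cheb = np.maximum(np.abs(ii), np.abs(jj))
    donut = (cheb <= w) & (cheb > p) & (ii != 0) & (jj != 0)
    horizontal = (np.abs(ii) <= 1) & (np.abs(jj) > p) & (np.abs(jj) <= w)
    vertical = (np.abs(jj) <= 1) & (np.abs(ii) > p) & (np.abs(ii) <= w)
    lowerleft = (ii > p) & (ii <= w) & (-jj > p) & (-jj <= w)
    return {"donut": donut.astype(float), "horizontal": horizontal.astype(float),
            "vertical": vertical.astype(float), "lowerleft": lowerleft.astype(float)}


def _conv(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    return signal.fftconvolve(a, k[::-1, ::-1], mode="same")


def poisson_sf(obs: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """P(Poisson(mu) >= obs) for real-valued obs (regularized gamma)."""
    obs = np.asarray(obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    p = np.ones_like(mu)
    pos = obs > 0
    p[pos] = special.gammainc(obs[pos], mu[pos])
    return p


def call_loops(m: ContactMatrix, resolution: int = LOOP_RESOLUTION,
               fdr: float = LOOP_FDR, window: int = LOOP_WINDOW,
               peak_width: int = LOOP_PEAK, merge_dist: int = MERGE_DIST,
               max_distance: int = 1_000_000,
               singleton_qval: float = SINGLETON_QVAL,
               enrich_hv: float = ENRICH_HV,
               enrich_donut: float = ENRICH_DONUT,
               enrich_singleton: float = ENRICH_SINGLETON) -> list[Loop]:
    """Call focal contact peaks (loops) on a balanced matrix.

    A pixel is a peak iff all four BH-adjusted Poisson p-values are <= fdr
    and the observed corrected count exceeds the donut/lower-left
    expectations by ``enrich_donut`` and the horizontal/vertical ones by
    ``enrich_hv``. Significant pixels within ``merge_dist`` are merged to
    the pixel with the smallest combined q-value; singleton clusters are
    kept only when clearly supported — q <= ``singleton_qval`` or observed
    >= ``enrich_singleton`` x the donut and lower-left expectations.
    """
    bt = m.bin_table
    if bt.kind == "uniform" and bt.resolution is not None \
            and resolution % bt.resolution != 0:
        raise ValueError("resolution must be a multiple of the bin width")
    mm = m
    if not (bt.kind == "uniform" and bt.resolution == resolution):
        mm = balance(aggregate(m, resolution))
    elif m.weights is None:
        mm = balance(m)
    prof = expected_profile(mm)
    kern = _kernels(window, peak_width)
    loops: list[Loop] = []
    maxd = max(1, int(max_distance // resolution))
    for chrom in mm.bin_table.chroms:
        lo, hi = mm.bin_table.chrom_range(chrom)
        n = hi - lo
        if n < 2 * window + 2:
            continue
        c = mm.dense(chrom=chrom, balanced=True)
        valid = mm.mask()[lo:hi]
        pvec = prof.profiles[chrom]
        offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        e = pvec[offs] * np.outer(valid, valid)
        convs = {name: (_conv(c, k), _conv(e, k)) for name, k in kern.items()}
        iu, ju = np.triu_indices(n, k=window + 1)
        band = (ju - iu) <= maxd
        iu, ju = iu[band], ju[band]
        # candidates: nonzero observed pixels away from the matrix edge
        obs = c[iu, ju]
        inbounds = (iu >= window) & (ju >= window) \
            & (iu < n - window) & (ju < n - window)
        cand = (obs > 0) & inbounds & (e[iu, ju] > 0)
        if not cand.any():
            continue
        iu, ju, obs = iu[cand], ju[cand], obs[cand]
        exp = {}
        pv = {}
        ok = np.ones(obs.size, dtype=bool)
        for name, (cc, ce) in convs.items():
            num, den = cc[iu, ju], ce[iu, ju]
            lam = np.where(den > 0, e[iu, ju] * num / np.maximum(den, 1e-300),
                           np.inf)
            exp[name] = lam
            pv[name] = poisson_sf(obs, lam)
            ok &= np.isfinite(lam)
        qv = {name: multipletests(p, method="fdr_bh")[1]
              for name, p in pv.items()}
        qmax = np.maximum.reduce(list(qv.values()))
        sig = ok & (qmax <= fdr) \
            & (obs > enrich_donut * exp["donut"]) \
            & (obs > enrich_donut * exp["lowerleft"]) \
            & (obs > enrich_hv * exp["horizontal"]) \
            & (obs > enrich_hv * exp["vertical"])
        if not sig.any():
            continue
        si, sj, so = iu[sig], ju[sig], obs[sig]
        sq = qmax[sig]
        sed, seh, sev, sel = (exp["donut"][sig], exp["horizontal"][sig],
                              exp["vertical"][sig], exp["lowerleft"][sig])
        # cluster significant pixels within merge_dist (Chebyshev, bp)
        mergeb = max(1, int(merge_dist // resolution))
        order = np.argsort(sq)
        assigned = np.full(si.size, -1)
        clusters: list[list[int]] = []
        for idx in order:
            placed = False
            for ci, members in enumerate(clusters):
                if any(max(abs(si[idx] - si[k]), abs(sj[idx] - sj[k])) <= mergeb
                       for k in members):
                    members.append(idx)
                    assigned[idx] = ci
                    placed = True
                    break
            if not placed:
                assigned[idx] = len(clusters)
                clusters.append([idx])
        bt2 = mm.bin_table
        for members in clusters:
            rep = members[0]  # smallest q (insertion ordered by q)
            if len(members) == 1:
                strong = (so[rep] >= enrich_singleton * sed[rep]
                          and so[rep] >= enrich_singleton * sel[rep])
                if sq[rep] > singleton_qval and not strong:
                    continue
            loops.append(Loop(
                bt2.interval(lo + si[rep]), bt2.interval(lo + sj[rep]),
                float(so[rep]), float(sed[rep]), float(seh[rep]),
                float(sev[rep]), float(sel[rep]), float(sq[rep])))
    loops.sort(key=lambda L: (L.chrom, L.anchor1.start, L.anchor2.start))
    return loops


# ---------------------------------------------------------------------------
# comparison and APA
# ---------------------------------------------------------------------------

def compare_loops(wt: list[Loop], kd: list[Loop],
                  anchor_tol: int = LOOP_RESOLUTION) -> list[LoopComparison]:
    """Maintained / partially maintained / lost status of each WT loop.

    A WT anchor is maintained if some knockdown loop has an anchor within
    ``anchor_tol``; both anchors -> maintained, exactly one -> partial,
    none -> lost. Knockdown loops are consumed greedily by total anchor
    distance.
    """
    cand = []
    for iw, w in enumerate(wt):
        for ik, k in enumerate(kd):
            if w.chrom != k.chrom:
                continue
            d1 = abs(w.anchor1.midpoint - k.anchor1.midpoint)
            d2 = abs(w.anchor2.midpoint - k.anchor2.midpoint)
            n_match = (d1 <= anchor_tol) + (d2 <= anchor_tol)
            if n_match:
                cand.append((-n_match, d1 + d2, iw, ik))
    cand.sort()
    wt_hit: dict[int, tuple[int, int]] = {}
    kd_used: set[int] = set()
    for negn, _, iw, ik in cand:
        if iw in wt_hit or ik in kd_used:
            continue
        wt_hit[iw] = (ik, -negn)
        kd_used.add(ik)
    out = []
    for iw, w in enumerate(wt):
        if iw not in wt_hit:
            out.append(LoopComparison(w, "lost"))
        else:
            ik, n_match = wt_hit[iw]
            status = "maintained" if n_match == 2 else "partial"
            out.append(LoopComparison(w, status, kd[ik]))
    return out


def apa(m: ContactMatrix, loops: list[Loop], resolution: int = LOOP_RESOLUTION,
        halfwidth: int = 15) -> tuple[np.ndarray, float]:
    """Aggregate peak analysis: mean O/E submatrix around loop pixels.

    Returns the (2*halfwidth+1)-square APA matrix and the center score
    (center value over the mean of the lower-left corner block).
    """
    mm = m
    bt = m.bin_table
    if not (bt.kind == "uniform" and bt.resolution == resolution):
        mm = balance(aggregate(m, resolution))
    elif m.weights is None:
        mm = balance(m)
    prof = expected_profile(mm)
    h = int(halfwidth)
    acc = np.zeros((2 * h + 1, 2 * h + 1))
    used = 0
    for chrom in mm.bin_table.chroms:
        sub = [L for L in loops if L.chrom == chrom]
        if not sub:
            continue
        lo, hi = mm.bin_table.chrom_range(chrom)
        n = hi - lo
        c = mm.dense(chrom=chrom, balanced=True)
        pvec = prof.profiles[chrom]
        offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(pvec[offs] > 0, c / pvec[offs], np.nan)
        for L in sub:
            i = mm.bin_table.bin_index(chrom, L.anchor1.midpoint) - lo
            j = mm.bin_table.bin_index(chrom, L.anchor2.midpoint) - lo
            if j - i < 2 * h or i < h or j >= n - h:
                continue
            acc += np.nan_to_num(oe[i - h:i + h + 1, j - h:j + h + 1], nan=1.0)
            used += 1
    if used == 0:
        raise ValueError("no loops far enough from the diagonal for APA")
    mat = acc / used
    corner = max(1, h // 3)
    score = float(mat[h, h] / mat[-corner:, :corner].mean())
    return mat, score


# ---------------------------------------------------------------------------
# annotation and expression at anchors
# ---------------------------------------------------------------------------

def _promoter_windows(genes: pd.DataFrame, upstream: int = 1000) -> pd.DataFrame:
    """Strand-aware promoter windows [TSS-upstream, TSS) per gene."""
    if genes["strand"].isin(["+", "-"]).sum() != len(genes):
        raise ValueError("every gene needs a '+' or '-' strand")
    tss = tss_positions(genes)
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, np.maximum(tss - upstream, 0), tss + 1)
    end = np.where(plus, tss, tss + 1 + upstream)
    return pd.DataFrame({"chrom": genes["chrom"], "start": start, "end": end,
                         "gene_id": genes["gene_id"]})


def _classify_anchor(anchor: GenomicInterval, promoters: pd.DataFrame,
                     enhancers: pd.DataFrame, genes: pd.DataFrame) -> str:
    q = pd.DataFrame({"chrom": [anchor.chrom], "start": [anchor.start],
                      "end": [anchor.end]})
    if len(promoters) and overlaps_any(q, promoters)[0]:
        return "P"
    if len(enhancers) and overlaps_any(q, enhancers)[0]:
        return "E"
    if len(genes) and overlaps_any(q, genes)[0]:
        return "G"
    return "O"


def annotate_loops(loops: list[Loop], genes: pd.DataFrame,
                   enhancers: pd.DataFrame,
                   promoter_upstream: int = 1000) -> list[LoopAnnotation]:
    """Annotate loop anchors as promoter (P), enhancer (E), gene body (G),
    or other (O), with precedence P > E > G > O."""
    promoters = _promoter_windows(genes, promoter_upstream)
    out = []
    for L in loops:
        out.append(LoopAnnotation(
            L,
            _classify_anchor(L.anchor1, promoters, enhancers, genes),
            _classify_anchor(L.anchor2, promoters, enhancers, genes),
        ))
    return out


def deg_at_loops(comparisons: list[LoopComparison], genes: pd.DataFrame,
                 deg: pd.DataFrame,
                 promoter_upstream: int = 1000) -> dict:
    """Fraction of differentially expressed genes whose promoter sits at a
    maintained versus a lost loop anchor, with a two-sided Fisher exact p.

    ``deg`` needs columns gene_id and status (up/down/not-DE). Each gene is
    counted once even when found at several anchors.
    """
    promoters = _promoter_windows(genes, promoter_upstream)
    status = dict(zip(deg["gene_id"].astype(str), deg["status"]))
    unknown = set(status) - set(genes["gene_id"].astype(str))
    if unknown:
        import warnings
        warnings.warn(f"{len(unknown)} DEG-table genes missing from the "
                      "annotation; skipped")
    groups = {"maintained": set(), "lost": set()}
    for c in comparisons:
        if c.status not in groups:
            continue
        for anchor in (c.wt_loop.anchor1, c.wt_loop.anchor2):
            sub = promoters[(promoters["chrom"] == anchor.chrom)
                            & (promoters["start"] < anchor.end)
                            & (promoters["end"] > anchor.start)]
            groups[c.status].update(sub["gene_id"].astype(str))
    counts = {}
    for grp, ids in groups.items():
        ids = {g for g in ids if g in status}
        n = len(ids)
        k = sum(1 for g in ids if status[g] in ("up", "down"))
        counts[grp] = (k, n)
    (k1, n1), (k2, n2) = counts["maintained"], counts["lost"]
    p = float(stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1]) \
        if n1 and n2 else 1.0
    return {
        "maintained": {"deg": k1, "genes": n1,
                       "fraction": k1 / n1 if n1 else 0.0},
        "lost": {"deg": k2, "genes": n2, "fraction": k2 / n2 if n2 else 0.0},
        "fisher_p": p,
    }


def loops_to_bedpe(loops: list[Loop]) -> pd.DataFrame:
    rows = [(L.chrom, L.anchor1.start, L.anchor1.end,
             L.chrom, L.anchor2.start, L.anchor2.end,
             f"loop_{i}", L.fdr) for i, L in enumerate(loops)]
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                       "start2", "end2", "name", "fdr"])
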