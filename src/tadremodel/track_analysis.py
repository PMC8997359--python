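"""Border-centered signal analysis: heatmaps, occupancy classes, Pol II
pausing, and position-weight-matrix site counting.

Signal tracks are bedGraph-style tables (chrom, start, end, value), sorted
and non-overlapping per chromosome; uncovered positions contribute zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, tss_positions
from .tad_analysis import Border

__all__ = [
    "BorderWindowMatrix",
    "PWM",
    "OccupancyClusterCall",
    "border_heatmap",
    "cluster_occupancy",
    "pausing_index",
    "count_pwm_sites",
    "group_signal_test",
    "save_heatmap",
]

HEATMAP_WINDOW = 5000
HEATMAP_COLS = 50  # 100-bp columns across the 5-kb window

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# signal extraction
# ---------------------------------------------------------------------------

def _track_arrays(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, ...]]:
    out = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[str(chrom)] = (sub["start"].to_numpy(np.int64),
                           sub["end"].to_numpy(np.int64),
                           sub["value"].to_numpy(float))
    return out


def interval_mean(track: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Length-weighted mean signal over [start, end); uncovered bases are 0."""
    arrays = _track_arrays(track).get(str(chrom))
    if arrays is None or end <= start:
        return 0.0
    ts, te, tv = arrays
    lo = np.searchsorted(te, start, side="right")
    hi = np.searchsorted(ts, end, side="left")
    if hi <= lo:
        return 0.0
    ov = (np.minimum(te[lo:hi], end) - np.maximum(ts[lo:hi], start)).clip(min=0)
    return float((ov * tv[lo:hi]).sum() / (end - start))


def _window_columns(arrays, start: int, end: int, n_cols: int) -> np.ndarray:
    """Per-column length-weighted mean over n_cols equal columns of [start,end)."""
    edges = np.linspace(start, end, n_cols + 1)
    out = np.zeros(n_cols)
    if arrays is None:
        return out
    ts, te, tv = arrays
    lo = np.searchsorted(te, start, side="right")
    hi = np.searchsorted(ts, end, side="left")
    if hi <= lo:
        return out
    s, e, v = ts[lo:hi], te[lo:hi], tv[lo:hi]
    ov = (np.minimum(e[:, None], edges[None, 1:])
          - np.maximum(s[:, None], edges[None, :-1])).clip(min=0)
    widths = np.diff(edges)
    return (ov * v[:, None]).sum(axis=0) / widths


@dataclass
class BorderWindowMatrix:
    """Borders x window-columns matrix of normalized signal."""

    borders: list[Border]
    values: np.ndarray          # normalized, dialect-bounded
    raw: np.ndarray             # pre-normalization column means
    window: int
    row_order: np.ndarray       # permutation applied to rows

    def window_sums(self) -> np.ndarray:
        """Per-border raw signal summed over the window columns."""
        return self.raw.sum(axis=1)


def _winsorize_normalize(raw: np.ndarray, dialect: str) -> np.ndarray:
    """Apply the dialect's winsorization and normalization rules.

    chip: clip to [q5(negatives), q95(positives)], positives scaled to
    (0, 1], negatives displayed as 0. dnase: negative cut-off 0, positive
    cut-off q75(positives). nascent: like chip but negatives additionally
    scaled to [-1, 0).
    """
    x = raw.copy().astype(float)
    pos = x[x > 0]
    neg = x[x < 0]
    if dialect == "chip" or dialect == "nascent":
        neg_cut = np.quantile(neg, 0.05) if neg.size else 0.0
        pos_cut = np.quantile(pos, 0.95) if pos.size else 0.0
    elif dialect == "dnase":
        neg_cut = 0.0
        pos_cut = np.quantile(pos, 0.75) if pos.size else 0.0
    else:
        raise ValueError(f"unknown heatmap dialect {dialect!r}")
    x = np.clip(x, neg_cut if neg_cut < 0 else None,
                pos_cut if pos_cut > 0 else None)
    out = np.zeros_like(x)
    if pos_cut > 0:
        out[x > 0] = x[x > 0] / pos_cut
    else:
        out[x > 0] = 1.0  # degenerate: constant positive signal
    if dialect == "nascent":
        if neg_cut < 0:
            out[x < 0] = -(x[x < 0] / neg_cut)  # maps to [-1, 0)
        elif (x < 0).any():
            out[x < 0] = -1.0
    return out


def border_heatmap(track: pd.DataFrame, borders: list[Border],
                   window: int = HEATMAP_WINDOW, dialect: str = "chip",
                   n_cols: int = HEATMAP_COLS,
                   reference_track: pd.DataFrame | None = None
                   ) -> BorderWindowMatrix:
    """Signal heatmap over border +/- window/2, winsorized per dialect.

    Rows are ordered by decreasing reference-track (e.g. BEAF-32) signal
    summarized over the window when ``reference_track`` is given, else kept
    in input order.
    """
    arrays = _track_arrays(track)
    half = window // 2
    raw = np.zeros((len(borders), n_cols))
    for r, b in enumerate(borders):
        raw[r] = _window_columns(arrays.get(b.chrom), b.midpoint - half,
                                 b.midpoint + half, n_cols)
    if not np.any(raw):
        warnings.warn("track empty over all border windows; all-zero heatmap")
    values = _winsorize_normalize(raw, dialect)
    order = np.arange(len(borders))
    if reference_track is not None:
        ref = np.array([interval_mean(reference_track, b.chrom,
                                      b.midpoint - half, b.midpoint + half)
                        for b in borders])
        order = np.argsort(-ref, kind="stable")
        values = values[order]
        raw = raw[order]
        borders = [borders[i] for i in order]
    return BorderWindowMatrix(borders, values, raw, window, order)


def save_heatmap(matrix: BorderWindowMatrix, path, cmap: str = "RdBu_r",
                 title: str = "") -> None:
    """Render a border-window matrix to PNG (rows = borders)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    half_kb = matrix.window / 2000
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(matrix.values, aspect="auto", cmap=cmap,
                   vmin=min(0.0, matrix.values.min()), vmax=1.0,
                   extent=(-half_kb, half_kb, len(matrix.borders), 0))
    ax.set_xlabel("distance from border (kb)")
    ax.set_ylabel("border")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# occupancy clustering
# ---------------------------------------------------------------------------

@dataclass
class OccupancyClusterCall:
    border: Border
    dataset: str
    window_sum: float
    occupancy_class: str  # no | extra_low | low | medium | high | extra_high


def _occupancy_class(window_vals: np.ndarray, cutoff: float) -> str:
    """Rule-based class from the quartiles of per-bin raw window signal.

    Zeros fall through to "low"; values exactly at the cut-off go to the
    lower class.
    """
    if window_vals.size == 0:
        return "no"
    q1, q2, q3 = np.quantile(window_vals, [0.25, 0.5, 0.75])
    if q2 < 0 and q3 < 0:
        return "no"
    if q2 < 0 <= q3:
        return "extra_low"
    if q1 > cutoff:
        return "extra_high"
    if q2 > cutoff:
        return "high"
    if q3 > cutoff:
        return "medium"
    return "low"


def cluster_occupancy(matrices: dict[str, BorderWindowMatrix]
                      ) -> list[OccupancyClusterCall]:
    """Classify each (border, dataset) by raw 5-kb window signal.

    The cut-off is the median of all positive window sums pooled across
    datasets, recomputed for every input collection. The rule quartiles
    are taken over the per-bin raw signal of each window, so the sum-scale
    cut-off is converted to per-bin units (divided by the column count)
    before comparison.
    """
    sums = np.concatenate([m.window_sums() for m in matrices.values()])
    pos = sums[sums > 0]
    cutoff_sum = float(np.median(pos)) if pos.size else 0.0
    calls = []
    for name, m in matrices.items():
        ws = m.window_sums()
        n_cols = m.raw.shape[1] if m.raw.size else 1
        cutoff = cutoff_sum / n_cols
        for r, b in enumerate(m.borders):
            cls = _occupancy_class(m.raw[r], cutoff)  # zeros fall to "low"
            calls.append(OccupancyClusterCall(b, name, float(ws[r]), cls))
    return calls


# ---------------------------------------------------------------------------
# Pol II pausing index
# ---------------------------------------------------------------------------

def pausing_index(polII: pd.DataFrame, genes: pd.DataFrame,
                  promoter_up: int = 200, promoter_down: int = 50,
                  body_up: int = 50) -> pd.Series:
    """Promoter-to-body ratio of mean Pol II signal per gene.

    Promoter spans TSS-200..TSS+50 and the body TSS-50..gene end (strand
    aware). Genes with an undefined or nonpositive index are discarded.
    """
    tss = tss_positions(genes)
    out = {}
    for (_, g), t in zip(genes.iterrows(), tss):
        if g["strand"] == "+":
            prom = (t - promoter_up, t + promoter_down)
            body = (t - body_up, g["end"])
        else:
            prom = (t - promoter_down + 1, t + promoter_up + 1)
            body = (g["start"], t + body_up + 1)
        if body[1] <= body[0] or prom[1] <= prom[0]:
            warnings.warn(f"gene {g['gene_id']}: zero-length region; skipped")
            continue
        pm = interval_mean(polII, g["chrom"], int(prom[0]), int(prom[1]))
        bm = interval_mean(polII, g["chrom"], int(body[0]), int(body[1]))
        if bm <= 0:
            continue
        idx = pm / bm
        if idx <= 0:
            continue
        out[str(g["gene_id"])] = idx
    return pd.Series(out, name="pausing_index", dtype=float)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix of per-position log-odds scores (L x 4, ACGT)."""

    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4 (A, C, G, T)")

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.8,
                    background: float = 0.25, name: str = "") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(
            axis=1, keepdims=True)
        return cls(np.log2(probs / background), name=name)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def score_threshold(self, threshold_fraction: float) -> float:
        """Relative-score convention: tf * (max - min) + min."""
        return threshold_fraction * (self.max_score - self.min_score) \
            + self.min_score


def _scan_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Score of every window on the forward strand; NaN where N occurs."""
    L = len(pwm)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for k in range(L):
        col = idx[k:k + n]
        ok = col >= 0
        bad |= ~ok
        scores += np.where(ok, pwm.matrix[k, np.maximum(col, 0)], 0.0)
    scores[bad] = np.nan
    return scores


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def count_pwm_sites(seq: str, pwm: PWM, region: GenomicInterval | None = None,
                    flank: int = 2000,
                    threshold_fraction: float = 0.85) -> int:
    """Count PWM matches on both strands at or above the relative threshold.

    ``seq`` is the chromosome (or ready-made window) sequence; when
    ``region`` is given, the scan covers region +/- ``flank`` clipped to the
    sequence. Windows containing N are skipped; overlapping sites all count.
    """
    seq = seq.upper()
    if region is not None:
        lo = max(0, region.start - flank)
        hi = min(len(seq), region.end + flank)
        seq = seq[lo:hi]
    thr = pwm.score_threshold(threshold_fraction)
    total = 0
    for s in (seq, reverse_complement(seq)):
        sc = _scan_scores(s, pwm)
        total += int(np.nansum(sc >= thr))
    return total


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_signal_test(a_values, b_values, exact_max: int = 12) -> float:
    """Two-sided Mann-Whitney U p between two groups of per-border signals.

    Exact null enumeration for groups of <= ``exact_max`` values without
    ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= exact_max and b.size <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)
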