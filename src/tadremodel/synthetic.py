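"""Synthetic Hi-C inputs with planted, machine-readable ground truth.

The generator emulates the statistical structure the analysis modules
assume: power-law distance decay with Poisson-sampled counts, TAD blocks
delimited by borders with a tunable insulation depth (fold reduction of
cross-border contacts), focal loop peaks (2D Gaussian bumps), an A/B
checkerboard with a GC covariate, ChIP-like bump tracks over Gaussian
noise, and gene/DEG tables with effects concentrated in chosen TADs.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contact_matrix import ContactMatrix
from .genome import BinTable

__all__ = [
    "PlantedBorder",
    "PlantedLoop",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_matrix",
    "simulate_condition_pair",
    "simulate_tracks",
    "simulate_expression",
]

DECAY_EXPONENT = 1.0      # contact probability ~ (1 + d)^-alpha
LOOP_SIGMA = 1.0          # bins, at 2-kb resolution
GC_BASE = 0.40
GC_DELTA = 0.10           # GC lift of the A compartment
GC_NOISE = 0.02


@dataclass(frozen=True)
class PlantedBorder:
    chrom: str
    pos: int       # bp, a bin edge
    depth: float   # fold reduction of cross-border contacts (> 1)


@dataclass(frozen=True)
class PlantedLoop:
    chrom: str
    pos1: int
    pos2: int
    enrichment: float  # fold enrichment at the peak center (> 1)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic Hi-C condition."""

    genome: dict[str, int]
    resolution: int = 5000
    decay_exponent: float = DECAY_EXPONENT
    borders: list[PlantedBorder] = field(default_factory=list)
    loops: list[PlantedLoop] = field(default_factory=list)
    compartment_blocks: int = 0          # alternating A/B blocks per chromosome
    checkerboard_factor: float = 1.0     # within:between contact ratio f
    depth: float = 1_000_000.0           # expected total contacts per chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.checkerboard_factor < 1:
            raise ValueError("checkerboard factor must be >= 1")
        for b in self.borders:
            if b.depth <= 1:
                raise ValueError("border insulation depth must exceed 1")
        for L in self.loops:
            if L.enrichment <= 1:
                raise ValueError("loop enrichment must exceed 1")
        self.borders = sorted(self.borders, key=lambda b: (b.chrom, b.pos))


@dataclass
class GroundTruth:
    """Planted features, in the coordinates the callers report."""

    borders: pd.DataFrame      # chrom, pos, depth, bin, status
    loops: pd.DataFrame        # chrom, pos1, pos2, enrichment, bin1, bin2, status
    compartments: pd.DataFrame  # chrom, start, end, label
    gc: np.ndarray | None = None
    degs: pd.DataFrame | None = None

    def write(self, prefix: str) -> None:
        self.borders.to_csv(f"{prefix}.borders.tsv", sep="\t", index=False)
        self.loops.to_csv(f"{prefix}.loops.tsv", sep="\t", index=False)
        self.compartments.to_csv(f"{prefix}.compartments.tsv", sep="\t",
                                 index=False)
        if self.degs is not None:
            self.degs.to_csv(f"{prefix}.degs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def _compartment_labels(n: int, blocks: int) -> np.ndarray:
    """Alternating A(+1)/B(-1) block labels over n bins."""
    if blocks <= 0:
        return np.zeros(n, dtype=np.int8)
    edges = np.linspace(0, n, blocks + 1).round().astype(int)
    lab = np.zeros(n, dtype=np.int8)
    for k, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
        lab[s:e] = 1 if k % 2 == 0 else -1
    return lab


def _lambda_chrom(spec: SyntheticSpec, chrom: str, n: int) -> np.ndarray:
    """Expected-intensity matrix for one chromosome (upper incl. diagonal)."""
    res = spec.resolution
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = (1.0 + d) ** (-spec.decay_exponent)
    # TAD blocks: crossing a border of depth D divides intensity by D
    borders = [b for b in spec.borders if b.chrom == chrom]
    if borders:
        cum = np.zeros(n)
        for b in borders:
            edge = min(n, max(0, int(round(b.pos / res))))
            cum[edge:] += np.log(b.depth)
        cross = np.abs(np.subtract.outer(cum, cum))
        lam = lam * np.exp(-cross)
    # compartment checkerboard with within:between ratio f
    lab = _compartment_labels(n, spec.compartment_blocks)
    if spec.checkerboard_factor > 1 and np.any(lab != 0):
        f = np.sqrt(spec.checkerboard_factor)
        same = np.equal.outer(lab, lab) & (lab != 0)[:, None] & (lab != 0)[None, :]
        diff = (~np.equal.outer(lab, lab)) & (lab != 0)[:, None] & (lab != 0)[None, :]
        lam = lam * np.where(same, f, 1.0) * np.where(diff, 1.0 / f, 1.0)
    # focal loops: multiplicative Gaussian bumps
    for L in (x for x in spec.loops if x.chrom == chrom):
        i = int(round(L.pos1 / res))
        j = int(round(L.pos2 / res))
        w = int(np.ceil(4 * LOOP_SIGMA))
        ii = np.arange(max(0, i - w), min(n, i + w + 1))
        jj = np.arange(max(0, j - w), min(n, j + w + 1))
        gi = np.exp(-((ii - i) ** 2) / (2 * LOOP_SIGMA ** 2))
        gj = np.exp(-((jj - j) ** 2) / (2 * LOOP_SIGMA ** 2))
        bump = 1.0 + (L.enrichment - 1.0) * np.outer(gi, gj)
        lam[np.ix_(ii, jj)] *= bump
        lam[np.ix_(jj, ii)] *= bump.T
    # scale to the requested sequencing depth (upper triangle + diagonal)
    upper_sum = np.triu(lam).sum()
    lam *= spec.depth / upper_sum
    if lam.max() < 1:
        warnings.warn("depth so low that no pixel expects a single contact")
    return lam


def _truth_tables(spec: SyntheticSpec, bt: BinTable) -> GroundTruth:
    res = spec.resolution
    brows = []
    for b in spec.borders:
        lo, _ = bt.chrom_range(b.chrom)
        brows.append((b.chrom, b.pos, b.depth, lo + int(round(b.pos / res)),
                      "planted"))
    lrows = []
    for L in spec.loops:
        lo, _ = bt.chrom_range(L.chrom)
        lrows.append((L.chrom, L.pos1, L.pos2, L.enrichment,
                      lo + int(round(L.pos1 / res)),
                      lo + int(round(L.pos2 / res)), "planted"))
    crows = []
    for chrom, size in spec.genome.items():
        lo, hi = bt.chrom_range(chrom)
        lab = _compartment_labels(hi - lo, spec.compartment_blocks)
        for i, l in enumerate(lab):
            if l == 0:
                continue
            s = i * res
            crows.append((chrom, s, min(s + res, size), "A" if l > 0 else "B"))
    return GroundTruth(
        pd.DataFrame(brows, columns=["chrom", "pos", "depth", "bin", "status"]),
        pd.DataFrame(lrows, columns=["chrom", "pos1", "pos2", "enrichment",
                                     "bin1", "bin2", "status"]),
        pd.DataFrame(crows, columns=["chrom", "start", "end", "label"]),
    )


def simulate_matrix(spec: SyntheticSpec) -> tuple[ContactMatrix, GroundTruth]:
    """Poisson-sample a contact matrix from the planted intensity model."""
    bt = BinTable.from_uniform(spec.genome, spec.resolution)
    rng = np.random.default_rng(spec.seed)
    blocks = []
    gc_all = np.zeros(bt.n_bins)
    for chrom in bt.chroms:
        lo, hi = bt.chrom_range(chrom)
        n = hi - lo
        lam = _lambda_chrom(spec, chrom, n)
        counts = rng.poisson(np.triu(lam))
        blocks.append(sp.coo_matrix(counts))
        lab = _compartment_labels(n, spec.compartment_blocks)
        gc_all[lo:hi] = (GC_BASE + GC_DELTA * (lab > 0)
                         + rng.normal(0, GC_NOISE, n))
    px = sp.block_diag(blocks, format="csr")
    m = ContactMatrix(bt, px.astype(np.float64))
    truth = _truth_tables(spec, bt)
    truth.gc = gc_all
    return m, truth


# ---------------------------------------------------------------------------
# scripted WT / knockdown pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorderEdit:
    """An edit to a planted border: delete, shift by delta bp, or re-depth."""

    chrom: str
    pos: int
    action: str              # "delete" | "shift" | "weaken"
    delta: int = 0           # bp, for shift
    new_depth: float = 0.0   # for weaken


@dataclass(frozen=True)
class LoopEdit:
    chrom: str
    pos1: int
    pos2: int
    action: str = "delete"


def simulate_condition_pair(spec: SyntheticSpec,
                            edits: list[BorderEdit | LoopEdit],
                            same_tol: int | None = None,
                            fuzzy_tol: int = 2000,
                            ) -> tuple[ContactMatrix, ContactMatrix,
                                       GroundTruth, GroundTruth]:
    """A WT matrix and a knockdown matrix regenerated under scripted edits.

    The knockdown uses the same seed stream, so shared structure is drawn
    under identical randomness. WT truth gains an ``intended`` status per
    feature, following the classifier's definitions: untouched -> maintained,
    deleted or moved beyond ``fuzzy_tol`` -> lost (plus a "new" record at
    the landing position), moved within (same_tol, fuzzy_tol] -> fuzzy,
    re-depth below the strong threshold -> weakened.
    """
    if same_tol is None:
        same_tol = spec.resolution
    bkey = {(b.chrom, b.pos): b for b in spec.borders}
    lkey = {(L.chrom, L.pos1, L.pos2): L for L in spec.loops}
    new_borders = dict(bkey)
    new_loops = dict(lkey)
    intended: dict[tuple[str, int], str] = {k: "maintained" for k in bkey}
    loop_status: dict[tuple, str] = {k: "maintained" for k in lkey}
    for e in edits:
        if isinstance(e, BorderEdit):
            key = (e.chrom, e.pos)
            if key not in bkey:
                raise ValueError(f"edit references unknown border {key}")
            b = bkey[key]
            if e.action == "delete":
                del new_borders[key]
                intended[key] = "lost"
            elif e.action == "shift":
                del new_borders[key]
                moved = replace(b, pos=b.pos + e.delta)
                new_borders[(e.chrom, moved.pos)] = moved
                d = abs(e.delta)
                intended[key] = ("maintained" if d <= same_tol
                                 else "fuzzy" if d <= fuzzy_tol else "lost")
                if d > fuzzy_tol:
                    intended[(e.chrom, moved.pos)] = "new"
            elif e.action == "weaken":
                if e.new_depth <= 1:
                    raise ValueError("weakened depth must still exceed 1")
                new_borders[key] = replace(b, depth=e.new_depth)
                intended[key] = "weakened"
            else:
                raise ValueError(f"unknown border edit action {e.action!r}")
        elif isinstance(e, LoopEdit):
            key = (e.chrom, e.pos1, e.pos2)
            if key not in lkey:
                raise ValueError(f"edit references unknown loop {key}")
            if e.action == "delete":
                del new_loops[key]
                loop_status[key] = "lost"
            else:
                raise ValueError(f"unknown loop edit action {e.action!r}")
        else:
            raise TypeError("edits must be BorderEdit or LoopEdit")
    kd_spec = copy.deepcopy(spec)
    kd_spec.borders = sorted(new_borders.values(),
                             key=lambda b: (b.chrom, b.pos))
    kd_spec.loops = list(new_loops.values())
    wt_m, wt_truth = simulate_matrix(spec)
    kd_m, kd_truth = simulate_matrix(kd_spec)
    wt_truth.borders["status"] = [
        intended[(c, p)] for c, p in zip(wt_truth.borders["chrom"],
                                         wt_truth.borders["pos"])]
    extra = [(c, p) for (c, p), s in intended.items() if s == "new"]
    if extra:
        res = spec.resolution
        rows = []
        bt = wt_m.bin_table
        for c, p in extra:
            lo, _ = bt.chrom_range(c)
            rows.append((c, p, new_borders[(c, p)].depth,
                         lo + int(round(p / res)), "new"))
        wt_truth.borders = pd.concat(
            [wt_truth.borders,
             pd.DataFrame(rows, columns=wt_truth.borders.columns)],
            ignore_index=True)
    wt_truth.loops["status"] = [
        loop_status[(c, p1, p2)]
        for c, p1, p2 in zip(wt_truth.loops["chrom"], wt_truth.loops["pos1"],
                             wt_truth.loops["pos2"])]
    return wt_m, kd_m, wt_truth, kd_truth


# ---------------------------------------------------------------------------
# ChIP-like tracks and peaks
# ---------------------------------------------------------------------------

def simulate_tracks(truth: GroundTruth, genome: dict[str, int], snr: float,
                    seed: int, step: int = 100, bump_halfwidth: int = 500,
                    bound_fraction: float = 1.0, divergent: bool = False
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP-like bedGraph track and peak BED over the planted borders.

    Gaussian bumps of amplitude ``snr`` (in units of the noise SD) are
    placed at a ``bound_fraction`` of the planted borders over N(0, 1)
    noise sampled in ``step``-bp intervals. With ``divergent``, each bump
    is replaced by an antisymmetric pair of opposite-sign bumps flanking
    the border (nascent-transcription style).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    peaks = []
    borders = truth.borders
    chosen = np.ones(len(borders), dtype=bool)
    if bound_fraction < 1.0:
        chosen = rng.random(len(borders)) < bound_fraction
    for chrom, size in genome.items():
        starts = np.arange(0, size, step)
        ends = np.minimum(starts + step, size)
        mids = (starts + ends) / 2
        vals = rng.normal(0, 1, starts.size)
        sub = borders[(borders["chrom"] == chrom)]
        for (idx, b), keep in zip(sub.iterrows(),
                                  chosen[borders["chrom"] == chrom]):
            if not keep:
                continue
            if divergent:
                off = bump_halfwidth
                vals += snr * np.exp(-((mids - (b["pos"] + off)) ** 2)
                                     / (2 * bump_halfwidth ** 2))
                vals -= snr * np.exp(-((mids - (b["pos"] - off)) ** 2)
                                     / (2 * bump_halfwidth ** 2))
            else:
                vals += snr * np.exp(-((mids - b["pos"]) ** 2)
                                     / (2 * bump_halfwidth ** 2))
            peaks.append((chrom, max(0, int(b["pos"]) - bump_halfwidth),
                          min(size, int(b["pos"]) + bump_halfwidth)))
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": ends, "value": vals}))
    track = pd.concat(rows, ignore_index=True)
    peak_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    return track, peak_df


# ---------------------------------------------------------------------------
# genes and DEG tables
# ---------------------------------------------------------------------------

def simulate_expression(truth: GroundTruth, genome: dict[str, int],
                        genes_per_tad: int, deg_odds: float, seed: int,
                        base_rate: float = 0.1,
                        padj_thresh: float = 0.05, log2fc_thresh: float = 2.0,
                        gene_width: int = 2000,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models placed inside TADs plus a DEG table with planted bias.

    Genes never span borders. A gene is differentially expressed with
    probability ``base_rate`` in TADs whose borders are all intended
    "maintained", and with odds multiplied by ``deg_odds`` in reorganized
    TADs (any border lost/fuzzy/new/weakened). log2FC and adjusted p values
    are drawn consistent with the status thresholds.
    """
    if deg_odds < 1:
        raise ValueError("deg_odds must be >= 1")
    rng = np.random.default_rng(seed)
    genes = []
    gid = 0
    borders = truth.borders
    base_odds = base_rate / (1 - base_rate)
    hi_rate = (base_odds * deg_odds) / (1 + base_odds * deg_odds)
    for chrom, size in genome.items():
        sub = borders[(borders["chrom"] == chrom)
                      & (borders["status"] != "new")].sort_values("pos")
        cuts = np.concatenate([[0], sub["pos"].to_numpy(), [size]])
        statuses = ["maintained"] + list(sub["status"]) + ["maintained"]
        n_tads = len(cuts) - 1
        reorganized_tad = np.array(
            [statuses[t] != "maintained" or statuses[t + 1] != "maintained"
             for t in range(n_tads)])
        k = genes_per_tad * n_tads
        if size <= gene_width + 2:
            warnings.warn(f"{chrom} too small for genes")
            continue
        # uniform placement along the chromosome, rejecting border-spanning
        # positions, so gene density is proportional to TAD length (the
        # permutation test's null model)
        starts = np.empty(0, dtype=np.int64)
        for _ in range(100):
            need = k - starts.size
            if need <= 0:
                break
            cand = (rng.random(2 * need) * (size - gene_width)).astype(np.int64)
            t_lo = np.searchsorted(cuts, cand, side="right") - 1
            t_hi = np.searchsorted(cuts, cand + gene_width, side="right") - 1
            keep = t_lo == t_hi
            starts = np.concatenate([starts, cand[keep][:need]])
        if starts.size < k:
            warnings.warn(f"{chrom}: placed only {starts.size} of {k} genes")
        tad_of = np.searchsorted(cuts, starts, side="right") - 1
        for s, ti in sorted(zip(starts.tolist(), tad_of.tolist())):
            reorganized = bool(reorganized_tad[ti])
            rate = hi_rate if reorganized else base_rate
            is_deg = rng.random() < rate
            if is_deg:
                lfc = float(rng.choice([-1, 1])
                            * (log2fc_thresh + rng.exponential(1.0)))
                padj = float(rng.uniform(0, padj_thresh))
                status = "up" if lfc > 0 else "down"
            else:
                lfc = float(rng.normal(0, 0.3))
                padj = float(rng.uniform(padj_thresh, 1))
                status = "not-DE"
            genes.append((f"gene{gid:05d}", chrom, int(s),
                          int(s + gene_width),
                          "+" if rng.random() < 0.5 else "-",
                          lfc, padj, status, reorganized))
            gid += 1
    df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                      "strand", "log2fc", "padj", "status",
                                      "in_reorganized_tad"])
    gene_set = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
    deg_table = df[["gene_id", "log2fc", "padj", "status"]].copy()
    truth.degs = df
    return gene_set, deg_table
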