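"""Binned Hi-C contact matrices: I/O, balancing, down-sampling, O/E, log2FC.

A :class:`ContactMatrix` stores the upper triangle of a symmetric binned
contact map as a ``scipy.sparse`` matrix over a :class:`~tadremodel.genome.BinTable`,
with optional per-bin balancing weights (NaN marks masked bins).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinTable

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_matrix",
    "write_matrix",
    "read_bin_table",
    "write_bin_table",
    "digest_genome",
    "balance",
    "downsample",
    "observed_expected",
    "aggregate",
    "bin_log2fc",
]


class MatrixParseError(ValueError):
    pass


class BalanceError(RuntimeError):
    def __init__(self, msg: str, cv: float):
        super().__init__(msg)
        self.cv = cv


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts, upper triangle stored.

    ``weights`` are multiplicative balancing factors b_i (corrected count
    c'_ij = c_ij * b_i * b_j); NaN flags a masked bin. ``is_oe`` marks a
    matrix whose values are observed/expected ratios rather than counts.
    """

    bin_table: BinTable
    pixels: sp.csr_matrix  # upper triangle, i <= j
    weights: np.ndarray | None = None
    is_oe: bool = False

    def __post_init__(self) -> None:
        n = self.bin_table.n_bins
        if self.pixels.shape != (n, n):
            raise ValueError("pixel matrix shape does not match bin table")
        if self.pixels.nnz and self.pixels.data.min() < 0:
            raise ValueError("negative contact counts")

    @classmethod
    def from_coo(cls, bin_table: BinTable, bin1, bin2, count,
                 weights: np.ndarray | None = None,
                 is_oe: bool = False) -> "ContactMatrix":
        """Build from COO triples; lower-triangle records folded by summation."""
        n = bin_table.n_bins
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        count = np.asarray(count, dtype=np.float64)
        if bin1.size and (bin1.min() < 0 or bin2.min() < 0
                          or bin1.max() >= n or bin2.max() >= n):
            raise MatrixParseError("bin index out of range of the bin table")
        if count.size and count.min() < 0:
            raise MatrixParseError("negative contact count")
        i = np.minimum(bin1, bin2)
        j = np.maximum(bin1, bin2)
        m = sp.coo_matrix((count, (i, j)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        return cls(bin_table, m, weights=weights, is_oe=is_oe)

    # -- queries --------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins

    @property
    def total_count(self) -> float:
        return float(self.pixels.sum())

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def mask(self) -> np.ndarray:
        """Boolean vector of valid (unmasked) bins."""
        if self.weights is None:
            return np.ones(self.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def value(self, i: int, j: int, balanced: bool = False) -> float:
        """Symmetric lookup of a single pixel."""
        a, b = (i, j) if i <= j else (j, i)
        v = float(self.pixels[a, b])
        if balanced and self.weights is not None:
            v *= self.weights[i] * self.weights[j]
        return v

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric sparse matrix (both triangles)."""
        u = self.pixels
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def dense(self, chrom: str | None = None, balanced: bool = False,
              dtype=np.float64) -> np.ndarray:
        """Dense symmetric (sub)matrix; masked bins zeroed when balanced."""
        s = self.symmetric()
        if chrom is not None:
            sl = self.bin_table.chrom_slice(chrom)
            s = s[sl, sl]
            w = None if self.weights is None else self.weights[sl]
        else:
            w = self.weights
        a = np.asarray(s.todense(), dtype=dtype)
        if balanced and w is not None:
            wv = np.where(np.isfinite(w), w, 0.0)
            a = a * wv[:, None] * wv[None, :]
        return a

    def marginals(self) -> np.ndarray:
        """Raw per-bin coverage (row sums of the symmetric matrix)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def with_weights(self, weights: np.ndarray) -> "ContactMatrix":
        return ContactMatrix(self.bin_table, self.pixels, weights=weights,
                             is_oe=self.is_oe)


@dataclass
class ExpectedProfile:
    """Per-chromosome mean corrected count at each diagonal offset."""

    profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def expected(self, chrom: str, offset) -> np.ndarray:
        prof = self.profiles[str(chrom)]
        return prof[np.asarray(offset, dtype=np.int64)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, d, v) for c, prof in self.profiles.items()
                for d, v in enumerate(prof)]
        return pd.DataFrame(rows, columns=["chrom", "offset", "expected"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def read_bin_table(path) -> BinTable:
    """Read a bin table from BED-like text (chrom, start, end[, bin_id])."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    widths = (df["end"] - df["start"]).to_numpy()
    uniform = len(np.unique(widths[:-1])) <= 1 if len(df) > 1 else True
    if uniform:
        return BinTable(df, kind="uniform", resolution=int(widths[0]))
    return BinTable(df, kind="fragment")


def write_bin_table(bt: BinTable, path) -> None:
    df = bt.df.copy()
    df["bin_id"] = np.arange(len(df))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path, bin_table_path) -> ContactMatrix:
    """Read pixels from whitespace-delimited text (bin_i, bin_j, count).

    Lower-triangle records are folded into the upper triangle by summation.
    """
    bt = read_bin_table(bin_table_path)
    try:
        px = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["bin1", "bin2", "count"])
    except pd.errors.EmptyDataError:
        px = pd.DataFrame({"bin1": [], "bin2": [], "count": []})
    n = bt.n_bins
    bad = (px["bin1"].lt(0) | px["bin2"].lt(0)
           | px["bin1"].ge(n) | px["bin2"].ge(n))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise MatrixParseError(
            f"{path}: line {line}: bin index out of range (0..{n - 1})")
    neg = px["count"].lt(0)
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise MatrixParseError(f"{path}: line {line}: negative count")
    return ContactMatrix.from_coo(bt, px["bin1"], px["bin2"], px["count"])


def write_matrix(m: ContactMatrix, path, weights_path=None) -> None:
    coo = sp.triu(m.pixels).tocoo()
    order = np.lexsort((coo.col, coo.row))
    df = pd.DataFrame({"bin1": coo.row[order], "bin2": coo.col[order],
                       "count": coo.data[order]})
    if np.allclose(df["count"], np.round(df["count"])):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)
    if weights_path is not None and m.weights is not None:
        out = m.bin_table.df.copy()
        out["weight"] = m.weights
        out.to_csv(weights_path, sep="\t", header=False, index=False,
                   na_rep="nan")


# ---------------------------------------------------------------------------
# restriction digestion -> fragment bin table
# ---------------------------------------------------------------------------

def digest_genome(fasta, motif: str = "GATC", min_gap: int = 150,
                  max_gap: int = 1000) -> BinTable:
    """Build a fragment bin table by in-silico restriction digestion.

    Cut positions are the motif occurrences; fragments shorter than
    ``min_gap`` are absorbed into the following fragment, and fragments
    longer than ``max_gap`` are split into equal pieces each <= ``max_gap``.
    ``fasta`` is a path or a {chrom: sequence} mapping.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be non-degenerate A/C/G/T")
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        from pyfaidx import Fasta
        fa = Fasta(str(fasta))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = {str(k): str(v) for k, v in fasta.items()}

    rows = []
    for chrom, seq in seqs.items():
        seq = seq.upper()
        size = len(seq)
        cuts = []
        p = seq.find(motif)
        while p != -1:
            cuts.append(p)
            p = seq.find(motif, p + 1)
        if not cuts:
            warnings.warn(f"{chrom}: motif {motif} absent; single-bin chromosome")
        edges = [0] + [c for c in cuts if 0 < c < size] + [size]
        edges = sorted(set(edges))
        # absorb short fragments forward: drop the edge that closes them
        kept = [edges[0]]
        for e in edges[1:-1]:
            if e - kept[-1] >= min_gap:
                kept.append(e)
        kept.append(edges[-1])
        if len(kept) > 2 and kept[-1] - kept[-2] < min_gap:
            kept.pop(-2)
        for s, e in zip(kept[:-1], kept[1:]):
            width = e - s
            if width > max_gap:
                k = int(np.ceil(width / max_gap))
                sub = np.linspace(s, e, k + 1).round().astype(int)
                rows.extend((chrom, int(a), int(b))
                            for a, b in zip(sub[:-1], sub[1:]))
            else:
                rows.append((chrom, s, e))
    return BinTable(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                    kind="fragment")


# ---------------------------------------------------------------------------
# balancing (iterative correction to equal marginals)
# ---------------------------------------------------------------------------

def balance(m: ContactMatrix, max_iter: int = 300, tol: float = 0.01,
            mask_percentile: float = 2.0) -> ContactMatrix:
    """Iterative-proportional (ICE-style) matrix balancing.

    Finds weights b_i so that corrected counts c'_ij = c_ij*b_i*b_j have
    near-equal row sums over unmasked bins (coefficient of variation <=
    ``tol``). Bins with zero raw marginal are always masked (weight NaN);
    additionally, low-coverage outlier bins below the ``mask_percentile``
    percentile of nonzero marginals are masked, but only when they also
    fall below half the median marginal — genuinely insulated bins sit
    well above that floor and must not be discarded. Raw counts are left
    untouched.
    """
    if m.pixels.nnz == 0:
        raise ValueError("cannot balance an empty matrix")
    s = m.symmetric()
    marg = np.asarray(s.sum(axis=1)).ravel()
    valid = marg > 0
    if mask_percentile > 0 and valid.any():
        cut = min(np.percentile(marg[valid], mask_percentile),
                  0.5 * np.median(marg[valid]))
        valid &= marg >= cut
    b = np.where(valid, 1.0, 0.0)
    cv = np.inf
    for _ in range(int(max_iter)):
        r = b * (s @ b)  # corrected row sums
        rv = r[valid]
        mean = rv.mean()
        if mean <= 0:
            raise BalanceError("balancing degenerated to zero marginals", np.inf)
        cv = float(rv.std() / mean)
        if cv <= tol:
            break
        adj = np.ones_like(b)
        adj[valid] = rv / mean
        b = b / np.where(adj > 0, adj, 1.0)
    else:
        raise BalanceError(
            f"balancing did not reach CV <= {tol} in {max_iter} iterations "
            f"(last CV {cv:.4g})", cv)
    # normalize so mean corrected count scale matches raw totals
    w = np.where(valid, b, np.nan)
    return m.with_weights(w)


# ---------------------------------------------------------------------------
# binomial down-sampling
# ---------------------------------------------------------------------------

def downsample(m: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomially thin every pixel count to ``fraction``, reproducibly."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return ContactMatrix(m.bin_table, m.pixels.copy(), weights=None)
    rng = np.random.default_rng(seed)
    u = m.pixels.tocoo()
    counts = np.round(u.data).astype(np.int64)
    new = rng.binomial(counts, fraction).astype(np.float64)
    px = sp.coo_matrix((new, (u.row, u.col)), shape=u.shape).tocsr()
    px.eliminate_zeros()
    return ContactMatrix(m.bin_table, px, weights=None)


# ---------------------------------------------------------------------------
# observed / expected
# ---------------------------------------------------------------------------

def _valid_pairs_per_offset(valid: np.ndarray) -> np.ndarray:
    """Number of unmasked (i, i+d) pairs for each offset d (0..n-1)."""
    v = valid.astype(np.float64)
    n = v.size
    corr = np.correlate(v, v, mode="full")[n - 1:]
    return np.round(corr).astype(np.int64)


def expected_profile(m: ContactMatrix) -> ExpectedProfile:
    """Mean corrected count at each intra-chromosomal diagonal offset."""
    prof = ExpectedProfile()
    w = m.weights
    valid_all = m.mask()
    coo = sp.triu(m.pixels).tocoo()
    for chrom in m.bin_table.chroms:
        lo, hi = m.bin_table.chrom_range(chrom)
        n = hi - lo
        sel = (coo.row >= lo) & (coo.row < hi) & (coo.col >= lo) & (coo.col < hi)
        r, c, d = coo.row[sel], coo.col[sel], coo.data[sel].astype(np.float64)
        if w is not None:
            wr = np.nan_to_num(w[r])
            wc = np.nan_to_num(w[c])
            d = d * wr * wc
        offs = c - r
        sums = np.bincount(offs, weights=d, minlength=n)
        npairs = _valid_pairs_per_offset(valid_all[lo:hi])
        with np.errstate(invalid="ignore", divide="ignore"):
            prof.profiles[chrom] = np.where(npairs > 0, sums / np.maximum(npairs, 1),
                                            0.0)
    return prof


def observed_expected(m: ContactMatrix) -> tuple[ContactMatrix, ExpectedProfile]:
    """Per-pixel corrected-count / distance-expected ratios (intra-chrom).

    The ratio matrix keeps the sparsity pattern of the input: an unstored
    pixel has zero counts, hence ratio exactly 0. Inter-chromosomal pixels
    and pixels at offsets with zero expected are dropped (masked).
    """
    prof = expected_profile(m)
    w = m.weights
    coo = sp.triu(m.pixels).tocoo()
    keep = np.zeros(coo.nnz, dtype=bool)
    vals = np.zeros(coo.nnz, dtype=np.float64)
    for chrom in m.bin_table.chroms:
        lo, hi = m.bin_table.chrom_range(chrom)
        sel = (coo.row >= lo) & (coo.row < hi) & (coo.col >= lo) & (coo.col < hi)
        if not sel.any():
            continue
        r, c = coo.row[sel], coo.col[sel]
        d = coo.data[sel].astype(np.float64)
        if w is not None:
            d = d * np.nan_to_num(w[r]) * np.nan_to_num(w[c])
        exp = prof.expected(chrom, c - r)
        ok = exp > 0
        v = np.zeros_like(d)
        v[ok] = d[ok] / exp[ok]
        vals[sel] = v
        keep[sel] = ok
    px = sp.coo_matrix((vals[keep], (coo.row[keep], coo.col[keep])),
                       shape=coo.shape).tocsr()
    out = ContactMatrix(m.bin_table, px, weights=None, is_oe=True)
    # carry the mask forward via 0/1 weights so dense() zeroes masked bins
    if m.weights is not None:
        out.weights = np.where(np.isfinite(m.weights), 1.0, np.nan)
    return out, prof


def oe_dense(m: ContactMatrix, chrom: str) -> np.ndarray:
    """Dense per-chromosome O/E map from an ``observed_expected`` result."""
    if not m.is_oe:
        raise ValueError("expected an O/E matrix from observed_expected()")
    return m.dense(chrom=chrom, balanced=False)


# ---------------------------------------------------------------------------
# aggregation and per-bin-pair log2 fold change
# ---------------------------------------------------------------------------

def aggregate(m: ContactMatrix, resolution: int) -> ContactMatrix:
    """Re-bin a matrix onto a uniform grid by bin-midpoint assignment."""
    bt = m.bin_table
    if bt.kind == "uniform" and bt.resolution == resolution:
        return ContactMatrix(bt, m.pixels.copy())
    new_bt = BinTable.from_uniform(bt.chromsizes, resolution)
    mids = bt.midpoints()
    mapping = np.empty(bt.n_bins, dtype=np.int64)
    for chrom in bt.chroms:
        lo, hi = bt.chrom_range(chrom)
        nlo, nhi = new_bt.chrom_range(chrom)
        idx = nlo + np.minimum(mids[lo:hi] // resolution, nhi - nlo - 1)
        mapping[lo:hi] = idx
    coo = sp.triu(m.pixels).tocoo()
    return ContactMatrix.from_coo(new_bt, mapping[coo.row], mapping[coo.col],
                                  coo.data)


def bin_log2fc(a: ContactMatrix, b: ContactMatrix, resolution: int = 5000,
               pseudocount: float = 1.0) -> sp.csr_matrix:
    """Library-size-normalized per-bin-pair log2 fold change (a over b).

    Both matrices are aggregated to ``resolution``; the value at (i, j) is
    log2((c_a+pc)/s_a) - log2((c_b+pc)/s_b) with s the total library size.
    Returned as a sparse upper-triangle matrix over the union of nonzero
    pixels of the two inputs.
    """
    aa = aggregate(a, resolution)
    bb = aggregate(b, resolution)
    if aa.bin_table != bb.bin_table:
        raise ValueError("matrices do not share a genome after aggregation")
    s_a, s_b = aa.total_count, bb.total_count
    pattern = ((aa.pixels != 0) + (bb.pixels != 0)).tocoo()
    ca = np.asarray(aa.pixels[pattern.row, pattern.col]).ravel()
    cb = np.asarray(bb.pixels[pattern.row, pattern.col]).ravel()
    lfc = (np.log2((ca + pseudocount) / s_a)
           - np.log2((cb + pseudocount) / s_b))
    return sp.coo_matrix((lfc, (pattern.row, pattern.col)),
                         shape=pattern.shape).tocsr()
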