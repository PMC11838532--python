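"""Binned sparse contact matrices, Knight-Ruiz balancing, and correlation.

Matrices are genome-wide, symmetric, and stored as the upper triangle of a
``scipy.sparse`` matrix over a dense global bin index. Text triplets plus a
chromsizes file are the canonical interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from cifi._seqio import xopen
from cifi.contacts import ContactPair


@dataclass
class BinTable:
    """Fixed-resolution genome binning with a dense, contiguous global index.

    The last bin of each chromosome may be short. ``offsets[chrom]`` is the
    global index of that chromosome's first bin.
    """

    chrom_sizes: dict[str, int]
    resolution: int
    offsets: dict[str, int] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be a positive integer")
        self.offsets = {}
        off = 0
        for chrom, size in self.chrom_sizes.items():
            if size < 1:
                raise ValueError(f"chromosome {chrom} has non-positive size")
            self.offsets[chrom] = off
            off += -(-size // self.resolution)  # ceil div
        self.n_bins = off

    def n_bins_chrom(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of 0-based position ``pos``."""
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < size:
            raise ValueError(f"position {chrom}:{pos} outside chromosome of size {size}")
        return self.offsets[chrom] + pos // self.resolution

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """``(chrom, start, end)`` of a global bin index."""
        for chrom, size in self.chrom_sizes.items():
            off = self.offsets[chrom]
            n = self.n_bins_chrom(chrom)
            if off <= index < off + n:
                start = (index - off) * self.resolution
                return chrom, start, min(start + self.resolution, size)
        raise IndexError(f"bin index {index} out of range [0, {self.n_bins})")

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))

    def same_binning(self, other: "BinTable") -> bool:
        return (
            self.resolution == other.resolution
            and self.chrom_sizes == other.chrom_sizes
        )

    def to_tsv(self, path: str | Path) -> None:
        with xopen(path, "wt") as fh:
            fh.write("chrom\tstart\tend\tbin\n")
            for i in range(self.n_bins):
                chrom, start, end = self.bin_coords(i)
                fh.write(f"{chrom}\t{start}\t{end}\t{i}\n")


@dataclass
class ContactMatrix:
    """Sparse symmetric contact matrix stored as its upper triangle.

    ``counts`` holds only entries with ``j >= i``. ``weights`` are
    per-bin balancing factors (NaN on masked bins) present only after a
    successful balance; ``norm`` records how they were produced.
    """

    bins: BinTable
    counts: sp.csr_matrix
    weights: np.ndarray | None = None
    norm: str = "raw"

    def __post_init__(self) -> None:
        self.counts = sp.triu(self.counts, k=0).tocsr()
        if self.counts.shape != (self.bins.n_bins, self.bins.n_bins):
            raise ValueError("counts shape does not match bin table")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("contact counts must be non-negative")

    @property
    def total(self) -> float:
        """Sum of all contacts (upper triangle, i.e. one count per pair)."""
        return float(self.counts.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal not double-counted)."""
        upper = self.counts
        diag = sp.diags_array(upper.diagonal(), dtype=None)
        return (upper + upper.T - diag).tocsr()

    def dense(self, chrom: str | None = None, balanced: bool = False) -> np.ndarray:
        """Dense symmetric array, optionally restricted to one chromosome.

        With ``balanced=True`` entries are scaled by the balancing weights;
        masked bins become NaN rows/columns.
        """
        full = self.symmetric()
        if chrom is not None:
            sl = self.bins.chrom_slice(chrom)
            arr = full[sl, sl].toarray().astype(float)
            w = self.weights[sl] if self.weights is not None else None
        else:
            arr = full.toarray().astype(float)
            w = self.weights
        if balanced:
            if w is None:
                raise ValueError("matrix has no balancing weights; run kr_balance first")
            arr = arr * np.outer(w, w)
        return arr

    def marginals(self) -> np.ndarray:
        """Row sums of the symmetric matrix (coverage per bin)."""
        full = self.symmetric()
        return np.asarray(full.sum(axis=1)).ravel()


def bin_pairs(
    pairs: Iterable[ContactPair],
    bin_table: BinTable,
    include_duplicates: bool = False,
) -> ContactMatrix:
    """Accumulate non-duplicate pairs into a raw contact matrix.

    Every pair increments exactly one upper-triangle cell, so the matrix
    total equals the number of pairs binned. A pair with a coordinate
    outside its chromosome raises, echoing the pair.
    """
    rows: list[int] = []
    cols: list[int] = []
    for p in pairs:
        if p.duplicate and not include_duplicates:
            continue
        try:
            i = bin_table.bin_index(p.chrom1, p.pos1)
            j = bin_table.bin_index(p.chrom2, p.pos2)
        except ValueError as exc:
            raise ValueError(f"cannot bin pair {p}: {exc}") from exc
        if i > j:
            i, j = j, i
        rows.append(i)
        cols.append(j)
    n = bin_table.n_bins
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n, n)
    ).tocsr()
    counts.sum_duplicates()
    return ContactMatrix(bins=bin_table, counts=counts)


@dataclass
class BalanceResult:
    """Outcome of a balancing attempt; weights are attached only on success."""

    weights: np.ndarray  # NaN at masked bins
    converged: bool
    method: str  # "KR" | "sinkhorn"
    iterations: int
    max_rowsum_error: float
    n_masked: int


def mask_low_coverage(matrix: ContactMatrix, percentile: float = 2.0) -> np.ndarray:
    """Boolean mask of bins to EXCLUDE from balancing.

    Masks bins with zero marginal plus bins whose marginal is below the
    given percentile of the nonzero marginals.
    """
    marg = matrix.marginals()
    masked = marg == 0
    nonzero = marg[~masked]
    if nonzero.size:
        floor = np.percentile(nonzero, percentile)
        masked |= marg < floor
    return masked


def _kr_core(A: np.ndarray, tol: float, max_outer: int) -> tuple[np.ndarray, bool, int]:
    """Knight-Ruiz inner-outer Newton iteration on a dense symmetric matrix.

    Finds x > 0 with diag(x) A diag(x) having unit row sums. Returns
    (x, converged, outer_iterations).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = float(np.min((delta - y[ind]) / ap[ind]))
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = float(np.min((Delta - y[ind]) / ap[ind]))
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > 2 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        eta = max(min(g * rat, etamax), (0.5 * tol) / max(np.sqrt(rout), 1e-300))
    return x, bool(rout <= rt), outer


def _sinkhorn_core(
    A: np.ndarray, tol: float, max_iter: int, damp: float = 1.0
) -> tuple[np.ndarray, bool, int]:
    """Damped symmetric Sinkhorn fallback: w <- w / rowsum(W A W)^(damp/2)."""
    n = A.shape[0]
    w = np.ones(n)
    for it in range(1, max_iter + 1):
        s = w * (A @ w)
        if np.abs(s - 1.0).max() < tol:
            return w, True, it
        s = np.clip(s, 1e-300, None)
        w = w / s ** (damp / 2.0)
    return w, False, max_iter


def kr_balance(
    matrix: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 300,
    mask_percentile: float = 2.0,
    attach: bool = True,
) -> BalanceResult:
    """Balance a raw matrix so unmasked row sums of w_i M_ij w_j equal 1.

    Low-coverage bins are masked first (see :func:`mask_low_coverage`) and
    receive NaN weights. The Knight-Ruiz Newton iteration is tried first;
    on failure a damped Sinkhorn iteration is used and the method tag
    records the substitution. Non-convergence of both leaves the matrix
    untouched and returns ``converged=False``.
    """
    masked = mask_low_coverage(matrix, mask_percentile)
    keep = ~masked
    weights = np.full(matrix.bins.n_bins, np.nan)
    if keep.sum() == 0:
        return BalanceResult(weights, False, "KR", 0, np.inf, int(masked.sum()))

    A = matrix.dense()[np.ix_(keep, keep)]
    x, ok, iters = _kr_core(A, tol, max_iter)
    method = "KR"
    if not ok or not np.all(np.isfinite(x)) or np.any(x <= 0):
        x, ok, iters = _sinkhorn_core(A, tol, max_iter * 20, damp=0.8)
        method = "sinkhorn"

    rowsums = x * (A @ x)
    err = float(np.abs(rowsums - 1.0).max()) if rowsums.size else np.inf
    ok = ok and err <= tol * 10  # final check on the actual row sums
    result = BalanceResult(
        weights=weights, converged=ok, method=method,
        iterations=iters, max_rowsum_error=err, n_masked=int(masked.sum()),
    )
    if ok:
        weights[keep] = x
        if attach:
            matrix.weights = weights
            matrix.norm = method
    return result


def _parse_region(region: str | None, bins: BinTable) -> tuple[int, int]:
    """``chrom`` or ``chrom:start-end`` (1-based inclusive) to a bin range."""
    if region is None:
        return 0, bins.n_bins
    if ":" in region:
        chrom, span = region.split(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start, end = int(lo) - 1, int(hi)
    else:
        chrom, start, end = region, 0, None
    if chrom not in bins.chrom_sizes:
        raise ValueError(f"unknown chromosome in region {region!r}")
    size = bins.chrom_sizes[chrom]
    end = size if end is None else min(end, size)
    off = bins.offsets[chrom]
    return off + start // bins.resolution, off + -(-end // bins.resolution)


def dump_counts(
    matrix: ContactMatrix,
    region1: str | None = None,
    region2: str | None = None,
    balanced: bool = False,
) -> list[tuple[int, int, float]]:
    """Upper-triangle triplets ``(bin1, bin2, value)`` for a region pair.

    Deterministic order (bin1, then bin2). With ``balanced=True`` the raw
    count is scaled by the balancing weights.
    """
    lo1, hi1 = _parse_region(region1, matrix.bins)
    lo2, hi2 = _parse_region(region2 if region2 is not None else region1, matrix.bins)
    if balanced and matrix.weights is None:
        raise ValueError("matrix has no balancing weights")
    coo = matrix.counts.tocoo()
    out: list[tuple[int, int, float]] = []
    for i, j, c in zip(coo.row, coo.col, coo.data):
        a, b = int(i), int(j)
        if (lo1 <= a < hi1 and lo2 <= b < hi2) or (lo1 <= b < hi1 and lo2 <= a < hi2):
            v = float(c)
            if balanced:
                v *= matrix.weights[a] * matrix.weights[b]
            out.append((a, b, v))
    out.sort()
    return out


def save_triplets(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the canonical text form: resolution header + bin triplets."""
    with xopen(path, "wt") as fh:
        fh.write(f"#resolution: {matrix.bins.resolution}\n")
        for chrom, size in matrix.bins.chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        if matrix.weights is not None:
            fh.write(f"#norm: {matrix.norm}\n")
            fh.write("#weights: " + " ".join(f"{w:.10g}" for w in matrix.weights) + "\n")
        fh.write("bin1\tbin2\tcount\n")
        for i, j, v in dump_counts(matrix):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def load_triplets(path: str | Path) -> ContactMatrix:
    """Read a matrix written by :func:`save_triplets`."""
    sizes: dict[str, int] = {}
    resolution = None
    weights = None
    norm = "raw"
    rows, cols, data = [], [], []
    with xopen(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#resolution:"):
                resolution = int(line.split()[1])
            elif line.startswith("#chromsize:"):
                _, chrom, size = line.split()
                sizes[chrom] = int(size)
            elif line.startswith("#norm:"):
                norm = line.split()[1]
            elif line.startswith("#weights:"):
                weights = np.array([float(x) for x in line.split()[1:]])
            elif line.startswith("#") or line.startswith("bin1") or not line:
                continue
            else:
                i, j, v = line.split("\t")
                rows.append(int(i))
                cols.append(int(j))
                data.append(float(v))
    if resolution is None or not sizes:
        raise ValueError(f"{path} is missing resolution/chromsize headers")
    bins = BinTable(sizes, resolution)
    counts = sp.coo_matrix((data, (rows, cols)), shape=(bins.n_bins, bins.n_bins)).tocsr()
    return ContactMatrix(bins=bins, counts=counts, weights=weights, norm=norm)


def coarsen(matrix: ContactMatrix, coarse_resolution: int) -> ContactMatrix:
    """Aggregate a fine matrix to a coarser resolution (must divide evenly).

    Exact: each fine-bin count lands in the coarse bin containing the fine
    bin's start, so totals are conserved integer-for-integer.
    """
    fine = matrix.bins
    if coarse_resolution % fine.resolution != 0:
        raise ValueError("coarse resolution must be a multiple of the fine resolution")
    coarse = BinTable(fine.chrom_sizes, coarse_resolution)
    # map fine global index -> coarse global index via bin start coordinate
    mapping = np.empty(fine.n_bins, dtype=np.int64)
    for chrom in fine.chrom_sizes:
        sl = fine.chrom_slice(chrom)
        starts = np.arange(sl.stop - sl.start) * fine.resolution
        mapping[sl] = coarse.offsets[chrom] + starts // coarse_resolution
    coo = matrix.counts.tocoo()
    i = mapping[coo.row]
    j = mapping[coo.col]
    swap = i > j
    i2 = np.where(swap, j, i)
    j2 = np.where(swap, i, j)
    counts = sp.coo_matrix(
        (coo.data, (i2, j2)), shape=(coarse.n_bins, coarse.n_bins)
    ).tocsr()
    counts.sum_duplicates()
    return ContactMatrix(bins=coarse, counts=counts)


def correlate_matrices(
    a: ContactMatrix,
    b: ContactMatrix,
    bin_mask: np.ndarray | None = None,
    balanced: bool = False,
) -> tuple[float, float, int]:
    """Pearson r (and r^2) over log1p-transformed matched cells.

    Cells are the union of nonzero upper-triangle entries of either matrix,
    optionally restricted to cells whose BOTH bins fall inside ``bin_mask``
    (boolean, True = keep). Requires identical bin tables. Returns
    ``(r, r_squared, n_cells)``.
    """
    if not a.bins.same_binning(b.bins):
        raise ValueError("correlate_matrices requires identical bin tables")
    ca, cb = a.counts.tocoo(), b.counts.tocoo()
    cells = set(zip(ca.row.tolist(), ca.col.tolist())) | set(
        zip(cb.row.tolist(), cb.col.tolist())
    )
    if bin_mask is not None:
        cells = {(i, j) for i, j in cells if bin_mask[i] and bin_mask[j]}
    if len(cells) < 2:
        raise ValueError("fewer than 2 matched cells to correlate")
    idx = sorted(cells)
    rows = np.array([i for i, _ in idx])
    cols = np.array([j for _, j in idx])
    va = np.asarray(a.counts[rows, cols]).ravel().astype(float)
    vb = np.asarray(b.counts[rows, cols]).ravel().astype(float)
    if balanced:
        if a.weights is None or b.weights is None:
            raise ValueError("balanced correlation requires weights on both matrices")
        va = va * a.weights[rows] * a.weights[cols]
        vb = vb * b.weights[rows] * b.weights[cols]
        ok = np.isfinite(va) & np.isfinite(vb)
        va, vb = va[ok], vb[ok]
    r = float(np.corrcoef(np.log1p(va), np.log1p(vb))[0, 1])
    return r, r * r, len(va)


def plot_heatmap(matrix: ContactMatrix, chrom: str, path: str | Path, balanced: bool = False):
    """Plain heatmap PNG helper (log scale). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = matrix.dense(chrom=chrom, balanced=balanced)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.log1p(arr), cmap="Reds", interpolation="nearest")
    ax.set_title(chrom)
    fig.savefig(path, dpi=120)
    plt.close(fig)
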