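"""Binned contact matrices: build from valid pairs, merge, balance, compare.

A :class:`ContactMatrix` stores the upper triangle (``i <= j`` in global bin
ids) of a symmetric whole-genome matrix as a sparse CSR; the diagonal is
stored once.  Balancing is iterative correction (alternating row/column
scaling) after masking bins whose coverage z-score falls outside a configured
window — the standard matrix-correction recipe for Hi-C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinnedGenome, Genome

__all__ = [
    "ContactMatrix",
    "BalanceConfig",
    "BalanceError",
    "read_pairs",
    "write_pairs",
    "build_matrix",
    "merge_replicates",
    "filter_and_balance",
    "matrix_correlation",
    "expected_by_distance",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class BalanceConfig:
    """Coverage-filter and iterative-correction settings.

    ``low_cutoff``/``high_cutoff`` are z-score bounds on per-bin coverage
    (computed over bins with any coverage); bins outside are masked before
    correction, as are zero-coverage bins.
    """

    low_cutoff: float = -1.24
    high_cutoff: float = 4.0
    max_iter: int = 200
    tolerance: float = 1e-7

    def __post_init__(self) -> None:
        if self.low_cutoff >= self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


class BalanceError(RuntimeError):
    """Iterative correction failed to converge; carries diagnostics."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"balancing did not converge in {iterations} iterations "
            f"(row-sum residual {residual:.3g})"
        )


class ContactMatrix:
    """Symmetric sparse binned contact counts with balancing state."""

    def __init__(
        self,
        binned_genome: BinnedGenome,
        counts: sp.spmatrix,
        balanced: bool = False,
        bin_mask: np.ndarray | None = None,
        library_total: float | None = None,
    ):
        n = binned_genome.n_bins
        counts = sp.triu(counts.tocoo(), k=0).tocsr()
        if counts.shape != (n, n):
            raise ValueError("counts shape does not match binned genome")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative contact count")
        self.binned_genome = binned_genome
        self.counts = counts
        self.balanced = balanced
        self.bin_mask = (
            np.zeros(n, dtype=bool) if bin_mask is None else np.asarray(bin_mask, bool)
        )
        self.library_total = (
            float(counts.sum()) if library_total is None else float(library_total)
        )

    # -- views -------------------------------------------------------------
    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once)."""
        upper = self.counts
        return upper + sp.triu(upper, k=1).T

    def coverage(self) -> np.ndarray:
        """Per-bin marginal (row sum of the symmetric matrix)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def cis_dense(self, chrom: str) -> np.ndarray:
        """Dense symmetric cis block for one chromosome."""
        lo, hi = self.binned_genome.chrom_bin_range(chrom)
        block = self.symmetric()[lo:hi, lo:hi]
        return np.asarray(block.todense(), dtype=float)

    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.binned_genome,
            self.counts.copy(),
            self.balanced,
            self.bin_mask.copy(),
            self.library_total,
        )


def read_pairs(path) -> pd.DataFrame:
    """Valid-pair TSV: chrom1, pos1, chrom2, pos2 (+ optional columns)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("chrom1", "pos1", "chrom2", "pos2"):
        if col not in frame.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    return frame


def write_pairs(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def build_matrix(pairs: pd.DataFrame, binned_genome: BinnedGenome) -> ContactMatrix:
    """Bin a valid-pair table; the matrix total equals the number of pairs."""
    bg = binned_genome
    n = bg.n_bins
    i = np.empty(len(pairs), dtype=np.int64)
    j = np.empty(len(pairs), dtype=np.int64)
    for k, (ccol, pcol, out) in enumerate(
        [("chrom1", "pos1", i), ("chrom2", "pos2", j)]
    ):
        for chrom, sub in pairs.groupby(ccol, sort=False):
            out[sub.index.to_numpy()] = bg.bin_id(chrom, sub[pcol].to_numpy())
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    mat = sp.coo_matrix(
        (np.ones(len(pairs)), (lo, hi)), shape=(n, n), dtype=float
    ).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(bg, mat, library_total=float(len(pairs)))


def merge_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Elementwise sum of replicate matrices on an identical binning."""
    if not matrices:
        raise ValueError("no matrices to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if (
            m.binned_genome.bin_size != first.binned_genome.bin_size
            or m.binned_genome.genome.chrom_sizes
            != first.binned_genome.genome.chrom_sizes
        ):
            raise ValueError("matrices have different binned genomes")
        if m.balanced != first.balanced:
            raise ValueError("cannot merge balanced with raw matrices")
    counts = first.counts.copy()
    for m in matrices[1:]:
        counts = counts + m.counts
    return ContactMatrix(
        first.binned_genome,
        counts,
        balanced=first.balanced,
        library_total=sum(m.library_total for m in matrices),
    )


def filter_and_balance(
    matrix: ContactMatrix, config: BalanceConfig | None = None
) -> ContactMatrix:
    """Mask outlier-coverage bins, then equalise row sums by iterative correction.

    Post-condition: every unmasked row sum equals the mean original unmasked
    coverage to within ``config.tolerance`` (relative); masked bins have no
    entries.  Raises :class:`BalanceError` on non-convergence.
    """
    config = config or BalanceConfig()
    cov = matrix.coverage()
    nz = cov > 0
    mask = ~nz
    if nz.sum() >= 2 and cov[nz].std() > 0:
        z = (cov - cov[nz].mean()) / cov[nz].std()
        mask |= (z < config.low_cutoff) | (z > config.high_cutoff)
    coo = matrix.counts.tocoo()
    keep = ~mask[coo.row] & ~mask[coo.col]
    row, col, data = coo.row[keep], coo.col[keep], coo.data[keep].astype(float)
    n = matrix.binned_genome.n_bins
    active = ~mask
    target = cov[active].mean() if active.any() else 0.0

    def row_sums(values: np.ndarray) -> np.ndarray:
        s = np.bincount(row, weights=values, minlength=n)
        off = row != col
        s += np.bincount(col[off], weights=values[off], minlength=n)
        return s

    converged = False
    residual = np.inf
    for it in range(config.max_iter):
        s = row_sums(data)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(active, s / target, 1.0)
        residual = np.abs(rel[active] - 1.0).max() if active.any() else 0.0
        if residual < config.tolerance:
            converged = True
            break
        corr = np.where(rel > 0, np.sqrt(rel), 1.0)
        data = data / (corr[row] * corr[col])
    if not converged and active.any():
        raise BalanceError(config.max_iter, residual)
    out = sp.coo_matrix((data, (row, col)), shape=(n, n)).tocsr()
    return ContactMatrix(
        matrix.binned_genome,
        out,
        balanced=True,
        bin_mask=mask,
        library_total=matrix.library_total,
    )


def matrix_correlation(m1: ContactMatrix, m2: ContactMatrix) -> float:
    """Pearson correlation of log1p counts over bin-pairs non-zero in either.

    Bins masked in either matrix are excluded.  Raises if no shared non-zero
    bin-pairs remain.
    """
    if m1.binned_genome.bin_size != m2.binned_genome.bin_size:
        raise ValueError("bin size mismatch")
    if m1.balanced != m2.balanced:
        raise ValueError("both matrices must be balanced, or both raw")
    mask = m1.bin_mask | m2.bin_mask
    a = m1.counts.tocsr()
    b = m2.counts.tocsr()
    union = (a != 0) + (b != 0)
    union = union.tocoo()
    keep = ~mask[union.row] & ~mask[union.col]
    r, c = union.row[keep], union.col[keep]
    if len(r) == 0:
        raise ValueError("no shared non-zero bin-pairs")
    x = np.log1p(np.asarray(a[r, c]).ravel())
    y = np.log1p(np.asarray(b[r, c]).ravel())
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) matrix entries")
    return float(np.corrcoef(x, y)[0, 1])


def expected_by_distance(
    matrix: ContactMatrix, monotone_smooth: bool = False
) -> pd.DataFrame:
    """Mean cis contact count per genomic-distance stratum.

    Strata are multiples of the bin size; the mean at distance ``d`` runs over
    *all* unmasked cis bin-pairs at that distance (zero entries included),
    pooled across chromosomes.  ``monotone_smooth`` enforces a non-increasing
    profile beyond distance 0 by a running minimum (optional, off by default).
    """
    bg = matrix.binned_genome
    max_n = max(bg.n_bins_per_chrom.values())
    sums = np.zeros(max_n)
    npairs = np.zeros(max_n, dtype=np.int64)
    valid = ~matrix.bin_mask
    coo = matrix.counts.tocoo()
    chrom_of_row = np.searchsorted(bg._bounds, coo.row, side="right") - 1
    chrom_of_col = np.searchsorted(bg._bounds, coo.col, side="right") - 1
    cis = chrom_of_row == chrom_of_col
    ok = cis & valid[coo.row] & valid[coo.col]
    d = coo.col[ok] - coo.row[ok]
    np.add.at(sums, d, coo.data[ok])
    for chrom in bg.genome.chroms:
        lo, hi = bg.chrom_bin_range(chrom)
        v = valid[lo:hi]
        n = hi - lo
        npairs[0] += v.sum()
        for dist in range(1, n):
            npairs[dist] += int(np.sum(v[:-dist] & v[dist:]))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(npairs > 0, sums / np.maximum(npairs, 1), np.nan)
    if monotone_smooth:
        prof = mean.copy()
        for k in range(2, len(prof)):
            if not np.isnan(prof[k]) and not np.isnan(prof[k - 1]):
                prof[k] = min(prof[k], prof[k - 1])
        mean = prof
    return pd.DataFrame(
        {
            "distance_bp": np.arange(max_n) * bg.bin_size,
            "mean_count": mean,
            "n_pairs": npairs,
        }
    )


def rebin(matrix: ContactMatrix, new_bin_size: int) -> ContactMatrix:
    """Aggregate counts into a coarser binning (must be a multiple)."""
    old = matrix.binned_genome
    if new_bin_size % old.bin_size != 0:
        raise ValueError("new bin size must be a multiple of the current one")
    bg = BinnedGenome(old.genome, new_bin_size)
    coo = matrix.counts.tocoo()

    def remap(bins: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(old._bounds, bins, side="right") - 1
        chrom_names = np.array(old._chrom_list, dtype=object)[idx]
        start = (bins - old._bounds[idx]) * old.bin_size
        out = np.empty(len(bins), dtype=np.int64)
        for c in set(chrom_names):
            m = chrom_names == c
            out[m] = bg.chrom_offsets[c] + start[m] // new_bin_size
        return out

    r = remap(coo.row)
    c = remap(coo.col)
    lo, hi = np.minimum(r, c), np.maximum(r, c)
    mat = sp.coo_matrix(
        (coo.data, (lo, hi)), shape=(bg.n_bins, bg.n_bins)
    ).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(
        bg, mat, balanced=matrix.balanced, library_total=matrix.library_total
    )


def write_matrix_tsv(matrix: ContactMatrix, path) -> None:
    """Bin-pair triplet TSV (chrom1, start1, chrom2, start2, count)."""
    coo = matrix.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    r, c, v = coo.row[order], coo.col[order], coo.data[order]
    bg = matrix.binned_genome
    frame = pd.DataFrame(
        {
            "chrom1": bg.bin_chrom(r),
            "start1": bg.bin_start(r),
            "chrom2": bg.bin_chrom(c),
            "start2": bg.bin_start(c),
            "count": v,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# bin_size={bg.bin_size} library_total={matrix.library_total!r} "
                 f"balanced={int(matrix.balanced)}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_matrix_tsv(path, binned_genome: BinnedGenome) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    bg = binned_genome
    if int(meta["bin_size"]) != bg.bin_size:
        raise ValueError("bin size mismatch between file and binned genome")
    i = np.empty(len(frame), dtype=np.int64)
    j = np.empty(len(frame), dtype=np.int64)
    for ch, sub in frame.groupby("chrom1", sort=False):
        i[sub.index.to_numpy()] = bg.bin_id(ch, sub["start1"].to_numpy())
    for ch, sub in frame.groupby("chrom2", sort=False):
        j[sub.index.to_numpy()] = bg.bin_id(ch, sub["start2"].to_numpy())
    mat = sp.coo_matrix(
        (frame["count"].to_numpy(float), (i, j)), shape=(bg.n_bins, bg.n_bins)
    ).tocsr()
    cm = ContactMatrix(
        bg,
        mat,
        balanced=bool(int(meta["balanced"])),
        library_total=float(meta["library_total"]),
    )
    if cm.balanced:
        cov = cm.coverage()
        cm.bin_mask = cov == 0
    return cm
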