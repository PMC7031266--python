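"""Distance-stratified loop enrichment (z-scores) and aggregate peak analysis.

Within each cis distance stratum the per-pixel z-score is computed against
the stratum mean and standard deviation over all unmasked pixels (zero
entries included).  Called loops are z >= 6 pixels within 1 Mb of the
diagonal, with adjacent called pixels merged to their local z-maximum.  APA
aggregates 21 x 21 submatrices (10-kb bins, +/-100 kb) centred on loop
pixels, excluding loops within 300 kb of the diagonal, and scales by the mean
of the four corner pixels of the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .contacts import ContactMatrix

__all__ = ["ZScoreMap", "APAResult", "loop_zscores", "call_loops", "apa"]

MIN_STRATUM_PIXELS = 10


@dataclass
class ZScoreMap:
    """Per-chromosome dense upper-triangle z matrices plus stratum stats."""

    matrix: ContactMatrix
    z_by_chrom: dict[str, np.ndarray]  # dense, NaN where undefined
    stratum_mean: dict[str, np.ndarray]
    stratum_sd: dict[str, np.ndarray]
    max_depth_bins: int


def loop_zscores(matrix: ContactMatrix, max_depth_bp: int = 100_000_000) -> ZScoreMap:
    """Per-pixel z by distance stratum over unmasked cis pixels.

    Strata with fewer than 10 unmasked pixels, and strata beyond
    ``max_depth_bp``, are left undefined (NaN).
    """
    bg = matrix.binned_genome
    max_depth_bins = max_depth_bp // bg.bin_size
    z_by_chrom: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for chrom in bg.genome.chroms:
        lo, hi = bg.chrom_bin_range(chrom)
        n = hi - lo
        dense = matrix.cis_dense(chrom)
        valid = ~matrix.bin_mask[lo:hi]
        z = np.full((n, n), np.nan)
        mean_d = np.full(n, np.nan)
        sd_d = np.full(n, np.nan)
        for d in range(min(n, max_depth_bins + 1)):
            idx = np.arange(n - d)
            ok = valid[idx] & valid[idx + d]
            if ok.sum() < MIN_STRATUM_PIXELS:
                continue
            vals = dense[idx[ok], idx[ok] + d]
            m = vals.mean()
            s = vals.std()
            mean_d[d] = m
            sd_d[d] = s
            if s > 1e-9 * max(abs(m), 1e-30):  # degenerate stratum -> z = 0
                z[idx[ok], idx[ok] + d] = (vals - m) / s
            else:
                z[idx[ok], idx[ok] + d] = 0.0
        z_by_chrom[chrom] = z
        means[chrom] = mean_d
        sds[chrom] = sd_d
    return ZScoreMap(matrix, z_by_chrom, means, sds, max_depth_bins)


def call_loops(
    zscores: ZScoreMap, z_min: float = 6.0, span_max: int = 1_000_000
) -> pd.DataFrame:
    """Threshold the z map and collapse touching pixels to their z-maximum.

    Connected components use 8-neighbourhood connectivity in (bin1, bin2)
    space.  Span is midpoint-to-midpoint of the two anchor bins.  Returns a
    BEDPE-style frame: chrom, bin1, bin2, anchor coordinates, count, zscore,
    span.
    """
    matrix = zscores.matrix
    bg = matrix.binned_genome
    rows = []
    span_max_bins = span_max // bg.bin_size
    for chrom, z in zscores.z_by_chrom.items():
        lo, hi = bg.chrom_bin_range(chrom)
        dense = matrix.cis_dense(chrom)
        hot = np.zeros_like(z, dtype=bool)
        with np.errstate(invalid="ignore"):
            hot = (z >= z_min) & ~np.isnan(z)
        # span filter before merging so far pixels never seed a call
        ii, jj = np.nonzero(hot)
        too_far = (jj - ii) > span_max_bins
        hot[ii[too_far], jj[too_far]] = False
        labels, n_comp = ndimage.label(hot, structure=np.ones((3, 3), dtype=int))
        if n_comp == 0:
            continue
        for comp in range(1, n_comp + 1):
            ci, cj = np.nonzero(labels == comp)
            best = np.argmax(z[ci, cj])
            i, j = int(ci[best]), int(cj[best])
            span = (j - i) * bg.bin_size
            rows.append(
                {
                    "chrom": chrom,
                    "bin1": i,
                    "bin2": j,
                    "start1": i * bg.bin_size,
                    "end1": (i + 1) * bg.bin_size,
                    "start2": j * bg.bin_size,
                    "end2": (j + 1) * bg.bin_size,
                    "count": float(dense[i, j]),
                    "zscore": float(z[i, j]),
                    "span": int(span),
                }
            )
    loops = pd.DataFrame(
        rows,
        columns=[
            "chrom", "bin1", "bin2", "start1", "end1", "start2", "end2",
            "count", "zscore", "span",
        ],
    )
    return loops.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)


@dataclass
class APAResult:
    """Aggregate submatrix around loop pixels, corner-scaled."""

    aggregate: np.ndarray  # (2k+1) x (2k+1), corner-scaled
    center_score: float
    corner_mean: float
    n_loops_used: int


def apa(
    matrix: ContactMatrix,
    loops: pd.DataFrame,
    window_bp: int = 100_000,
    bin_bp: int = 10_000,
    min_diag_bp: int = 300_000,
) -> APAResult:
    """Aggregate peak analysis at loop pixels.

    Sums the (2w+1) x (2w+1) submatrix around each loop pixel (loops closer
    than ``min_diag_bp`` to the diagonal, or too close to a matrix edge, are
    excluded), then scales by the mean of the aggregate's four corner pixels.
    ``center_score`` is the scaled centre pixel.  Raises if every loop is
    excluded.
    """
    bg = matrix.binned_genome
    if bg.bin_size != bin_bp:
        raise ValueError(f"matrix bin size {bg.bin_size} != requested {bin_bp}")
    k = window_bp // bin_bp
    size = 2 * k + 1
    agg = np.zeros((size, size))
    used = 0
    for chrom, sub in loops.groupby("chrom", sort=False):
        lo, hi = bg.chrom_bin_range(chrom)
        n = hi - lo
        dense = matrix.cis_dense(chrom)
        for _, row in sub.iterrows():
            i, j = int(row["bin1"]), int(row["bin2"])
            if (j - i) * bin_bp < min_diag_bp:
                continue
            if i - k < 0 or j + k >= n or (j - k) - (i + k) < 1:
                continue
            agg += dense[i - k : i + k + 1, j - k : j + k + 1]
            used += 1
    if used == 0:
        raise ValueError("no loops usable for APA after diagonal/edge exclusion")
    corner_mean = float(
        np.mean([agg[0, 0], agg[0, -1], agg[-1, 0], agg[-1, -1]])
    )
    if corner_mean <= 0:
        raise ValueError("APA corner background is zero; cannot scale")
    scaled = agg / corner_mean
    return APAResult(
        aggregate=scaled,
        center_score=float(scaled[k, k]),
        corner_mean=corner_mean,
        n_loops_used=used,
    )
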