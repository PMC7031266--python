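"""A/B compartments and insulation-based TAD segmentation.

Compartments come from the leading eigenvector of the per-chromosome
observed/expected correlation matrix, sign-oriented by a user-supplied
activity track (planted active regions, gene density, ...).  TADs come from a
multi-window TAD-separation (insulation) score: diamond means across each
bin, log-ratio normalised, with boundaries at local minima that drop at least
``delta`` below their flanking maxima and whose cross-boundary contacts are
significantly depleted relative to the flanking diamonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .contacts import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "TADSet",
    "compartment_pc1",
    "insulation_tads",
    "boundary_colocalization",
]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B/masked labels (bedGraph-style frame)."""

    frame: pd.DataFrame  # chrom, start, end, pc1, label

    def write_bedgraph(self, path) -> None:
        self.frame[["chrom", "start", "end", "pc1"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class TADSet:
    """Boundaries, domains and the separation-score track."""

    boundaries: pd.DataFrame  # chrom, bin, pos_bp, sep_score, p, fdr
    domains: pd.DataFrame  # chrom, start, end
    scores: pd.DataFrame  # chrom, start, end, sep_score
    bin_size: int

    def boundary_positions(self, chrom: str) -> np.ndarray:
        sub = self.boundaries[self.boundaries["chrom"] == chrom]
        return sub["pos_bp"].to_numpy()

    def write_domains_bed(self, path) -> None:
        self.domains.to_csv(path, sep="\t", header=False, index=False)

    def write_boundaries_bed(self, path) -> None:
        out = self.boundaries.assign(end=lambda f: f["pos_bp"] + self.bin_size)
        out[["chrom", "pos_bp", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _oe_matrix(dense: np.ndarray) -> np.ndarray:
    """Observed/expected by diagonal; distances with zero mean become neutral 1."""
    n = dense.shape[0]
    oe = np.ones_like(dense)
    for d in range(n):
        diag = np.diagonal(dense, offset=d)
        m = np.nanmean(diag) if len(diag) else 0.0
        if m > 0:
            vals = diag / m
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def compartment_pc1(
    matrix_50kb: ContactMatrix,
    orientation_track: pd.DataFrame,
    min_bins: int = 20,
) -> CompartmentTrack:
    """Leading eigenvector of the O/E correlation matrix, per chromosome.

    The sign is fixed so bins overlapping ``orientation_track`` intervals have
    positive mean PC1; label is A iff PC1 > 0.  Chromosomes with fewer than
    ``min_bins`` usable bins are masked with a warning, as are bins whose O/E
    row is degenerate (zero variance).
    """
    bg = matrix_50kb.binned_genome
    frames = []
    for chrom in bg.genome.chroms:
        lo, hi = bg.chrom_bin_range(chrom)
        n = hi - lo
        starts = np.arange(n) * bg.bin_size
        ends = np.minimum(starts + bg.bin_size, bg.genome.chrom_sizes[chrom])
        pc1 = np.zeros(n)
        label = np.array(["masked"] * n, dtype=object)
        valid = ~matrix_50kb.bin_mask[lo:hi]
        dense = matrix_50kb.cis_dense(chrom)[np.ix_(valid, valid)]
        usable = np.flatnonzero(valid)
        if len(usable) >= min_bins:
            oe = _oe_matrix(dense)
            sd = oe.std(axis=1)
            good = sd > 0
            if good.sum() >= min_bins:
                corr = np.corrcoef(oe[np.ix_(good, good)])
                evals, evecs = np.linalg.eigh(corr)
                vec = evecs[:, -1]
                keep = usable[good]
                # orient: bins overlapping the activity track get positive mean
                track = orientation_track[orientation_track["chrom"] == chrom]
                active = np.zeros(n, dtype=bool)
                for s, e in zip(track["start"], track["end"]):
                    b0, b1 = s // bg.bin_size, (e - 1) // bg.bin_size
                    active[b0 : b1 + 1] = True
                sel = active[keep]
                if sel.any() and vec[sel].mean() < 0:
                    vec = -vec
                pc1[keep] = vec
                label[keep] = np.where(vec > 0, "A", "B")
                label[keep[vec == 0]] = "masked"
            else:
                warnings.warn(
                    f"{chrom}: degenerate O/E matrix; compartments masked",
                    stacklevel=2,
                )
        else:
            warnings.warn(
                f"{chrom}: fewer than {min_bins} unmasked bins; compartments masked",
                stacklevel=2,
            )
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "pc1": pc1,
                 "label": label}
            )
        )
    return CompartmentTrack(pd.concat(frames, ignore_index=True))


def _diamond_scores(dense: np.ndarray, window: int) -> np.ndarray:
    """Mean contacts in the w x w diamond across each bin (NaN at edges)."""
    n = dense.shape[0]
    out = np.full(n, np.nan)
    for i in range(window, n - window):
        block = dense[i - window : i, i + 1 : i + window + 1]
        if np.all(np.isnan(block)):
            continue
        out[i] = np.nanmean(block)
    return out


def insulation_tads(
    matrix: ContactMatrix,
    window_bins: tuple[int, ...] = (5, 10, 20),
    delta: float = 0.1,
    comparison_p: float = 0.05,
    fdr_correct: bool = True,
) -> TADSet:
    """Insulation-minimum TAD segmentation with a delta and significance filter.

    Per bin, the TAD-separation score is the minimum over ``window_bins`` of
    ``log2(diamond mean / chromosome mean diamond)``.  A boundary is a strict
    local minimum that (i) drops >= ``delta`` below both flanking maxima
    within the largest window and (ii) has cross-boundary diamond contacts
    significantly below the two flanking within-domain diamonds (one-sided
    rank test at ``comparison_p``, BH-corrected when ``fdr_correct``).
    """
    bg = matrix.binned_genome
    wmax = max(window_bins)
    bounds_rows, score_rows, dom_rows = [], [], []
    for chrom in bg.genome.chroms:
        lo, hi = bg.chrom_bin_range(chrom)
        n = hi - lo
        if wmax * 2 + 1 > n:
            raise ValueError(
                f"window {wmax} bins too large for chromosome {chrom} ({n} bins)"
            )
        dense = matrix.cis_dense(chrom)
        masked = matrix.bin_mask[lo:hi]
        dense[masked, :] = np.nan
        dense[:, masked] = np.nan
        per_window = []
        for w in window_bins:
            raw = _diamond_scores(dense, w)
            mean = np.nanmean(raw)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_window.append(np.log2(raw / mean) if mean > 0 else raw * np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
            sep = np.nanmin(np.vstack(per_window), axis=0)
        starts = np.arange(n) * bg.bin_size
        ends = np.minimum(starts + bg.bin_size, bg.genome.chrom_sizes[chrom])
        score_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "sep_score": sep}
            )
        )
        # candidate minima with the delta test
        cand = []
        for i in range(1, n - 1):
            if np.isnan(sep[i]) or np.isnan(sep[i - 1]) or np.isnan(sep[i + 1]):
                continue
            if not (sep[i] < sep[i - 1] and sep[i] <= sep[i + 1]):
                continue
            left = sep[max(0, i - wmax) : i]
            right = sep[i + 1 : i + 1 + wmax]
            if not len(left) or not len(right):
                continue
            lm, rm = np.nanmax(left), np.nanmax(right)
            if min(lm, rm) - sep[i] >= delta:
                cand.append(i)
        # significance: boundary diamond vs flanking diamonds
        pvals = []
        w = min(window_bins)
        for i in cand:
            cross = dense[i - w : i, i + 1 : i + w + 1].ravel()
            flank = np.concatenate(
                [
                    dense[max(0, i - 2 * w) : i - w, max(0, i - w) + 1 : i + 1].ravel(),
                    dense[i : i + w, i + 1 + w : i + 1 + 2 * w].ravel(),
                ]
            )
            cross = cross[~np.isnan(cross)]
            flank = flank[~np.isnan(flank)]
            if len(cross) < 3 or len(flank) < 3 or (
                np.ptp(np.concatenate([cross, flank])) == 0
            ):
                pvals.append(1.0)
                continue
            pvals.append(
                float(mannwhitneyu(cross, flank, alternative="less").pvalue)
            )
        pvals = np.array(pvals) if cand else np.array([])
        if len(pvals):
            fdr = (
                multipletests(pvals, method="fdr_bh")[1] if fdr_correct else pvals
            )
            keep = fdr < comparison_p
        else:
            fdr = pvals
            keep = np.array([], dtype=bool)
        kept = [c for c, k in zip(cand, keep) if k]
        for c, p, q in zip(np.array(cand)[keep], pvals[keep], fdr[keep]):
            bounds_rows.append(
                {
                    "chrom": chrom,
                    "bin": int(c),
                    "pos_bp": int(c * bg.bin_size),
                    "sep_score": float(sep[c]),
                    "p": float(p),
                    "fdr": float(q),
                }
            )
        for b0, b1 in zip(kept[:-1], kept[1:]):
            dom_rows.append(
                {"chrom": chrom, "start": b0 * bg.bin_size, "end": b1 * bg.bin_size}
            )
    boundaries = pd.DataFrame(
        bounds_rows, columns=["chrom", "bin", "pos_bp", "sep_score", "p", "fdr"]
    )
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
    scores = pd.concat(score_rows, ignore_index=True)
    return TADSet(boundaries, domains, scores, bg.bin_size)


def boundary_colocalization(
    tads_a: TADSet, tads_b: TADSet, tolerance_bp: int | None = None
) -> tuple[float, float]:
    """Fractions of boundaries with a partner within ``tolerance_bp``.

    Returned in both directions (A-in-B, B-in-A).  Default tolerance is one
    bin.  Empty boundary sets are errors.
    """
    if tolerance_bp is None:
        tolerance_bp = tads_a.bin_size

    def frac(x: TADSet, y: TADSet) -> float:
        if not len(x.boundaries):
            raise ValueError("empty boundary set")
        hits = 0
        for chrom, sub in x.boundaries.groupby("chrom", sort=False):
            other = np.sort(y.boundary_positions(chrom))
            if not len(other):
                continue
            pos = sub["pos_bp"].to_numpy()
            idx = np.searchsorted(other, pos)
            near = np.full(len(pos), np.inf)
            left_ok = idx > 0
            near[left_ok] = np.abs(pos[left_ok] - other[idx[left_ok] - 1])
            right_ok = idx < len(other)
            near[right_ok] = np.minimum(
                near[right_ok], np.abs(other[idx[right_ok]] - pos[right_ok])
            )
            hits += int(np.sum(near <= tolerance_bp))
        return hits / len(x.boundaries)

    return frac(tads_a, tads_b), frac(tads_b, tads_a)
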