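"""Differential count testing and the loop-dynamics classification.

The core test is an exact negative-binomial test with a common
method-of-moments dispersion (floored at 0.01): replicate counts are
library-size normalised by total-count scaling, pooled per condition, and
the observed split of the pooled total between conditions is compared with
its exact NB conditional distribution.  With two replicates per condition a
per-unit dispersion cannot be estimated stably, hence the common dispersion.

Interactions are then classified into the two diet-responsive categories —
rewired (the contact frequency itself changes, p < 0.001) versus
preformed-activated (contact stable but the distal end carries a
differential acetylation peak) — plus a static remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .genome import FragmentMap, Genome, overlap_query

__all__ = [
    "bh_fdr",
    "nb_count_test",
    "classify_loop_dynamics",
    "link_dynamics_to_genes",
    "BinnedTrack",
    "signal_profile",
    "cobinding_split",
    "DIRECTION_THRESHOLDS",
]

# unit-type significance contracts: interactions by raw p, peaks and genes by
# BH-FDR plus a fold-change floor
DIRECTION_THRESHOLDS = {
    "interaction": {"p": 1e-3, "fdr": None, "fc": None},
    "peak": {"p": None, "fdr": 0.05, "fc": 1.5},
    "gene": {"p": None, "fdr": 0.05, "fc": 1.2},
}

DISPERSION_FLOOR = 0.01


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _nb_logpmf(k: np.ndarray, size: float, mean: float) -> np.ndarray:
    p = size / (size + mean)
    return (
        gammaln(k + size)
        - gammaln(size)
        - gammaln(k + 1)
        + size * np.log(p)
        + k * np.log1p(-p)
    )


def _exact_nb_pvalue(a: int, t: int, n_a: int, n_b: int, alpha: float,
                     _cache: dict) -> float:
    """Two-sided exact test of the split of total t between the two groups."""
    if t == 0:
        return 1.0
    probs = _cache.get(t)
    if probs is None:
        k = np.arange(t + 1)
        mu = t / (n_a + n_b)
        la = _nb_logpmf(k, n_a / alpha, n_a * mu)
        lb = _nb_logpmf(t - k, n_b / alpha, n_b * mu)
        logp = la + lb
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        _cache[t] = probs
    p_obs = probs[a]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def estimate_common_dispersion(
    normalized: np.ndarray, groups: list[np.ndarray], floor: float = DISPERSION_FLOOR
) -> float:
    """Pooled method-of-moments dispersion: E[var] = mean + alpha * mean^2."""
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = normalized[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return floor
    return max(num / den, floor)


def nb_count_test(
    counts,
    condition_labels,
    kind: str = "interaction",
    unit_ids=None,
    dispersion: float | None = None,
    thresholds: dict | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Exact NB differential test per unit (interaction, peak, or gene).

    ``counts`` is units x replicates (non-negative integers);
    ``condition_labels`` assigns each column to one of two conditions — the
    first label encountered is condition A and positive ``log2fc`` means
    higher in A.  Direction thresholds follow the unit ``kind``
    (interactions: p < 0.001; peaks: FDR < 0.05 & FC > 1.5; genes:
    FDR < 0.05 & FC > 1.2) unless ``thresholds`` overrides them.
    """
    if isinstance(counts, pd.DataFrame):
        if unit_ids is None:
            unit_ids = counts.index.to_numpy()
        counts = counts.to_numpy()
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be units x replicates")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(np.int64)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    labels = np.asarray(condition_labels)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError("need exactly two conditions")
    idx_a = np.flatnonzero(labels == uniq[0])
    idx_b = np.flatnonzero(labels == uniq[1])
    n_units = counts.shape[0]
    if unit_ids is None:
        unit_ids = np.arange(n_units)

    if normalize:
        lib = counts.sum(axis=0).astype(float)
        mean_lib = lib[lib > 0].mean() if (lib > 0).any() else 1.0
        factors = np.where(lib > 0, mean_lib / np.maximum(lib, 1.0), 1.0)
    else:
        factors = np.ones(counts.shape[1])
    normalized = counts * factors[None, :]

    if dispersion is None:
        dispersion = estimate_common_dispersion(normalized, [idx_a, idx_b])

    pooled_a = np.round(normalized[:, idx_a].sum(axis=1)).astype(np.int64)
    pooled_b = np.round(normalized[:, idx_b].sum(axis=1)).astype(np.int64)
    cache: dict = {}
    pvals = np.ones(n_units)
    for u in range(n_units):
        pvals[u] = _exact_nb_pvalue(
            int(pooled_a[u]),
            int(pooled_a[u] + pooled_b[u]),
            len(idx_a),
            len(idx_b),
            dispersion,
            cache,
        )
    mean_a = normalized[:, idx_a].mean(axis=1)
    mean_b = normalized[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    fdr = bh_fdr(pvals)

    thr = thresholds or DIRECTION_THRESHOLDS[kind]
    sig = np.ones(n_units, dtype=bool)
    if thr.get("p") is not None:
        sig &= pvals < thr["p"]
    if thr.get("fdr") is not None:
        sig &= fdr < thr["fdr"]
    if thr.get("fc") is not None:
        sig &= np.abs(log2fc) > np.log2(thr["fc"])
    direction = np.where(~sig, "ns", np.where(log2fc > 0, "up_A", "up_B"))

    out = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )
    out.attrs["dispersion"] = float(dispersion)
    out.attrs["condition_a"] = uniq[0]
    out.attrs["condition_b"] = uniq[1]
    return out


LOOP_CLASSES = (
    "rewired_gained_A",
    "rewired_gained_B",
    "preformed_activated_A",
    "preformed_activated_B",
    "static",
)


def classify_loop_dynamics(
    interactions: pd.DataFrame,
    interaction_diffs: pd.DataFrame,
    peak_diffs: pd.DataFrame,
    fragments: FragmentMap,
    overlap_fraction: float = 0.0,
    p_rewired: float = 1e-3,
    gene_col: str = "bait_gene",
) -> pd.DataFrame:
    """Label each interaction rewired / preformed-activated / static.

    Rewired: differential-interaction p < ``p_rewired`` (takes precedence).
    Preformed-activated: interaction stable but >= 1 differential acetylation
    peak overlaps the distal (non-bait) fragment; the label's condition is the
    peak's direction (ties between opposing peaks go to the larger |log2fc|).
    ``peak_diffs`` must carry chrom/start/end/direction/log2fc and a
    ``peak_id`` column.  Every interaction must have a differential record.
    """
    inter = interactions.reset_index(drop=True)
    diffs = interaction_diffs.set_index("unit_id")
    if "unit_id" not in inter.columns:
        raise ValueError("interactions need a 'unit_id' column")
    missing = set(inter["unit_id"]) - set(diffs.index)
    if missing:
        raise ValueError(
            f"{len(missing)} interaction(s) missing a differential record"
        )
    joined = inter.join(diffs, on="unit_id", rsuffix="_diff")

    distal = fragments.frame.iloc[inter["other_end_id"].to_numpy()][
        ["chrom", "start", "end"]
    ].reset_index(drop=True)
    diff_peaks = peak_diffs[peak_diffs["direction"] != "ns"].reset_index(drop=True)
    hits = (
        overlap_query(distal, diff_peaks, overlap_fraction)
        if len(diff_peaks)
        else pd.DataFrame({"a_index": [], "b_index": [], "overlap_bp": []})
    )
    peak_dir: dict[int, str] = {}
    peak_ids: dict[int, list] = {}
    for a_idx, sub in hits.groupby("a_index"):
        cand = diff_peaks.iloc[sub["b_index"].to_numpy()]
        best = cand.iloc[np.argmax(np.abs(cand["log2fc"].to_numpy()))]
        peak_dir[int(a_idx)] = best["direction"]
        peak_ids[int(a_idx)] = list(cand["peak_id"])

    classes = []
    distal_peaks_col = []
    for i in range(len(joined)):
        row = joined.iloc[i]
        if row["p"] < p_rewired:
            cls = "rewired_gained_A" if row["log2fc"] > 0 else "rewired_gained_B"
        elif i in peak_dir:
            cls = (
                "preformed_activated_A"
                if peak_dir[i] == "up_A"
                else "preformed_activated_B"
            )
        else:
            cls = "static"
        classes.append(cls)
        distal_peaks_col.append(peak_ids.get(i, []))
    out = joined.copy()
    out["loop_class"] = classes
    out["distal_peak_ids"] = distal_peaks_col
    out["linked_genes"] = (
        out[gene_col].apply(lambda g: g if isinstance(g, list) else [g])
        if gene_col in out.columns
        else [[] for _ in range(len(out))]
    )
    return out


def link_dynamics_to_genes(
    records: pd.DataFrame, degs: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per (gene, loop class), deduplicated, with DE status attached.

    Genes without any classified loop are absent; a gene carrying loops of
    several classes appears once per class.
    """
    exploded = records[["loop_class", "linked_genes"]].explode("linked_genes")
    exploded = exploded.dropna(subset=["linked_genes"])
    table = (
        exploded.drop_duplicates()
        .rename(columns={"linked_genes": "gene_id"})
        .reset_index(drop=True)
    )
    if degs is not None:
        status = degs.set_index("unit_id")["direction"]
        table["de_status"] = table["gene_id"].map(status).fillna("ns")
    return table.sort_values(["gene_id", "loop_class"]).reset_index(drop=True)


@dataclass
class BinnedTrack:
    """A per-bin signal track (coverage, ChIP signal, ...) over a genome."""

    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray]

    @classmethod
    def from_bedgraph(cls, frame: pd.DataFrame, genome: Genome, bin_size: int):
        values = {
            c: np.zeros(-(-genome.chrom_sizes[c] // bin_size))
            for c in genome.chroms
        }
        for _, row in frame.iterrows():
            arr = values[row["chrom"]]
            b0 = int(row["start"]) // bin_size
            b1 = (int(row["end"]) - 1) // bin_size
            arr[b0 : b1 + 1] = row["value"]
        return cls(genome, bin_size, values)

    def value_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        arr = self.values[chrom]
        idx = np.clip(np.asarray(pos) // self.bin_size, 0, len(arr) - 1).astype(int)
        return arr[idx]


def signal_profile(
    track: BinnedTrack,
    regions: pd.DataFrame,
    flank_bp: int,
    n_points: int = 41,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signal resampled to ``n_points`` across region centres +/- flank.

    Returns (per-region matrix, mean curve, indices of regions used).
    Regions whose centre lies outside the chromosome are skipped with a
    warning; positions beyond chromosome ends clamp to the edge bin.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if not len(regions):
        raise ValueError("no regions supplied")
    offsets = np.linspace(-flank_bp, flank_bp, n_points)
    mats = []
    used = []
    for i, row in regions.reset_index(drop=True).iterrows():
        chrom = row["chrom"]
        center = (int(row["start"]) + int(row["end"])) // 2
        if chrom not in track.genome or not (
            0 <= center < track.genome.chrom_sizes[chrom]
        ):
            warnings.warn(f"region {i} centre outside chromosome; skipped",
                          stacklevel=2)
            continue
        pos = np.clip(center + offsets, 0, track.genome.chrom_sizes[chrom] - 1)
        mats.append(track.value_at(chrom, pos.astype(int)))
        used.append(i)
    if not mats:
        raise ValueError("no usable regions")
    matrix = np.vstack(mats)
    return matrix, matrix.mean(axis=0), np.array(used)


def cobinding_split(
    sites_primary: pd.DataFrame, sites_premark: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition primary sites by >= 1 bp overlap with the premark set."""
    primary = sites_primary.reset_index(drop=True)
    if not len(primary):
        return primary, primary
    if not len(sites_premark):
        return primary.iloc[0:0], primary
    hits = overlap_query(primary, sites_premark, 0.0)
    with_idx = np.zeros(len(primary), dtype=bool)
    with_idx[hits["a_index"].unique()] = True
    return (
        primary[with_idx].reset_index(drop=True),
        primary[~with_idx].reset_index(drop=True),
    )
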