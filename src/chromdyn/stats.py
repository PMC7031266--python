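"""Expression/interaction association statistics, permutation overlap tests,
nearest-TSS assignment, and the indirect-calorimetry energy formula.

The Mann-Whitney U test is implemented here rather than delegated: the exact
path enumerates all group assignments (used for small samples, and by the
test suite as its own contract), and the asymptotic path applies midrank tie
and continuity corrections.  The Monte-Carlo overlap test mirrors the
size-matched `shuffle`-within-universe procedure: every iteration re-places
the query intervals uniformly inside the universe, preserving their number
and lengths, and the empirical p uses the add-one estimator so it is never
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .genome import overlap_query, validate_intervals

__all__ = [
    "mann_whitney",
    "tpm_bin",
    "TPM_BIN_LABELS",
    "expression_by_loop_count",
    "gene_loop_strata",
    "expression_by_strata",
    "nearest_tss_assignment",
    "ShuffleConfig",
    "ShuffleResult",
    "shuffle_intervals",
    "shuffle_overlap_test",
    "matched_control_annotation_overlap",
    "energy_expenditure",
]

EXACT_MW_MAX_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midrank ties).

    Exact enumeration of all assignments when n1 + n2 <= 8; otherwise the
    normal approximation with tie and continuity corrections.  Returns
    (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.ptp(pooled) == 0:
        return u1, 1.0

    n = n1 + n2
    if n <= EXACT_MW_MAX_N:
        us = []
        for idx in combinations(range(n), n1):
            r = ranks[list(idx)].sum()
            us.append(r - n1 * (n1 + 1) / 2)
        us = np.asarray(us)
        lo = float(np.mean(us <= u1 + 1e-9))
        hi = float(np.mean(us >= u1 - 1e-9))
        return u1, min(1.0, 2 * min(lo, hi))

    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return u1, min(1.0, 2 * float(norm.sf(abs(z))))


TPM_BIN_LABELS = ("0", "(0,1]", "(1,10]", ">10")


def tpm_bin(tpm) -> np.ndarray:
    """Four expression categories: TPM = 0, (0,1], (1,10], > 10."""
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm < 0):
        raise ValueError("TPM must be non-negative")
    out = np.empty(tpm.shape, dtype=object)
    out[tpm == 0] = TPM_BIN_LABELS[0]
    out[(tpm > 0) & (tpm <= 1)] = TPM_BIN_LABELS[1]
    out[(tpm > 1) & (tpm <= 10)] = TPM_BIN_LABELS[2]
    out[tpm > 10] = TPM_BIN_LABELS[3]
    return out


def expression_by_loop_count(
    expression: pd.DataFrame,
    interactions: pd.DataFrame,
    tpm_col: str,
    gene_col: str = "bait_gene",
) -> dict:
    """Loop counts per gene, stratified by TPM bin, with adjacent-bin tests.

    Genes absent from the interaction table count zero loops.  Adjacent
    expression bins are compared by Mann-Whitney; empty bins are skipped
    with a warning.
    """
    per_gene = interactions.groupby(gene_col).size()
    loops = expression["gene_id"].map(per_gene).fillna(0).astype(int)
    bins = tpm_bin(expression[tpm_col])
    counts = {lab: loops[bins == lab].to_numpy() for lab in TPM_BIN_LABELS}
    medians = {
        lab: (float(np.median(v)) if len(v) else np.nan)
        for lab, v in counts.items()
    }
    means = {
        lab: (float(np.mean(v)) if len(v) else np.nan) for lab, v in counts.items()
    }
    pairwise = {}
    for lo, hi in zip(TPM_BIN_LABELS[:-1], TPM_BIN_LABELS[1:]):
        if len(counts[lo]) == 0 or len(counts[hi]) == 0:
            warnings.warn(f"empty TPM bin; skipping {lo} vs {hi}", stacklevel=2)
            continue
        _, p = mann_whitney(counts[lo], counts[hi])
        pairwise[(lo, hi)] = p
    return {
        "loop_counts": counts,
        "medians": medians,
        "means": means,
        "pairwise_p": pairwise,
    }


STRATA_BANDS = ((1, 1, "1"), (2, 5, "2-5"), (6, np.inf, ">5"))


def gene_loop_strata(
    expression: pd.DataFrame,
    interactions: pd.DataFrame,
    acetylated_col: str = "acetylated",
    gene_col: str = "bait_gene",
) -> pd.Series:
    """Per-gene stratum from loop count and distal-end acetylation.

    Strata: ``none``; ``1/2-5/>5`` loops crossed ``with``/``without`` at
    least one acetylated distal end.  Exhaustive and disjoint over genes.
    """
    n_loops = interactions.groupby(gene_col).size()
    n_acet = interactions.groupby(gene_col)[acetylated_col].sum()
    labels = []
    for g in expression["gene_id"]:
        n = int(n_loops.get(g, 0))
        if n == 0:
            labels.append("none")
            continue
        a = int(n_acet.get(g, 0)) > 0
        for lo, hi, name in STRATA_BANDS:
            if lo <= n <= hi:
                labels.append(f"{name}_{'with' if a else 'without'}")
                break
    return pd.Series(labels, index=expression.index, name="stratum")


def expression_by_strata(
    expression: pd.DataFrame, strata: pd.Series, tpm_col: str
) -> dict:
    """TPM distributions per stratum and with-vs-without tests per band."""
    tpm = expression[tpm_col]
    groups = {s: tpm[strata == s].to_numpy(float) for s in strata.unique()}
    medians = {s: float(np.median(v)) for s, v in groups.items() if len(v)}
    tests = {}
    for _, _, name in STRATA_BANDS:
        w, wo = groups.get(f"{name}_with", []), groups.get(f"{name}_without", [])
        if len(w) == 0 or len(wo) == 0:
            warnings.warn(f"empty stratum in band {name}; test skipped",
                          stacklevel=2)
            continue
        _, p = mann_whitney(w, wo)
        tests[name] = p
    sizes = {s: int(len(v)) for s, v in groups.items()}
    return {"groups": groups, "medians": medians, "tests": tests, "sizes": sizes}


def nearest_tss_assignment(
    sites: pd.DataFrame, expression: pd.DataFrame, window_bp: int = 50_000
) -> pd.DataFrame:
    """Assign each site to the nearest TSS within +/- ``window_bp``.

    Distance is the gap between the site interval and the TSS point (zero if
    the TSS falls inside the site).  Equidistant ties break to the smaller
    gene_id.  Unassigned sites get gene_id None.
    """
    validate_intervals(sites)
    rows = []
    by_chrom = {
        c: sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, sub in expression.groupby("chrom", sort=False)
    }
    for i, site in sites.reset_index(drop=True).iterrows():
        sub = by_chrom.get(site["chrom"])
        best_gene, best_d = None, None
        if sub is not None:
            tss = sub["tss"].to_numpy()
            d = np.maximum.reduce(
                [site["start"] - tss, tss - (site["end"] - 1),
                 np.zeros(len(tss), dtype=np.int64)]
            )
            ok = d <= window_bp
            if ok.any():
                dmin = d[ok].min()
                cand = sub.loc[np.flatnonzero(ok)[d[ok] == dmin], "gene_id"]
                best_gene = sorted(cand)[0]
                best_d = int(dmin)
        rows.append({"site_index": i, "gene_id": best_gene, "distance": best_d})
    return pd.DataFrame(rows)


@dataclass
class ShuffleConfig:
    """Monte-Carlo shuffle settings; placements are always size-matched."""

    n_iter: int = 10_000
    seed: int = 0
    max_rounds: int = 200

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class ShuffleResult:
    observed: int
    p: float
    null_counts: np.ndarray

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_counts.std())


class _Universe:
    """Linearised placement universe shared by all iterations."""

    def __init__(self, universe: pd.DataFrame):
        validate_intervals(universe)
        uni = universe.sort_values(["chrom", "start"]).reset_index(drop=True)
        chroms = list(dict.fromkeys(uni["chrom"]))
        self.offsets = {}
        off = 0
        for c in chroms:
            self.offsets[c] = off
            off += int(uni.loc[uni["chrom"] == c, "end"].max()) + 1
        self.chroms = chroms
        self.start_lin = (
            uni["start"] + uni["chrom"].map(self.offsets)
        ).to_numpy(np.int64)
        self.lengths = (uni["end"] - uni["start"]).to_numpy(np.int64)
        self.frame = uni

    def to_linear(self, frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        off = frame["chrom"].map(self.offsets)
        if off.isna().any():
            # chromosomes absent from the universe get their own far offsets
            extra = sorted(set(frame.loc[off.isna(), "chrom"]))
            base = max(self.offsets.values()) + int(self.lengths.sum()) + 1
            for k, c in enumerate(extra):
                self.offsets[c] = base + (k + 1) * 10**10
            off = frame["chrom"].map(self.offsets)
        start = (frame["start"] + off).to_numpy(np.int64)
        end = (frame["end"] + off).to_numpy(np.int64)
        return start, end


def shuffle_intervals(
    lengths: np.ndarray, uni: _Universe, rng: np.random.Generator,
    max_rounds: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Place intervals of the given lengths uniformly inside the universe,
    without overlap among the placed intervals.  Returns linear (start, end).
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = np.empty(len(lengths), dtype=np.int64)
    # sample per unique length: weights = placeable starts per universe interval
    for L in np.unique(lengths):
        sel = lengths == L
        w = np.maximum(uni.lengths - L + 1, 0).astype(float)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"universe too small to place an interval of length {L}"
            )
        cum = np.cumsum(w)
        k = int(sel.sum())
        u = rng.random(k) * total
        idx = np.searchsorted(cum, u, side="right")
        off = (rng.random(k) * w[idx]).astype(np.int64)
        starts[sel] = uni.start_lin[idx] + off
    ends = starts + lengths
    for _ in range(max_rounds):
        order = np.argsort(starts, kind="stable")
        s, e = starts[order], ends[order]
        bad_pos = np.flatnonzero(s[1:] < np.maximum.accumulate(e[:-1])) + 1
        if len(bad_pos) == 0:
            return starts, ends
        redo = order[bad_pos]
        for L in np.unique(lengths[redo]):
            sel = redo[lengths[redo] == L]
            w = np.maximum(uni.lengths - L + 1, 0).astype(float)
            cum = np.cumsum(w)
            u = rng.random(len(sel)) * cum[-1]
            idx = np.searchsorted(cum, u, side="right")
            off = (rng.random(len(sel)) * w[idx]).astype(np.int64)
            starts[sel] = uni.start_lin[idx] + off
            ends[sel] = starts[sel] + L
    raise ValueError("universe too crowded: could not place intervals "
                     f"without overlap in {max_rounds} rounds")


def _count_overlapping(
    q_start: np.ndarray, q_end: np.ndarray,
    ref_start: np.ndarray, ref_end: np.ndarray,
) -> int:
    """Number of query intervals overlapping (>= 1 bp) the merged reference."""
    idx = np.searchsorted(ref_start, q_end, side="left")
    hit = (idx > 0) & (ref_end[np.maximum(idx - 1, 0)] > q_start)
    return int(hit.sum())


def _merge_linear(start: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(start)
    s, e = start[order], end[order]
    keep_s, keep_e = [], []
    for a, b in zip(s, e):
        if keep_e and a <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], b)
        else:
            keep_s.append(a)
            keep_e.append(b)
    return np.array(keep_s), np.array(keep_e)


def shuffle_overlap_test(
    query_set: pd.DataFrame,
    reference_set: pd.DataFrame,
    universe: pd.DataFrame,
    config: ShuffleConfig | None = None,
) -> ShuffleResult:
    """Monte-Carlo significance of query/reference interval overlap.

    Observed statistic: number of query intervals overlapping the reference
    by >= 1 bp.  Each iteration re-places the query set (size-matched, count
    preserved) uniformly within the universe; the empirical p-value is
    ``(r + 1) / (n_iter + 1)`` with ``r`` the number of iterations reaching
    the observed overlap.
    """
    config = config or ShuffleConfig()
    validate_intervals(query_set)
    validate_intervals(reference_set)
    uni = _Universe(universe)
    q_len = (query_set["end"] - query_set["start"]).to_numpy(np.int64)
    if uni.lengths.sum() < 2 * q_len.sum():
        raise ValueError(
            "universe too small: must cover at least twice the summed query length"
        )
    q_start, q_end = uni.to_linear(query_set)
    r_start, r_end = uni.to_linear(reference_set)
    r_start, r_end = _merge_linear(r_start, r_end)
    observed = _count_overlapping(q_start, q_end, r_start, r_end)
    rng = np.random.default_rng(config.seed)
    null_counts = np.empty(config.n_iter, dtype=np.int64)
    for it in range(config.n_iter):
        s, e = shuffle_intervals(q_len, uni, rng, config.max_rounds)
        null_counts[it] = _count_overlapping(s, e, r_start, r_end)
    r = int(np.sum(null_counts >= observed))
    p = (r + 1) / (config.n_iter + 1)
    return ShuffleResult(observed=observed, p=p, null_counts=null_counts)


def matched_control_annotation_overlap(
    query_set: pd.DataFrame,
    annotation_sets: dict[str, pd.DataFrame],
    universe: pd.DataFrame,
    min_overlap_fraction: float = 0.10,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Query vs size-matched-control annotation overlap percentages.

    For each annotation set: the percentage of query intervals with at least
    ``min_overlap_fraction`` of their length covered by an annotation
    interval, and the same for ``n_controls`` control sets obtained by
    reshuffling the query positions within the universe (region count and
    size distribution retained).
    """
    validate_intervals(query_set)
    uni = _Universe(universe)
    q_len = (query_set["end"] - query_set["start"]).to_numpy(np.int64)
    rng = np.random.default_rng(seed)

    def pct(frame: pd.DataFrame, annot: pd.DataFrame) -> float:
        if not len(frame):
            return np.nan
        hits = overlap_query(frame, annot, min_overlap_fraction)
        return 100.0 * len(set(hits["a_index"])) / len(frame)

    controls = []
    inv_off = {v: k for k, v in uni.offsets.items()}
    bounds = np.array(sorted(uni.offsets.values()) + [np.iinfo(np.int64).max])
    names = [inv_off[b] for b in sorted(uni.offsets.values())]
    for _ in range(n_controls):
        s, e = shuffle_intervals(q_len, uni, rng)
        which = np.searchsorted(bounds, s, side="right") - 1
        chroms = [names[w] for w in which]
        offs = np.array([uni.offsets[c] for c in chroms], dtype=np.int64)
        controls.append(
            pd.DataFrame({"chrom": chroms, "start": s - offs, "end": e - offs})
        )

    rows = []
    for name, annot in annotation_sets.items():
        qpct = pct(query_set, annot)
        cpcts = np.array([pct(c, annot) for c in controls])
        rows.append(
            {
                "annotation": name,
                "query_pct": qpct,
                "control_mean": float(cpcts.mean()),
                "control_sd": float(cpcts.std()),
            }
        )
    return pd.DataFrame(rows)


EE_VO2_COEF = 3.941  # kcal per litre O2
EE_VCO2_COEF = 1.106  # kcal per litre CO2


def energy_expenditure(vo2, vco2):
    """Indirect-calorimetry energy expenditure (kcal/h).

    ``EE = 3.941 * VO2 + 1.106 * VCO2`` with gas rates in l/h.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas exchange rates must be non-negative")
    out = EE_VO2_COEF * vo2 + EE_VCO2_COEF * vco2
    return float(out) if out.ndim == 0 else out
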