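"""Planted-truth simulation of every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes, at
desk scale: distance-decaying cis contacts with planted compartments, TADs
and loops; promoter-capture count tables with planted rewired /
preformed-activated / static interactions across two dietary conditions;
transcription-factor and acetylation peak sets with planted co-binding and
fold changes; expression counts tied to the planted loop classes; and
metabolic-cage gas-exchange tables.  Ground truth is carried alongside every
output so each pipeline stage can be scored against what was planted.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMatrix
from .genome import BinnedGenome, FragmentMap, Genome
from .stats import _Universe, energy_expenditure, shuffle_intervals

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_genome",
    "simulate_contacts",
    "simulate_capture",
    "simulate_peaks_expression_cage",
    "write_outputs",
]

CONDITIONS = ("A", "B")  # A = lipid-rich-style, B = carbohydrate-rich-style

LOOP_CLASS_FRACTIONS = {
    "rewired_gained_A": 0.08,
    "rewired_gained_B": 0.08,
    "preformed_activated_A": 0.12,
    "preformed_activated_B": 0.12,
    "static": 0.60,
}

# expression tiers map onto the four TPM bins; mean planted loops per tier
# rise with expression (the association the capture analysis is meant to see)
EXPR_TIERS = (
    {"frac": 0.15, "tpm_range": (0.0, 0.0), "mean_loops": 0.3},
    {"frac": 0.20, "tpm_range": (0.2, 0.9), "mean_loops": 1.2},
    {"frac": 0.35, "tpm_range": (1.5, 9.0), "mean_loops": 3.0},
    {"frac": 0.30, "tpm_range": (12.0, 300.0), "mean_loops": 6.0},
)


@dataclass
class SimulationConfig:
    """Defaults are the desk-scale study conditions used throughout."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    bin_size: int = 10_000
    compartment_bin: int = 50_000
    compartment_block: int = 2_000_000
    compartment_strength: float = 0.4
    decay_alpha: float = 1.0
    tad_size: int = 400_000
    tad_cross_ratio: float = 0.2
    tad_range: int = 300_000
    n_loops_per_chrom: int = 20
    loop_fc: float = 5.0
    loop_span_range: tuple = (350_000, 950_000)
    pairs_per_replicate: int = 5_000_000
    hic_replicates: int = 2
    chip_replicates: int = 3
    rna_replicates: int = 5
    nb_dispersion: float = 0.05
    capture_dispersion: float = 0.02
    fragment_mean: int = 4_000
    fragment_min: int = 200
    n_genes: int = 2_500
    gene_min_spacing: int = 10_000
    n_baits: int = 2_000
    n_capture_interactions: int = 5_000
    n_capture_background: int = 45_000
    capture_base_count: float = 120.0
    capture_ref_distance: int = 50_000
    capture_span_range: tuple = (30_000, 950_000)
    capture_enrichment: float = 8.0
    rewired_fc: float = 4.0
    class_fractions: dict = field(
        default_factory=lambda: dict(LOOP_CLASS_FRACTIONS)
    )
    peak_base_count: float = 100.0
    peak_fc: float = 3.0
    n_background_acetyl: int = 2_000
    acetyl_peak_len: int = 1_000
    n_enhancers: int = 8_000
    enhancer_len: int = 1_000
    n_tf_peaks: int = 2_000
    tf_peak_len: int = 500
    cobinding_fraction: float = 0.5
    expr_base_lib: float = 3e6
    de_fc: float = 2.0
    acetyl_expr_boost: float = 3.0
    cage_mice_per_group: int = 4
    cage_intervals: int = 100
    cage_vo2_mean: dict = field(default_factory=lambda: {"A": 0.070, "B": 0.085})
    cage_rer: dict = field(default_factory=lambda: {"A": 0.75, "B": 0.95})
    cage_vo2_sd: float = 0.006

    def validate(self) -> None:
        if self.nb_dispersion < 0 or self.capture_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(l < 5_000_000 for l in self.chrom_lengths.values()):
            raise ValueError("chromosomes must be at least 5 Mb")
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")


@dataclass
class SyntheticTruth:
    """Everything that was planted, sufficient to score every stage."""

    config: SimulationConfig
    genome: Genome
    fragments: FragmentMap
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, length, tier, base_tpm
    comp_labels: dict  # chrom -> array of 'A'/'B' per compartment_bin
    boundaries_bp: dict  # chrom -> array of planted boundary positions
    loops: pd.DataFrame  # chrom, bin1, bin2, fc, condition_effect
    capture: pd.DataFrame | None = None
    enhancers: pd.DataFrame | None = None
    tf_peaks: dict | None = None
    acetyl_peaks: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    cage: pd.DataFrame | None = None

    def bait_ids(self) -> np.ndarray:
        if self.capture is None:
            raise ValueError("capture interactions not simulated yet")
        return np.unique(self.capture["bait_id"])


def _rng(config: SimulationConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed * 1_000_003 + salt) % 2**63)


def make_genome(config: SimulationConfig | None = None) -> SyntheticTruth:
    """Chromosomes, restriction-fragment map, gene table, and planted
    compartments / TAD boundaries / loop anchors."""
    config = config or SimulationConfig()
    config.validate()
    rng = _rng(config, 1)
    genome = Genome(dict(config.chrom_lengths))

    # fragments: exponential lengths with a floor, trimmed to tile exactly
    frames = []
    for chrom, size in genome.chrom_sizes.items():
        n_guess = int(size / config.fragment_mean * 1.5) + 10
        lens = np.maximum(
            rng.exponential(config.fragment_mean - config.fragment_min, n_guess)
            + config.fragment_min,
            config.fragment_min,
        ).astype(np.int64)
        ends = np.cumsum(lens)
        ends = ends[ends < size]
        cuts = np.concatenate([[0], ends, [size]])
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": cuts[:-1], "end": cuts[1:]})
        )
    fragments = FragmentMap(pd.concat(frames, ignore_index=True), genome)

    # genes on a spaced grid with jitter
    slots = []
    margin = 5_000
    for chrom, size in genome.chrom_sizes.items():
        pos = np.arange(margin, size - margin, config.gene_min_spacing)
        slots.extend((chrom, int(p)) for p in pos)
    if config.n_genes > len(slots):
        raise ValueError(
            f"cannot place {config.n_genes} genes with spacing "
            f"{config.gene_min_spacing} (only {len(slots)} slots)"
        )
    pick = rng.choice(len(slots), size=config.n_genes, replace=False)
    pick.sort()
    jitter = rng.integers(0, config.gene_min_spacing // 4, size=config.n_genes)
    tiers = rng.choice(
        len(EXPR_TIERS), size=config.n_genes,
        p=[t["frac"] for t in EXPR_TIERS],
    )
    base_tpm = np.empty(config.n_genes)
    for k, tier in enumerate(EXPR_TIERS):
        sel = tiers == k
        lo, hi = tier["tpm_range"]
        if hi == 0:
            base_tpm[sel] = 0.0
        else:
            base_tpm[sel] = np.exp(
                rng.uniform(np.log(lo), np.log(hi), size=int(sel.sum()))
            )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{k:05d}" for k in range(config.n_genes)],
            "chrom": [slots[s][0] for s in pick],
            "tss": [slots[s][1] + int(j) for s, j in zip(pick, jitter)],
            "strand": rng.choice(["+", "-"], size=config.n_genes),
            "length": np.exp(rng.normal(np.log(2_000), 0.4, config.n_genes))
            .astype(np.int64)
            .clip(300, 20_000),
            "tier": tiers,
            "base_tpm": base_tpm,
        }
    )

    # compartments: alternating blocks (a multiple of the TAD size so block
    # edges coincide with planted boundaries)
    comp_labels = {}
    per_block = config.compartment_block // config.compartment_bin
    for chrom, size in genome.chrom_sizes.items():
        n = -(-size // config.compartment_bin)
        block = np.arange(n) // per_block
        comp_labels[chrom] = np.where(block % 2 == 0, "A", "B")

    boundaries_bp = {
        chrom: np.arange(config.tad_size, size, config.tad_size, dtype=np.int64)
        for chrom, size in genome.chrom_sizes.items()
    }

    # loop anchors at bin resolution, spans inside the configured range; both
    # anchors sit inside one compartment block, clear of block edges, as
    # regulatory loops are intra-compartment structures
    bs = config.bin_size
    block_bins = config.compartment_block // bs
    edge_clear = 8
    rows = []
    for chrom, size in genome.chrom_sizes.items():
        n = size // bs
        n_blocks = n // block_bins
        lo_span, hi_span = (s // bs for s in config.loop_span_range)
        hi_span = min(hi_span, block_bins - 2 * edge_clear - 1)
        taken: set[tuple[int, int]] = set()
        tries = 0
        while (
            len([r for r in rows if r["chrom"] == chrom]) < config.n_loops_per_chrom
        ):
            tries += 1
            if tries > 10_000:
                raise ValueError("could not place loops; loosen constraints")
            span = int(rng.integers(lo_span, hi_span + 1))
            blk = int(rng.integers(0, n_blocks))
            lo_ok = blk * block_bins + edge_clear
            hi_ok = (blk + 1) * block_bins - edge_clear - span
            if hi_ok <= lo_ok:
                continue
            i = int(rng.integers(lo_ok, hi_ok))
            j = i + span
            if any(abs(i - a) < 4 and abs(j - b) < 4 for a, b in taken):
                continue
            taken.add((i, j))
            rows.append(
                {
                    "chrom": chrom,
                    "bin1": i,
                    "bin2": j,
                    "fc": config.loop_fc,
                    "condition_effect": "shared",
                }
            )
    loops = pd.DataFrame(
        rows, columns=["chrom", "bin1", "bin2", "fc", "condition_effect"]
    )
    return SyntheticTruth(
        config=config,
        genome=genome,
        fragments=fragments,
        genes=genes,
        comp_labels=comp_labels,
        boundaries_bp=boundaries_bp,
        loops=loops,
    )


def _cis_weights(truth: SyntheticTruth, chrom: str) -> tuple[np.ndarray, ...]:
    """Upper-triangle planted intensity for one chromosome at bin_size."""
    cfg = truth.config
    bs = cfg.bin_size
    n = truth.genome.chrom_sizes[chrom] // bs
    iu = np.triu_indices(n)
    i, j = iu
    d = j - i
    w = (d + 1.0) ** (-cfg.decay_alpha)
    # compartment preference
    ratio = cfg.compartment_bin // bs
    labels = truth.comp_labels[chrom]
    lab_per_bin = labels[np.minimum(np.arange(n) // ratio, len(labels) - 1)]
    same = lab_per_bin[i] == lab_per_bin[j]
    s = cfg.compartment_strength
    w *= np.where(same, 1.0 + s, 1.0 - s)
    # TAD suppression of short-range cross-boundary contacts
    dom = (np.arange(n) * bs) // cfg.tad_size
    cross = (dom[i] != dom[j]) & (d * bs <= cfg.tad_range)
    w[cross] *= cfg.tad_cross_ratio
    # loops
    sub = truth.loops[truth.loops["chrom"] == chrom]
    if len(sub):
        flat = i * n + j  # i <= j on the upper triangle
        order = np.argsort(flat)
        targets = sub["bin1"].to_numpy() * n + sub["bin2"].to_numpy()
        pos = order[np.searchsorted(flat[order], targets)]
        w[pos] *= sub["fc"].to_numpy()
    return i, j, w, n


def simulate_contacts(
    truth: SyntheticTruth,
    return_pairs: bool = False,
    pairs_per_replicate: int | None = None,
):
    """Cis contact data per (condition, replicate).

    Returns ``{(cond, rep): ContactMatrix}`` by default, or valid-pair
    DataFrames (chrom1, pos1, chrom2, pos2) when ``return_pairs`` — the
    matrix path avoids materialising pair rows at depth.  Replicate counts
    are gamma-overdispersed multinomial draws (NB-like) around the planted
    intensity; the matrix total equals the library size exactly.
    """
    cfg = truth.config
    rng = _rng(cfg, 2)
    n_pairs = pairs_per_replicate or cfg.pairs_per_replicate
    bs = cfg.bin_size
    bg = BinnedGenome(truth.genome, bs)
    per_chrom = {c: _cis_weights(truth, c) for c in truth.genome.chroms}
    chrom_w = np.array([per_chrom[c][2].sum() for c in truth.genome.chroms])
    chrom_p = chrom_w / chrom_w.sum()
    out = {}
    for cond in CONDITIONS:
        for rep in range(cfg.hic_replicates):
            alloc = rng.multinomial(n_pairs, chrom_p)
            pieces = []
            mat_rows, mat_cols, mat_vals = [], [], []
            for ci, chrom in enumerate(truth.genome.chroms):
                i, j, w, nb = per_chrom[chrom]
                if cfg.nb_dispersion > 0:
                    shape = 1.0 / cfg.nb_dispersion
                    noisy = w * rng.gamma(shape, 1.0 / shape, size=len(w))
                else:
                    noisy = w
                p = noisy / noisy.sum()
                counts = rng.multinomial(alloc[ci], p)
                nz = counts > 0
                ii, jj, cc = i[nz], j[nz], counts[nz]
                if return_pairs:
                    reps = np.repeat(np.arange(len(cc)), cc)
                    b1, b2 = ii[reps], jj[reps]
                    pos1 = b1 * bs + rng.integers(0, bs, size=len(b1))
                    pos2 = b2 * bs + rng.integers(0, bs, size=len(b2))
                    pieces.append(
                        pd.DataFrame(
                            {
                                "chrom1": chrom,
                                "pos1": pos1,
                                "chrom2": chrom,
                                "pos2": pos2,
                            }
                        )
                    )
                else:
                    off = bg.chrom_offsets[chrom]
                    mat_rows.append(ii + off)
                    mat_cols.append(jj + off)
                    mat_vals.append(cc)
            if return_pairs:
                out[(cond, rep)] = pd.concat(pieces, ignore_index=True)
            else:
                mat = sp.coo_matrix(
                    (
                        np.concatenate(mat_vals).astype(float),
                        (np.concatenate(mat_rows), np.concatenate(mat_cols)),
                    ),
                    shape=(bg.n_bins, bg.n_bins),
                ).tocsr()
                out[(cond, rep)] = ContactMatrix(
                    bg, mat, library_total=float(alloc.sum())
                )
    return out


def simulate_capture(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-bait capture count tables with planted dynamics classes.

    Baits are the fragments containing gene TSSs.  Planted interactions are
    allocated to genes in proportion to their expression tier; each gets the
    capture enrichment over the decay background.  Rewired classes add a
    between-condition fold change on the interaction counts; preformed
    classes keep counts equal across conditions (their signal is the
    differential acetylation peak planted later at the distal end).
    Background (non-interacting) pairs anchor the decay background.
    Replicate counts are NB with the capture dispersion.  The result is also
    stored on ``truth.capture``.
    """
    cfg = truth.config
    rng = _rng(cfg, 3)
    frags = truth.fragments
    mids = frags.midpoints()
    chroms = frags.frame["chrom"].to_numpy()

    bait_frag = np.array(
        [
            frags.fragment_at(c, t)
            for c, t in zip(truth.genes["chrom"], truth.genes["tss"])
        ]
    )
    gene_order = np.argsort(bait_frag, kind="stable")
    seen: dict[int, str] = {}
    for gidx in gene_order:
        f = int(bait_frag[gidx])
        if f not in seen:
            seen[f] = truth.genes["gene_id"].iloc[gidx]
    bait_items = list(seen.items())[: cfg.n_baits]
    bait_of_gene = {g: f for f, g in bait_items}

    # allocate planted interactions per gene by expression tier
    mean_loops = np.array([EXPR_TIERS[t]["mean_loops"] for t in truth.genes["tier"]])
    n_per_gene = rng.poisson(mean_loops)
    rows = []
    lo_span, hi_span = cfg.capture_span_range
    used_distal: set[int] = set()  # unique distal ends keep planting clean
    for gidx in np.flatnonzero(n_per_gene):
        gene = truth.genes["gene_id"].iloc[gidx]
        if gene not in bait_of_gene:
            continue
        b = bait_of_gene[gene]
        chrom = chroms[b]
        size = truth.genome.chrom_sizes[chrom]
        for _ in range(int(n_per_gene[gidx])):
            for _try in range(8):
                span = int(
                    np.exp(rng.uniform(np.log(lo_span), np.log(hi_span)))
                )
                sign = rng.choice([-1, 1])
                target = mids[b] + sign * span
                if not (0 <= target < size):
                    target = mids[b] - sign * span
                if not (0 <= target < size):
                    continue
                o = int(frags.fragment_at(chrom, int(target)))
                if o == b or o in used_distal:
                    continue
                used_distal.add(o)
                rows.append((b, o, gene))
                break
    planted = pd.DataFrame(rows, columns=["bait_id", "other_end_id", "bait_gene"])
    planted = planted.drop_duplicates(["bait_id", "other_end_id"])
    if len(planted) > cfg.n_capture_interactions:
        keep = rng.choice(
            len(planted), size=cfg.n_capture_interactions, replace=False
        )
        planted = planted.iloc[np.sort(keep)]
    planted = planted.reset_index(drop=True)

    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    planted["true_class"] = rng.choice(
        classes, size=len(planted), p=probs / probs.sum()
    )

    # background pairs: random bait, random cis fragment in the span window
    bait_arr = np.array([f for f, _ in bait_items])
    gene_arr = np.array([g for _, g in bait_items], dtype=object)
    nbg = cfg.n_capture_background
    bsel = rng.integers(0, len(bait_arr), size=nbg)
    spans = np.exp(rng.uniform(np.log(lo_span), np.log(hi_span), size=nbg))
    signs = rng.choice([-1, 1], size=nbg)
    bg_rows = []
    for b_i, sp_, sg in zip(bsel, spans, signs):
        b = int(bait_arr[b_i])
        chrom = chroms[b]
        size = truth.genome.chrom_sizes[chrom]
        target = mids[b] + sg * sp_
        if not (0 <= target < size):
            target = mids[b] - sg * sp_
        if not (0 <= target < size):
            continue
        o = frags.fragment_at(chrom, int(target))
        if o == b:
            continue
        bg_rows.append((b, int(o), gene_arr[b_i]))
    background = pd.DataFrame(
        bg_rows, columns=["bait_id", "other_end_id", "bait_gene"]
    ).drop_duplicates(["bait_id", "other_end_id"])
    background["true_class"] = "background"
    planted_keys = set(zip(planted["bait_id"], planted["other_end_id"]))
    background = background[
        [
            k not in planted_keys
            for k in zip(background["bait_id"], background["other_end_id"])
        ]
    ]

    table = pd.concat([planted, background], ignore_index=True)
    span = np.abs(
        mids[table["bait_id"].to_numpy()] - mids[table["other_end_id"].to_numpy()]
    )
    table["span_true"] = span
    bg_mean = cfg.capture_base_count * (
        cfg.capture_ref_distance / np.maximum(span, 1_000)
    )
    enriched = table["true_class"] != "background"
    base = np.where(enriched, cfg.capture_enrichment * bg_mean, bg_mean)
    mean_a = base.copy()
    mean_b = base.copy()
    is_ra = (table["true_class"] == "rewired_gained_A").to_numpy()
    is_rb = (table["true_class"] == "rewired_gained_B").to_numpy()
    mean_b[is_ra] /= cfg.rewired_fc
    mean_a[is_rb] /= cfg.rewired_fc
    table["mean_A"] = mean_a
    table["mean_B"] = mean_b

    disp = cfg.capture_dispersion
    for cond, mu in (("A", mean_a), ("B", mean_b)):
        for rep in range(cfg.hic_replicates):
            if disp > 0:
                lam = rng.gamma(1.0 / disp, disp * mu)
            else:
                lam = mu
            table[f"count_{cond}{rep + 1}"] = rng.poisson(lam)
    table["unit_id"] = [f"cap{k:06d}" for k in range(len(table))]
    truth.capture = table
    return table


def _place_nonoverlapping(
    n: int, length: int, universe: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    uni = _Universe(universe)
    s, e = shuffle_intervals(np.full(n, length, dtype=np.int64), uni, rng)
    inv = {v: k for k, v in uni.offsets.items()}
    bounds = np.array(sorted(uni.offsets.values()) + [np.iinfo(np.int64).max])
    names = [inv[b] for b in sorted(uni.offsets.values())]
    which = np.searchsorted(bounds, s, side="right") - 1
    chroms = [names[w] for w in which]
    offs = np.array([uni.offsets[c] for c in chroms], dtype=np.int64)
    return (
        pd.DataFrame({"chrom": chroms, "start": s - offs, "end": e - offs})
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def simulate_peaks_expression_cage(truth: SyntheticTruth) -> SyntheticTruth:
    """Peak sets, peak/expression count matrices, and cage tables.

    Plants: an enhancer universe; TF-A peaks inside enhancers; TF-B peaks
    with the configured co-binding fraction placed inside TF-A peaks;
    differential acetylation peaks at the distal ends of preformed-activated
    capture interactions (direction matching the planted condition) plus
    non-differential background acetylation peaks; expression counts whose
    DE effects follow the planted loop classes; and VO2/VCO2 cage records
    with group offsets, with energy expenditure from the calorimetry
    formula.
    """
    cfg = truth.config
    rng = _rng(cfg, 4)
    genome_uni = pd.DataFrame(
        {
            "chrom": list(truth.genome.chrom_sizes),
            "start": 0,
            "end": list(truth.genome.chrom_sizes.values()),
        }
    )
    enhancers = _place_nonoverlapping(
        cfg.n_enhancers, cfg.enhancer_len, genome_uni, rng
    )
    truth.enhancers = enhancers

    # TF-A inside distinct enhancers
    idx_a = rng.choice(len(enhancers), size=cfg.n_tf_peaks, replace=False)
    off_a = rng.integers(
        0, cfg.enhancer_len - cfg.tf_peak_len + 1, size=cfg.n_tf_peaks
    )
    tf_a = pd.DataFrame(
        {
            "chrom": enhancers["chrom"].to_numpy()[idx_a],
            "start": enhancers["start"].to_numpy()[idx_a] + off_a,
        }
    )
    tf_a["end"] = tf_a["start"] + cfg.tf_peak_len
    tf_a = tf_a.sort_values(["chrom", "start"]).reset_index(drop=True)

    # TF-B: a fraction inside TF-A peaks, the rest in TF-A-free enhancers
    n_co = int(round(cfg.cobinding_fraction * cfg.n_tf_peaks))
    co_idx = rng.choice(len(tf_a), size=n_co, replace=False)
    tf_b_co = tf_a.iloc[co_idx][["chrom", "start", "end"]]
    free = np.setdiff1d(np.arange(len(enhancers)), idx_a)
    idx_b = rng.choice(free, size=cfg.n_tf_peaks - n_co, replace=False)
    off_b = rng.integers(
        0, cfg.enhancer_len - cfg.tf_peak_len + 1, size=cfg.n_tf_peaks - n_co
    )
    tf_b_solo = pd.DataFrame(
        {
            "chrom": enhancers["chrom"].to_numpy()[idx_b],
            "start": enhancers["start"].to_numpy()[idx_b] + off_b,
        }
    )
    tf_b_solo["end"] = tf_b_solo["start"] + cfg.tf_peak_len
    tf_b = (
        pd.concat([tf_b_co, tf_b_solo], ignore_index=True)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    truth.tf_peaks = {"tf_a": tf_a, "tf_b": tf_b, "cobound": n_co}

    # acetylation peaks: differential at preformed distal ends, background
    # elsewhere (kept clear of all planted distal fragments)
    if truth.capture is None:
        raise ValueError("simulate_capture must run before peaks")
    cap = truth.capture
    frame = truth.fragments.frame
    acetyl_rows = []
    pk = 0
    preformed = cap[cap["true_class"].str.startswith("preformed")]
    for _, row in preformed.iterrows():
        f = frame.iloc[int(row["other_end_id"])]
        mid = (int(f["start"]) + int(f["end"])) // 2
        half = cfg.acetyl_peak_len // 2
        size = truth.genome.chrom_sizes[f["chrom"]]
        start = max(0, min(mid - half, size - cfg.acetyl_peak_len))
        direction = "up_A" if row["true_class"].endswith("_A") else "up_B"
        acetyl_rows.append(
            {
                "peak_id": f"ac{pk:05d}",
                "chrom": f["chrom"],
                "start": start,
                "end": start + cfg.acetyl_peak_len,
                "planted_direction": direction,
            }
        )
        pk += 1
    # background acetylation peaks away from planted distal fragments
    distal = frame.iloc[cap["other_end_id"].to_numpy()]
    forbidden = {
        c: np.sort(sub["start"].to_numpy())
        for c, sub in distal.groupby("chrom", sort=False)
    }
    forbidden_end = {
        c: np.sort(sub["end"].to_numpy())
        for c, sub in distal.groupby("chrom", sort=False)
    }
    n_bg = cfg.n_background_acetyl
    chrom_names = list(truth.genome.chrom_sizes)
    placed = 0
    while placed < n_bg:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        size = truth.genome.chrom_sizes[chrom]
        start = int(rng.integers(0, size - cfg.acetyl_peak_len))
        end = start + cfg.acetyl_peak_len
        fs = forbidden.get(chrom)
        if fs is not None:
            k = np.searchsorted(fs, end, side="left")
            if k > 0 and forbidden_end[chrom][k - 1] > start - 2_000:
                continue
        acetyl_rows.append(
            {
                "peak_id": f"ac{pk:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "planted_direction": "ns",
            }
        )
        pk += 1
        placed += 1
    acetyl = pd.DataFrame(acetyl_rows)
    mean_a = np.where(
        acetyl["planted_direction"] == "up_A",
        cfg.peak_base_count * cfg.peak_fc,
        cfg.peak_base_count,
    )
    mean_b = np.where(
        acetyl["planted_direction"] == "up_B",
        cfg.peak_base_count * cfg.peak_fc,
        cfg.peak_base_count,
    )
    for cond, mu in (("A", mean_a), ("B", mean_b)):
        for rep in range(cfg.chip_replicates):
            lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
            acetyl[f"count_{cond}{rep + 1}"] = rng.poisson(lam)
    truth.acetyl_peaks = acetyl

    # expression: planted DE follows the gene's dominant planted loop class;
    # acetylated (preformed) loops boost expression in the matching condition
    genes = truth.genes.copy()
    gene_class = {}
    priority = {
        "rewired_gained_A": 0,
        "rewired_gained_B": 0,
        "preformed_activated_A": 1,
        "preformed_activated_B": 1,
    }
    for _, row in cap[cap["true_class"] != "background"].iterrows():
        g = row["bait_gene"]
        c = row["true_class"]
        if c == "static":
            gene_class.setdefault(g, "static")
            continue
        prev = gene_class.get(g)
        if prev in (None, "static") or priority.get(c, 9) < priority.get(prev, 9):
            gene_class[g] = c
    genes["planted_class"] = genes["gene_id"].map(gene_class).fillna("none")

    # expression model: genes contacting an acetylated (preformed) enhancer
    # are boosted in both conditions; the planted DE fold change sits on top
    # in the condition the gene's dominant loop class points to
    tpm_a = genes["base_tpm"].to_numpy().copy()
    tpm_b = genes["base_tpm"].to_numpy().copy()
    pre_genes = set(
        cap.loc[cap["true_class"].str.startswith("preformed"), "bait_gene"]
    )
    has_pre = genes["gene_id"].isin(pre_genes).to_numpy()
    tpm_a[has_pre] *= cfg.acetyl_expr_boost
    tpm_b[has_pre] *= cfg.acetyl_expr_boost
    cls = genes["planted_class"].to_numpy()
    up_a = (cls == "rewired_gained_A") | (cls == "preformed_activated_A")
    up_b = (cls == "rewired_gained_B") | (cls == "preformed_activated_B")
    tpm_a[up_a] *= cfg.de_fc
    tpm_b[up_b] *= cfg.de_fc
    genes["true_tpm_A"] = tpm_a
    genes["true_tpm_B"] = tpm_b
    length_kb = genes["length"].to_numpy() / 1_000
    for cond, tpm in (("A", tpm_a), ("B", tpm_b)):
        mu = tpm * length_kb * cfg.expr_base_lib / 1e6
        for rep in range(cfg.rna_replicates):
            lam = np.where(
                mu > 0,
                rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu + 1e-12),
                0.0,
            )
            genes[f"count_{cond}{rep + 1}"] = rng.poisson(lam)
    for cond in CONDITIONS:
        cols = [f"count_{cond}{r + 1}" for r in range(cfg.rna_replicates)]
        rate = genes[cols].mean(axis=1) / length_kb
        # per-million scaling against the simulated depth: a strict
        # within-sample renormalisation over a 2,500-gene desk genome would
        # inflate values and detach them from the absolute bin edges
        genes[f"tpm_{cond}"] = 1e6 * rate / cfg.expr_base_lib
    truth.expression = genes

    # metabolic cages
    rows = []
    for cond in CONDITIONS:
        for mouse in range(cfg.cage_mice_per_group):
            vo2 = np.maximum(
                rng.normal(
                    cfg.cage_vo2_mean[cond], cfg.cage_vo2_sd, cfg.cage_intervals
                ),
                0.0,
            )
            vco2 = np.maximum(
                vo2 * cfg.cage_rer[cond]
                + rng.normal(0, cfg.cage_vo2_sd / 4, cfg.cage_intervals),
                0.0,
            )
            for k in range(cfg.cage_intervals):
                rows.append(
                    {
                        "group": cond,
                        "mouse": f"{cond}{mouse + 1}",
                        "interval": k,
                        "vo2_l_per_h": vo2[k],
                        "vco2_l_per_h": vco2[k],
                    }
                )
    cage = pd.DataFrame(rows)
    cage["ee_kcal_per_h"] = energy_expenditure(
        cage["vo2_l_per_h"], cage["vco2_l_per_h"]
    )
    truth.cage = cage
    return truth


def write_outputs(truth: SyntheticTruth, outdir) -> None:
    """Write every pipeline input format plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from .genome import write_bed, write_chrom_sizes, write_expression

    write_chrom_sizes(truth.genome, out / "chrom.sizes")
    write_bed(truth.fragments.frame, out / "fragments.bed")
    if truth.expression is not None:
        write_expression(truth.expression, out / "expression.tsv")
    if truth.capture is not None:
        truth.capture.to_csv(out / "capture_counts.tsv", sep="\t", index=False)
    if truth.acetyl_peaks is not None:
        truth.acetyl_peaks.to_csv(out / "acetyl_peaks.tsv", sep="\t", index=False)
    if truth.tf_peaks is not None:
        write_bed(truth.tf_peaks["tf_a"], out / "tf_a_peaks.bed")
        write_bed(truth.tf_peaks["tf_b"], out / "tf_b_peaks.bed")
    if truth.enhancers is not None:
        write_bed(truth.enhancers, out / "enhancers.bed")
    if truth.cage is not None:
        truth.cage.to_csv(out / "cage.tsv", sep="\t", index=False)
    payload = {
        "seed": truth.config.seed,
        "chrom_sizes": truth.genome.chrom_sizes,
        "boundaries_bp": {c: v.tolist() for c, v in truth.boundaries_bp.items()},
        "comp_labels": {c: v.tolist() for c, v in truth.comp_labels.items()},
        "loops": truth.loops.to_dict(orient="records"),
        "n_capture": 0 if truth.capture is None else int(len(truth.capture)),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
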