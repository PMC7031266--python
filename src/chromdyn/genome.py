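"""Coordinate conventions, interval algebra, binning, and tabular I/O.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
everywhere in the package.  Readers for 1-based dialects must convert at the
boundary; none of the formats used here are 1-based.

Interval tables are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom``, ``start``, ``end`` (``name``/``strand`` optional).  A
:class:`Genome` records chromosome names and lengths and is the validation
authority: unknown chromosomes are errors, never silent drops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Genome",
    "BinnedGenome",
    "FragmentMap",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "write_bed",
    "validate_intervals",
    "overlap_query",
    "promoter_regions",
    "read_expression",
    "write_expression",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome table (name -> length in bp)."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


class BinnedGenome:
    """Fixed-width tiling of a genome.

    Position ``p`` lies in bin ``b`` iff ``b*bin_size <= p < (b+1)*bin_size``;
    each chromosome has ``ceil(length / bin_size)`` bins (the last may be
    short).  Bins carry global integer ids, concatenated in chromosome order,
    so a whole-genome matrix can be indexed by a single axis.
    """

    def __init__(self, genome: Genome, bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.n_bins_per_chrom = {
            c: math.ceil(size / bin_size) for c, size in genome.chrom_sizes.items()
        }
        self.chrom_offsets: dict[str, int] = {}
        off = 0
        for c, n in self.n_bins_per_chrom.items():
            self.chrom_offsets[c] = off
            off += n
        self.n_bins = off
        # reverse lookup: global bin id -> chrom
        self._bounds = np.array(
            [self.chrom_offsets[c] for c in genome.chroms] + [self.n_bins]
        )
        self._chrom_list = genome.chroms

    def bin_id(self, chrom: str, pos) -> np.ndarray | int:
        """Global bin id(s) for position(s) on one chromosome."""
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(pos)
        size = self.genome.chrom_sizes[chrom]
        if np.any(pos < 0) or np.any(pos >= size):
            raise ValueError(f"position out of range for {chrom} (length {size})")
        out = self.chrom_offsets[chrom] + pos // self.bin_size
        return out if out.ndim else int(out)

    def bin_chrom(self, bin_ids) -> np.ndarray:
        """Chromosome name per global bin id."""
        bin_ids = np.atleast_1d(np.asarray(bin_ids))
        idx = np.searchsorted(self._bounds, bin_ids, side="right") - 1
        return np.array(self._chrom_list, dtype=object)[idx]

    def bin_start(self, bin_ids) -> np.ndarray:
        """Start coordinate (bp, on its chromosome) per global bin id."""
        bin_ids = np.atleast_1d(np.asarray(bin_ids))
        idx = np.searchsorted(self._bounds, bin_ids, side="right") - 1
        return (bin_ids - self._bounds[idx]) * self.bin_size

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin id range for one chromosome."""
        lo = self.chrom_offsets[chrom]
        return lo, lo + self.n_bins_per_chrom[chrom]

    def bins_frame(self) -> pd.DataFrame:
        """All bins as an interval table (chrom, start, end, bin_id)."""
        rows = []
        for c in self.genome.chroms:
            n = self.n_bins_per_chrom[c]
            size = self.genome.chrom_sizes[c]
            starts = np.arange(n) * self.bin_size
            ends = np.minimum(starts + self.bin_size, size)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": starts,
                        "end": ends,
                        "bin_id": self.chrom_offsets[c] + np.arange(n),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    Fragments are adjacent and non-overlapping; fragment ids are integer row
    indices into the table, which is sorted by (chromosome order, start).
    """

    def __init__(self, frame: pd.DataFrame, genome: Genome):
        frame = frame.reset_index(drop=True)
        validate_intervals(frame, genome)
        for chrom, sub in frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != genome.chrom_sizes[chrom]:
                raise ValueError(f"fragments do not cover chromosome {chrom}")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"fragments not adjacent on {chrom}")
        self.frame = frame.assign(frag_id=np.arange(len(frame)))
        self.genome = genome
        self._starts = {
            c: sub["start"].to_numpy()
            for c, sub in self.frame.groupby("chrom", sort=False)
        }
        self._first_id = {
            c: int(sub["frag_id"].iloc[0])
            for c, sub in self.frame.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.frame)

    def fragment_at(self, chrom: str, pos) -> np.ndarray | int:
        """Fragment id(s) containing position(s) on one chromosome."""
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(pos)
        size = self.genome.chrom_sizes[chrom]
        if np.any(pos < 0) or np.any(pos >= size):
            raise ValueError(f"position out of range for {chrom}")
        idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        out = self._first_id[chrom] + idx
        return out if out.ndim else int(out)

    def midpoints(self) -> np.ndarray:
        return ((self.frame["start"] + self.frame["end"]) // 2).to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Genome:
    """Two-column TSV (chrom, length) -> Genome."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sizes[parts[0]] = int(parts[1])
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")


def validate_intervals(frame: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """Check the 0-based half-open invariants; returns the frame unchanged."""
    for col in ("chrom", "start", "end"):
        if col not in frame.columns:
            raise ValueError(f"interval table missing column {col!r}")
    if len(frame):
        if (frame["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if (frame["start"] >= frame["end"]).any():
            bad = frame.index[frame["start"] >= frame["end"]][0]
            raise ValueError(f"empty or inverted interval at row {bad}")
        if genome is not None:
            unknown = set(frame["chrom"]) - set(genome.chrom_sizes)
            if unknown:
                raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
            ends = frame["chrom"].map(genome.chrom_sizes)
            if (frame["end"] > ends).any():
                raise ValueError("interval extends past chromosome end")
    return frame


def read_intervals(path, genome: Genome | None = None, fmt: str = "bed") -> pd.DataFrame:
    """Read an interval table from BED3+ or headered TSV.

    BED columns beyond the third are kept as ``name``, ``score``, ``strand``.
    Malformed lines raise with the 1-based line number; unknown chromosomes
    (when a genome is supplied) are errors.
    """
    if fmt == "bed":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
                row = {"chrom": parts[0], "start": start, "end": end}
                if len(parts) > 3:
                    row["name"] = parts[3]
                if len(parts) > 4:
                    row["score"] = parts[4]
                if len(parts) > 5:
                    row["strand"] = parts[5]
                rows.append(row)
        frame = (
            pd.DataFrame(rows)
            if rows
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return validate_intervals(frame, genome)


def write_bed(frame: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [
        c for c in ("name", "score", "strand") if c in frame.columns
    ]
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def read_expression(path, genome: Genome | None = None) -> pd.DataFrame:
    """Headered expression TSV (gene_id, chrom, tss, strand, counts..., tpm...)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "chrom", "tss"):
        if col not in frame.columns:
            raise ValueError(f"expression table missing column {col!r}")
    if genome is not None:
        unknown = set(frame["chrom"]) - set(genome.chrom_sizes)
        if unknown:
            raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
    return frame


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlap_query(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_overlap_fraction: float = 0.0,
) -> pd.DataFrame:
    """All pairs (a, b) overlapping by at least ``max(1 bp, fraction*len(a))``.

    The fraction is relative to the **query** (first) set's interval length —
    the reading of the "at least 10% overlap" control-overlap criterion used
    throughout.  Output rows are ordered by (a_index, b_index); indices are
    positional row numbers into the input frames.
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    validate_intervals(set_a)
    validate_intervals(set_b)
    trees: dict[str, IntervalTree] = {}
    b_pos = set_b.reset_index(drop=True)
    for chrom, sub in b_pos.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub.index)
        )
    a_chrom = set_a["chrom"].to_numpy()
    a_start = set_a["start"].to_numpy()
    a_end = set_a["end"].to_numpy()
    out_a, out_b, out_bp = [], [], []
    for i in range(len(set_a)):
        tree = trees.get(a_chrom[i])
        if tree is None:
            continue
        need = max(1.0, min_overlap_fraction * (a_end[i] - a_start[i]))
        hits = []
        for iv in tree.overlap(a_start[i], a_end[i]):
            ov = min(a_end[i], iv.end) - max(a_start[i], iv.begin)
            if ov >= need:
                hits.append((iv.data, ov))
        for j, ov in sorted(hits):
            out_a.append(i)
            out_b.append(j)
            out_bp.append(ov)
    return pd.DataFrame(
        {
            "a_index": np.array(out_a, dtype=np.int64),
            "b_index": np.array(out_b, dtype=np.int64),
            "overlap_bp": np.array(out_bp, dtype=np.int64),
        }
    )


def promoter_regions(
    expression: pd.DataFrame, genome: Genome, flank_bp: int = 2000
) -> pd.DataFrame:
    """Strand-symmetric promoter windows ``[tss-flank, tss+flank)``.

    Windows are clipped at chromosome ends; a TSS outside its chromosome is an
    error.  Strand does not enter: the window is symmetric by design.
    """
    if "tss" not in expression.columns:
        raise ValueError("expression table has no 'tss' column")
    sizes = expression["chrom"].map(genome.chrom_sizes)
    if sizes.isna().any():
        bad = expression.loc[sizes.isna(), "chrom"].iloc[0]
        raise ValueError(f"unknown chromosome {bad!r}")
    tss = expression["tss"]
    if ((tss < 0) | (tss >= sizes)).any():
        raise ValueError("TSS outside chromosome bounds")
    return pd.DataFrame(
        {
            "chrom": expression["chrom"],
            "start": np.maximum(tss - flank_bp, 0),
            "end": np.minimum(tss + flank_bp, sizes),
            "name": expression["gene_id"],
        }
    ).reset_index(drop=True)
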