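"""Gabriel-style haplotype blocks from |D'| confidence intervals.

Each within-span marker pair is classified from its profile-likelihood
|D'| confidence interval: *strong LD* when the lower limit reaches 0.70
and the upper limit reaches 0.98; *strong recombination* when the upper
limit stays below 0.90; otherwise uninformative.  A candidate run of
contiguous markers is a block when it has at least one informative pair
and the strong-LD fraction among informative pairs reaches the required
threshold (default 0.95).  Non-overlapping blocks are selected greedily,
longest physical span first, ties broken toward the smaller start
position.  Markers below the MAF floor are excluded from block finding.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, allele_stats
from .ld_core import _dprime_ci_batch, _pair_counts

__all__ = [
    "BlockConfig",
    "HaplotypeBlock",
    "BlockStats",
    "gabriel_blocks",
    "block_stats",
    "recommended_marker_count",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class BlockConfig:
    """Thresholds of the confidence-interval block criterion."""

    ci_level: float = 0.90
    strong_low_min: float = 0.70
    strong_high_min: float = 0.98
    recomb_high_max: float = 0.90
    strong_fraction: float = 0.95
    max_span_bp: int = 500_000
    min_maf: float = 0.05
    ci_grid_points: int = 201

    def __post_init__(self):
        for name in ("ci_level", "strong_low_min", "strong_high_min",
                     "recomb_high_max", "strong_fraction", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass
class HaplotypeBlock:
    """A contiguous marker run passing the block criterion."""

    chrom: str
    start_idx: int  # column index into the full marker map
    end_idx: int
    start_bp: int
    end_bp: int
    n_markers: int
    span_bp: int
    mean_spacing_bp: float
    spacings_bp: tuple = ()  # within-block adjacent intermarker distances


STRONG, RECOMB, UNINFORMATIVE = 1, -1, 0


def _classify_pairs(genotypes, cidx, config):
    """CI-classify all within-span pairs on one chromosome.

    Returns a dict (local_i, local_j) -> class over the retained markers
    ``cidx`` (global column indices, map order).
    """
    pos = genotypes.markers["pos"].to_numpy()
    pairs_i, pairs_j = [], []
    for a in range(len(cidx) - 1):
        for b in range(a + 1, len(cidx)):
            if pos[cidx[b]] - pos[cidx[a]] > config.max_span_bp:
                break
            pairs_i.append(a)
            pairs_j.append(b)
    classes = {}
    if not pairs_i:
        return classes
    gi = cidx[np.asarray(pairs_i)]
    gj = cidx[np.asarray(pairs_j)]
    counts = _pair_counts(genotypes.dosages, gi, gj)
    n = counts.sum(axis=1)
    c3 = counts.reshape(-1, 3, 3).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (2 * c3[:, 2, :].sum(1) + c3[:, 1, :].sum(1)) / (2 * n)
        pB = (2 * c3[:, :, 2].sum(1) + c3[:, :, 1].sum(1)) / (2 * n)
    ok = (n >= 2) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    lo = np.full(len(gi), np.nan)
    hi = np.full(len(gi), np.nan)
    if ok.any():
        lo[ok], hi[ok] = _dprime_ci_batch(
            counts[ok], level=config.ci_level, grid_points=config.ci_grid_points
        )
    for k, (a, b) in enumerate(zip(pairs_i, pairs_j)):
        if not ok[k]:
            classes[(a, b)] = UNINFORMATIVE  # undefined LD: carries no evidence
        elif lo[k] >= config.strong_low_min and hi[k] >= config.strong_high_min:
            classes[(a, b)] = STRONG
        elif hi[k] < config.recomb_high_max:
            classes[(a, b)] = RECOMB
        else:
            classes[(a, b)] = UNINFORMATIVE
    return classes


def gabriel_blocks(genotypes: GenotypeMatrix, config: BlockConfig = None) -> list:
    """Find haplotype blocks per chromosome.

    Returns a list of :class:`HaplotypeBlock`, ordered by chromosome then
    start position.  A chromosome with fewer than two (MAF-retained)
    markers yields no blocks.
    """
    if config is None:
        config = BlockConfig()
    mk = genotypes.markers
    st = allele_stats(genotypes)
    maf_ok = np.nan_to_num(st["maf"].to_numpy(), nan=0.0) >= config.min_maf
    pos = mk["pos"].to_numpy()
    blocks = []
    for chrom in genotypes.chromosomes():
        cidx = np.flatnonzero((mk["chrom"] == chrom).to_numpy() & maf_ok)
        if len(cidx) < 2:
            continue
        classes = _classify_pairs(genotypes, cidx, config)

        candidates = []
        for a in range(len(cidx) - 1):
            for b in range(a + 1, len(cidx)):
                if pos[cidx[b]] - pos[cidx[a]] > config.max_span_bp:
                    break
                strong = sum(
                    1
                    for u in range(a, b)
                    for v in range(u + 1, b + 1)
                    if classes.get((u, v)) == STRONG
                )
                recomb = sum(
                    1
                    for u in range(a, b)
                    for v in range(u + 1, b + 1)
                    if classes.get((u, v)) == RECOMB
                )
                informative = strong + recomb
                if informative >= 1 and strong / informative >= config.strong_fraction:
                    candidates.append((a, b))

        taken = np.zeros(len(cidx), dtype=bool)
        candidates.sort(key=lambda ab: (-(pos[cidx[ab[1]]] - pos[cidx[ab[0]]]), ab[0]))
        for a, b in candidates:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            span_pos = pos[cidx[a : b + 1]]
            blocks.append(
                HaplotypeBlock(
                    chrom=chrom,
                    start_idx=int(cidx[a]),
                    end_idx=int(cidx[b]),
                    start_bp=int(span_pos[0]),
                    end_bp=int(span_pos[-1]),
                    n_markers=b - a + 1,
                    span_bp=int(span_pos[-1] - span_pos[0]),
                    mean_spacing_bp=float(np.mean(np.diff(span_pos))),
                    spacings_bp=tuple(int(x) for x in np.diff(span_pos)),
                )
            )
    blocks.sort(key=lambda blk: (_chrom_order(blk.chrom), blk.start_bp))
    return blocks


def _chrom_order(label):
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


@dataclasses.dataclass
class BlockStats:
    """Block counts, size histogram and within-block spacing summary."""

    per_chromosome: pd.DataFrame
    size_histogram: pd.Series  # n_markers -> block count
    mean_spacing_mb: float
    sd_spacing_mb: float
    n_blocks: int


def block_stats(blocks: list) -> BlockStats:
    """Summarize a block list (Table-3-style).

    The spacing summary pools every within-block adjacent intermarker
    distance genome-wide (mean and sample SD, in Mb).
    """
    if not blocks:
        return BlockStats(
            per_chromosome=pd.DataFrame(columns=["chrom", "n_blocks", "n_markers_total"]),
            size_histogram=pd.Series(dtype=int),
            mean_spacing_mb=float("nan"),
            sd_spacing_mb=float("nan"),
            n_blocks=0,
        )
    rows = {}
    spacings = []
    sizes = []
    for blk in blocks:
        rows.setdefault(blk.chrom, {"n_blocks": 0, "n_markers_total": 0})
        rows[blk.chrom]["n_blocks"] += 1
        rows[blk.chrom]["n_markers_total"] += blk.n_markers
        sizes.append(blk.n_markers)
        spacings.extend(blk.spacings_bp if blk.spacings_bp
                        else [blk.mean_spacing_bp] * (blk.n_markers - 1))
    per_chrom = pd.DataFrame(
        [{"chrom": c, **v} for c, v in rows.items()],
        columns=["chrom", "n_blocks", "n_markers_total"],
    )
    spacings_mb = np.asarray(spacings) / 1e6
    hist = pd.Series(sizes).value_counts().sort_index()
    hist.index.name = "n_markers"
    return BlockStats(
        per_chromosome=per_chrom,
        size_histogram=hist,
        mean_spacing_mb=float(np.mean(spacings_mb)),
        sd_spacing_mb=float(np.std(spacings_mb, ddof=1)) if len(spacings_mb) > 1 else 0.0,
        n_blocks=len(blocks),
    )


def recommended_marker_count(genome_size_mb: float, mean_block_spacing_mb: float) -> int:
    """Marker-density recommendation: round(genome size / block spacing)."""
    if genome_size_mb <= 0 or mean_block_spacing_mb <= 0:
        raise ValueError("genome size and block spacing must be positive")
    return int(np.floor(genome_size_mb / mean_block_spacing_mb + 0.5))
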