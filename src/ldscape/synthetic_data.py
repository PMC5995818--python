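"""Synthetic genotype datasets with known ground truth.

Four generators:

* :func:`simulate_wright_fisher` — a forward discrete-generation
  Wright-Fisher population of N diploids: random mating with replacement,
  no mutation, and recombination as a memoryless crossover process along
  each chromosome (per-interval switch probabilities from the Haldane map
  function at the configured cM/Mb rate).  LD builds up by drift, so the
  Sved relation E[r^2] = 1/(1 + 4 Ne c) can be checked against the known
  census size.
* :func:`make_pedigreed_sample` — founders in linkage equilibrium plus a
  final generation produced by specified sire/dam matings (full sibs
  within a dam, half sibs across dams of one sire), with the truth
  pedigree recorded.
* :func:`plant_ld_block` — markers inside a chosen range drawn from a
  restricted haplotype pool (two complementary haplotypes give complete
  mutual LD), flanking markers independent: a planted fixture for block
  finders.
* :func:`worked_example_tables` — the small fixed two-locus tables and
  inbreeding inputs used in worked examples.

All generators are driven by numpy's PCG64 `default_rng`, so a seed fully
determines the output on any platform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, make_marker_map

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "FamilySpec",
    "BlockSpec",
    "simulate_wright_fisher",
    "make_pedigreed_sample",
    "plant_ld_block",
    "worked_example_tables",
]


@dataclasses.dataclass
class SimulationConfig:
    """Wright-Fisher simulation parameters.

    Defaults emulate the structure of a high-density ovine panel study:
    26 autosomes at ~0.07-Mb marker spacing (~38k SNPs), a census of 400
    diploids with 395 sampled, 1 cM/Mb, and an initial allele-A frequency
    uniform on [0.2, 0.8] (mean MAF 0.35).
    """

    n_diploid: int = 400
    n_chromosomes: int = 26
    markers_per_chromosome: int = 1470
    spacing_bp: int = 70_000
    cm_per_mb: float = 1.0
    generations: int = 400
    freq_range: tuple = (0.2, 0.8)
    sample_size: int = 395
    seed: int = 0

    def __post_init__(self):
        for name in ("n_diploid", "n_chromosomes", "markers_per_chromosome",
                     "spacing_bp", "generations", "sample_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_size > self.n_diploid:
            raise ValueError("sample_size cannot exceed the diploid population size")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")


@dataclasses.dataclass
class SimulatedDataset:
    """Genotypes plus the ground truth that produced them."""

    genotypes: GenotypeMatrix
    truth: dict  # haplotypes, pop sizes per generation, pedigree, config


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    chroms, ids, pos = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.markers_per_chromosome):
            chroms.append(str(c))
            ids.append(f"snp_{c}_{j + 1}")
            pos.append(1 + j * config.spacing_bp)
    return make_marker_map(chroms, ids, pos,
                           ["A"] * len(ids), ["B"] * len(ids))


def _switch_prob(config: SimulationConfig) -> float:
    """Haldane recombination fraction between adjacent markers."""
    d_morgan = config.spacing_bp / 1e6 * config.cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def _meiosis(H: np.ndarray, parents: np.ndarray, r: float, rng) -> np.ndarray:
    """One gamete per parent index: recombinant of the parent's haplotypes.

    The crossover process is memoryless, so the source haplotype along the
    chromosome is a two-state Markov chain with switch probability ``r``
    per marker interval.
    """
    n, m = len(parents), H.shape[1]
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switches = rng.random((n, m - 1)) < r
        choice = (start[:, None] + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        choice = start[:, None]
    a = H[2 * parents]
    b = H[2 * parents + 1]
    return np.where(choice == 0, a, b).astype(np.uint8)


def simulate_wright_fisher(config: SimulationConfig) -> SimulatedDataset:
    """Evolve a neutral Wright-Fisher population and emit a genotype sample.

    All chromosomes segregate through the same individuals each generation
    (one shared pedigree draw), so the sampled individuals are internally
    consistent.  Returns the sampled diploids' genotypes with the truth
    record (sampled haplotypes per chromosome, census size per
    generation).
    """
    rng = np.random.default_rng(config.seed)
    N = config.n_diploid
    m = config.markers_per_chromosome
    r = _switch_prob(config)

    init_freq = rng.uniform(*config.freq_range, size=(config.n_chromosomes, m))
    haps = [
        (rng.random((2 * N, m)) < init_freq[c]).astype(np.uint8)
        for c in range(config.n_chromosomes)
    ]
    for _ in range(config.generations):
        parents = rng.integers(0, N, size=(N, 2))
        for c in range(config.n_chromosomes):
            g0 = _meiosis(haps[c], parents[:, 0], r, rng)
            g1 = _meiosis(haps[c], parents[:, 1], r, rng)
            new = np.empty_like(haps[c])
            new[0::2] = g0
            new[1::2] = g1
            haps[c] = new

    sample = rng.choice(N, size=config.sample_size, replace=False)
    sampled_haps = [H[np.stack([2 * sample, 2 * sample + 1], 1).ravel()] for H in haps]
    dosages = np.concatenate(
        [(H[0::2].astype(np.int8) + H[1::2].astype(np.int8)) for H in sampled_haps],
        axis=1,
    )
    gm = GenotypeMatrix(
        dosages,
        [f"ind_{i + 1}" for i in range(config.sample_size)],
        _marker_map(config),
    )
    truth = {
        "config": config,
        "pop_size_per_generation": [N] * (config.generations + 1),
        "haplotypes": sampled_haps,
        "pedigree": None,
        "sampled_individuals": sample,
    }
    return SimulatedDataset(genotypes=gm, truth=truth)


# ---------------------------------------------------------------------------
# Pedigreed samples
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FamilySpec:
    """One sire mated to ``n_dams`` dams, ``offspring_per_dam`` each.

    Offspring of the same dam are full sibs; offspring of different dams
    of the same sire are paternal half sibs.
    """

    n_dams: int
    offspring_per_dam: int

    def __post_init__(self):
        if self.n_dams < 1 or self.offspring_per_dam < 1:
            raise ValueError("family spec requires >= 1 dam and >= 1 offspring per dam")


def make_pedigreed_sample(config: SimulationConfig, families,
                          n_unrelated: int = 0) -> SimulatedDataset:
    """Final generation from specified matings over linkage-equilibrium founders.

    The emitted sample holds every family offspring followed by
    ``n_unrelated`` founder-drawn singles.  The truth record carries the
    pedigree table and the full-sib / half-sib pair index lists.
    """
    rng = np.random.default_rng(config.seed)
    m_total = config.n_chromosomes * config.markers_per_chromosome
    freqs = rng.uniform(*config.freq_range, size=m_total)
    r = _switch_prob(config)
    mpc = config.markers_per_chromosome

    def founder_haplotypes(k):
        return (rng.random((2 * k, m_total)) < freqs).astype(np.uint8)

    def gamete(H2):
        # one meiosis per chromosome; H2 is (2, m_total) for one founder
        out = np.empty(m_total, dtype=np.uint8)
        for c in range(config.n_chromosomes):
            sl = slice(c * mpc, (c + 1) * mpc)
            out[sl] = _meiosis(H2[:, sl], np.array([0]), r, rng)[0]
        return out

    hap_rows, ids, pedigree = [], [], []
    full_sib_pairs, half_sib_pairs = [], []
    for fam_i, fam in enumerate(families):
        sire = founder_haplotypes(1)
        sire_id = f"sire_{fam_i + 1}"
        fam_offspring_by_dam = []
        for dam_j in range(fam.n_dams):
            dam = founder_haplotypes(1)
            dam_id = f"dam_{fam_i + 1}_{dam_j + 1}"
            dam_offspring = []
            for o in range(fam.offspring_per_dam):
                oid = f"off_{fam_i + 1}_{dam_j + 1}_{o + 1}"
                hap_rows.append(gamete(sire))
                hap_rows.append(gamete(dam))
                ids.append(oid)
                pedigree.append({"id": oid, "sire": sire_id, "dam": dam_id})
                dam_offspring.append(len(ids) - 1)
            fam_offspring_by_dam.append(dam_offspring)
            for a in range(len(dam_offspring)):
                for b in range(a + 1, len(dam_offspring)):
                    full_sib_pairs.append((dam_offspring[a], dam_offspring[b]))
        for d1 in range(len(fam_offspring_by_dam)):
            for d2 in range(d1 + 1, len(fam_offspring_by_dam)):
                for a in fam_offspring_by_dam[d1]:
                    for b in fam_offspring_by_dam[d2]:
                        half_sib_pairs.append((a, b))
    for u in range(n_unrelated):
        H = founder_haplotypes(1)
        hap_rows.append(H[0])
        hap_rows.append(H[1])
        uid = f"unrel_{u + 1}"
        ids.append(uid)
        pedigree.append({"id": uid, "sire": "0", "dam": "0"})

    if not ids:
        raise ValueError("family spec produced no individuals")
    haps = np.stack(hap_rows)
    dosages = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
    gm = GenotypeMatrix(dosages, ids, _marker_map(config))
    truth = {
        "config": config,
        "haplotypes": haps,
        "pedigree": pd.DataFrame(pedigree),
        "full_sib_pairs": full_sib_pairs,
        "half_sib_pairs": half_sib_pairs,
        "founder_frequencies": freqs,
    }
    return SimulatedDataset(genotypes=gm, truth=truth)


# ---------------------------------------------------------------------------
# Planted LD blocks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BlockSpec:
    """Marker range (inclusive, chromosome-local) drawn from a haplotype pool."""

    chromosome: int = 1  # 1-based
    start_marker: int = 0  # 0-based within the chromosome
    end_marker: int = 2
    n_haplotypes: int = 2
    hap_freqs: tuple = None  # defaults to uniform over the pool

    def __post_init__(self):
        if self.end_marker - self.start_marker + 1 < 2:
            raise ValueError("a planted block needs at least two markers")
        if self.n_haplotypes < 2:
            raise ValueError("need at least two pool haplotypes")


def plant_ld_block(config: SimulationConfig, block: BlockSpec) -> SimulatedDataset:
    """Sample unphased genotypes with one planted high-LD block.

    Haplotypes inside the block range are drawn from a fixed pool (two
    complementary haplotypes for ``n_haplotypes=2``, giving |D'| = 1 for
    every within-block pair); markers outside the range are independent.
    """
    rng = np.random.default_rng(config.seed)
    mpc = config.markers_per_chromosome
    if not (1 <= block.chromosome <= config.n_chromosomes):
        raise ValueError("block chromosome outside the simulated map")
    if block.start_marker < 0 or block.end_marker >= mpc:
        raise ValueError("block marker range outside the chromosome map")

    m_total = config.n_chromosomes * mpc
    freqs = rng.uniform(*config.freq_range, size=m_total)
    n_hap = 2 * config.sample_size
    haps = (rng.random((n_hap, m_total)) < freqs).astype(np.uint8)

    width = block.end_marker - block.start_marker + 1
    if block.n_haplotypes == 2:
        h0 = rng.integers(0, 2, size=width).astype(np.uint8)
        pool = np.stack([h0, 1 - h0])
    else:
        for _ in range(1000):
            pool = rng.integers(0, 2, size=(block.n_haplotypes, width)).astype(np.uint8)
            col_poly = (pool.min(0) == 0) & (pool.max(0) == 1)
            distinct = len({tuple(row) for row in pool}) == block.n_haplotypes
            if col_poly.all() and distinct:
                break
        else:
            raise ValueError("could not draw a polymorphic distinct haplotype pool")
    p = (np.asarray(block.hap_freqs, float) if block.hap_freqs is not None
         else np.full(block.n_haplotypes, 1.0 / block.n_haplotypes))
    p = p / p.sum()
    picks = rng.choice(block.n_haplotypes, size=n_hap, p=p)
    sl = slice((block.chromosome - 1) * mpc + block.start_marker,
               (block.chromosome - 1) * mpc + block.end_marker + 1)
    haps[:, sl] = pool[picks]

    dosages = haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)
    gm = GenotypeMatrix(
        dosages,
        [f"ind_{i + 1}" for i in range(config.sample_size)],
        _marker_map(config),
    )
    truth = {
        "config": config,
        "haplotypes": haps,
        "block": block,
        "pool": pool,
        "pedigree": None,
    }
    return SimulatedDataset(genotypes=gm, truth=truth)


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

def worked_example_tables() -> dict:
    """Fixed small inputs used throughout the worked examples and tests.

    Keys: ``phase_known`` (no double heterozygotes), ``double_het_only``
    (EM saddle), ``em_oracle_n10`` (mixed table checked against a
    likelihood-grid oracle), ``complete_ld_n100`` (overwhelming complete
    LD) and ``inbreeding_example`` dict (O, E, L).
    """
    phase_known = np.zeros((3, 3), dtype=int)
    phase_known[2, 2] = 2
    phase_known[0, 0] = 2

    double_het = np.zeros((3, 3), dtype=int)
    double_het[1, 1] = 4

    oracle = np.zeros((3, 3), dtype=int)
    oracle[2, 2] = 3
    oracle[0, 0] = 3
    oracle[1, 1] = 2
    oracle[2, 1] = 1
    oracle[1, 2] = 1

    complete = np.zeros((3, 3), dtype=int)
    complete[2, 2] = 50
    complete[0, 0] = 50

    return {
        "phase_known": phase_known,
        "double_het_only": double_het,
        "em_oracle_n10": oracle,
        "complete_ld_n100": complete,
        "inbreeding_example": {"O": 70, "E": 60.0, "L": 100},
    }
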