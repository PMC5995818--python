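"""Excess-homozygosity inbreeding and the VanRaden genomic relationship matrix.

The inbreeding coefficient of individual i is

    F_i = (O_i - E_i) / (L_i - E_i)

with O_i the observed homozygous loci, L_i the non-missing genotyped loci
and E_i = sum over i's non-missing markers of (1 - 2 p (1 - p)), the
homozygosity expected under Hardy-Weinberg at the in-sample allele
frequencies.  Negative F occurs exactly when O < E (more heterozygous than
expected).

The genomic relationship matrix is VanRaden method 1:

    G = Z Z' / (2 sum_j p_j (1 - p_j)),   Z = X - 2p

with X the dosage matrix and p the in-sample allele-A frequencies.
Missing dosages contribute 0 to Z (they sit at their expectation; no
genotype is imputed).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, allele_stats

__all__ = [
    "InbreedingResult",
    "RelationshipMatrix",
    "inbreeding",
    "vanraden_grm",
    "relationship_summary",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class InbreedingResult:
    """Per-individual table (id, O, E, L, F) and the population mean F."""

    table: pd.DataFrame
    mean_f: float


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric VanRaden G with the allele frequencies used for centering."""

    G: np.ndarray
    samples: list
    frequencies: np.ndarray
    n_markers_used: int
    n_monomorphic_dropped: int


def inbreeding(genotypes: GenotypeMatrix) -> InbreedingResult:
    """Excess-homozygosity F per individual.

    E_i is accumulated over each individual's own non-missing markers, so
    missingness never biases the expected count.  Individuals with the
    degenerate denominator L_i = E_i get F = NaN and are excluded from the
    population mean.
    """
    d = genotypes.dosages
    st = allele_stats(genotypes)
    p = st["freq_a"].to_numpy(float)
    exp_hom = 1.0 - 2.0 * p * (1.0 - p)  # per-marker expected homozygosity
    nonmiss = d >= 0
    hom = (d == 0) | (d == 2)
    L = nonmiss.sum(axis=1)
    O = hom.sum(axis=1)
    # markers with undefined frequency contribute to neither E nor L
    usable = nonmiss & np.isfinite(exp_hom)[None, :]
    E = usable @ np.nan_to_num(exp_hom)
    L = usable.sum(axis=1)
    O = (hom & usable).sum(axis=1)
    denom = L - E
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    table = pd.DataFrame(
        {"id": genotypes.samples, "O": O, "E": E, "L": L, "F": F}
    )
    mean_f = float(np.nanmean(F)) if np.isfinite(F).any() else float("nan")
    return InbreedingResult(table=table, mean_f=mean_f)


def vanraden_grm(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Monomorphic markers carry no relationship information and are dropped
    with a logged count; an all-monomorphic panel is an error.
    """
    st = allele_stats(genotypes)
    p = st["freq_a"].to_numpy(float)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~poly).sum())
    if not poly.any():
        raise ValueError("all markers monomorphic: G undefined")
    if n_dropped:
        log.info("vanraden_grm: dropped %d monomorphic markers", n_dropped)
    d = genotypes.dosages[:, poly].astype(float)
    p = p[poly]
    Z = np.where(d >= 0, d - 2.0 * p, 0.0)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(
        G=G,
        samples=list(genotypes.samples),
        frequencies=p,
        n_markers_used=int(poly.sum()),
        n_monomorphic_dropped=n_dropped,
    )


def relationship_summary(G) -> dict:
    """Distribution summary of the off-diagonal relationships.

    Operates on the strict upper triangle.  ``counts`` classifies pairs
    into bins around the canonical pedigree relationships: half-sib-like
    [0.15, 0.375), full-sib-like [0.375, 0.75) and duplicate/twin-like
    >= 0.75.
    """
    if isinstance(G, RelationshipMatrix):
        G = G.G
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals to summarize relationships")
    iu = np.triu_indices(n, k=1)
    vals = G[iu]
    return {
        "n_pairs": len(vals),
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "counts": {
            "near_0.25": int(((vals >= 0.15) & (vals < 0.375)).sum()),
            "near_0.5": int(((vals >= 0.375) & (vals < 0.75)).sum()),
            "near_1.0": int((vals >= 0.75).sum()),
        },
        "mean_diagonal": float(np.mean(np.diag(G))),
    }
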