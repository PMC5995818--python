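"""Genotype quality control: sample call rate, SNP call rate, MAF and HWE.

The filter protocol drops, in order: (1) non-autosomal markers, (2) samples
with call rate below threshold, then — after recomputing marker statistics
on the retained samples — SNPs failing (3) call rate, (4) MAF and (5) the
Hardy-Weinberg chi-square test.  All thresholds are strict ("lower than"),
and a SNP failing several filters is attributed to the first one in order,
so the audit report is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotype_io import GenotypeMatrix, allele_stats

__all__ = ["QCConfig", "QCReport", "EmptyAfterQCError", "hwe_chi_square", "run_qc"]

#: Ovine autosome labels (OAR1..OAR26) as plain numbers.
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 27))


class EmptyAfterQCError(RuntimeError):
    """All samples or all markers were removed by quality control."""


@dataclasses.dataclass
class QCConfig:
    """Thresholds for the QC protocol (all comparisons strict ``<``)."""

    sample_call_rate_min: float = 0.90
    snp_call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 0.1
    autosomes_only: bool = True
    autosomes: tuple = DEFAULT_AUTOSOMES

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.autosomes = tuple(str(c) for c in self.autosomes)

    @classmethod
    def from_file(cls, path) -> "QCConfig":
        """Load from a YAML (or flat ``key: value``) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclasses.dataclass
class QCReport:
    """Audit record of one :func:`run_qc` invocation.

    ``per_chromosome`` mirrors a before/after SNP-count table (chromosome,
    snps_before, snps_after); conservation before - removed = after holds
    per chromosome and overall.
    """

    n_samples_before: int
    n_samples_after: int
    samples_removed: list
    n_markers_before: int
    n_markers_after: int
    markers_removed: dict  # filter name -> count
    per_chromosome: pd.DataFrame

    def to_table(self) -> pd.DataFrame:
        return self.per_chromosome.copy()


def hwe_chi_square(n_AA, n_Aa, n_aa):
    """Hardy-Weinberg equilibrium chi-square test from genotype counts.

    Expected counts derive from the estimated allele frequency under HWE;
    the statistic has 1 degree of freedom (no continuity correction).  For a
    monomorphic marker the test is undefined and ``(nan, nan)`` is returned
    (such a marker passes: no evidence against HWE).

    Returns
    -------
    (chi2_statistic, p_value)
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return (float("nan"), float("nan"))
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return (chi2, float(stats.chi2.sf(chi2, df=1)))


def _hwe_p_vector(stats_df: pd.DataFrame) -> np.ndarray:
    """Vectorized HWE p-values for the markers of an allele_stats table."""
    nAA = stats_df["n_AA"].to_numpy(float)
    nAa = stats_df["n_Aa"].to_numpy(float)
    naa = stats_df["n_aa"].to_numpy(float)
    n = nAA + nAa + naa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * nAA + nAa) / (2 * n)
        exp_AA = n * p * p
        exp_Aa = 2 * n * p * (1 - p)
        exp_aa = n * (1 - p) ** 2
        chi2 = (
            (nAA - exp_AA) ** 2 / exp_AA
            + (nAa - exp_Aa) ** 2 / exp_Aa
            + (naa - exp_aa) ** 2 / exp_aa
        )
    pval = stats.chi2.sf(chi2, df=1)
    # monomorphic or empty markers: test undefined -> NaN (passes)
    undefined = (n == 0) | (p <= 0) | (p >= 1)
    pval = np.where(undefined, np.nan, pval)
    return pval


def run_qc(genotypes: GenotypeMatrix, config: QCConfig = None):
    """Apply the QC protocol and return ``(filtered, QCReport)``.

    Raises :class:`EmptyAfterQCError` if no samples or no markers survive.
    """
    if config is None:
        config = QCConfig()
    mk = genotypes.markers
    chrom_before = mk["chrom"].value_counts(sort=False)

    # (1) non-autosomal markers
    if config.autosomes_only:
        keep_auto = mk["chrom"].isin(config.autosomes).to_numpy()
    else:
        keep_auto = np.ones(len(mk), dtype=bool)
    n_nonauto = int((~keep_auto).sum())
    gm = genotypes.subset(marker_idx=np.flatnonzero(keep_auto))
    if gm.n_markers == 0:
        raise EmptyAfterQCError("no markers remain after autosome restriction")

    # (2) sample call rate
    nonmiss = (gm.dosages >= 0).mean(axis=1)
    keep_samples = nonmiss >= config.sample_call_rate_min
    removed_samples = [s for s, k in zip(gm.samples, keep_samples) if not k]
    gm = gm.subset(sample_idx=np.flatnonzero(keep_samples))
    if gm.n_individuals == 0:
        raise EmptyAfterQCError("no samples remain after sample call-rate filter")

    # (3-5) marker filters on recomputed statistics, attributed in order
    st = allele_stats(gm)
    fail_cr = st["call_rate"].to_numpy() < config.snp_call_rate_min
    maf = st["maf"].to_numpy()
    fail_maf = ~fail_cr & (np.nan_to_num(maf, nan=0.0) < config.maf_min)
    hwe_p = _hwe_p_vector(st)
    with np.errstate(invalid="ignore"):
        fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < config.hwe_p_min)
    keep = ~(fail_cr | fail_maf | fail_hwe)
    filtered = gm.subset(marker_idx=np.flatnonzero(keep))
    if filtered.n_markers == 0:
        raise EmptyAfterQCError("no markers remain after SNP filters")

    chrom_after = filtered.markers["chrom"].value_counts(sort=False)
    per_chrom = pd.DataFrame(
        {
            "chrom": chrom_before.index,
            "snps_before": chrom_before.to_numpy(),
            "snps_after": [int(chrom_after.get(c, 0)) for c in chrom_before.index],
        }
    )
    report = QCReport(
        n_samples_before=genotypes.n_individuals,
        n_samples_after=filtered.n_individuals,
        samples_removed=removed_samples,
        n_markers_before=genotypes.n_markers,
        n_markers_after=filtered.n_markers,
        markers_removed={
            "non_autosomal": n_nonauto,
            "call_rate": int(fail_cr.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        per_chromosome=per_chrom,
    )
    return filtered, report
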