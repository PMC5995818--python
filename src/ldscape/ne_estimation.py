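"""Effective population size from LD decay (Sved relation) and allied formulas.

At drift-recombination equilibrium the expected r^2 between loci a
recombination distance c apart in a population of effective size Ne is
E[r^2] = 1 / (1 + 4 Ne c).  Inverting over distance bins gives a history:

    Ne(t) = (4 c_t)^-1 (E[r^2 | c_t]^-1 - alpha),   t = 1 / (2 c_t)

where alpha absorbs the mutation model (1 = none, 2 or 2.2 = mutation-drift
equilibrium) and pairs at recombination distance c_t reflect the population
roughly 1/(2c) generations ago.  Physical distance maps to genetic distance
at a constant rate (default 1 cM per Mb).  An optional sample-size
correction subtracts 1/n (n sampled diploids) from the mean observed r^2 to
remove the finite-sample inflation of the estimator.

Two further classical quantities are provided: the Hill-Robertson
expectation of D^2 after inbreeding to level F,

    E(D^2) = (1/15) p0(1-p0) q0(1-q0) [6(1-F) - 5(1-F)^3 - (1-F)^6],

and the one-generation recursion E(D_t) = (1-c)(1 - 1/(2Ne)) E(D_{t-1}).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "NeConfig",
    "NeTrajectory",
    "physical_to_genetic",
    "sved_expected_r2",
    "ne_from_bin",
    "ne_trajectory",
    "hill_robertson_expected_d2",
    "sved_recursion_step",
    "d2_f_correlation",
]

ALLOWED_ALPHA = (1.0, 2.0, 2.2)


def _default_bins() -> tuple:
    # 0.05-Mb-wide bins from 0.05 to 4 Mb
    return tuple(np.round(np.arange(0.05, 4.0 + 1e-9, 0.05), 10))


@dataclasses.dataclass
class NeConfig:
    """Knobs of the Ne-trajectory estimator.

    alpha must be one of {1, 2, 2.2}; the default 2.2 is the
    mutation-drift-equilibrium value (Ohta-Kimura).  bin_edges_mb are
    left-closed right-open distance bins.
    """

    cm_per_mb: float = 1.0
    alpha: float = 2.2
    sample_size_correction: bool = True
    bin_edges_mb: tuple = dataclasses.field(default_factory=_default_bins)
    min_pairs_per_bin: int = 50

    def __post_init__(self):
        if not any(np.isclose(self.alpha, a) for a in ALLOWED_ALPHA):
            raise ValueError(f"alpha must be one of {ALLOWED_ALPHA}, got {self.alpha}")
        edges = np.asarray(self.bin_edges_mb, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclasses.dataclass
class NeTrajectory:
    """Per-bin Ne history plus per-chromosome harmonic means.

    ``table`` columns: bin_lo_mb, bin_hi_mb, mean_dist_mb, c, t_exact, t,
    n_pairs, mean_r2, adj_r2, ne, usable.  ``recent_ne`` is the Ne of the
    usable bin with the largest recombination rate (most recent
    generation).
    """

    table: pd.DataFrame
    per_chromosome: pd.DataFrame
    recent_ne: float
    recent_t: int


def physical_to_genetic(distance_bp, cm_per_mb: float = 1.0) -> float:
    """Physical distance (bp) to genetic distance (Morgans)."""
    distance_bp = np.asarray(distance_bp, dtype=float)
    if np.any(distance_bp < 0):
        raise ValueError("distance must be nonnegative")
    out = distance_bp / 1e6 * cm_per_mb / 100.0
    return float(out) if out.ndim == 0 else out


def sved_expected_r2(ne: float, c) -> float:
    """Equilibrium expectation E[r^2] = 1 / (1 + 4 Ne c)."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("recombination rate must be nonnegative")
    out = 1.0 / (1.0 + 4.0 * ne * c)
    return float(out) if out.ndim == 0 else out


def ne_from_bin(mean_r2: float, c: float, alpha: float = 2.2,
                n_samples: int = None, correction: bool = True):
    """Invert the Sved relation for one distance bin.

    Returns ``(ne, usable)``; the bin is unusable when the (corrected) r^2
    leaves no positive drift signal (adjusted r^2 <= 0 or Ne <= 0).
    """
    if c <= 0:
        raise ValueError("recombination rate must be positive for inversion")
    adj = mean_r2 - (1.0 / n_samples if (correction and n_samples) else 0.0)
    if adj <= 0.0:
        return (float("nan"), False)
    ne = (1.0 / (4.0 * c)) * (1.0 / adj - alpha)
    return (ne, ne > 0.0)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _bin_table(estimates: pd.DataFrame, config: NeConfig, n_samples: int) -> pd.DataFrame:
    edges = np.asarray(config.bin_edges_mb, dtype=float)
    dist_mb = estimates["dist_bp"].to_numpy(float) / 1e6
    r2 = estimates["r2"].to_numpy(float)
    idx = np.searchsorted(edges, dist_mb, side="right") - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        npairs = int(sel.sum())
        if npairs == 0:
            continue
        mean_dist = float(dist_mb[sel].mean())
        c = mean_dist * config.cm_per_mb / 100.0
        mean_r2 = float(r2[sel].mean())
        ne, ok = ne_from_bin(
            mean_r2, c, config.alpha, n_samples, config.sample_size_correction
        )
        adj = mean_r2 - (1.0 / n_samples if config.sample_size_correction else 0.0)
        t_exact = 1.0 / (2.0 * c)
        rows.append(
            {
                "bin_lo_mb": edges[k],
                "bin_hi_mb": edges[k + 1],
                "mean_dist_mb": mean_dist,
                "c": c,
                "t_exact": t_exact,
                "t": _round_half_up(t_exact),
                "n_pairs": npairs,
                "mean_r2": mean_r2,
                "adj_r2": adj,
                "ne": ne,
                "usable": bool(ok and npairs >= config.min_pairs_per_bin),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bin_lo_mb", "bin_hi_mb", "mean_dist_mb", "c", "t_exact", "t",
                 "n_pairs", "mean_r2", "adj_r2", "ne", "usable"],
    )


def harmonic_mean(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(len(values) / np.sum(1.0 / values))


def ne_trajectory(estimates: pd.DataFrame, config: NeConfig = None,
                  n_samples: int = None) -> NeTrajectory:
    """Distance-binned Ne history from pairwise LD estimates.

    ``n_samples`` (sampled diploids) is required when the sample-size
    correction is on; it defaults to the maximum pairwise n in the
    estimates.  Per-chromosome Ne is the harmonic mean over that
    chromosome's usable bins.  Raises if no bin is usable.
    """
    if config is None:
        config = NeConfig()
    if len(estimates) == 0:
        raise ValueError("no LD estimates supplied")
    if n_samples is None:
        n_samples = int(estimates["n"].max())

    table = _bin_table(estimates, config, n_samples)
    usable = table[table["usable"]]
    if len(usable) == 0:
        raise ValueError("no usable distance bins for Ne estimation")
    top = usable.loc[usable["c"].idxmax()]

    chrom_rows = []
    for chrom, grp in estimates.groupby("chrom", sort=False):
        sub = _bin_table(grp, config, n_samples)
        sub = sub[sub["usable"]]
        chrom_rows.append(
            {
                "chrom": chrom,
                "n_bins": len(sub),
                "ne_harmonic": harmonic_mean(sub["ne"]) if len(sub) else float("nan"),
            }
        )
    return NeTrajectory(
        table=table,
        per_chromosome=pd.DataFrame(chrom_rows, columns=["chrom", "n_bins", "ne_harmonic"]),
        recent_ne=float(top["ne"]),
        recent_t=int(top["t"]),
    )


def hill_robertson_expected_d2(p0: float, q0: float, F: float) -> float:
    """Expected D^2 after inbreeding to level F (Hill-Robertson).

    p0 and q0 are the initial allele frequencies at the two loci; the
    expectation vanishes at F = 0 and F = 1.
    """
    if not (0.0 < p0 < 1.0) or not (0.0 < q0 < 1.0):
        raise ValueError("initial frequencies must lie in (0, 1)")
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    g = 1.0 - F
    return (1.0 / 15.0) * p0 * (1 - p0) * q0 * (1 - q0) * (6 * g - 5 * g**3 - g**6)


def sved_recursion_step(d_prev: float, c: float, ne: float) -> float:
    """One generation of LD decay: E(D_t) = (1-c)(1 - 1/(2Ne)) E(D_{t-1})."""
    if not 0.0 <= c <= 0.5:
        raise ValueError("recombination rate must lie in [0, 0.5]")
    if ne <= 0.5:
        raise ValueError("Ne must exceed 0.5")
    return (1.0 - c) * (1.0 - 1.0 / (2.0 * ne)) * d_prev


def d2_f_correlation(estimates: pd.DataFrame, inbreeding_f: pd.Series,
                     allele_freq: pd.Series = None) -> float:
    """Correlation between inbreeding-predicted and observed per-chromosome D^2.

    For each chromosome the Hill-Robertson formula predicts E(D^2) from the
    chromosome's inbreeding level (``inbreeding_f``, indexed by chromosome)
    and its mean allele frequency (``allele_freq``, same index; used for
    both p0 and q0; defaults to 0.5).  The observed series is the
    chromosome mean of D^2 from the LD estimates.  Undefined (returns NaN
    with a warning) when a series is constant; requires >= 3 chromosomes.
    """
    obs = estimates.assign(d2=estimates["D"] ** 2).groupby("chrom", sort=False)["d2"].mean()
    chroms = [c for c in obs.index if c in inbreeding_f.index]
    if len(chroms) < 3:
        raise ValueError("need at least three chromosomes")
    pred = []
    for c in chroms:
        p0 = float(allele_freq[c]) if allele_freq is not None else 0.5
        f = float(np.clip(inbreeding_f[c], 0.0, 1.0))
        pred.append(hill_robertson_expected_d2(p0, p0, f))
    pred = np.asarray(pred)
    observed = obs[chroms].to_numpy(float)
    if np.std(pred) == 0.0 or np.std(observed) == 0.0:
        import warnings

        warnings.warn("constant series; D^2-F correlation undefined")
        return float("nan")
    return float(np.corrcoef(pred, observed)[0, 1])
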