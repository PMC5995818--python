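"""Aggregation of pairwise LD estimates into reporting tables.

Four surfaces: per-chromosome means of r^2 and |D'| (with a genome-wide
row), distance-binned decay tables, low/medium/high LD category tables
(low: r^2 <= 0.16; medium: 0.16 < r^2 < 0.70; high: r^2 >= 0.70), and the
product-moment correlation between the two LD metrics.  Standard
deviations are sample SDs (n - 1 denominator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "LOW_LD_MAX",
    "HIGH_LD_MIN",
    "summarize_by_chromosome",
    "bin_by_distance",
    "categorize",
    "correlate_metrics",
]

LOW_LD_MAX = 0.16
HIGH_LD_MIN = 0.70

GENOME_LABEL = "genome"


def _mean_sd(x: np.ndarray):
    if len(x) == 0:
        return (np.nan, np.nan)
    return (float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)


def summarize_by_chromosome(estimates: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-chromosome means/SDs of r^2 and |D'|.

    The final row (chrom = ``genome``) pools all pairs, so its mean is the
    pair-count-weighted mean of the chromosome means; a chromosome-averaged
    genome mean is also reported (``*_chrom_avg`` columns) since reporting
    conventions differ.
    """
    rows = []
    for chrom, grp in estimates.groupby("chrom", sort=False):
        r2m, r2s = _mean_sd(grp["r2"].to_numpy())
        dpm, dps = _mean_sd(grp["Dprime_abs"].to_numpy())
        rows.append(
            {
                "chrom": chrom,
                "n_pairs": len(grp),
                "mean_dist_mb": float(grp["dist_bp"].mean()) / 1e6,
                "mean_r2": r2m,
                "sd_r2": r2s,
                "mean_dprime": dpm,
                "sd_dprime": dps,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "n_pairs", "mean_dist_mb", "mean_r2", "sd_r2",
                 "mean_dprime", "sd_dprime"],
    )
    if len(estimates):
        r2m, r2s = _mean_sd(estimates["r2"].to_numpy())
        dpm, dps = _mean_sd(estimates["Dprime_abs"].to_numpy())
        genome = {
            "chrom": GENOME_LABEL,
            "n_pairs": len(estimates),
            "mean_dist_mb": float(estimates["dist_bp"].mean()) / 1e6,
            "mean_r2": r2m,
            "sd_r2": r2s,
            "mean_dprime": dpm,
            "sd_dprime": dps,
            "mean_r2_chrom_avg": float(out["mean_r2"].mean()),
            "mean_dprime_chrom_avg": float(out["mean_dprime"].mean()),
        }
        out = pd.concat([out, pd.DataFrame([genome])], ignore_index=True)
    return out


def bin_by_distance(estimates: pd.DataFrame, edges_mb) -> pd.DataFrame:
    """Distance-binned LD decay table.

    Bins are left-closed right-open ``[edges[k], edges[k+1])`` in Mb.
    Pairs beyond the last edge are counted in ``attrs["n_overflow"]``
    (pairs below the first edge in ``attrs["n_underflow"]``).
    """
    edges = np.asarray(edges_mb, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    dist_mb = estimates["dist_bp"].to_numpy() / 1e6 if len(estimates) else np.array([])
    idx = np.searchsorted(edges, dist_mb, side="right") - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        grp_r2 = estimates.loc[sel, "r2"] if len(estimates) else pd.Series(dtype=float)
        grp_dp = estimates.loc[sel, "Dprime_abs"] if len(estimates) else pd.Series(dtype=float)
        rows.append(
            {
                "bin_lo_mb": edges[k],
                "bin_hi_mb": edges[k + 1],
                "n_pairs": int(sel.sum()),
                "mean_dist_mb": float(dist_mb[sel].mean()) if sel.any() else np.nan,
                "mean_r2": float(grp_r2.mean()) if sel.any() else np.nan,
                "mean_dprime": float(grp_dp.mean()) if sel.any() else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_overflow"] = int((idx >= len(edges) - 1).sum())
    out.attrs["n_underflow"] = int((idx < 0).sum())
    return out


def ld_category(r2):
    """Classify r^2 values into low / medium / high LD categories."""
    r2 = np.asarray(r2, dtype=float)
    return np.where(r2 >= HIGH_LD_MIN, "high", np.where(r2 > LOW_LD_MAX, "medium", "low"))


def categorize(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per chromosome x LD-category mean r^2, mean distance and frequency.

    Frequencies are percentages of that chromosome's pairs and sum to 100
    per chromosome.
    """
    rows = []
    cats = ld_category(estimates["r2"]) if len(estimates) else np.array([])
    for chrom, grp_idx in estimates.groupby("chrom", sort=False).groups.items():
        sub = estimates.loc[grp_idx]
        sub_cat = cats[estimates.index.get_indexer(grp_idx)]
        total = len(sub)
        for cat in ("high", "medium", "low"):
            sel = sub_cat == cat
            rows.append(
                {
                    "chrom": chrom,
                    "category": cat,
                    "n_pairs": int(sel.sum()),
                    "mean_r2": float(sub.loc[sel, "r2"].mean()) if sel.any() else np.nan,
                    "mean_dist_mb": float(sub.loc[sel, "dist_bp"].mean()) / 1e6
                    if sel.any()
                    else np.nan,
                    "freq_percent": 100.0 * sel.sum() / total,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "category", "n_pairs", "mean_r2", "mean_dist_mb", "freq_percent"],
    )


def correlate_metrics(estimates: pd.DataFrame) -> float:
    """Product-moment correlation between the r^2 and |D'| series.

    Returns NaN (flagged via a warning) when either series has zero
    variance or fewer than two estimates are available.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two LD estimates to correlate")
    r2 = estimates["r2"].to_numpy(float)
    dp = estimates["Dprime_abs"].to_numpy(float)
    if np.std(r2) == 0.0 or np.std(dp) == 0.0:
        import warnings

        warnings.warn("zero variance in an LD metric series; correlation undefined")
        return float("nan")
    return float(np.corrcoef(r2, dp)[0, 1])
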