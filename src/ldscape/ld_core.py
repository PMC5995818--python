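"""Two-locus linkage disequilibrium from unphased genotypes.

For a pair of biallelic markers the data reduce to a 3x3 table of joint
dosage counts.  Phase is unknown only for double heterozygotes (AB/ab is
indistinguishable from Ab/aB), so the haplotype frequency rho_AB is
estimated by maximum likelihood with an EM algorithm: the E-step splits
double heterozygotes between the two phase resolutions proportionally to
rho_AB*rho_ab vs rho_Ab*rho_aB, the M-step re-estimates the joint
frequencies from expected haplotype counts.  The marginal allele
frequencies are fixed by the observed dosages, so the EM moves along a
one-parameter family indexed by rho_AB on the admissible interval
[max(0, rho_A + rho_B - 1), min(rho_A, rho_B)].  Because the profile
likelihood can be bimodal, the EM is restarted from three deterministic
points (linkage equilibrium and near each boundary) and the highest-
likelihood iterate is kept.

From the fitted frequencies the classical statistics follow:

    D      = rho_AB - rho_A * rho_B
    D_max  = min(rho_A*rho_b, rho_a*rho_B)   if D > 0
             min(rho_A*rho_B, rho_a*rho_b)   if D < 0  (magnitude)
    |D'|   = |D| / D_max                      (0 when D = 0)
    r^2    = D^2 / (rho_A * rho_a * rho_B * rho_b)

Confidence limits on |D'| (used by the Gabriel block criterion) come from
the profile likelihood over rho_AB: the genotype log-likelihood is
evaluated on a grid of the admissible interval, normalized to a unit mass,
mapped to |D'|, and the equal-tail level-mass interval is returned.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "UndefinedLDError",
    "HaplotypeFreqs",
    "LDEstimate",
    "two_locus_counts",
    "em_haplotype_freqs",
    "ld_from_freqs",
    "genotype_log_likelihood",
    "dprime_confidence_interval",
    "pairwise_ld",
]

log = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class UndefinedLDError(ValueError):
    """LD is undefined (a marker is monomorphic in the pairwise subset)."""


@dataclasses.dataclass
class HaplotypeFreqs:
    """ML haplotype frequencies for one marker pair.

    ``saddle`` flags the degenerate table containing only double
    heterozygotes, where the linkage-equilibrium start is a stationary
    point of the EM and D = 0 is reported by convention.
    """

    rho_AB: float
    rho_Ab: float
    rho_aB: float
    rho_ab: float
    rho_A: float
    rho_B: float
    n_iterations: int
    converged: bool
    saddle: bool = False

    @property
    def rho_a(self) -> float:
        return 1.0 - self.rho_A

    @property
    def rho_b(self) -> float:
        return 1.0 - self.rho_B


@dataclasses.dataclass
class LDEstimate:
    """D, D_max, |D'| and r^2 for one marker pair."""

    D: float
    D_max: float
    dprime_abs: float
    r2: float
    freqs: HaplotypeFreqs = None


def two_locus_counts(g1, g2) -> np.ndarray:
    """3x3 joint dosage table from two dosage vectors (missing = negative).

    ``counts[i, j]`` is the number of individuals with dosage ``i`` at the
    first marker and ``j`` at the second, over individuals non-missing at
    both.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0) & (g2 >= 0)
    code = g1[ok] * 3 + g2[ok]
    return np.bincount(code, minlength=9).reshape(3, 3)


# ---------------------------------------------------------------------------
# Batched EM core (scalar API wraps the batch of size one)
# ---------------------------------------------------------------------------

def _margins(counts9: np.ndarray):
    """Allele-A/B frequencies and pair counts from (P, 9) count tables."""
    c = counts9.reshape(-1, 3, 3).astype(float)
    n = c.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (2 * c[:, 2, :].sum(axis=1) + c[:, 1, :].sum(axis=1)) / (2 * n)
        pB = (2 * c[:, :, 2].sum(axis=1) + c[:, :, 1].sum(axis=1)) / (2 * n)
    return c, n, pA, pB


def _batch_ll(counts3, pAB, pA, pB):
    """Genotype log-likelihood of (P,) rho_AB values at fixed margins."""
    pAb = pA - pAB
    paB = pB - pAB
    pab = 1.0 - pA - pB + pAB
    probs = _cell_probs(pAB, pAb, paB, pab)
    obs = counts3.reshape(len(counts3), 9)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(obs > 0, obs * np.log(probs), 0.0).sum(axis=-1)
    return np.where(np.isnan(ll), -np.inf, ll)


def _em_batch(counts9: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Maximum-likelihood rho_AB over a batch of 3x3 tables via EM.

    The profile likelihood in rho_AB can be bimodal (a coupling and a
    repulsion mode), so the EM is run from three deterministic starts —
    linkage equilibrium and near each admissible boundary — and the
    iterate with the highest genotype log-likelihood wins.  Tables that
    consist solely of double heterozygotes carry no phase information at
    all; they are kept at the linkage-equilibrium stationary point and
    flagged (``saddle``) so D = 0 is reported by convention.

    Returns (pAB, pA, pB, n, iterations, converged, saddle).  Tables whose
    margins are degenerate yield NaN; callers filter on the margins.
    """
    c, n, pA, pB = _margins(counts9)
    # unambiguous haplotype contributions
    kAB = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    dh = c[:, 1, 1]

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    twon = np.where(n > 0, 2 * n, 1.0)
    valid = np.isfinite(pA) & (n > 0)
    saddle = (dh == n) & (n > 0)

    def run(pAB0):
        pAB = np.where(valid, np.clip(pAB0, lo, hi), np.nan)
        iters = np.zeros(len(n), dtype=int)
        active = valid.copy()
        converged = ~active
        for _ in range(max_iter):
            if not active.any():
                break
            pab = 1.0 - pA - pB + pAB
            pAb = pA - pAB
            paB = pB - pAB
            num = pAB * pab
            den = num + pAb * paB
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(den > 0, num / den, 0.5)
            new = np.clip((kAB + dh * w) / twon, lo, hi)
            delta = np.abs(new - pAB)
            pAB = np.where(active, new, pAB)
            iters += active
            newly = active & (delta < tol)
            converged |= newly
            active &= ~newly
        return pAB, iters, converged

    le = pA * pB
    eps = 0.02
    starts = (le, lo + eps * (hi - lo), hi - eps * (hi - lo))
    best_pAB, best_iters, best_conv = run(starts[0])
    best_ll = _batch_ll(c, best_pAB, pA, pB)
    le_result = (best_pAB.copy(), best_iters.copy(), best_conv.copy())
    for s0 in starts[1:]:
        pAB_s, iters_s, conv_s = run(s0)
        ll_s = _batch_ll(c, pAB_s, pA, pB)
        better = ll_s > best_ll + 1e-12
        best_pAB = np.where(better, pAB_s, best_pAB)
        best_iters = np.where(better, iters_s, best_iters)
        best_conv = np.where(better, conv_s, best_conv)
        best_ll = np.where(better, ll_s, best_ll)
    # the constrained MLE may sit exactly on a boundary, which EM only
    # approaches geometrically; evaluate both endpoints in closed form
    for endpoint in (lo, hi):
        ll_e = _batch_ll(c, np.where(valid, endpoint, np.nan), pA, pB)
        better = ll_e > best_ll + 1e-12
        best_pAB = np.where(better, endpoint, best_pAB)
        best_conv = np.where(better, True, best_conv)
        best_ll = np.where(better, ll_e, best_ll)
    # phase-free tables stay at the LE stationary point by convention
    best_pAB = np.where(saddle, le_result[0], best_pAB)
    best_iters = np.where(saddle, le_result[1], best_iters)
    best_conv = np.where(saddle, le_result[2], best_conv)
    return best_pAB, pA, pB, n, best_iters, best_conv, saddle


def _ld_stats(pAB, pA, pB):
    """Vectorized D, D_max, |D'|, r^2 from rho_AB and the margins."""
    pa = 1.0 - pA
    pb = 1.0 - pB
    D = pAB - pA * pB
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_pos = np.minimum(pA * pb, pa * pB)
        dmax_neg = np.minimum(pA * pB, pa * pb)
        D_max = np.where(D >= 0, dmax_pos, dmax_neg)
        dprime = np.where(D == 0, 0.0, np.abs(D) / D_max)
        r2 = D * D / (pA * pa * pB * pb)
    return D, D_max, np.minimum(dprime, 1.0), np.minimum(r2, 1.0)


def genotype_log_likelihood(counts, rho_AB, rho_A, rho_B) -> float:
    """Multinomial genotype log-likelihood at given haplotype frequencies.

    Genotype cell probabilities assume random union of gametes, e.g.
    P(dosage 1, dosage 1) = 2(rho_AB*rho_ab + rho_Ab*rho_aB).
    """
    c = np.asarray(counts, dtype=float).reshape(3, 3)
    pAB = float(rho_AB)
    pAb = rho_A - pAB
    paB = rho_B - pAB
    pab = 1.0 - rho_A - rho_B + pAB
    probs = _cell_probs(np.array([pAB]), np.array([pAb]), np.array([paB]), np.array([pab]))[0]
    obs = c.reshape(9)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(probs), 0.0)
    return float(terms.sum())


def _cell_probs(pAB, pAb, paB, pab):
    """Stack of the nine genotype-cell probabilities, shape (..., 9).

    Cell order matches ``counts.reshape(-1, 9)``: (dosage1, dosage2) =
    (0,0), (0,1), (0,2), (1,0), (1,1), (1,2), (2,0), (2,1), (2,2).
    """
    pAB, pAb, paB, pab = (np.clip(x, 0.0, 1.0) for x in (pAB, pAb, paB, pab))
    return np.stack(
        [
            pab * pab,
            2 * paB * pab,
            paB * paB,
            2 * pAb * pab,
            2 * (pAB * pab + pAb * paB),
            2 * pAB * paB,
            pAb * pAb,
            2 * pAB * pAb,
            pAB * pAB,
        ],
        axis=-1,
    )


def em_haplotype_freqs(counts, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER) -> HaplotypeFreqs:
    """ML haplotype frequencies for one 3x3 dosage-count table.

    Raises :class:`UndefinedLDError` when either marker is monomorphic in
    the pairwise-complete subset or fewer than two individuals are jointly
    observed.
    """
    counts9 = np.asarray(counts, dtype=float).reshape(1, 9)
    _, n, pA, pB = _margins(counts9)
    if n[0] < 2:
        raise UndefinedLDError("need at least two pairwise-complete individuals")
    if not (0.0 < pA[0] < 1.0) or not (0.0 < pB[0] < 1.0):
        raise UndefinedLDError("marker monomorphic in the pairwise-complete subset")
    pAB, pA, pB, n, iters, conv, saddle = _em_batch(counts9, tol, max_iter)
    pAB_ = float(pAB[0])
    return HaplotypeFreqs(
        rho_AB=pAB_,
        rho_Ab=float(pA[0] - pAB_),
        rho_aB=float(pB[0] - pAB_),
        rho_ab=float(1.0 - pA[0] - pB[0] + pAB_),
        rho_A=float(pA[0]),
        rho_B=float(pB[0]),
        n_iterations=int(iters[0]),
        converged=bool(conv[0]),
        saddle=bool(saddle[0]),
    )


def ld_from_freqs(freqs: HaplotypeFreqs) -> LDEstimate:
    """D, D_max, |D'| and r^2 from fitted haplotype frequencies."""
    if not (0.0 < freqs.rho_A < 1.0) or not (0.0 < freqs.rho_B < 1.0):
        raise UndefinedLDError("marginal frequency at 0 or 1: LD undefined")
    D, D_max, dprime, r2 = (
        x.item() for x in _ld_stats(
            np.array([freqs.rho_AB]), np.array([freqs.rho_A]), np.array([freqs.rho_B])
        )
    )
    return LDEstimate(D=D, D_max=D_max, dprime_abs=dprime, r2=r2, freqs=freqs)


# ---------------------------------------------------------------------------
# |D'| confidence intervals (profile likelihood)
# ---------------------------------------------------------------------------

def _dprime_ci_batch(counts9: np.ndarray, level: float = 0.90, grid_points: int = 201):
    """Equal-tail likelihood-mass intervals on |D'| for a batch of tables.

    For each table the genotype log-likelihood is profiled over rho_AB on
    its admissible interval (``grid_points`` points), the likelihood curve
    is normalized to unit mass, mapped to |D'|, and the central
    ``level``-mass interval is returned as (lower, upper) arrays.
    """
    c, n, pA, pB = _margins(counts9)
    P = len(n)
    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    s = np.linspace(0.0, 1.0, grid_points)
    pAB = lo[:, None] + s[None, :] * (hi - lo)[:, None]
    pAb = pA[:, None] - pAB
    paB = pB[:, None] - pAB
    pab = 1.0 - pA[:, None] - pB[:, None] + pAB
    probs = _cell_probs(pAB, pAb, paB, pab)  # (P, G, 9)
    obs = c.reshape(P, 1, 9)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(obs > 0, obs * np.log(probs), 0.0).sum(axis=-1)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)

    _, _, dprime, _ = _ld_stats(pAB, pA[:, None], pB[:, None])
    order = np.argsort(dprime, axis=1, kind="stable")
    dp_sorted = np.take_along_axis(dprime, order, axis=1)
    w_sorted = np.take_along_axis(w, order, axis=1)
    cdf = np.cumsum(w_sorted, axis=1)
    alpha = (1.0 - level) / 2.0
    ilo = np.argmax(cdf >= alpha, axis=1)
    ihi = np.argmax(cdf >= 1.0 - alpha, axis=1)
    rows = np.arange(P)
    return dp_sorted[rows, ilo], dp_sorted[rows, ihi]


def dprime_confidence_interval(counts, level: float = 0.90, grid_points: int = 2001):
    """Profile-likelihood confidence limits on |D'| for one marker pair.

    Returns ``(lower, upper)`` at the given likelihood-mass level
    (default 0.90, the level the Gabriel block criterion uses).
    """
    counts9 = np.asarray(counts, dtype=float).reshape(1, 9)
    _, n, pA, pB = _margins(counts9)
    if n[0] < 2:
        raise UndefinedLDError("need at least two pairwise-complete individuals")
    if not (0.0 < pA[0] < 1.0) or not (0.0 < pB[0] < 1.0):
        raise UndefinedLDError("marker monomorphic in the pairwise-complete subset")
    lo, hi = _dprime_ci_batch(counts9, level=level, grid_points=grid_points)
    return float(lo[0]), float(hi[0])


# ---------------------------------------------------------------------------
# Pairwise LD over a genotype matrix
# ---------------------------------------------------------------------------

def _pair_counts(dosages: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """(P, 9) joint dosage tables for the marker pairs (idx1, idx2)."""
    x1 = dosages[:, idx1].astype(np.int16)
    x2 = dosages[:, idx2].astype(np.int16)
    valid = (x1 >= 0) & (x2 >= 0)
    code = np.where(valid, x1 * 3 + x2, 9)
    counts = np.empty((len(idx1), 9), dtype=np.int64)
    for k in range(9):
        counts[:, k] = (code == k).sum(axis=0)
    return counts


def _chromosome_pairs(n_markers: int, mode: str):
    if mode == "adjacent":
        i = np.arange(n_markers - 1)
        return i, i + 1
    if mode == "all":
        i, j = np.triu_indices(n_markers, k=1)
        return i, j
    raise ValueError(f"mode must be 'adjacent' or 'all', got {mode!r}")


def pairwise_ld(
    genotypes: GenotypeMatrix,
    mode: str = "adjacent",
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    chunk_size: int = 20000,
) -> pd.DataFrame:
    """Within-chromosome LD estimates for adjacent or all marker pairs.

    Pairs whose LD is undefined (a marker monomorphic among the
    pairwise-complete individuals, or fewer than two such individuals) are
    skipped; the skip count is logged and stored in
    ``result.attrs["n_skipped"]``.

    Returns a DataFrame with columns chrom, id1, id2, bp1, bp2, dist_bp,
    D, Dprime_abs, r2, n plus EM bookkeeping (n_iter, converged, saddle).
    """
    mk = genotypes.markers
    frames = []
    n_skipped = 0
    for chrom in genotypes.chromosomes():
        cidx = np.flatnonzero((mk["chrom"] == chrom).to_numpy())
        if len(cidx) < 2:
            continue
        i_loc, j_loc = _chromosome_pairs(len(cidx), mode)
        for start in range(0, len(i_loc), chunk_size):
            sl = slice(start, start + chunk_size)
            gi = cidx[i_loc[sl]]
            gj = cidx[j_loc[sl]]
            counts = _pair_counts(genotypes.dosages, gi, gj)
            pAB, pA, pB, n, iters, conv, saddle = _em_batch(counts, tol, max_iter)
            ok = (n >= 2) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
            n_skipped += int((~ok).sum())
            if not ok.any():
                continue
            D, D_max, dprime, r2 = _ld_stats(pAB[ok], pA[ok], pB[ok])
            pos = mk["pos"].to_numpy()
            ids = mk["id"].to_numpy()
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "id1": ids[gi[ok]],
                        "id2": ids[gj[ok]],
                        "bp1": pos[gi[ok]],
                        "bp2": pos[gj[ok]],
                        "dist_bp": pos[gj[ok]] - pos[gi[ok]],
                        "D": D,
                        "Dprime_abs": dprime,
                        "r2": r2,
                        "n": n[ok].astype(int),
                        "n_iter": iters[ok],
                        "converged": conv[ok],
                        "saddle": saddle[ok],
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=[
                "chrom", "id1", "id2", "bp1", "bp2", "dist_bp",
                "D", "Dprime_abs", "r2", "n", "n_iter", "converged", "saddle",
            ]
        )
    if n_skipped:
        log.info("pairwise_ld(%s): skipped %d undefined-LD pairs", mode, n_skipped)
    out.attrs["n_skipped"] = n_skipped
    out.attrs["mode"] = mode
    return out
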