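"""Shared independent oracles used by the unit and acceptance suites."""

import numpy as np


def exhaustive_em_oracle_check(max_n=8, grid_points=801, chunk=2000):
    """Compare batch-EM likelihoods with a brute-force profile-grid oracle.

    Enumerates every 3x3 genotype-count table with total n <= ``max_n``
    whose margins admit an LD estimate, computes the EM genotype
    log-likelihood and the maximum over a dense rho_AB grid, and returns
    ``(n_tables, em_ll, oracle_ll, saddle)`` arrays for assertion by the
    caller.  The oracle never calls the EM path.
    """
    from itertools import combinations_with_replacement

    from ldscape.ld_core import _cell_probs, _em_batch, _margins, _batch_ll

    tables = []
    for total in range(2, max_n + 1):
        for combo in combinations_with_replacement(range(9), total):
            tables.append(np.bincount(combo, minlength=9))
    tables = np.unique(np.array(tables), axis=0)
    _, n, pA, pB = _margins(tables)
    ok = (n >= 2) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    tables = tables[ok]

    pAB, pA, pB, n, _, _, saddle = _em_batch(tables.astype(float))
    em_ll = _batch_ll(tables.reshape(-1, 3, 3).astype(float), pAB, pA, pB)

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    oracle_ll = np.full(len(tables), -np.inf)
    s = np.linspace(0.0, 1.0, grid_points)
    for start in range(0, len(tables), chunk):
        sl = slice(start, start + chunk)
        grid = lo[sl, None] + s[None, :] * (hi - lo)[sl, None]
        pAb = pA[sl, None] - grid
        paB = pB[sl, None] - grid
        pab = 1.0 - pA[sl, None] - pB[sl, None] + grid
        probs = _cell_probs(grid, pAb, paB, pab)
        obs = tables[sl].reshape(-1, 1, 9)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(obs > 0, obs * np.log(probs), 0.0).sum(-1)
        oracle_ll[sl] = np.where(np.isnan(ll), -np.inf, ll).max(axis=1)
    return len(tables), em_ll, oracle_ll, saddle


def wf_recent_ne(n_diploid, seed, n_chromosomes=12, markers_per_chromosome=100,
                 generations_multiple=2):
    """Recent-Ne recovery experiment on a constant-size Wright-Fisher run.

    Marker spacing is set so that 4 N c = 1 between adjacent markers and
    the distance bins cover 4 N c in [1, 2] — the regime where the Sved
    inversion is a faithful estimator; the run length 2N generations
    equilibrates those bins while most markers stay polymorphic.
    """
    from ldscape.ld_core import pairwise_ld
    from ldscape.ne_estimation import NeConfig, ne_trajectory
    from ldscape.qc import QCConfig, run_qc
    from ldscape.synthetic_data import SimulationConfig, simulate_wright_fisher

    spacing_mb = 25.0 / n_diploid
    cfg = SimulationConfig(
        n_diploid=n_diploid,
        n_chromosomes=n_chromosomes,
        markers_per_chromosome=markers_per_chromosome,
        spacing_bp=int(round(spacing_mb * 1e6)),
        generations=generations_multiple * n_diploid,
        freq_range=(0.2, 0.8),
        sample_size=min(100, n_diploid),
        seed=seed,
    )
    ds = simulate_wright_fisher(cfg)
    filtered, _ = run_qc(ds.genotypes, QCConfig(autosomes_only=False))
    estimates = pairwise_ld(filtered, mode="all")
    edges = tuple(spacing_mb * np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0]))
    traj = ne_trajectory(
        estimates,
        NeConfig(alpha=1.0, bin_edges_mb=edges),
        cfg.sample_size,
    )
    return traj
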