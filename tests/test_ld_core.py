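import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldscape.genotype_io import GenotypeMatrix, MISSING, make_marker_map
from ldscape.ld_core import (
    HaplotypeFreqs,
    UndefinedLDError,
    dprime_confidence_interval,
    em_haplotype_freqs,
    genotype_log_likelihood,
    ld_from_freqs,
    pairwise_ld,
    two_locus_counts,
)
from ldscape.synthetic_data import worked_example_tables


def grid_oracle_loglik(counts, step=1e-4):
    """Brute-force maximum of the genotype likelihood over rho_AB."""
    c = np.asarray(counts, float).reshape(3, 3)
    n = c.sum()
    pA = (2 * c[2, :].sum() + c[1, :].sum()) / (2 * n)
    pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.arange(lo, hi + step / 2, step)
    lls = [genotype_log_likelihood(c, g, pA, pB) for g in grid]
    k = int(np.argmax(lls))
    return grid[k], lls[k]


class TestEmHaplotypeFreqs:
    def test_phase_known_table_is_exact_counting(self):
        """Without double heterozygotes the EM is direct haplotype counting."""
        f = em_haplotype_freqs(worked_example_tables()["phase_known"])
        assert f.rho_AB == pytest.approx(0.5)
        assert f.rho_ab == pytest.approx(0.5)
        assert f.rho_Ab == pytest.approx(0.0)
        assert f.converged

    def test_double_het_only_table_stays_at_equilibrium(self):
        """The all-double-het table is a stationary point of the EM."""
        f = em_haplotype_freqs(worked_example_tables()["double_het_only"])
        assert f.rho_AB == pytest.approx(0.25)
        assert f.saddle

    def test_em_matches_grid_oracle_on_mixed_table(self):
        """n=10 table: EM agrees with a 1e-6-step likelihood grid search."""
        counts = worked_example_tables()["em_oracle_n10"]
        f = em_haplotype_freqs(counts)
        g, _ = grid_oracle_loglik(counts, step=1e-6)
        assert f.rho_AB == pytest.approx(g, abs=1e-4)

    def test_em_beats_grid_oracle_on_exhaustive_small_tables(self):
        """Every 3x3 table with n <= 6: EM log-likelihood >= grid maximum - 1e-6.

        The oracle is an independent profile of the multinomial genotype
        likelihood over the admissible rho_AB range; the full n <= 8
        enumeration runs in the acceptance suite.
        """
        from oracle_utils import exhaustive_em_oracle_check

        n_tables, em_ll, oracle_ll, saddle = exhaustive_em_oracle_check(max_n=6)
        assert n_tables > 2000
        # phase-free double-het-only tables are deliberately reported at the
        # linkage-equilibrium stationary point (D = 0), not the boundary MLE
        assert np.all(em_ll[~saddle] >= oracle_ll[~saddle] - 1e-6)

    def test_monomorphic_or_tiny_tables_rejected(self):
        mono = np.zeros((3, 3), int)
        mono[2, 2] = 5
        with pytest.raises(UndefinedLDError):
            em_haplotype_freqs(mono)
        single = np.zeros((3, 3), int)
        single[1, 1] = 1
        with pytest.raises(UndefinedLDError):
            em_haplotype_freqs(single)

    def test_frequencies_sum_to_one_and_margins_consistent(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t = rng.multinomial(30, np.full(9, 1 / 9)).reshape(3, 3)
            try:
                f = em_haplotype_freqs(t)
            except UndefinedLDError:
                continue
            total = f.rho_AB + f.rho_Ab + f.rho_aB + f.rho_ab
            assert total == pytest.approx(1.0, abs=1e-9)
            assert f.rho_AB + f.rho_Ab == pytest.approx(f.rho_A, abs=1e-9)
            assert f.rho_AB + f.rho_aB == pytest.approx(f.rho_B, abs=1e-9)
            lo = max(0.0, f.rho_A + f.rho_B - 1.0)
            hi = min(f.rho_A, f.rho_B)
            assert lo - 1e-12 <= f.rho_AB <= hi + 1e-12


class TestLdFromFreqs:
    def _freqs(self, pAB, pA, pB):
        return HaplotypeFreqs(pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB,
                              pA, pB, 0, True)

    def test_equilibrium_gives_zero_ld(self):
        e = ld_from_freqs(self._freqs(0.3 * 0.6, 0.3, 0.6))
        assert e.D == pytest.approx(0.0, abs=1e-15)
        assert e.dprime_abs == 0.0
        assert e.r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_positive_d(self):
        e = ld_from_freqs(self._freqs(0.35, 0.6, 0.5))
        assert e.D == pytest.approx(0.05)
        assert e.D_max == pytest.approx(0.20)
        assert e.dprime_abs == pytest.approx(0.25)
        assert e.r2 == pytest.approx(0.0025 / 0.06)

    def test_missing_haplotype_forces_complete_dprime(self):
        # rho_Ab = 0: |D'| = 1
        e = ld_from_freqs(self._freqs(0.3, 0.3, 0.7))
        assert e.dprime_abs == pytest.approx(1.0)

    def test_fixed_margin_rejected(self):
        with pytest.raises(UndefinedLDError):
            ld_from_freqs(self._freqs(0.5, 1.0, 0.5))

    @settings(max_examples=300, derandomize=True)
    @given(
        pA=st.floats(0.01, 0.99),
        pB=st.floats(0.01, 0.99),
        s=st.floats(0.0, 1.0),
    )
    def test_r2_bounded_by_dprime(self, pA, pB, s):
        """0 <= r^2 <= |D'| <= 1 across the whole admissible frequency space."""
        lo = max(0.0, pA + pB - 1.0)
        hi = min(pA, pB)
        pAB = lo + s * (hi - lo)
        e = ld_from_freqs(self._freqs(pAB, pA, pB))
        assert 0.0 <= e.r2 <= e.dprime_abs + 1e-12
        assert e.dprime_abs <= 1.0 + 1e-12

    def test_symmetry_under_marker_swap_and_allele_relabel(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            t = rng.multinomial(60, np.full(9, 1 / 9)).reshape(3, 3)
            try:
                e = ld_from_freqs(em_haplotype_freqs(t))
                e_swap = ld_from_freqs(em_haplotype_freqs(t.T))
                e_flip = ld_from_freqs(em_haplotype_freqs(t[::-1, :]))
            except UndefinedLDError:
                continue
            assert e_swap.dprime_abs == pytest.approx(e.dprime_abs, abs=1e-6)
            assert e_swap.r2 == pytest.approx(e.r2, abs=1e-6)
            assert e_flip.dprime_abs == pytest.approx(e.dprime_abs, abs=1e-6)
            assert e_flip.r2 == pytest.approx(e.r2, abs=1e-6)


class TestDprimeConfidenceInterval:
    def test_overwhelming_complete_ld_concentrates_near_one(self):
        lo, hi = dprime_confidence_interval(worked_example_tables()["complete_ld_n100"])
        assert lo > 0.95  # exact 5% quantile of the profile mass is 0.9703
        assert hi == pytest.approx(1.0)

    def test_independent_markers_exclude_high_dprime(self):
        # expected counts at linkage equilibrium, p = q = 0.5, n = 500
        counts = np.array([[31, 63, 31], [63, 124, 63], [31, 63, 31]])
        lo, hi = dprime_confidence_interval(counts)
        assert hi < 0.90

    def test_sparse_table_gives_wide_interval(self):
        t = np.zeros((3, 3), int)
        t[2, 2] = 1
        t[0, 0] = 1
        lo, hi = dprime_confidence_interval(t)
        assert lo < 0.5
        assert hi > 0.95

    def test_interval_ordered_and_in_unit_range(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            t = rng.multinomial(40, np.full(9, 1 / 9)).reshape(3, 3)
            try:
                lo, hi = dprime_confidence_interval(t)
            except UndefinedLDError:
                continue
            assert 0.0 <= lo <= hi <= 1.0


class TestPairwiseLD:
    def _panel(self, n_markers, n_ind=40, seed=2, chroms=None):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.5, size=(n_ind, n_markers)).astype(np.int8)
        chroms = chroms or ["1"] * n_markers
        markers = make_marker_map(
            chroms, [f"m{j}" for j in range(n_markers)],
            [100 * (sum(1 for c in chroms[: j + 1] if c == chroms[j])) for j in range(n_markers)],
        )
        return GenotypeMatrix(d, [f"s{i}" for i in range(n_ind)], markers)

    def test_pair_counts_by_mode(self):
        gm = self._panel(7)
        assert len(pairwise_ld(gm, "adjacent")) == 6
        assert len(pairwise_ld(gm, "all")) == 7 * 6 // 2

    def test_pairs_restricted_to_same_chromosome(self):
        gm = self._panel(6, chroms=["1", "1", "1", "2", "2", "2"])
        est = pairwise_ld(gm, "all")
        assert len(est) == 2 * 3
        assert set(est["chrom"]) == {"1", "2"}

    def test_monomorphic_pair_skipped_and_counted(self):
        gm = self._panel(3)
        d = gm.dosages.copy()
        d[:, 1] = 2  # monomorphic after missingness
        gm2 = GenotypeMatrix(d, gm.samples, gm.markers)
        est = pairwise_ld(gm2, "adjacent")
        assert len(est) == 0  # both adjacent pairs touch the monomorphic marker
        assert est.attrs["n_skipped"] == 2

    def test_batch_matches_scalar_em(self):
        gm = self._panel(12, n_ind=50, seed=4)
        gm.dosages[gm.dosages == 0] = np.where(
            np.random.default_rng(0).random((gm.dosages == 0).sum()) < 0.1, MISSING, 0
        ).astype(np.int8)
        est = pairwise_ld(gm, "all")
        pos = {m: k for k, m in enumerate(gm.markers["id"])}
        for row in est.sample(10, random_state=1).itertuples():
            counts = two_locus_counts(
                gm.dosages[:, pos[row.id1]], gm.dosages[:, pos[row.id2]]
            )
            e = ld_from_freqs(em_haplotype_freqs(counts))
            assert row.r2 == pytest.approx(e.r2, abs=1e-9)
            assert row.Dprime_abs == pytest.approx(e.dprime_abs, abs=1e-9)

    def test_phase_known_consistency_on_truth_haplotypes(self, wf_dataset):
        """EM r^2 tracks the direct haplotype-count r^2 on simulated truth."""
        gm = wf_dataset.genotypes
        H = wf_dataset.truth["haplotypes"][0]
        est = pairwise_ld(gm, "adjacent")
        est = est[est["chrom"] == "1"].reset_index(drop=True)
        pos = {m: k for k, m in enumerate(gm.markers["id"])}
        checked = 0
        for row in est.itertuples():
            j1, j2 = pos[row.id1], pos[row.id2]
            h1, h2 = H[:, j1].astype(float), H[:, j2].astype(float)
            if h1.std() == 0 or h2.std() == 0:
                continue
            r2_true = np.corrcoef(h1, h2)[0, 1] ** 2
            assert row.r2 == pytest.approx(r2_true, abs=0.05)
            checked += 1
        assert checked > 20
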