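import numpy as np
import pandas as pd
import pytest

from ldscape.ne_estimation import (
    NeConfig,
    d2_f_correlation,
    harmonic_mean,
    hill_robertson_expected_d2,
    ne_from_bin,
    ne_trajectory,
    physical_to_genetic,
    sved_expected_r2,
    sved_recursion_step,
)


class TestClosedForms:
    def test_one_mb_is_one_centimorgan(self):
        assert physical_to_genetic(1_000_000) == pytest.approx(0.01)
        assert physical_to_genetic(0) == 0.0
        assert physical_to_genetic(150_000) == pytest.approx(0.0015)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            physical_to_genetic(-1)

    def test_sved_expectation(self):
        assert sved_expected_r2(100, 0.0) == 1.0
        assert sved_expected_r2(96, 0.0025) == pytest.approx(1 / 1.96)
        c = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        vals = sved_expected_r2(200, c)
        assert np.all(np.diff(vals) < 0)  # monotone decreasing in c

    def test_hill_robertson_d2_vanishes_at_f_extremes(self):
        assert hill_robertson_expected_d2(0.3, 0.6, 0.0) == pytest.approx(0.0)
        assert hill_robertson_expected_d2(0.3, 0.6, 1.0) == pytest.approx(0.0)

    def test_hill_robertson_d2_hand_value(self):
        assert hill_robertson_expected_d2(0.5, 0.5, 0.5) == pytest.approx(
            0.0098307, abs=1e-6
        )

    def test_recursion_step_hand_values(self):
        assert sved_recursion_step(0.0, 0.1, 100) == 0.0
        assert sved_recursion_step(1.0, 0.5, 50) == pytest.approx(0.495)
        assert sved_recursion_step(1.0, 0.0, 1e12) == pytest.approx(1.0, abs=1e-9)

    def test_recursion_step_domain(self):
        with pytest.raises(ValueError):
            sved_recursion_step(1.0, 0.6, 100)
        with pytest.raises(ValueError):
            sved_recursion_step(1.0, 0.1, 0.4)


class TestNeFromBin:
    def test_published_style_arithmetic(self):
        """r2 = 0.1033 at 0.15 cM, alpha = 1, no correction -> Ne ~ 1446.7."""
        ne, ok = ne_from_bin(0.1033, 0.0015, alpha=1.0, correction=False)
        assert ok
        assert ne == pytest.approx(1446.7, abs=0.5)

    def test_exact_inversion_of_sved(self):
        r2 = sved_expected_r2(100, 0.001)
        ne, ok = ne_from_bin(r2, 0.001, alpha=1.0, correction=False)
        assert ne == pytest.approx(100.0)

    def test_round_trip_over_parameter_grid(self):
        """Sved forward then inverse recovers Ne to 1e-6 relative error."""
        for ne_true in (50, 500, 5000):
            for c in (1e-4, 1e-3, 1e-2):
                r2 = sved_expected_r2(ne_true, c)
                ne, ok = ne_from_bin(r2, c, alpha=1.0, correction=False)
                assert ok
                assert ne == pytest.approx(ne_true, rel=1e-6)

    def test_nonpositive_adjusted_r2_flagged_unusable(self):
        ne, ok = ne_from_bin(0.005, 0.001, alpha=1.0, n_samples=100, correction=True)
        assert not ok and np.isnan(ne)

    def test_sample_size_correction_subtracts_reciprocal_n(self):
        ne_raw, _ = ne_from_bin(0.2, 0.001, alpha=1.0, correction=False)
        ne_adj, _ = ne_from_bin(0.2 + 0.01, 0.001, alpha=1.0, n_samples=100,
                                correction=True)
        assert ne_adj == pytest.approx(ne_raw)


def _estimates_from_bins(bins, n=100):
    """bins: (chrom, dist_mb, r2, n_pairs) -> flat estimate rows."""
    rows = []
    for chrom, dist_mb, r2, npairs in bins:
        for _ in range(npairs):
            rows.append((chrom, int(dist_mb * 1e6), r2))
    df = pd.DataFrame(rows, columns=["chrom", "dist_bp", "r2"])
    df["Dprime_abs"] = df["r2"]
    df["n"] = n
    return df


class TestNeTrajectory:
    def test_generation_mapping(self):
        est = _estimates_from_bins([("1", 1.6, 0.3, 60)])
        traj = ne_trajectory(est, NeConfig(alpha=1.0, sample_size_correction=False))
        # c = 0.016 -> t = 1/(2c) = 31.25 -> rounds to 31
        assert traj.table.loc[0, "t"] == 31
        assert traj.table.loc[0, "t_exact"] == pytest.approx(31.25)

    def test_t_sixteen_at_c_point03125(self):
        est = _estimates_from_bins([("1", 3.125, 0.3, 60)])
        cfg = NeConfig(alpha=1.0, sample_size_correction=False,
                       bin_edges_mb=(3.0, 3.2))
        traj = ne_trajectory(est, cfg)
        assert traj.table.loc[0, "t"] == 16

    def test_harmonic_mean_per_chromosome(self):
        assert harmonic_mean([100, 300]) == pytest.approx(150.0)
        r2_a = sved_expected_r2(100, 0.001)
        r2_b = sved_expected_r2(300, 0.002)
        est = _estimates_from_bins([("1", 0.1, r2_a, 60), ("1", 0.2, r2_b, 60)])
        traj = ne_trajectory(est, NeConfig(alpha=1.0, sample_size_correction=False,
                                           bin_edges_mb=(0.05, 0.15, 0.25)))
        row = traj.per_chromosome.set_index("chrom").loc["1"]
        assert row["ne_harmonic"] == pytest.approx(150.0, rel=1e-6)

    def test_recent_ne_is_largest_c_usable_bin(self):
        r2_near = sved_expected_r2(500, 0.001)
        r2_far = sved_expected_r2(120, 0.01)
        est = _estimates_from_bins([("1", 0.1, r2_near, 60), ("1", 1.0, r2_far, 60)])
        traj = ne_trajectory(est, NeConfig(alpha=1.0, sample_size_correction=False,
                                           bin_edges_mb=(0.05, 0.15, 0.95, 1.05)))
        assert traj.recent_ne == pytest.approx(120.0, rel=1e-6)
        assert traj.recent_t == 50  # 1/(2 * 0.01)

    def test_smaller_c_maps_to_strictly_larger_exact_t(self):
        est = _estimates_from_bins(
            [("1", d, 0.4, 60) for d in (0.1, 0.5, 1.0, 2.0, 3.9)]
        )
        traj = ne_trajectory(est, NeConfig(alpha=1.0, sample_size_correction=False))
        tab = traj.table.sort_values("c", ascending=False)
        assert np.all(np.diff(tab["t_exact"].to_numpy()) > 0)

    def test_sparse_bins_dropped_by_min_pairs(self):
        est = _estimates_from_bins([("1", 0.1, 0.4, 10), ("1", 0.2, 0.4, 60)])
        traj = ne_trajectory(est, NeConfig(alpha=1.0, sample_size_correction=False))
        usable = traj.table[traj.table["usable"]]
        assert len(usable) == 1
        assert usable.iloc[0]["n_pairs"] == 60

    def test_no_usable_bins_is_error(self):
        est = _estimates_from_bins([("1", 0.1, 0.9, 5)])
        with pytest.raises(ValueError, match="usable"):
            ne_trajectory(est, NeConfig(alpha=1.0))

    def test_alpha_restricted_to_allowed_set(self):
        with pytest.raises(ValueError):
            NeConfig(alpha=1.5)


class TestD2FCorrelation:
    def _panel(self, n_chrom=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        f = {}
        for c in range(1, n_chrom + 1):
            chrom = str(c)
            f[chrom] = rng.uniform(0.0, 0.3)
            d_vals = rng.normal(0.05 * f[chrom] + 0.01, 0.002, size=30)
            for d in d_vals:
                rows.append((chrom, 100_000, d))
        est = pd.DataFrame(rows, columns=["chrom", "dist_bp", "D"])
        return est, pd.Series(f)

    def test_matches_independent_computation(self):
        est, f = self._panel()
        got = d2_f_correlation(est, f)
        pred = np.array(
            [hill_robertson_expected_d2(0.5, 0.5, f[c]) for c in f.index]
        )
        obs = est.assign(d2=est["D"] ** 2).groupby("chrom")["d2"].mean()[f.index]
        expected = np.corrcoef(pred, obs)[0, 1]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_perfectly_aligned_series_correlate_to_one(self):
        f = pd.Series({"1": 0.1, "2": 0.2, "3": 0.3})
        rows = []
        for chrom, fv in f.items():
            d2 = hill_robertson_expected_d2(0.5, 0.5, fv)
            rows.append((chrom, 100_000, np.sqrt(d2)))
        est = pd.DataFrame(rows, columns=["chrom", "dist_bp", "D"])
        assert d2_f_correlation(est, f) == pytest.approx(1.0)

    def test_constant_predictor_flagged_undefined(self):
        f = pd.Series({"1": 0.1, "2": 0.1, "3": 0.1})
        est = pd.DataFrame(
            [("1", 1, 0.01), ("2", 1, 0.02), ("3", 1, 0.03)],
            columns=["chrom", "dist_bp", "D"],
        )
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(d2_f_correlation(est, f))

    def test_fewer_than_three_chromosomes_rejected(self):
        f = pd.Series({"1": 0.1, "2": 0.2})
        est = pd.DataFrame([("1", 1, 0.01), ("2", 1, 0.02)],
                           columns=["chrom", "dist_bp", "D"])
        with pytest.raises(ValueError):
            d2_f_correlation(est, f)
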