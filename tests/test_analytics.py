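import math

import numpy as np
import pytest

import decoysim as ds
from decoysim.bursts import BurstDistribution


class TestNoDecoyForms:
    @pytest.mark.parametrize("kx, bmean, gf, expected", [
        (10.0, 20.0, 1.0, 200.0),
        (0.75, 20.0, 1.0, 15.0),
        (0.0, 20.0, 1.0, 0.0),
    ])
    def test_mean(self, kx, bmean, gf, expected):
        assert ds.no_decoy_mean(kx, bmean, gf) == pytest.approx(expected)

    def test_mean_rejects_nonpositive_decay(self):
        with pytest.raises(ds.InvalidParameterError):
            ds.no_decoy_mean(10, 20, 0.0)

    def test_fano_poisson_limit_for_single_molecule_bursts(self):
        assert ds.no_decoy_fano(BurstDistribution.degenerate(1)) == 1.0

    def test_fano_equals_mean_burst_for_geometric(self, geometric20):
        assert ds.no_decoy_fano(geometric20) == pytest.approx(20.0, rel=1e-12)

    def test_fano_explicit(self):
        d = BurstDistribution.explicit({0: 0.5, 2: 0.5})
        assert ds.no_decoy_fano(d) == pytest.approx(1.5)


class TestFastBindingMean:
    def test_beta_zero_mean_is_independent_of_decoys(self):
        for n in (0, 10, 1e3, 1e6):
            for kd in (0.1, 1, 100):
                sol = ds.mean_with_decoys(200.0, n, kd, 0.0)
                assert sol.x_free == pytest.approx(200.0, rel=1e-12)

    def test_fig6_low_affinity_mean_rounds_to_15(self):
        sol = ds.mean_with_decoys(200.0, 1400, 100.0, 1.0)
        assert round(sol.x_free) == 15
        assert sol.x_free == pytest.approx(15.207, abs=5e-3)

    def test_quadratic_root_value(self):
        sol = ds.mean_with_decoys(200.0, 100, 1.0, 1.0)
        assert sol.x_free == pytest.approx((99 + math.sqrt(10601)) / 2, rel=1e-12)
        assert sol.x_bound == pytest.approx(
            100 * sol.x_free / (1 + sol.x_free), rel=1e-12)

    def test_bound_fraction_consistency(self):
        sol = ds.mean_with_decoys(200.0, 500, 10.0, 2.0)
        assert 0 <= sol.bound_fraction <= 1
        assert sol.bound_fraction == pytest.approx(
            sol.x_free / (10.0 + sol.x_free), abs=1e-9)
        assert sol.x_bound <= 500

    def test_mean_strictly_decreasing_in_N_when_beta_positive(self):
        grid = np.unique(np.round(np.geomspace(1, 1e4, 40)))
        values = [ds.mean_with_decoys(200.0, n, 1.0, 1.0).x_free
                  for n in np.concatenate(([0.0], grid))]
        assert np.all(np.diff(values) < 0)

    def test_kd_zero_rejected(self):
        with pytest.raises(ds.InvalidParameterError):
            ds.mean_with_decoys(200.0, 10, 0.0, 1.0)


class TestMeanApproximations:
    def test_small_N_trivial_limits(self):
        assert ds.mean_small_N_approx(200, 0, 1, 1) == 200
        assert ds.mean_small_N_approx(200, 50, 1, 0.0) == 200

    def test_small_N_value_and_accuracy(self):
        approx = ds.mean_small_N_approx(200.0, 10, 1.0, 1.0)
        assert approx == pytest.approx(200 - 10 * 200 / 201, rel=1e-12)
        exact = ds.mean_with_decoys(200.0, 10, 1.0, 1.0).x_free
        assert abs(approx - exact) / exact < 0.01

    @pytest.mark.parametrize("kd", [1.0, 10.0, 100.0])
    def test_small_N_within_1pc_in_stated_limit(self, kd):
        # N <= 0.02 * x_f0 / beta
        exact = ds.mean_with_decoys(200.0, 4, kd, 1.0).x_free
        approx = ds.mean_small_N_approx(200.0, 4, kd, 1.0)
        assert abs(approx - exact) / exact < 0.01

    def test_large_N_values(self):
        assert ds.mean_large_N_approx(200.0, 1e5, 1.0, 1.0) == pytest.approx(2e-3)
        assert ds.mean_large_N_approx(200.0, 1e4, 100.0, 1.0) == pytest.approx(2.0)

    def test_large_N_one_over_N_scaling(self):
        a = ds.mean_large_N_approx(200.0, 1e4, 1.0, 1.0)
        b = ds.mean_large_N_approx(200.0, 2e4, 1.0, 1.0)
        assert a == pytest.approx(2 * b, rel=1e-12)

    @pytest.mark.parametrize("kd", [1.0, 10.0, 100.0])
    def test_large_N_within_1pc_deep_in_limit(self, kd):
        # relative error of the 1/N form decays like x_f0/(N beta); 1% needs
        # N >= 100 * x_f0 / beta
        n = 100 * 200.0
        exact = ds.mean_with_decoys(200.0, n, kd, 1.0).x_free
        approx = ds.mean_large_N_approx(200.0, n, kd, 1.0)
        assert abs(approx - exact) / exact < 0.01

    def test_large_N_rejects_beta_zero(self):
        with pytest.raises(ds.InvalidParameterError):
            ds.mean_large_N_approx(200.0, 100, 1.0, 0.0)


class TestFanoWithDecoys:
    def test_no_decoys_recovers_reference(self):
        assert ds.fano_with_decoys(200.0, 20.0, 0, 1.0, 1.0) == 20.0

    def test_chained_value(self):
        assert ds.fano_with_decoys(200.0, 20.0, 100, 1.0, 1.0) == pytest.approx(
            38.87, abs=0.01)

    def test_poisson_limit_at_huge_N(self):
        for kd in (0.1, 1.0, 100.0):
            for beta in (0.5, 1.0, 5.0):
                f = ds.fano_with_decoys(200.0, 20.0, 1e8, kd, beta)
                assert 1.0 <= f <= 1.0 + 1e-3

    def test_small_N_limit_approaches_reference(self):
        assert ds.fano_with_decoys(200.0, 20.0, 1e-9, 1.0, 1.0) == pytest.approx(
            20.0, rel=1e-6)

    def test_beta0_equals_dedicated_formula(self):
        for kd in (0.1, 1.0, 10.0, 100.0, 1e3):
            for n in (0, 1, 10, 100, 1e4):
                full = ds.fano_with_decoys(200.0, 20.0, n, kd, 0.0)
                simple = ds.fano_beta0(200.0, 20.0, n, kd)
                assert full == pytest.approx(simple, abs=1e-12, rel=1e-12)

    def test_beta0_value_and_monotonicity(self):
        assert ds.fano_beta0(200.0, 20.0, 300, 100.0) == pytest.approx(15.25)
        grid = np.geomspace(1, 1e6, 60)
        values = [ds.fano_beta0(200.0, 20.0, n, 1.0) for n in grid]
        assert np.all(np.diff(values) < 0)


class TestAmplificationThresholds:
    def test_threshold_value(self):
        assert ds.kd_threshold(20.0, 200.0, 1.0) == pytest.approx(4000 / 19)

    def test_threshold_vanishes_at_beta_zero(self):
        assert ds.kd_threshold(20.0, 200.0, 0.0) == 0.0

    def test_threshold_large_burst_limit(self):
        assert ds.kd_threshold(1e6, 200.0, 1.0) == pytest.approx(200.0, rel=1e-5)

    def test_threshold_requires_bursty_noise(self):
        with pytest.raises(ds.InvalidParameterError):
            ds.kd_threshold(1.0, 200.0, 1.0)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 5.0])
    def test_initial_slope_sign_matches_threshold(self, beta):
        """dF/dN at N -> 0+ is positive exactly when k_d < k_d^th."""
        kth = ds.kd_threshold(20.0, 200.0, beta)
        h = 1e-3
        for kd in np.concatenate((np.linspace(0.2, 0.98, 5) * kth,
                                  np.linspace(1.02, 3.0, 5) * kth)):
            slope = (ds.fano_with_decoys(200.0, 20.0, 2 * h, kd, beta)
                     - ds.fano_with_decoys(200.0, 20.0, h, kd, beta)) / h
            assert (slope > 0) == (kd < kth)

    def test_occupancy_threshold(self):
        assert ds.occupancy_threshold(1.0) == 0.5
        assert ds.occupancy_threshold(0.0) == 1.0
        assert ds.occupancy_threshold(1e9) == pytest.approx(0.0, abs=1e-8)


class TestRequiredKx:
    def test_no_decoy_inversion(self):
        assert ds.required_kx_for_mean(20.0, 0, 1.0, 1.0, 20.0, 1.0) == \
            pytest.approx(1.0)

    def test_worked_inversion(self):
        kx = ds.required_kx_for_mean(20.0, 100, 10.0, 5.0, 20.0, 1.0)
        assert kx == pytest.approx(17.6667, abs=1e-3)

    def test_beta0_is_independent_of_N(self):
        values = {ds.required_kx_for_mean(20.0, n, 1.0, 0.0, 20.0, 1.0)
                  for n in (0, 10, 1e4)}
        assert len(values) == 1

    @pytest.mark.parametrize("n, kd, beta", [
        (100, 10.0, 5.0), (245, 1.0, 1.0), (1400, 100.0, 1.0)])
    def test_round_trip_recovers_target(self, n, kd, beta):
        kx = ds.required_kx_for_mean(20.0, n, kd, beta, 20.0, 1.0)
        x_f0 = ds.no_decoy_mean(kx, 20.0, 1.0)
        assert ds.mean_with_decoys(x_f0, n, kd, beta).x_free == pytest.approx(
            20.0, abs=1e-9)


class TestTargetFano:
    def test_no_decoy_reduction(self):
        full = ds.target_fano(200.0, 20.0, 0, 1.0, 1.0, 10.0, 1.0, 1.0, 1.0, 1.0)
        ref = ds.target_fano_no_decoy(20.0, 10.0, 1.0, 1.0, 1.0, 1.0)
        assert full == pytest.approx(ref, abs=1e-12)
        assert ref == pytest.approx(101.0)

    def test_poisson_upstream(self):
        assert ds.target_fano_no_decoy(1.0, 10.0, 1.0, 1.0, 1.0, 1.0) == \
            pytest.approx(6.0)

    def test_weak_activation_leaves_burst_term(self):
        assert ds.target_fano_no_decoy(20.0, 0.0, 1.0, 1.0, 1.0, 1.0) == 1.0

    def test_many_protected_decoys_remove_propagated_term(self):
        # the propagated term decays like 1/(N f (1-f)); check the decay and
        # the burst-term-only limit
        values = [ds.target_fano(200.0, 20.0, n, 1.0, 0.0,
                                 10.0, 1.0, 1.0, 1.0, 1.0)
                  for n in (1e4, 1e6, 1e8, 1e10)]
        assert np.all(np.diff(values) < 0)
        assert values[-1] == pytest.approx(1.0, abs=1e-3)
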