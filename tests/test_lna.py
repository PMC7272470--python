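import numpy as np
import pytest

import decoysim as ds
from decoysim.bursts import BurstDistribution


def single_decoy_model(geometric20, n, kd, beta, kb, kx=10.0):
    return ds.TFDecoyModel(
        k_x=kx, burst=geometric20, gamma_f=1.0, gamma_b=beta,
        decoys=(ds.DecoySpecies.from_kd(n, kd, kb),))


class TestFixedPoint:
    def test_no_decoy(self, fig2_model):
        np.testing.assert_allclose(
            ds.deterministic_fixed_point(fig2_model), [200.0])

    def test_fast_binding_limit_matches_quadratic_root(self, geometric20):
        model = single_decoy_model(geometric20, 100, 10.0, 1.0, kb=1e6)
        fp = ds.deterministic_fixed_point(model)
        sol = ds.mean_with_decoys(200.0, 100, 10.0, 1.0)
        assert fp[0] == pytest.approx(sol.x_free, abs=1e-6)
        assert fp[1] == pytest.approx(sol.x_bound, rel=1e-6)

    def test_fig6_high_affinity_deterministic_value(self, geometric20):
        # the deterministic balance sits near 4 molecules; the stochastic
        # mean of the same model is much larger (a beyond-LNA effect,
        # exercised in the simulation tests).  At finite k_b the balance is
        # the fast-binding quadratic with k_d replaced by k_d + gamma_b/k_b.
        model = single_decoy_model(geometric20, 245, 1.0, 1.0, kb=50.0)
        fp = ds.deterministic_fixed_point(model)
        kd_eff = 1.0 + 1.0 / 50.0
        a = 200.0 - 245.0 - kd_eff
        expected = 0.5 * (a + np.sqrt(a * a + 4 * kd_eff * 200.0))
        assert expected == pytest.approx(4.07, abs=0.01)   # near 4 molecules
        assert fp[0] == pytest.approx(expected, rel=1e-9)

    def test_flux_balance_residual(self, geometric20):
        model = single_decoy_model(geometric20, 500, 5.0, 2.0, kb=50.0)
        fp = ds.deterministic_fixed_point(model)
        drain = model.gamma_f * fp[0] + model.gamma_b * fp[1]
        assert drain == pytest.approx(model.k_x * model.burst.mean, rel=1e-10)


class TestLinearizedSystem:
    def test_no_decoy_matrices(self, fig2_model):
        system = ds.build_lna_system(fig2_model)
        np.testing.assert_allclose(system.A, [[-1.0]])
        # burst second moment 780 * k_x + gamma_f * 200
        np.testing.assert_allclose(system.D, [[10 * 780 + 200.0]])

    def test_no_decoy_variance_recovers_burst_fano(self, fig2_model):
        system, sigma = ds.lna_moments(fig2_model)
        assert sigma[0, 0] / system.fixed_point[0] == pytest.approx(20.0,
                                                                    abs=1e-9)

    def test_binding_channel_stoichiometry(self, geometric20):
        model = single_decoy_model(geometric20, 100, 10.0, 1.0, kb=50.0)
        system = ds.build_lna_system(model)
        x_f, x_b = system.fixed_point
        d = model.decoys[0]
        bind = d.k_b * x_f * (d.N - x_b)
        unbind = d.k_u * x_b
        bdeg = model.gamma_b * x_b
        assert system.D[0, 1] == pytest.approx(-(bind + unbind))
        assert system.D[1, 1] == pytest.approx(bind + unbind + bdeg)
        assert system.A[1, 0] == pytest.approx(d.k_b * (d.N - x_b))

    def test_diffusion_symmetric_psd_and_drift_stable(self, geometric20):
        model = single_decoy_model(geometric20, 300, 2.0, 0.5, kb=200.0)
        system = ds.build_lna_system(model)
        np.testing.assert_allclose(system.D, system.D.T)
        assert np.min(np.linalg.eigvalsh(system.D)) >= -1e-9
        assert np.max(np.linalg.eigvals(system.A).real) < 0


class TestSteadyCovariance:
    def test_one_species_closed_form(self, fig2_model):
        system, sigma = ds.lna_moments(fig2_model)
        assert sigma[0, 0] == pytest.approx(system.D[0, 0] / 2.0, rel=1e-12)

    def test_fast_binding_fano_matches_closed_form(self, geometric20):
        model = single_decoy_model(geometric20, 100, 10.0, 1.0, kb=1e5)
        fano = ds.lna_fano(model)["x_f"]
        assert fano == pytest.approx(
            ds.fano_with_decoys(200.0, 20.0, 100, 10.0, 1.0), rel=1e-3)

    def test_convergence_to_fast_binding_is_monotone(self, geometric20):
        target = ds.fano_with_decoys(200.0, 20.0, 100, 10.0, 1.0)
        errors = []
        for kb in (1e2, 1e3, 1e4):
            model = single_decoy_model(geometric20, 100, 10.0, 1.0, kb=kb)
            errors.append(abs(ds.lna_fano(model)["x_f"] - target))
        assert errors[0] > errors[1] > errors[2]

    def test_correlations_bounded(self, geometric20):
        model = ds.TFDecoyModel(
            k_x=10.0, burst=geometric20, gamma_f=1.0, gamma_b=1.0,
            decoys=(ds.DecoySpecies.from_kd(200, 1.0, 1000.0),
                    ds.DecoySpecies.from_kd(500, 100.0, 1000.0)),
            target=ds.TargetGene(k_y=10.0,
                                 burst=BurstDistribution.degenerate(1),
                                 gamma_y=1.0))
        system, sigma = ds.lna_moments(model)
        assert np.all(np.diag(sigma) >= 0)
        corr = sigma / np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.all(np.abs(corr) <= 1 + 1e-9)


class TestMixtures:
    def test_two_identical_decoy_species_merge(self, geometric20):
        merged = single_decoy_model(geometric20, 100, 5.0, 1.0, kb=1000.0)
        split = ds.TFDecoyModel(
            k_x=10.0, burst=geometric20, gamma_f=1.0, gamma_b=1.0,
            decoys=(ds.DecoySpecies.from_kd(60, 5.0, 1000.0),
                    ds.DecoySpecies.from_kd(40, 5.0, 1000.0)))
        f1 = ds.lna_fano(merged)["x_f"]
        f2 = ds.lna_fano(split)["x_f"]
        assert f2 == pytest.approx(f1, abs=1e-6)

    def test_buffering_decoys_mitigate_amplifying_decoys(self, geometric20):
        # strong amplifier alone vs the same plus a large weak-decoy pool
        alone = ds.lna_fano(
            single_decoy_model(geometric20, 200, 1.0, 1.0, kb=1000.0))["x_f"]
        mixed = ds.lna_fano(ds.TFDecoyModel(
            k_x=10.0, burst=geometric20, gamma_f=1.0, gamma_b=1.0,
            decoys=(ds.DecoySpecies.from_kd(200, 1.0, 1000.0),
                    ds.DecoySpecies.from_kd(5000, 100.0, 1000.0))))["x_f"]
        assert mixed < alone


class TestTargetGene:
    def test_no_decoy_target_fano_matches_closed_form(self, geometric20):
        model = ds.TFDecoyModel(
            k_x=10.0, burst=geometric20, gamma_f=1.0, gamma_b=0.0,
            target=ds.TargetGene(k_y=10.0,
                                 burst=BurstDistribution.degenerate(1),
                                 gamma_y=1.0))
        fano = ds.lna_fano(model)["y"]
        assert fano == pytest.approx(101.0, rel=1e-3)


class TestAutocorrelation:
    def test_no_decoy_exponential_decay(self, fig2_model):
        system, sigma = ds.lna_moments(fig2_model)
        taus = np.linspace(0.0, 4.0, 9)
        r = ds.lna_autocorrelation(system, sigma, taus)
        np.testing.assert_allclose(r, np.exp(-taus), atol=1e-10)

    def test_r_zero_is_one(self, geometric20):
        model = single_decoy_model(geometric20, 100, 1.0, 1.0, kb=50.0)
        system, sigma = ds.lna_moments(model)
        assert ds.lna_autocorrelation(system, sigma, np.array([0.0]))[0] == \
            pytest.approx(1.0, abs=1e-12)

    def test_protected_decoys_slow_fluctuations(self, geometric20):
        # beta = 0: the autocorrelation shifts right of exp(-gamma_f tau)
        model = ds.TFDecoyModel(
            k_x=1.0, burst=geometric20, gamma_f=1.0, gamma_b=0.0,
            decoys=(ds.DecoySpecies.from_kd(100, 1.0, 50.0),))
        system, sigma = ds.lna_moments(model)
        taus = np.array([0.5, 1.0, 2.0, 4.0])
        r = ds.lna_autocorrelation(system, sigma, taus)
        assert np.all(r > np.exp(-taus))
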