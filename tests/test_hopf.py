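import numpy as np
import pytest
from scipy import signal as sps, stats

import brainclock as bc
from brainclock.hopf import (
    _normalized_weights,
    _per_region,
    hopf_drift,
    linear_covariance,
)

from conftest import two_node_connectome


def single_node_connectome():
    return bc.StructuralConnectome(np.zeros((1, 1)), np.zeros((1, 3)),
                                   np.array([True]))


class TestLinearSystem:
    def test_single_node_block(self):
        p = bc.HopfParameters(a=0.01, f=10.0, G=0.0)
        A = bc.build_linear_system(single_node_connectome(), p)
        w = 2 * np.pi * 10.0
        assert np.allclose(A, [[0.01, -w], [w, 0.01]])
        eig = np.linalg.eigvals(A)
        assert sorted(np.round(eig.real, 10)) == [0.01, 0.01]
        assert sorted(np.round(np.abs(eig.imag), 6)) == pytest.approx([w, w])

    def test_matches_finite_difference_jacobian_of_drift(self, connectome16):
        p = bc.HopfParameters(a=0.01, f=10.0, G=0.7)
        A = bc.build_linear_system(connectome16, p)
        M = _normalized_weights(connectome16)
        a = _per_region(p.a, 16)
        w = 2 * np.pi * _per_region(p.f, 16)
        eps = 1e-7
        J = np.zeros((32, 32))
        for j in range(32):
            e = np.zeros(32)
            e[j] = eps
            J[:, j] = (hopf_drift(e, M, a, w, p.G)
                       - hopf_drift(-e, M, a, w, p.G)) / (2 * eps)
        assert np.abs(J - A).max() < 1e-6


class TestStability:
    def test_single_node_margin_is_a(self):
        p = bc.HopfParameters(a=0.01, f=10.0, G=0.0)
        A = bc.build_linear_system(single_node_connectome(), p)
        assert bc.stability_margin(A) == pytest.approx(0.01)
        A = bc.build_linear_system(single_node_connectome(),
                                   bc.HopfParameters(a=-1.0, f=10.0, G=0.0))
        assert bc.stability_margin(A) == pytest.approx(-1.0)

    def test_two_node_spectrum_has_modes_a_and_a_minus_2gm(self):
        """Diffusive coupling leaves the homogeneous mode at rate a for any
        G (zero Laplacian eigenvalue); the antisymmetric mode decays at
        a - 2*G*M12. The margin therefore equals a, never G-dependent."""
        a, G = 0.01, 2.0
        A = bc.build_linear_system(two_node_connectome(),
                                   bc.HopfParameters(a=a, f=10.0, G=G))
        reals = np.sort(np.unique(np.round(np.linalg.eigvals(A).real, 9)))
        assert reals == pytest.approx([a - 2 * G * 1.0, a])  # normalized M12 = 1
        assert bc.stability_margin(A) == pytest.approx(a)


class TestLinearFC:
    def test_two_node_closed_form_one_third(self):
        """Lyapunov solution in the (sum, difference) eigenbasis: mode
        variances beta^2/2|a| and beta^2/2|a - 2G*M12| give correlation
        (s - d) / (s + d) = 1/3 at a=-1, G*M12=0.5."""
        p = bc.HopfParameters(a=-1.0, f=10.0, beta=0.1, G=0.5)
        fc = bc.linear_fc(two_node_connectome(), p)
        assert fc.values[0, 1] == pytest.approx(1 / 3, abs=1e-9)

    def test_uncoupled_stable_system_has_identity_fc(self, connectome16):
        fc = bc.linear_fc(connectome16, bc.HopfParameters(a=-0.5, G=0.0))
        assert np.allclose(fc.values, np.eye(16), atol=1e-9)

    def test_unstable_linearization_raises(self, connectome16):
        with pytest.raises(bc.UnstableLinearizationError, match="invalid"):
            bc.linear_fc(connectome16, bc.HopfParameters(a=0.01, G=1.0))

    def test_spectral_fast_path_matches_lyapunov_solver(self, connectome16):
        """Uniform parameters use an eigen decomposition; per-region values
        fall back to the 2n-dimensional Lyapunov solve. On a uniform system
        nudged infinitesimally they must agree."""
        p_uniform = bc.HopfParameters(a=-0.1, f=10.0, G=0.8)
        a_vec = np.full(16, -0.1)
        a_vec[0] -= 1e-12
        p_general = bc.HopfParameters(a=a_vec, f=10.0, G=0.8)
        fc_fast = bc.linear_fc(connectome16, p_uniform)
        fc_gen = bc.linear_fc(connectome16, p_general)
        assert np.allclose(fc_fast.values, fc_gen.values, atol=1e-6)

    def test_lyapunov_residual_below_threshold(self, connectome16):
        for params in (bc.HopfParameters(a=-0.05, G=1.0),
                       bc.HopfParameters(a=np.linspace(-0.3, -0.05, 16),
                                         G=0.5)):
            cov_x = linear_covariance(connectome16, params)
            # reconstruct the full-state residual through the drift matrix
            A = bc.build_linear_system(connectome16, params)
            n = 16
            full = np.zeros((2 * n, 2 * n))
            full[:n, :n] = cov_x
            full[n:, n:] = cov_x  # rotational symmetry of the stationary law
            resid = A @ full + full @ A.T + params.beta**2 * np.eye(2 * n)
            assert np.abs(resid).max() < 1e-8


class TestSimulate:
    def test_zero_noise_stable_system_stays_at_fixed_point(self):
        p = bc.HopfParameters(a=-0.5, f=10.0, beta=0.0, G=0.0, dt=0.002,
                              duration=5.0, seed=0)
        ts = bc.simulate_hopf(single_node_connectome(), p)
        assert np.allclose(ts.data, 0.0)

    def test_deterministic_given_seed(self):
        p = bc.HopfParameters(a=0.01, f=10.0, beta=0.1, G=0.0, dt=0.002,
                              duration=3.0, seed=5)
        a = bc.simulate_hopf(single_node_connectome(), p)
        b = bc.simulate_hopf(single_node_connectome(), p)
        assert np.array_equal(a.data, b.data)

    def test_supercritical_node_oscillates_at_natural_frequency(self):
        p = bc.HopfParameters(a=0.01, f=10.0, beta=0.1, G=0.0, dt=0.002,
                              duration=60.0, seed=2)
        ts = bc.simulate_hopf(single_node_connectome(), p)
        f, pxx = sps.welch(ts.data[0], fs=ts.sampling_rate, nperseg=4096)
        assert f[np.argmax(pxx)] == pytest.approx(10.0, abs=0.25)

    def test_coarse_time_step_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            bc.simulate_hopf(single_node_connectome(),
                             bc.HopfParameters(f=10.0, dt=0.01))

    def test_coupling_raises_internode_correlation(self):
        c = two_node_connectome()
        r = {}
        for g in (0.0, 2.0):
            p = bc.HopfParameters(a=-0.2, f=10.0, beta=0.1, G=g, dt=0.002,
                                  duration=120.0, seed=7)
            r[g] = bc.compute_fc(bc.simulate_hopf(c, p)).values[0, 1]
        assert r[2.0] > r[0.0]


class TestSSIM:
    def test_self_identity_is_exactly_one(self, rng):
        m = rng.normal(size=(30, 30))
        assert bc.ssim(m, m.copy()) == 1.0

    def test_equal_constant_matrices(self):
        assert bc.ssim(np.full((10, 10), 0.4), np.full((10, 10), 0.4)) == 1.0

    def test_symmetry_and_upper_bound(self, rng):
        a = rng.normal(size=(20, 20))
        b = rng.normal(size=(20, 20))
        assert bc.ssim(a, b) == pytest.approx(bc.ssim(b, a), abs=1e-12)
        assert bc.ssim(a, b) <= 1.0

    def test_matches_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.normal(size=(8, 8))
        b = a + 0.4 * rng.normal(size=(8, 8))
        drange = max(a.max(), b.max()) - min(a.min(), b.min())
        ref = structural_similarity(a, b, win_size=7, data_range=drange,
                                    gaussian_weights=False)
        assert bc.ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            bc.ssim(rng.normal(size=(5, 5)), rng.normal(size=(6, 6)))

    def test_distinct_constant_matrices_score_below_one(self):
        # joint data range is the gap between the two constants
        s = bc.ssim(np.full((10, 10), 0.0), np.full((10, 10), 1.0))
        assert s < 1.0


class TestFitGlobalCoupling:
    def test_noiseless_self_consistency_recovers_grid_value(self, connectome16):
        params = bc.HopfParameters(a=-0.05)
        target = bc.linear_fc(connectome16,
                              bc.HopfParameters(a=-0.05, G=1.5))
        res = bc.fit_global_coupling(target, connectome16, params)
        assert res.g_best == pytest.approx(1.5)
        assert res.ssim_curve[res.stable_mask].max() == pytest.approx(1.0)

    def test_single_element_grid(self, connectome16):
        target = bc.linear_fc(connectome16, bc.HopfParameters(a=-0.05, G=1.0))
        res = bc.fit_global_coupling(target, connectome16,
                                     bc.HopfParameters(a=-0.05), g_grid=[0.7])
        assert res.g_best == 0.7

    def test_no_stable_grid_value_raises(self, connectome16):
        target = bc.linear_fc(connectome16, bc.HopfParameters(a=-0.05, G=1.0))
        with pytest.raises(bc.UnstableLinearizationError):
            bc.fit_global_coupling(target, connectome16,
                                   bc.HopfParameters(a=0.01))

    def test_estimator_protocol_and_monotone_group_recovery(self, connectome16):
        """Cohorts generated at higher coupling must yield higher fitted G."""
        from sklearn.base import clone

        est = bc.GlobalCouplingEstimator(connectome=connectome16, a=-0.05)
        assert clone(est).get_params()["a"] == -0.05
        fits = []
        rng = np.random.default_rng(3)
        from brainclock.cohort import _fisher_noise

        for g_true in (0.6, 1.2, 2.0):
            fc = bc.linear_fc(connectome16, bc.HopfParameters(a=-0.05, G=g_true))
            noisy = bc.ConnectivityMatrix(
                _fisher_noise(fc.values, 0.02, rng), "correlation")
            fits.append(clone(est).fit(noisy).g_best_)
        assert fits[0] < fits[1] < fits[2]
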