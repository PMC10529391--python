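import numpy as np
import pytest

from pahydro import (
    N4SIDConfig,
    NoDynamicsError,
    PASignal,
    SecondOrderParams,
    SignalTooShortError,
    build_hankel,
    estimate_order,
    n4sid_fit,
    orthogonal_project,
    simulate_pa_signal,
)
from pahydro.subspace import controllability, extended_observability, impulse_toeplitz
from pahydro import discretize


class TestBuildHankel:
    def test_index_pattern_of_partitions(self):
        sig = PASignal(np.arange(6.0), ts=1.0)
        h = build_hankel(sig, i=2, j=3)
        np.testing.assert_array_equal(h.Yp, [[0, 1, 2], [1, 2, 3]])
        np.testing.assert_array_equal(h.Yf, [[2, 3, 4], [3, 4, 5]])
        np.testing.assert_array_equal(h.Yp_plus, [[0, 1, 2], [1, 2, 3], [2, 3, 4]])
        np.testing.assert_array_equal(h.Yf_minus, [[3, 4, 5]])

    def test_auto_columns_use_all_samples(self):
        sig = PASignal(np.arange(100.0), ts=1.0)
        h = build_hankel(sig, i=10)
        assert h.j == 100 - 20 + 1
        assert h.Yf[-1, -1] == 99.0

    def test_constant_signal_gives_rank_one_projection(self):
        sig = PASignal(np.full(40, 3.0), ts=1.0)
        h = build_hankel(sig, i=4)
        assert np.all(h.Yp == 3.0) and np.all(h.Yf == 3.0)
        Oi = orthogonal_project(h.Yf, h.Yp)
        assert np.linalg.matrix_rank(Oi) == 1

    def test_too_short_record_names_minimum(self):
        sig = PASignal(np.arange(10.0), ts=1.0)
        with pytest.raises(SignalTooShortError, match="at least"):
            build_hankel(sig, i=10)


class TestProjection:
    def test_contained_rows_are_fixed_points(self):
        rng = np.random.default_rng(0)
        Wp = rng.normal(size=(3, 8))
        Yf = rng.normal(size=(2, 3)) @ Wp  # rows inside span(Wp)
        np.testing.assert_allclose(orthogonal_project(Yf, Wp), Yf, atol=1e-10)

    def test_orthogonal_rows_project_to_zero(self):
        Wp = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        Yf = np.array([[0.0, 0.0, 2.0, -1.0]])
        np.testing.assert_allclose(orthogonal_project(Yf, Wp), 0.0, atol=1e-12)

    def test_matches_normal_equations_least_squares(self):
        # oracle: G* = argmin ||Yf - G Wp||_F via lstsq, compare G* Wp
        rng = np.random.default_rng(0)
        Yf = rng.normal(size=(4, 6))
        Wp = rng.normal(size=(4, 6))
        G, *_ = np.linalg.lstsq(Wp.T, Yf.T, rcond=None)
        np.testing.assert_allclose(orthogonal_project(Yf, Wp), (G.T @ Wp), atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        Yf, Wp = rng.normal(size=(5, 9)), rng.normal(size=(3, 9))
        once = orthogonal_project(Yf, Wp)
        np.testing.assert_allclose(orthogonal_project(once, Wp), once, atol=1e-10)

    def test_oblique_reduces_to_orthogonal_for_vanishing_input(self):
        rng = np.random.default_rng(5)
        Yf, Wp = rng.normal(size=(4, 7)), rng.normal(size=(3, 7))
        Uf = np.zeros((2, 7))
        np.testing.assert_allclose(
            orthogonal_project(Yf, Wp, Uf), orthogonal_project(Yf, Wp), atol=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="column"):
            orthogonal_project(np.ones((2, 3)), np.ones((2, 4)))


class TestOrderSelection:
    @pytest.mark.parametrize(
        "sv,expected",
        [([10.0, 9.0, 0.01, 0.005], 2), ([5.0, 0.0, 0.0, 0.0], 1), ([3.0], 1)],
    )
    def test_gap_rule(self, sv, expected):
        assert estimate_order(np.array(sv)) == expected

    def test_all_zero_spectrum_warns_order_zero(self):
        with pytest.warns(RuntimeWarning, match="no dynamics"):
            assert estimate_order(np.zeros(4)) == 0

    def test_noise_free_second_order_signal_selects_two(self):
        # ~30 samples/period so no decimation stage intervenes
        p = SecondOrderParams(omega_n=2 * np.pi * 2e6, zeta=0.3, gain=1e-9)
        sig = simulate_pa_signal(p, ts=1 / (2e6 * 30), n_samples=2000)
        res = n4sid_fit(sig)
        assert res.order == 2

    def test_third_singular_value_vanishes_on_noise_free_data(self):
        p = SecondOrderParams(omega_n=2 * np.pi * 2e6, zeta=0.3, gain=1e-9)
        sig = simulate_pa_signal(p, ts=1 / (2e6 * 30), n_samples=2000)
        res = n4sid_fit(sig)
        s = res.singular_values
        assert s[2] <= 1e-8 * s[0]


class TestSVDTruncation:
    def test_truncation_error_bound_and_exactness_at_full_rank(self):
        rng = np.random.default_rng(1)
        Yf, Wp = rng.normal(size=(6, 12)), rng.normal(size=(4, 12))
        Oi = orthogonal_project(Yf, Wp)
        U, s, Vt = np.linalg.svd(Oi, full_matrices=False)
        n = 2
        approx = U[:, :n] @ np.diag(s[:n]) @ Vt[:n]
        bound = s[n] * np.sqrt(min(Oi.shape))
        assert np.linalg.norm(Oi - approx, "fro") <= bound + 1e-12
        r = np.linalg.matrix_rank(Oi)
        exact = U[:, :r] @ np.diag(s[:r]) @ Vt[:r]
        np.testing.assert_allclose(Oi, exact, atol=1e-10)


class TestN4SIDFit:
    def test_noise_free_recovery_to_tenth_percent(self, clean_signal, reference_params):
        res = n4sid_fit(clean_signal)
        assert res.order == 2
        assert res.modal.omega_n == pytest.approx(reference_params.omega_n, rel=1e-3)
        assert res.modal.zeta == pytest.approx(reference_params.zeta, rel=1e-3)
        assert res.nrmse_percent > 99.9
        assert res.stable

    def test_median_zeta_recovery_at_20db_over_seeds(self, reference_params):
        errs = []
        for seed in range(50):
            sig = simulate_pa_signal(
                reference_params, 1e-8, 2000, noise_snr_db=20.0, seed=seed
            )
            res = n4sid_fit(sig, config=N4SIDConfig(order=2))
            errs.append(abs(res.modal.zeta - reference_params.zeta) / reference_params.zeta)
        assert np.median(errs) < 0.05

    def test_constant_zero_signal_raises_no_dynamics(self):
        with pytest.raises(NoDynamicsError):
            n4sid_fit(PASignal(np.zeros(500), ts=1e-8))

    def test_fit_invariant_under_amplitude_scaling(self, noisy_signal):
        res1 = n4sid_fit(noisy_signal, config=N4SIDConfig(order=2))
        scaled = PASignal(noisy_signal.samples * 50.0, noisy_signal.ts)
        res2 = n4sid_fit(scaled, config=N4SIDConfig(order=2))
        assert res2.nrmse_percent == pytest.approx(res1.nrmse_percent, abs=1e-6)
        np.testing.assert_allclose(
            sorted(res2.eigenvalues, key=lambda z: z.imag),
            sorted(res1.eigenvalues, key=lambda z: z.imag),
            rtol=1e-8,
        )
        # the amplitude scale lands in the state/gain side of the model
        np.testing.assert_allclose(
            res2.predicted_segment, 50.0 * res1.predicted_segment, rtol=1e-6
        )

    def test_measured_input_path_runs(self, clean_signal):
        u = np.zeros(clean_signal.n_samples)
        u[0] = 1.0
        res = n4sid_fit(clean_signal, config=N4SIDConfig(order=2), u=u)
        assert res.order == 2
        assert res.modal.omega_n == pytest.approx(1e7, rel=0.05)


class TestDiagnostics:
    def test_observability_controllability_toeplitz_shapes(self):
        m = discretize(SecondOrderParams(1e7, 0.3, 1e-9), 1e-8)
        Gam = extended_observability(m, 5)
        assert Gam.shape == (5, 2)
        np.testing.assert_allclose(Gam[0], m.C[0])
        Delta = controllability(m, 5)
        assert Delta.shape == (2, 5)
        np.testing.assert_allclose(Delta[:, -1], m.B[:, 0])
        T = impulse_toeplitz(m, 6)
        assert np.all(np.triu(T) == 0.0)
        h = m.impulse_response(6)
        np.testing.assert_allclose(T[:, 0], h)
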