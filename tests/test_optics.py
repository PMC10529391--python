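import numpy as np
import pytest

from pahydro import (
    InversionConfig,
    OpticalProperties,
    SphereMeasurement,
    invert_optical_props,
    mc_forward_slab,
    reduced_scattering,
    reflectance_cd,
    transmittance_cd,
    transmittance_coherent,
)


class TestSphereAlgebra:
    def test_reflectance_formula(self):
        m = SphereMeasurement(Pd=2.0, Pr=2.0, Pt=0.0, Pcoh=0.0, Po=1.0)
        assert reflectance_cd(m) == pytest.approx(0.98)
        m0 = SphereMeasurement(Pd=2.0, Pr=0.0, Pt=0.0, Pcoh=0.0, Po=1.0)
        assert reflectance_cd(m0) == 0.0

    def test_reflectance_anchor_ratio(self):
        # Rcd = 0.44 with m = 0.98 requires Pr/Pd = 0.44/0.98
        ratio = 0.44 / 0.98
        m = SphereMeasurement(Pd=1.0, Pr=ratio, Pt=0.0, Pcoh=0.0, Po=1.0)
        assert reflectance_cd(m) == pytest.approx(0.44)
        assert ratio == pytest.approx(0.44898, abs=1e-5)

    def test_transmittance_proportional_in_pt(self):
        m1 = SphereMeasurement(Pd=2.0, Pr=0.0, Pt=1.0, Pcoh=0.0, Po=1.0)
        m2 = SphereMeasurement(Pd=2.0, Pr=0.0, Pt=2.0, Pcoh=0.0, Po=1.0)
        assert transmittance_cd(m2) == pytest.approx(2 * transmittance_cd(m1))
        assert transmittance_cd(m2) == pytest.approx(0.98)

    def test_coherent_transmittance(self):
        m = SphereMeasurement(Pd=1.0, Pr=0.0, Pt=0.0, Pcoh=0.5, Po=1.0)
        assert transmittance_coherent(m) == pytest.approx(0.5)
        m_full = SphereMeasurement(Pd=1.0, Pr=0.0, Pt=0.0, Pcoh=1.0, Po=1.0)
        assert transmittance_coherent(m_full) == pytest.approx(1.0)
        m_none = SphereMeasurement(Pd=1.0, Pr=0.0, Pt=0.0, Pcoh=0.0, Po=1.0)
        assert transmittance_coherent(m_none) == 0.0

    def test_zero_reference_power_rejected(self):
        m = SphereMeasurement(Pd=0.0, Pr=1.0, Pt=1.0, Pcoh=0.0, Po=0.0)
        with pytest.raises(ZeroDivisionError):
            reflectance_cd(m)
        with pytest.raises(ZeroDivisionError):
            transmittance_coherent(m)

    @pytest.mark.parametrize(
        "mu_s,g,expected", [(51.82, 0.80, 10.364), (40.0, 0.0, 40.0), (40.0, 1.0, 0.0)]
    )
    def test_reduced_scattering(self, mu_s, g, expected):
        assert reduced_scattering(mu_s, g) == pytest.approx(expected, abs=1e-9)


class TestMonteCarloSlab:
    def test_beer_lambert_limit_without_scattering(self):
        props = OpticalProperties(mu_a=5.0, mu_s=0.0, g=0.0)
        res = mc_forward_slab(props, 100.0, n_photons=100_000, seed=1)
        se = np.sqrt(res.t_coherent * (1 - res.t_coherent) / res.n_photons)
        assert res.t_coherent == pytest.approx(np.exp(-5.0 * 0.01), abs=3 * se + 1e-4)
        assert res.r_diffuse == 0.0

    def test_energy_conserved_without_absorption(self):
        props = OpticalProperties(mu_a=0.0, mu_s=50.0, g=0.8)
        res = mc_forward_slab(props, 100.0, n_photons=50_000, seed=2)
        assert res.r_diffuse + res.t_diffuse + res.t_coherent == pytest.approx(1.0, abs=1e-9)
        assert res.absorbed == pytest.approx(0.0, abs=1e-9)

    def test_exact_weight_bookkeeping(self):
        props = OpticalProperties(mu_a=0.5, mu_s=50.0, g=0.8)
        res = mc_forward_slab(props, 100.0, n_photons=20_000, seed=3)
        assert res.total == pytest.approx(1.0, abs=1e-9)

    def test_self_consistency_against_higher_photon_reference(self):
        props = OpticalProperties(mu_a=0.5, mu_s=50.0, g=0.8)
        small = mc_forward_slab(props, 100.0, n_photons=100_000, seed=4)
        ref = mc_forward_slab(props, 100.0, n_photons=1_000_000, seed=5)
        for a, b in [
            (small.r_diffuse, ref.r_diffuse),
            (small.t_diffuse, ref.t_diffuse),
            (small.t_coherent, ref.t_coherent),
        ]:
            se = np.sqrt(b * (1 - b) / small.n_photons + b * (1 - b) / ref.n_photons)
            assert a == pytest.approx(b, abs=3 * se + 1e-4)

    def test_fresnel_boundaries_raise_reflectance_conserving_energy(self):
        props = OpticalProperties(mu_a=0.0, mu_s=50.0, g=0.8)
        matched = mc_forward_slab(props, 100.0, n_photons=50_000, seed=2)
        mismatched = mc_forward_slab(props, 100.0, n_photons=50_000, seed=2, n_rel=1.33)
        assert mismatched.r_diffuse > matched.r_diffuse
        assert mismatched.total == pytest.approx(1.0, abs=1e-9)

    def test_determinism_and_photon_floor(self):
        props = OpticalProperties(mu_a=1.0, mu_s=10.0, g=0.5)
        r1 = mc_forward_slab(props, 100.0, n_photons=5000, seed=9)
        r2 = mc_forward_slab(props, 100.0, n_photons=5000, seed=9)
        assert r1 == r2
        with pytest.raises(ValueError):
            mc_forward_slab(props, 100.0, n_photons=10)


class TestInversion:
    def test_fixed_anisotropy_round_trip(self):
        truth = OpticalProperties(mu_a=1.0, mu_s=40.0, g=0.7)
        cfg = InversionConfig(n_photons=30_000, seed=6, fix_g=0.7)
        fwd = mc_forward_slab(truth, 100.0, cfg.n_photons, seed=cfg.seed)
        res = invert_optical_props(fwd.r_diffuse, fwd.t_diffuse, fwd.t_coherent, 100.0, cfg)
        assert res.props.g == 0.7
        assert res.props.mu_a == pytest.approx(1.0, rel=0.10)
        assert res.props.mu_s == pytest.approx(40.0, rel=0.10)

    def test_pure_absorption_closed_form(self):
        tc = 0.6
        res = invert_optical_props(
            0.0, 0.0, tc, 100.0, InversionConfig(fix_mu_s=0.0)
        )
        assert res.props.mu_a == pytest.approx(-np.log(tc) / 0.01, rel=1e-12)
        assert res.converged

    def test_black_sample_flagged_as_diverging_absorption(self):
        res = invert_optical_props(0.0, 0.0, 0.0, 100.0)
        assert res.diverging_absorption
        assert not res.converged

    def test_observables_scale_free_in_powers(self):
        m = SphereMeasurement(Pd=2.0, Pr=0.9, Pt=0.8, Pcoh=0.1, Po=1.5)
        m_scaled = m.scaled(7.3)
        assert reflectance_cd(m_scaled) == pytest.approx(reflectance_cd(m), rel=1e-12)
        assert transmittance_cd(m_scaled) == pytest.approx(transmittance_cd(m), rel=1e-12)
        assert transmittance_coherent(m_scaled) == pytest.approx(
            transmittance_coherent(m), rel=1e-12
        )

    def test_out_of_range_observables_rejected(self):
        with pytest.raises(ValueError):
            invert_optical_props(1.5, 0.0, 0.0, 100.0)

    def test_measurement_reader_and_results_writer(self, tmp_path):
        from pahydro.optics import read_sphere_measurements, write_optical_results

        src = tmp_path / "sphere.csv"
        src.write_text(
            "sample_id,Pd,Pr,Pt,Pcoh,Po,thickness_um\n"
            "MW1-7pct,2.0,0.9,0.95,0.0,1.5,100\n"
        )
        meas = read_sphere_measurements(src)
        assert reflectance_cd(meas["MW1-7pct"]) == pytest.approx(0.98 * 0.45)
        out = tmp_path / "optics.csv"
        df = write_optical_results(
            {"MW1-7pct": OpticalProperties(2.17, 51.82, 0.80)}, out
        )
        assert df.loc[0, "mu_s_prime_cm1"] == pytest.approx(10.364)
        assert out.exists()

    def test_property_invariants(self):
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=-1.0, mu_s=1.0, g=0.0)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=1.0, mu_s=1.0, g=1.0)
        p = OpticalProperties(mu_a=2.17, mu_s=51.82, g=0.80)
        assert p.mu_s_prime == pytest.approx(10.364)
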