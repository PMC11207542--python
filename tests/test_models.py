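"""Forward-model tests: amplitudes against radial-quadrature oracles,
closed-form sphere limits, paracrystal structure-factor identities, size
averaging, and the electron-density profile round trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from lnpsaxs import (IntensityParams, LamellarStacking, ShellParticle,
                     average_form_factor, electron_density_profile,
                     form_factor, model_intensity, normalized_sf,
                     paracrystal_sf, particle_amplitude, size_distribution,
                     sphere_amplitude)
from lnpsaxs.models import ContrastError, DomainError

from conftest import radial_quadrature_amplitude


class TestSphereAmplitude:
    def test_q_zero_limit_is_sphere_volume(self):
        assert sphere_amplitude(0.0, 1.0) == pytest.approx(4 * math.pi / 3,
                                                           rel=1e-12)
        assert sphere_amplitude(1e-9, 36.4) == pytest.approx(
            4 / 3 * math.pi * 36.4 ** 3, rel=1e-8)

    def test_first_zero_at_tan_x_equals_x(self):
        # first positive root of tan(x) = x
        x0 = brentq(lambda x: math.tan(x) - x, math.pi / 2 + 1e-9,
                    3 * math.pi / 2 - 1e-9)
        assert x0 == pytest.approx(4.4934, abs=1e-4)
        for radius in (1.0, 36.4, 80.0):
            val = sphere_amplitude(x0 / radius, radius)
            assert abs(val) < 1e-8 * (4 / 3 * math.pi * radius ** 3)

    @pytest.mark.parametrize("q,radius", [(1.0, 36.4), (0.05, 80.0),
                                          (2.0, 22.7), (10.0, 90.0)])
    def test_matches_radial_quadrature(self, q, radius):
        from scipy.integrate import quad
        oracle = 4 * math.pi * quad(
            lambda r: r * r * np.sinc(q * r / math.pi), 0, radius,
            limit=500, epsabs=1e-13, epsrel=1e-13)[0]
        assert sphere_amplitude(q, radius) == pytest.approx(oracle, rel=1e-8)

    def test_continuity_across_series_switch(self):
        # series branch applies for qR < 1e-2
        radius = 10.0
        qs = np.array([9.9e-4, 1.01e-3, 1.1e-3])
        vals = sphere_amplitude(qs, radius)
        assert np.all(np.diff(vals) < 0)
        # deviation from the volume limit is O((qR)^2/10) ~ 1e-5 here
        assert np.allclose(vals, 4 / 3 * math.pi * radius ** 3, rtol=3e-5)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            sphere_amplitude(1.0, -1.0)
        with pytest.raises(DomainError):
            sphere_amplitude(-0.1, 1.0)


class TestParticleAmplitude:
    def test_uniform_contrast_equals_outer_sphere(self, gv_particle):
        uniform = ShellParticle(36.4, region_contrasts=(0.7, 0.7, 0.7, 0.7))
        q = np.linspace(0.0, 2.0, 50)
        expected = 0.7 * sphere_amplitude(q, uniform.radii()[-1])
        assert np.allclose(particle_amplitude(q, uniform), expected,
                           rtol=1e-12, atol=1e-10)

    def test_core_only_contrast_at_q0(self):
        p = ShellParticle(30.0, region_contrasts=(1.0, 0.0, 0.0, 0.0))
        assert particle_amplitude(0.0, p) == pytest.approx(
            4 / 3 * math.pi * 30.0 ** 3, rel=1e-12)

    def test_matches_piecewise_quadrature_oracle(self, gv_particle):
        for q in np.linspace(0.05, 2.0, 7):
            oracle = radial_quadrature_amplitude(q, gv_particle)
            assert particle_amplitude(q, gv_particle) == pytest.approx(
                oracle, rel=1e-8, abs=1e-8)

    def test_linear_in_contrasts(self, gv_particle):
        q = np.linspace(0.1, 2.0, 20)
        doubled = ShellParticle(
            36.4, region_contrasts=tuple(2 * c for c in
                                         gv_particle.region_contrasts))
        assert np.allclose(particle_amplitude(q, doubled),
                           2 * particle_amplitude(q, gv_particle), rtol=1e-12)

    def test_all_zero_contrast_raises(self):
        p = ShellParticle(30.0, region_contrasts=(0, 0, 0, 0))
        with pytest.raises(ContrastError):
            particle_amplitude(1.0, p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(core=st.floats(10.0, 60.0),
           contrasts=st.tuples(*[st.floats(-2.0, 2.0) for _ in range(4)]),
           q=st.floats(0.05, 2.0))
    def test_oracle_equivalence_property(self, core, contrasts, q):
        if all(abs(c) < 1e-3 for c in contrasts):
            contrasts = (1.0,) + contrasts[1:]
        p = ShellParticle(core, region_contrasts=contrasts)
        oracle = radial_quadrature_amplitude(q, p)
        got = particle_amplitude(q, p)
        scale = 4 / 3 * math.pi * p.radii()[-1] ** 3 * max(
            abs(c) for c in contrasts)
        assert got == pytest.approx(oracle, rel=1e-6, abs=1e-6 * scale)


class TestFormFactor:
    def test_unity_at_q0(self, gv_particle):
        assert form_factor(0.0, gv_particle) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_contrast_closed_form(self):
        p = ShellParticle(30.0, region_contrasts=(1.0, 1.0, 1.0, 1.0))
        q = np.linspace(0.01, 2.0, 100)
        x = q * p.radii()[-1]
        expected = (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        assert np.allclose(form_factor(q, p), expected, rtol=1e-10, atol=1e-10)

    def test_contrast_matched_raises(self):
        # choose rho_3 so the telescoping steps cancel exactly at q = 0:
        # F(0) = rho_2 (V2 - V1) + rho_3 (V3 - V2) = 0
        rho3 = -(32.0 ** 3 - 30.0 ** 3) / (34.0 ** 3 - 32.0 ** 3)
        p = ShellParticle(30.0, shell_thicknesses=(2.0, 2.0, 2.0),
                          region_contrasts=(0.0, 1.0, rho3, 0.0))
        assert abs(particle_amplitude(0.0, p)) < 1e-9
        with pytest.raises(ContrastError):
            form_factor(1.0, p)

    def test_nonnegative(self, gv_particle):
        q = np.linspace(0.0, 3.0, 500)
        assert np.all(form_factor(q, gv_particle) >= 0)


class TestSizeDistribution:
    def test_normalized_over_support(self):
        from scipy.integrate import quad
        total, _ = quad(lambda r: size_distribution(r, 36.4, 7.28), 0.0,
                        36.4 + 12 * 7.28, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_peak_value(self):
        r_av, sigma = 36.4, 0.2 * 36.4
        assert size_distribution(r_av, r_av, sigma) == pytest.approx(
            1.0 / (sigma * math.sqrt(2 * math.pi)), rel=1e-6)

    def test_tail_mass_outside_4_sigma(self):
        from scipy import special
        # two-sided Gaussian tail beyond 4 sigma
        assert special.erfc(4 / math.sqrt(2)) < 1e-4

    def test_zero_below_zero_radius(self):
        assert size_distribution(-1.0, 10.0, 5.0) == 0.0
        with pytest.raises(DomainError):
            size_distribution(1.0, -1.0, 1.0)


class TestAverageFormFactor:
    def test_unity_at_q0(self, gv_particle):
        assert average_form_factor(0.0, gv_particle) == pytest.approx(
            1.0, abs=1e-6)

    def test_monodisperse_limit(self):
        p0 = ShellParticle(36.4, rel_polydispersity=0.0)
        q = np.linspace(0.05, 2.0, 50)
        assert np.allclose(average_form_factor(q, p0), form_factor(q, p0),
                           rtol=1e-12)

    def test_quadrature_against_dense_trapezoid(self, gv_particle):
        q = np.linspace(0.05, 2.0, 30)
        r_av = gv_particle.core_radius_mean
        sigma = 0.2 * r_av
        grid = np.linspace(max(0.1, r_av - 4 * sigma), r_av + 4 * sigma, 10_000)
        dens = size_distribution(grid, r_av, sigma)
        pmat = np.array([form_factor(q, gv_particle, r) for r in grid])
        oracle = np.trapezoid(dens[:, None] * pmat, grid, axis=0) / \
            np.trapezoid(dens, grid)
        got = average_form_factor(q, gv_particle)
        assert np.allclose(got, oracle, rtol=1e-6)

    def test_first_minimum_fills_in_with_polydispersity(self):
        q = np.linspace(0.08, 0.25, 800)
        depths = []
        for pd_ in (0.0, 0.05, 0.1, 0.2):
            p = ShellParticle(36.4, rel_polydispersity=pd_)
            depths.append(np.min(average_form_factor(q, p)))
        assert all(d2 >= d1 * (1 - 1e-9) for d1, d2 in
                   zip(depths, depths[1:]))


class TestParacrystal:
    def test_single_layer_no_interference(self):
        s = paracrystal_sf(np.linspace(0, 5, 50), LamellarStacking(6.3, 1))
        assert np.all(s == 1.0)

    def test_two_layer_destructive_at_half_period(self):
        st_ = LamellarStacking(6.3, 2, rel_disorder=0.0)
        qd_pi = math.pi / 6.3
        assert paracrystal_sf(qd_pi, st_) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_q0_equals_n_squared(self, n):
        assert paracrystal_sf(0.0, LamellarStacking(6.3, n)) == pytest.approx(
            float(n * n), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_large_q_limit_approaches_n(self, n):
        # damping exp(-k (q d Delta)^2 / 2) kills interference at q d = 500
        st_ = LamellarStacking(6.3, n, rel_disorder=0.01)
        q = 500.0 / 6.3
        assert abs(paracrystal_sf(q, st_) / n - 1.0) < 0.01

    def test_nonnegative_on_grid(self):
        q = np.linspace(0.0, 3.0, 1000)
        for n in (2, 3, 4):
            assert np.min(paracrystal_sf(q, LamellarStacking(6.3, n))) > -1e-12

    def test_non_integer_n_rejected(self):
        with pytest.raises(DomainError):
            paracrystal_sf(1.0, LamellarStacking(6.3, 2.3))


class TestNormalizedSf:
    def test_single_layer_identity(self):
        q = np.linspace(0, 3, 100)
        assert np.all(normalized_sf(q, LamellarStacking(6.3, 1.0)) == 1.0)

    def test_midpoint_interpolation(self):
        q = np.linspace(0.0, 3.0, 60)
        s2 = paracrystal_sf(q, LamellarStacking(6.3, 2)) / 2
        s3 = paracrystal_sf(q, LamellarStacking(6.3, 3)) / 3
        got = normalized_sf(q, LamellarStacking(6.3, 2.5))
        assert np.allclose(got, 0.5 * (s2 + s3), rtol=1e-12)

    def test_q0_equals_interpolated_layer_number(self):
        assert normalized_sf(0.0, LamellarStacking(6.3, 2.2)) == \
            pytest.approx(2.2, abs=1e-12)


class TestModelIntensity:
    def test_unilamellar_reduces_to_scale_at_q0(self, gv_particle):
        ip = IntensityParams(scale=3.0, multilayer_fraction=0.0,
                             background=0.0)
        assert model_intensity(0.0, gv_particle, None, ip) == pytest.approx(
            3.0, rel=1e-6)

    def test_fully_multilamellar_q0(self, gv_particle):
        ip = IntensityParams(scale=1.5, multilayer_fraction=1.0,
                             background=0.0)
        st_ = LamellarStacking(6.3, 2.0)
        assert model_intensity(0.0, gv_particle, st_, ip) == pytest.approx(
            3.0, rel=1e-6)

    def test_positive_everywhere(self, gv_particle, q_grid):
        ip = IntensityParams(scale=1.0, multilayer_fraction=0.72,
                             background=1e-7)
        st_ = LamellarStacking(6.3, 2.3)
        assert np.all(model_intensity(q_grid, gv_particle, st_, ip) > 0)

    def test_multilamellar_bump_near_1_inverse_nm(self, gv_particle, q_grid):
        """The lamellar interference lifts I over the unilamellar envelope
        inside q in [0.8, 1.2] nm^-1 for the commercial-style parameters."""
        st_ = LamellarStacking(6.3, 2.3)
        multi = model_intensity(q_grid, gv_particle, st_,
                                IntensityParams(1.0, 0.72, 0.0))
        uni = model_intensity(q_grid, gv_particle, None,
                              IntensityParams(1.0, 0.0, 0.0))
        ratio = multi / uni
        band = (q_grid >= 0.8) & (q_grid <= 1.2)
        assert np.max(ratio[band]) > 1.5
        peak_q = q_grid[band][np.argmax(ratio[band])]
        assert 0.8 <= peak_q <= 1.2

    def test_missing_stacking_raises(self, gv_particle):
        ip = IntensityParams(scale=1.0, multilayer_fraction=0.5)
        with pytest.raises(DomainError):
            model_intensity(1.0, gv_particle, None, ip)


class TestElectronDensityProfile:
    def test_plateaus_match_definition(self):
        p = ShellParticle(30.0, region_contrasts=(0.0, 1.0, -1.0, 1.0))
        prof = electron_density_profile(p)
        assert prof(15.0) == 0.0
        assert prof(31.0) == 1.0
        assert prof(33.0) == -1.0
        assert prof(35.0) == 1.0
        assert prof(40.0) == 0.0
        assert prof.breakpoints == (30.0, 32.0, 34.0, 36.0)

    def test_excess_mass_consistent_with_amplitude(self, gv_particle):
        radii = gv_particle.radii()
        mass = float(gv_particle.contrast_steps @
                     (4 / 3 * math.pi * radii ** 3))
        assert mass == pytest.approx(particle_amplitude(0.0, gv_particle),
                                     rel=1e-12)

    def test_round_trip_quadrature_matches_amplitude(self, gv_particle):
        """Integrating the exported step profile reproduces the amplitude."""
        for q in np.linspace(0.1, 2.0, 10):
            oracle = radial_quadrature_amplitude(q, gv_particle)
            assert particle_amplitude(q, gv_particle) == pytest.approx(
                oracle, rel=1e-8, abs=1e-8)

    def test_save_two_column_text(self, gv_particle, tmp_path):
        path = tmp_path / "rho.txt"
        electron_density_profile(gv_particle).save(path)
        data = np.loadtxt(path)
        assert data.shape[1] == 2
        assert data[0, 0] == 0.0


class TestInvariants:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(core=st.floats(10.0, 60.0), pd_=st.floats(0.01, 0.4))
    def test_average_form_factor_normalization(self, core, pd_):
        p = ShellParticle(core, rel_polydispersity=pd_)
        assert abs(average_form_factor(0.0, p) - 1.0) < 1e-6
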