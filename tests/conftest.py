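import numpy as np
import pytest

from lnpsaxs import (BeamlineConfig, IntensityParams, LamellarStacking,
                     ShellParticle, simulate_profile, table1_fixtures)


@pytest.fixture
def gv_particle():
    """Mean-size particle of the commercial-formulation fixture."""
    return ShellParticle(core_radius_mean=36.4, rel_polydispersity=0.2,
                         shell_thicknesses=(2.0, 2.0, 2.0),
                         region_contrasts=(0.2, 1.0, -1.0, 1.0))


@pytest.fixture
def q_grid():
    return np.linspace(0.05, 2.0, 400)


@pytest.fixture(scope="session")
def fixtures():
    return table1_fixtures()


def radial_quadrature_amplitude(q, particle, core_radius=None):
    """Independent oracle: F(q) = 4 pi int_0^R4 rho(r) r^2 sinc(q r) dr by
    adaptive piecewise quadrature of the step density profile."""
    from scipy.integrate import quad

    radii = particle.radii(core_radius)
    contrasts = particle.region_contrasts

    def rho(r):
        for R, c in zip(radii, contrasts):
            if r < R:
                return c
        return 0.0

    def integrand(r):
        return rho(r) * r * r * np.sinc(q * r / np.pi)

    total = 0.0
    edges = np.concatenate(([0.0], radii))
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(integrand, a, b, limit=200, epsabs=1e-12, epsrel=1e-12)
        total += val
    return 4.0 * np.pi * total
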