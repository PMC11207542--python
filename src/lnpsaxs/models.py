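"""Forward SAXS model for mRNA-loaded lipid nanoparticles.

The particle is a polydisperse multi-shell sphere: a homogeneous core of mean
radius ``R_av`` (Gaussian size distribution, relative width ``sigma/R_av``)
wrapped in three concentric 2 nm shells representing the inner polar headgroup
region, the hydrophobic tail region and the outer polar headgroup region of a
lipid bilayer.  Each region carries an electron-density contrast relative to
the solvent.  Multilamellar particles additionally show a one-dimensional
paracrystal structure factor from the stacking of concentric bilayers with
repeat distance ``d`` and Gaussian spacing disorder.

The assembled intensity is

    I(q) = scale * [(1 - f) + f * S_hat(q)] * <P>(q) + background

where ``<P>`` is the size-averaged normalized form factor, ``S_hat = S/N`` the
layer-normalized paracrystal structure factor and ``f`` the multilamellar
fraction ("Multilayer %" / 100).

Units: lengths in nm, momentum transfer q in nm^-1, contrasts in arbitrary
electron-density units relative to solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special

__all__ = [
    "ShellParticle",
    "LamellarStacking",
    "IntensityParams",
    "ElectronDensityProfile",
    "sphere_amplitude",
    "particle_amplitude",
    "form_factor",
    "size_distribution",
    "average_form_factor",
    "paracrystal_sf",
    "normalized_sf",
    "model_intensity",
    "electron_density_profile",
]


class DomainError(ValueError):
    """Invalid physical parameter or argument."""


class ContrastError(DomainError):
    """Particle has no usable scattering contrast."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShellParticle:
    """Core + three-shell spherical LNP with Gaussian core-size dispersion.

    Parameters
    ----------
    core_radius_mean : float
        Mean radius of the homogeneous core, nm (R_av).
    rel_polydispersity : float
        Relative width sigma/R_av of the Gaussian core-size distribution,
        in [0, 0.5].  The three shells translate rigidly with the core.
    shell_thicknesses : tuple of 3 floats
        Thickness of the inner-polar, hydrophobic and outer-polar shells, nm.
    region_contrasts : tuple of 4 floats
        Electron-density contrast (relative to solvent) of core, inner polar,
        hydrophobic and outer polar regions.
    """

    core_radius_mean: float
    rel_polydispersity: float = 0.2
    shell_thicknesses: tuple = (2.0, 2.0, 2.0)
    region_contrasts: tuple = (0.2, 1.0, -1.0, 1.0)

    def __post_init__(self):
        if self.core_radius_mean <= 0:
            raise DomainError("core_radius_mean must be > 0")
        if not 0.0 <= self.rel_polydispersity <= 0.5:
            raise DomainError("rel_polydispersity must be in [0, 0.5]")
        object.__setattr__(self, "shell_thicknesses",
                           tuple(float(t) for t in self.shell_thicknesses))
        object.__setattr__(self, "region_contrasts",
                           tuple(float(c) for c in self.region_contrasts))
        if len(self.shell_thicknesses) != 3:
            raise DomainError("exactly 3 shell thicknesses required")
        if len(self.region_contrasts) != 4:
            raise DomainError("exactly 4 region contrasts required (core + 3 shells)")
        if any(t <= 0 for t in self.shell_thicknesses):
            raise DomainError("all shell thicknesses must be > 0")

    def radii(self, core_radius: Optional[float] = None) -> np.ndarray:
        """Outer radii R_1..R_4 of the four regions for a given core radius."""
        rc = self.core_radius_mean if core_radius is None else float(core_radius)
        if rc <= 0:
            raise DomainError("core radius must be > 0")
        return rc + np.concatenate(([0.0], np.cumsum(self.shell_thicknesses)))

    @property
    def outer_radius_mean(self) -> float:
        return self.core_radius_mean + float(sum(self.shell_thicknesses))

    @property
    def contrast_steps(self) -> np.ndarray:
        """Telescoping contrast steps drho_i = rho_i - rho_{i+1}, rho_5 = 0."""
        rho = np.asarray(self.region_contrasts, float)
        return rho - np.append(rho[1:], 0.0)


@dataclass(frozen=True)
class LamellarStacking:
    """Multilamellar stacking correlation of concentric bilayers.

    repeat_distance : nm, bilayer repeat d.
    n_layers : average number of bilayers N_av (real >= 1; non-integer values
        are handled by interpolation in :func:`normalized_sf`).
    rel_disorder : Gaussian spacing disorder sigma_d/d of the paracrystal.
    """

    repeat_distance: float
    n_layers: float
    rel_disorder: float = 0.01

    def __post_init__(self):
        if self.repeat_distance <= 0:
            raise DomainError("repeat_distance must be > 0")
        if self.n_layers < 1:
            raise DomainError("n_layers must be >= 1")
        if self.rel_disorder < 0:
            raise DomainError("rel_disorder must be >= 0")


@dataclass(frozen=True)
class IntensityParams:
    """Overall scale, multilamellar fraction f and flat background."""

    scale: float
    multilayer_fraction: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise DomainError("scale must be > 0")
        if not 0.0 <= self.multilayer_fraction <= 1.0:
            raise DomainError("multilayer_fraction must be in [0, 1]")
        if self.background < 0:
            raise DomainError("background must be >= 0")


# ---------------------------------------------------------------------------
# form factor
# ---------------------------------------------------------------------------


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * float(radius) ** 3


def sphere_amplitude(q, radius):
    """Scattering amplitude of a homogeneous sphere of unit contrast.

    A(R, q) = 4 pi [sin(qR) - qR cos(qR)] / q^3, with the analytic q -> 0
    limit V(R) = (4 pi / 3) R^3.  Broadcasts over ``q`` and ``radius``.
    """
    q = np.asarray(q, dtype=float)
    radius_arr = np.asarray(radius, dtype=float)
    if np.any(radius_arr <= 0):
        raise DomainError("radius must be > 0")
    if np.any(q < 0):
        raise DomainError("q must be >= 0")
    x = q * radius_arr
    vol = 4.0 / 3.0 * np.pi * radius_arr ** 3
    out = vol * _sphere_shape(np.asarray(x, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def _sphere_shape(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3 with a series branch for small x."""
    if x.ndim == 0:
        x = x[np.newaxis]
        scalar = True
    else:
        scalar = False
    small = x < 1e-2
    any_small = bool(small.any())
    xsafe = np.where(small, 1.0, x) if any_small else x  # avoid 0/0
    out = np.sin(xsafe)
    out -= xsafe * np.cos(xsafe)
    out *= 3.0
    out /= xsafe * xsafe * xsafe
    if any_small:
        x2 = x * x
        out = np.where(small, 1.0 - x2 / 10.0 + x2 * x2 / 280.0, out)
    return out[0] if scalar else out


def particle_amplitude(q, particle: ShellParticle,
                       core_radius_override: Optional[float] = None):
    """Amplitude F(q) of one multi-shell particle.

    Implemented as the telescoping contrast-step sum
    F(q) = sum_i (rho_i - rho_{i+1}) A(R_i, q) with rho_5 = 0 (solvent),
    equivalent to summing rho_i [A(R_i) - A(R_{i-1})] over the four regions.
    ``core_radius_override`` is the polydisperse integration variable.
    """
    steps = particle.contrast_steps
    if np.all(np.asarray(particle.region_contrasts) == 0.0):
        raise ContrastError("no scattering contrast: all region contrasts are zero")
    radii = particle.radii(core_radius_override)
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    amp = sphere_amplitude(np.atleast_1d(q)[..., np.newaxis], radii)
    out = amp @ steps
    if scalar:
        return float(out[0])
    return out


def form_factor(q, particle: ShellParticle,
                core_radius_override: Optional[float] = None):
    """Normalized single-particle form factor P(q) = F(q)^2 / F(0)^2."""
    f0 = particle_amplitude(0.0, particle, core_radius_override)
    radii = particle.radii(core_radius_override)
    vol_scale = float(np.abs(particle.contrast_steps) @ (4.0 / 3.0 * np.pi * radii ** 3))
    if abs(f0) < 1e-12 * max(vol_scale, 1.0):
        raise ContrastError("contrast-matched particle: F(0) = 0, form factor undefined")
    f = particle_amplitude(q, particle, core_radius_override)
    p = (np.asarray(f) / f0) ** 2
    if p.ndim == 0:
        return float(p)
    return p


def size_distribution(R, R_av: float, sigma: float):
    """Gaussian core-size density, truncated at R <= 0 and renormalized.

    Returns the probability density (nm^-1) at radius ``R`` for a Gaussian of
    mean ``R_av`` and standard deviation ``sigma``, restricted to R > 0 so
    that its integral over the positive half-line is exactly 1.
    """
    if R_av <= 0:
        raise DomainError("R_av must be > 0")
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    R = np.asarray(R, dtype=float)
    z = (R - R_av) / sigma
    norm = 0.5 * special.erfc(-R_av / (sigma * math.sqrt(2.0)))
    dens = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi)) / norm
    dens = np.where(R <= 0, 0.0, dens)
    if dens.ndim == 0:
        return float(dens)
    return dens


_GL_CACHE: dict = {}


def _gauss_legendre(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = leggauss(n)
    return _GL_CACHE[n]


def _size_average_tables(q: np.ndarray, core_radius_mean: float,
                         rel_polydispersity: float,
                         shell_thicknesses) -> tuple:
    """Quadrature tables for the size average, independent of contrasts.

    Returns (radii, volumes, amp, weights, wsum): per-node region radii and
    volumes, the sphere-amplitude matrix A(R_i, q) of shape
    (n_q, n_nodes, 4), and the renormalized distribution weights.  Cached by
    callers that vary only the contrasts (e.g. least-squares Jacobians).
    """
    r_av = core_radius_mean
    sigma = rel_polydispersity * r_av
    lo = max(0.1, r_av - 4.0 * sigma)
    hi = r_av + 4.0 * sigma
    # Gauss-Legendre resolves exp(i q R) once n exceeds ~phase/(2 pi) nodes
    # per period; 2.5 nodes/period keeps a ~1.6x margin over that threshold.
    q_max = float(np.max(q, initial=0.0))
    n_nodes = max(61, int(math.ceil(2.5 * (hi - lo) * q_max / math.pi)) | 1)
    gl_nodes, gl_weights = _gauss_legendre(n_nodes)
    nodes = 0.5 * (hi - lo) * gl_nodes + 0.5 * (hi + lo)
    weights = 0.5 * (hi - lo) * gl_weights * size_distribution(nodes, r_av,
                                                               sigma)
    wsum = float(weights.sum())
    if not np.isfinite(wsum) or wsum <= 0:
        raise DomainError(
            f"size-average quadrature failed on [{lo:g}, {hi:g}] "
            f"with {n_nodes} nodes")
    offsets = np.concatenate(
        ([0.0], np.cumsum(np.asarray(shell_thicknesses, float))))
    radii = nodes[:, None] + offsets
    volumes = 4.0 / 3.0 * np.pi * radii ** 3
    amp = _shell_amplitudes(q, nodes, offsets)  # (..., n_nodes, 4)
    return radii, volumes, amp, weights, wsum


def _shell_amplitudes(q, nodes: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """A(R_j, q) for R_j = nodes + offsets, shaped (n_q, n_nodes, n_offsets).

    Equivalent to ``sphere_amplitude(q[..., None, None], nodes[:, None] +
    offsets)`` but computes sin/cos once per node and extends to the shell
    radii by the angle-addition identities, since the shells are rigid
    offsets of the core radius.
    """
    qa = np.atleast_1d(np.asarray(q, dtype=float))
    scalar = np.asarray(q).ndim == 0
    qn = qa[:, None] * nodes[None, :]  # (nq, n)
    s0, c0 = np.sin(qn), np.cos(qn)
    amp = np.empty((qa.size, nodes.size, offsets.size))
    for j, off in enumerate(offsets):
        qo = qa * off
        so, co = np.sin(qo)[:, None], np.cos(qo)[:, None]
        x = qn + qo[:, None]
        sx = s0 * co + c0 * so
        cx = c0 * co - s0 * so
        small = x < 1e-2
        xsafe = np.where(small, 1.0, x)
        shape = 3.0 * (sx - x * cx) / (xsafe * xsafe * xsafe)
        if small.any():
            x2 = x * x
            shape = np.where(small, 1.0 - x2 / 10.0 + x2 * x2 / 280.0, shape)
        amp[:, :, j] = 4.0 / 3.0 * np.pi * (nodes + off) ** 3 * shape
    return amp[0] if scalar else amp


def _apply_contrasts(tables: tuple, steps: np.ndarray) -> np.ndarray:
    """<P>(q) from precomputed tables and telescoping contrast steps."""
    radii, volumes, amp, weights, wsum = tables
    f0 = volumes @ steps  # (n_nodes,)
    if np.any(np.abs(f0) < 1e-12 * np.max(volumes)):
        raise ContrastError(
            "contrast-matched particle inside the size distribution")
    p = ((amp @ steps) / f0) ** 2  # (..., n_nodes)
    return (p @ weights) / wsum


def average_form_factor(q, particle: ShellParticle):
    """Size-averaged form factor <P>(q) = int D(R) P(q, R) dR.

    Polydispersity applies to the core radius only; the shells ride rigidly.
    Gauss-Legendre quadrature over [max(0.1 nm, R_av - 4 sigma),
    R_av + 4 sigma] with the distribution weight renormalized on the window
    so that <P>(0) = 1 exactly.  The node count starts at 61 and grows with
    the total oscillation phase q_max * window so the rapidly oscillating
    form factor stays resolved at the high-q end of wide distributions
    (about four nodes per oscillation period).
    """
    q = np.asarray(q, dtype=float)
    if particle.rel_polydispersity == 0.0:
        return form_factor(q, particle)
    tables = _size_average_tables(q, particle.core_radius_mean,
                                  particle.rel_polydispersity,
                                  particle.shell_thicknesses)
    out = _apply_contrasts(tables, particle.contrast_steps)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# structure factor
# ---------------------------------------------------------------------------


def paracrystal_sf(q, stacking: LamellarStacking):
    """1D ideal-paracrystal structure factor for an integer layer number.

    S_N(q) = N + 2 sum_{k=1}^{N-1} (N - k) cos(k q d) exp(-k q^2 d^2 D^2 / 2)

    with cumulative Gaussian nearest-neighbour spacing disorder D (sigma_d/d).
    S(0) = N^2 and S -> N at large q for D > 0.
    """
    n = stacking.n_layers
    if abs(n - round(n)) > 1e-9:
        raise DomainError(
            "paracrystal_sf requires integer n_layers; use normalized_sf for "
            "fractional average layer numbers")
    n = int(round(n))
    q = np.asarray(q, dtype=float)
    d = stacking.repeat_distance
    delta = stacking.rel_disorder
    s = np.full(q.shape, float(n))
    qd = q * d
    damp_arg = (qd * delta) ** 2 / 2.0
    for k in range(1, n):
        s = s + 2.0 * (n - k) * np.cos(k * qd) * np.exp(-k * damp_arg)
    if s.ndim == 0:
        return float(s)
    return s


def normalized_sf(q, stacking: LamellarStacking):
    """Layer-normalized structure factor S_hat = S/N, continuous in n_layers.

    For non-integer average layer numbers (Table-1 style values such as 2.3),
    S_hat is linearly interpolated between the adjacent integer stacks.
    """
    n = stacking.n_layers
    lo = math.floor(n)
    hi = math.ceil(n)
    s_lo = paracrystal_sf(q, LamellarStacking(stacking.repeat_distance, lo,
                                              stacking.rel_disorder)) / lo
    if hi == lo:
        return s_lo
    s_hi = paracrystal_sf(q, LamellarStacking(stacking.repeat_distance, hi,
                                              stacking.rel_disorder)) / hi
    t = n - lo
    return (1.0 - t) * s_lo + t * s_hi


# ---------------------------------------------------------------------------
# assembled intensity
# ---------------------------------------------------------------------------


def model_intensity(q, particle: ShellParticle,
                    stacking: Optional[LamellarStacking],
                    ip: IntensityParams):
    """Total model intensity I(q) = scale [(1-f) + f S_hat(q)] <P>(q) + back.

    With f = 0 the profile reduces exactly to a pure polydisperse-sphere
    envelope and ``stacking`` may be None.
    """
    f = ip.multilayer_fraction
    avg_p = average_form_factor(q, particle)
    if f == 0.0:
        sf_term = 1.0
    else:
        if stacking is None:
            raise DomainError("multilayer_fraction > 0 requires a LamellarStacking")
        sf_term = (1.0 - f) + f * normalized_sf(q, stacking)
    return ip.scale * sf_term * avg_p + ip.background


# ---------------------------------------------------------------------------
# electron-density profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectronDensityProfile:
    """Piecewise-constant radial electron-density contrast profile rho(r).

    ``breakpoints`` are the region boundaries [R_1, .., R_4]; ``densities``
    the contrasts of the four regions.  rho(r) = 0 beyond R_4 (solvent).
    """

    breakpoints: tuple
    densities: tuple

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        idx = np.searchsorted(self.breakpoints, r, side="right")
        vals = np.append(self.densities, 0.0)
        out = vals[np.minimum(idx, len(self.densities))]
        out = np.where(idx >= len(self.densities), 0.0, out)
        if out.ndim == 0:
            return float(out)
        return out

    def step_arrays(self, r_max: Optional[float] = None):
        """(r, rho) arrays tracing the steps, suitable for plotting/export."""
        if r_max is None:
            r_max = 1.2 * self.breakpoints[-1]
        edges = np.concatenate(([0.0], self.breakpoints, [r_max]))
        vals = np.append(self.densities, 0.0)
        r = np.repeat(edges, 2)[1:-1]
        rho = np.repeat(vals, 2)
        return r, rho

    def save(self, path) -> None:
        """Write a two-column whitespace text file (r_nm, rho_au)."""
        r, rho = self.step_arrays()
        header = ("radial electron-density contrast profile\n"
                  "columns: r_nm rho_au (contrast relative to solvent)")
        np.savetxt(path, np.column_stack([r, rho]), header=header, fmt="%.10g")


def electron_density_profile(particle: ShellParticle) -> ElectronDensityProfile:
    """Radial electron-density contrast profile of the mean-size particle."""
    radii = particle.radii()
    return ElectronDensityProfile(tuple(radii), tuple(particle.region_contrasts))
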