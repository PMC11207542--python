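# Methods

## The scattering model

`lnpsaxs` models a reduced 1D SAXS profile I(q) of mRNA-loaded lipid
nanoparticles (LNPs) as a polydisperse core/multi-shell sphere dressed with a
one-dimensional paracrystal structure factor for multilamellar stacking:

    I(q) = scale * [(1 - f) + f * S_hat(q)] * <P>(q) + background

**Particle.** Each particle is a homogeneous core of radius R wrapped in
three concentric shells of fixed 2 nm thickness representing the inner polar
headgroup region, the hydrocarbon tail region and the outer polar headgroup
region of one bilayer. Region i carries an electron-density contrast rho_i
relative to solvent. The scattering amplitude is the telescoping
contrast-step sum

    F(q) = sum_i (rho_i - rho_{i+1}) A(R_i, q),      rho_5 = 0,
    A(R, q) = 4 pi [sin(qR) - qR cos(qR)] / q^3,

mathematically identical to summing rho_i [A(R_i) - A(R_{i-1})] over the
four regions but free of sign ambiguities. The normalized single-particle
form factor is P(q) = F(q)^2 / F(0)^2; a contrast-matched particle
(F(0) = 0) is rejected explicitly rather than silently divided.

**Polydispersity.** The core radius follows a Gaussian of relative width
sigma/R_av (default 0.2), truncated at R <= 0 and renormalized; the shells
translate rigidly with the core, since their thickness is a property of the
lipids, not of the particle size. The size average
`<P>(q) = int D(R) P(q, R) dR` uses Gauss-Legendre quadrature on
[max(0.1 nm, R_av - 4 sigma), R_av + 4 sigma] with the distribution weight
renormalized on the window, so `<P>(0) = 1` holds exactly. The node count
starts at 61 and grows proportionally to the total oscillation phase
q_max * window (2.5 nodes per period of the form-factor oscillation,
~1.6x the Gauss-Legendre resolution threshold); against a 10^4-point
trapezoid reference the error is below 1e-7 across the default grid. The
amplitude tables exploit that the shell radii are rigid offsets of the core
radius (angle-addition identities), and the fitter caches them because they
do not depend on the contrasts.

**Stacking.** Concentric-bilayer correlations enter through the 1D ideal
paracrystal (Hosemann) structure factor with cumulative Gaussian
nearest-neighbour spacing disorder,

    S_N(q) = N + 2 sum_{k=1}^{N-1} (N - k) cos(k q d) exp(-k q^2 d^2 D^2 / 2),

with repeat distance d, integer layer count N and relative disorder
D = sigma_d/d fixed at 0.01. S_N(0) = N^2 exactly and S_N -> N at large q.
Fractional average layer numbers N_av (e.g. 2.3) are handled by linear
interpolation of the layer-normalized S_hat = S/N between the adjacent
integers; at q = 0 the interpolated S_hat equals N_av.

**Assembly.** The multilamellar fraction f in [0, 1] mixes the unilamellar
envelope with the stacked one; "Multilayer %" = 100 f is a direct model
parameter, and f = 0 reduces exactly to the pure polydisperse-sphere
profile. The overall scale and a flat background complete the model. No
instrumental resolution smearing is applied.

### Parameters

| name                | meaning                                    | unit  | default / bounds |
|---------------------|--------------------------------------------|-------|------------------|
| core_radius_mean    | mean core radius R_av                      | nm    | free, [5, 80]    |
| rel_polydispersity  | sigma/R_av of the core size distribution   | —     | fixed 0.2        |
| shell_thickness     | thickness of each of the 3 shells          | nm    | fixed 2.0        |
| contrast_0..3       | region contrasts (core, polar, tail, polar)| a.u.  | free, [-5, 5]    |
| multilayer_fraction | f, share of stacked-bilayer scattering     | —     | free, [0, 1]     |
| n_layers            | average number of bilayers N_av            | —     | free, [1, 5]     |
| repeat_distance     | lamellar repeat d                          | nm    | free, [4, 10], start 6.3 = 2 pi / q_bump |
| rel_disorder        | paracrystal spacing disorder sigma_d/d     | —     | fixed 0.01       |
| scale, background   | intensity scale / flat background          | a.u.  | free, data-driven bounds |

The repeat-distance start of 6.3 nm corresponds to the lamellar interference
bump near q = 1 nm^-1 characteristic of bilamellar lipid vesicles. The
reported diameter is the outer diameter 2 (R_av + 6 nm), the quantity
comparable with cryo-TEM and DLS sizes.

## Fitting

Weighted least squares on r_i = (I_i - I_model(q_i)) / sigma_i over the
window q in [0.08, 2.0] nm^-1 (excluding the beamstop region). When the
input carries no uncertainty column, sigma_i = c sqrt(max(I_i, floor)) with
c set so the median sigma/I is 2%, the level expected from ten averaged
10 s synchrotron exposures on a photon-counting detector.

The optimizer is bounded trust-region reflective least squares
(`scipy.optimize.least_squares`) with multi-starts: the first start comes
from a deterministic coarse scan — for each core radius on a grid the model
is linear in (scale, scale*f, background) once the stacking shape is held
at its start values, so a weighted linear solve per radius locates the
envelope cheaply — and subsequent starts jitter every free parameter by a
seeded uniform +-20% of its bound range. The best start is chosen by lowest
reduced chi^2, ties broken by smallest scaled distance from the start
point. Each start is capped at 120 function evaluations per free parameter;
with the scan initializer the first start converges well inside the cap and
the cap mainly truncates hopeless jittered basins. Everything is
deterministic given the seed.

Reduced chi^2 is sum(r^2)/(n_points - n_free). 1-sigma uncertainties come
from the Jacobian-based covariance of the linearized problem scaled by
reduced chi^2, using a pseudo-inverse so that degenerate directions (see
below) yield large-but-finite errors instead of a crash. Parameters within
1e-6 of a bound are flagged in the result. With the multilayer fraction
*fixed* at zero the layer number is reported absent (the unilamellar
reporting convention).

### Identifiability

Two structural degeneracies are worth knowing:

- **Contrast gauge.** P(q) is normalized by F(0)^2, so the contrast vector
  only enters through its direction: (c * rho) fits identically for any
  c != 0. Geometry, f, N_av, d, scale and background are unaffected;
  individual contrast values and their uncertainties are only meaningful up
  to this gauge.
- **f–N_av coupling below two layers.** With the interpolated stack,
  for N_av in [1, 2) the intensity depends on (f, N_av) only through the
  product f (N_av - 1): sf_term = 1 + f t (S_hat_2 - 1) with t = N_av - 1.
  The two parameters are therefore individually unidentifiable in that
  range (the product, and all other parameters, are recovered). Above
  N_av = 2 the S_hat_2/S_hat_3 shapes differ and both become identifiable.
  Recovery tolerances on f and N_av are accordingly only asserted for
  parameter sets with N_av > 2.

## Synthetic data

The generator emulates reduced measurements from a 10 keV beam
(lambda = hc/E, hc = 1.2398419 keV nm) at 3.2 m sample-detector distance:
q = (4 pi / lambda) sin(atan(r/L)/2) puts the default linear grid of 400
points on q in [0.05, 2.0] nm^-1 comfortably inside the detector reach.
Noise is additive Gaussian with counting-statistics scaling

    sigma_i = noise_rel * sqrt(I_i * median(I)) * sqrt(T_0 / T),

anchored so the median-intensity point has relative error `noise_rel`
(default 2%); T = n_frames * frame_time relative to the default 100 s total
exposure makes longer acquisitions proportionally quieter. High-count low-q
points are more precise and the weak high-q tail noisier, as in real
reduced data. Negative noisy intensities are clipped to a small positive
floor (logged). The stored sigma column is the generating one, and the
profile is deterministic per seed.

Five named parameter sets ("GV", "LM1".."LM4") span outer diameters
57.4–97.1 nm, multilayer fractions 0–0.72 and layer numbers 1.2–2.3, with
shared conventions: contrasts (0.2, 1.0, -1.0, 1.0) — a symmetric
polar/tail bilayer on a weak core, chosen because the recovery questions
concern geometry and stacking, which are identifiable independent of the
contrast gauge — repeat distance 6.3 nm, sigma/R = 0.2, scale 1 and
background 1e-7 (comparable to the envelope at q = 2 nm^-1, i.e.
well-subtracted data).

What the generator does **not** emulate: instrumental resolution smearing,
inter-particle interference at high concentration, radiation-damage frames,
capillary/buffer mis-subtraction structure, and Poisson (rather than
Gaussian) statistics at very low counts. Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to these real-data effects.

## Recovery harness and problem sizes

`recovery_study` simulates 20 seeded noisy profiles per parameter set
(consecutive seeds from a base seed) and refits each with core radius, all
four contrasts, multilayer fraction, stacking parameters (where present),
scale and background free — ten free parameters — using 2 multistarts per
fit (the deterministic scan start plus one jittered backup; medians over
20 seeds are insensitive to the occasional inferior local solution). A full
four-fixture study (80 fits, 400 points each) runs in a few minutes on one
CPU. Medians over seeds are reported; `scripts/acceptance.py` writes them
as JSON.

## Numerical choices and edge cases

- Sphere amplitude uses the series 1 - x^2/10 + x^4/280 below x = qR = 1e-2
  to avoid catastrophic cancellation; the q -> 0 limit is the sphere volume.
- The truncated-Gaussian size density renormalizes by the positive-half
  mass (erfc), so it integrates to 1 for any R_av/sigma.
- All-zero contrasts and contrast-matched particles raise typed errors.
- Profiles are validated on construction (finite, strictly increasing
  positive q, positive sigma); readers drop non-finite rows with a logged
  count, sort by q, reject duplicate q, and convert Angstrom^-1 input by
  the exact factor 10.
- Hemolysis readings below the negative control clip to 0% (physical
  floor, logged); values above the positive control are kept with a
  warning. Encapsulation efficiency rejects free > total as a calibration
  error rather than clamping.

## Known limitations

- Absolute-intensity calibration (e-/nm^3) is out of scope; contrasts are
  relative and the scale is arbitrary.
- The bump detector (quadratic log-log envelope over q in [0.4, 1.6] nm^-1,
  band ratio threshold 1.3) is calibrated for the default geometry and
  20% polydispersity; strongly oscillating low-polydispersity envelopes
  would need a different baseline model.
- Uncertainties are linearized-covariance estimates; they cover the truth
  at roughly the nominal rate in seeded replicates but are not a posterior.
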