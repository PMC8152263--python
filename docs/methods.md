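# Methods

`oildrop-rt` simulates how dispersed oil droplets change the ocean-color
signal of open-ocean (Case-1) waters. The chain has four stages: a
bio-optical water model parameterized by chlorophyll-a, a Lorenz–Mie
engine that turns oil optical constants and droplet size distributions
into bulk inherent optical properties (IOPs), a Monte Carlo
radiative-transfer solver that produces remote sensing reflectance
R_rs(λ) at 0⁺, and ocean-color analytics (band ratios, band differences,
color index) evaluated on the simulated spectra.

## Case-1 water model

Water IOPs are built additively from pure water, phytoplankton particles
and CDOM, all tied to the chlorophyll concentration Chl (mg m⁻³), assumed
vertically uniform:

* **Pure-water absorption** a_w(λ): the Pope & Fry clear-water
  tabulation, shipped as a packaged CSV at 5 nm resolution and linearly
  interpolated. Requests outside 400–700 nm fail loudly rather than
  extrapolate.
* **Pure-seawater scattering** b_w(λ) = b_w(550)·(550/λ)^4.32 with
  b_w(550) = 1.93×10⁻³ m⁻¹ (Morel's power law at oceanic salinity).
* **Particle absorption** a_p(λ) = A(λ)·Chl^E with the standard
  non-dimensional chlorophyll-specific absorption shape (unit value at
  440 nm, secondary maximum at 670 nm) scaled by 0.06 m⁻¹ and a constant
  exponent E = 0.65 — the classic Case-1 power law. A and E are packaged
  as a CSV table so other calibrations can be dropped in.
* **CDOM absorption** a_g(λ) = f_c·a_p(440)·exp(−S(λ−440)) with
  f_c = 0.2 and S = 0.014 nm⁻¹, the common Case-1 default tying dissolved
  organic absorption to the particle stock. All three constants are
  exposed in `WaterModelConfig`.
* **Particle scattering** b_p(λ) = 0.416·Chl^0.766·(λ/550)^v(Chl) with
  the Morel chlorophyll-dependent slope v = 0.5(log₁₀Chl − 0.3) clipped
  to [−1, 0] and v = 0 for Chl ≥ 2: clear water scatters more in the
  blue, green water is spectrally flat.
* **Phase function**: a scattering-weighted mixture of the pure-seawater
  shape (∝ 1 + 0.835 cos²θ) and a Fournier–Forand particle shape. The
  Fournier–Forand slope μ is solved (with relative index n = 1.08) so the
  particulate backscatter ratio equals the Case-1 law
  b_bp/b_p = 0.002 + 0.01(0.5 − 0.25 log₁₀Chl); the solve is done by
  bisection against the numerically integrated backscatter fraction, not
  the closed form, so a convention slip in the latter cannot bias it.
  All phase functions follow one convention repo-wide:
  ∫ p(θ)·2π sinθ dθ = 1, enforced to 10⁻³.

## Lorenz–Mie oil model

Single spheres are solved by the standard partial-wave series with the
logarithmic-derivative downward recursion (stable for absorbing spheres),
Riccati–Bessel functions of the real size parameter by upward recursion,
and truncation at n_max = ⌈x + 4x^{1/3} + 2⌉. The size parameter uses
the wavelength in the medium, x = πD·n_medium/λ_vacuum, with the real
saline-water index from the Quan–Fry empirical fit (35 PSU, 20 °C by
default). The medium is treated as non-absorbing in the Mie solution —
the salinity correction enters only through the real medium index — and
the oil's own k is used unmodified. The test suite cross-checks the
efficiencies against a second, independently coded series implementation
(explicit Bessel-ratio form) to 10⁻⁶ relative.

Polydisperse suspensions: the volume size distribution (ppm/µm over
diameter bins) is converted to number densities via the bin volume
πD³/6; absorption and scattering coefficients are number-weighted sums
of single-sphere cross sections, and the suspension phase function is
the scattering-cross-section-weighted mean of single-sphere phase
functions. Coefficients are exactly linear in the total ppm. The angle
grid is 0–180° at 0.5° with logarithmic refinement below 5°, because the
forward diffraction peak dominates sampling accuracy.

## Synthetic oil archetypes

Measured optical constants for the three oils the package emulates
(a biodiesel BD, a cylinder lubricant CL, a North Sea crude FL) are not
publicly deposited, so `oildrop.oils` generates synthetic surrogates
with the same statistical structure:

* real index: 4th-order polynomial of wavelength confined to
  [1.45, 1.53] (well above seawater's ~1.34), normal dispersion. BD
  carries the lowest index and the steepest dispersion of the three
  (≈1.49 in the blue to ≈1.45 in the red); since droplet backscatter
  scales roughly with (n_rel − 1)², that tilt makes BD's backscattering
  distinctly blue-weighted, which is the trait behind its green-to-red
  ratio signature;
* imaginary index: exponential decay for CL and FL with the FL amplitude
  exactly 100× CL (a strongly absorbing crude vs. a clear refined
  product); a three-bump shape for BD with maxima near 435, 520 and
  655 nm;
* size distributions: 2–3-mode log-normal volume distributions with the
  main density mode at 5 µm (BD, FL) or 7 µm (CL), geometric widths near
  1.5, and negligible volume above 100 µm. Modes are parameterized by
  the peak of dV/dD (the log-normal median is shifted by exp(ln²σ_g) so
  the density peak lands on the nominal diameter).

The numeric amplitudes were calibrated once, before the acceptance runs,
against the qualitative structure reported for these oils at 1 ppm in
clear ocean water: FL absorption impact far above BD ≈ CL (tens of
percent of the water total vs. a few percent), scattering impacts of all
three comparable and large (~0.4–0.7 m⁻¹ at 1 ppm, i.e. most of the
mixed-layer scattering in oligotrophic water), and the distinct
fold-change patterns of the three oils across blue/green/red bands.
They are surrogates and are labeled as such in the code; they do not
reproduce the original laboratory spectra. `jitter_template` provides
seeded ≤10% perturbations for robustness sweeps.

## Monte Carlo radiative transfer

Plane-parallel, horizontally homogeneous geometry; z positive downward.
Per wavelength, photons are launched from above the surface as a direct
beam at the sun zenith angle (default 30°) plus a diffuse fraction drawn
from a cardioid sky radiance (1 + 2cosθ), with the diffuse fraction
following a smooth spectral curve from 0.35 at 400 nm to 0.15 at 700 nm
(configurable; R_rs from a nadir receiver is weakly sensitive to this
split). The rough surface is an isotropic Cox–Munk facet model: slope
components are Gaussian with total variance 0.003 + 0.00512·W, refraction
and unpolarized Fresnel reflection are evaluated on the sampled facet,
and reflected-but-still-moving-down (or up) photons re-test a new facet.
Photons reflected at the interface on entry never enter the water and are
excluded from R_rs by construction (tagged surface-lost).

In water, path lengths are sampled against the local beam attenuation
c = a + b with exact layer-crossing bookkeeping (two layers when oil is
present: oil+water in the mixed layer, clean water below). Transport is
weighted (semi-analog): at each interaction the weight is multiplied by
the single-scattering albedo and the absorbed part tallied; the
scatterer component (water vs. oil) is chosen proportionally to its
share of b, and the scattering angle is drawn from that component's
phase function by inverse-CDF lookup on an 8192-entry cos θ quantile
table. Russian roulette terminates histories below weight 10⁻⁴ with
survival probability 0.1; the compensating weight is injected into or
withdrawn from the column-absorption tally so the four-way energy budget
(absorbed in column, absorbed at bottom, water-leaving, surface-lost)
sums to the launched weight exactly, not just in expectation. The bottom
at 1000 m reflects specularly with probability 0.02 and Lambertian with
0.08 (absorbing otherwise); at that depth no photon reaches it in any
scenario studied, which the suite verifies by perturbing the bottom
albedo.

The receiver is nadir-viewing just above the surface: photons that
refract out of the water within the receiver half-angle (default 3.5°)
of zenith accumulate into the radiance tally, and
R_rs = ΣW_cone/(N·ΔΩ) with ΔΩ = 2π(1 − cos α). The downwelling
irradiance normalization is the launched photon flux itself. Standard
errors come from per-photon contribution statistics and scale as
n^{−1/2} (verified). Runs are bit-for-bit reproducible for a fixed seed;
per-wavelength seeds are derived from the scenario seed.

### Receiver width for sign checks

The 3.5° receiver matches field radiometers and is used for the
quantitative color-index comparisons. For the 12-cell directional
screening (orderings and signs of metric changes), the package's default
configuration widens the receiver to 15° and boosts red-band photon
budgets 4×: near-nadir upwelling radiance varies slowly over that cone,
so the widening trades a negligible bias for an ~18× variance reduction
exactly where clear-water R_rs is smallest. These choices were fixed
from predicted counting statistics, not adjusted afterwards.

## Problem sizes

Desk-scale defaults: 10⁶ photons per wavelength for exploratory runs,
10⁷ for the color-index comparisons, 3×10⁵ (×4 on red bands) per cell
for the 12-cell directional grid on a reduced 8-band set
{410, 440, 490, 550, 555, 560, 670, 680} nm. A `full_scale` flag raises
the budget to 2×10⁹ photons per wavelength for full-fidelity runs. At
10⁷ photons the Monte Carlo standard error of the oligotrophic color
index is ~0.1×10⁻³ sr⁻¹, small against the ±30% comparison band.

## What the synthetic data do and do not show

The templates reproduce the *class structure* of the three oils (which
absorbs, which scatters, where the size modes sit), so passing tests
demonstrate that the pipeline propagates those structural differences
into the documented ocean-color signatures. They do not validate the
exact magnitudes of any published fold change or percentage table —
those depend on the original laboratory spectra — and the unpolluted
color-index comparison is therefore the only quantitative bridge to
published numbers. Raman scattering, fluorescence, polarization,
whitecaps and Case-2 (sediment-dominated) waters are out of scope; the
vertical chlorophyll profile is uniform; droplets are homogeneous
spheres (no emulsions or coatings).

## Numerical notes and edge cases

* Additivity of a_tot and b_tot is exact (same arrays, no re-fit).
* The Fournier–Forand θ→0 singularity is integrable; the tabulated value
  at 0° is extended from the first finite node, and phase functions are
  renormalized after construction.
* A pure absorber (b = 0) yields R_rs = 0 exactly and a zero standard
  error — the one case where stderr is not positive.
* Band lookups accept the nearest grid band within 5 nm (so 443-nm
  requests resolve to a 440 or 445 nm band); anything farther raises.
* A band ratio with a non-positive denominator returns NaN with a
  warning instead of raising, since Monte Carlo red-band estimates can
  legitimately be zero at tiny budgets.
* The eutrophic threshold between trophic classes is Chl = 1.67 mg m⁻³;
  class labels are informational and do not alter any physics.
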