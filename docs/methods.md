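# Methods

This package implements the computation chain that links spectral
irradiance measured below forest canopies to the leaf epidermal UV-A
absorbance (flavonol index, I_flav) of the understorey plant community.
Because the kind of field dataset it targets is rarely deposited, the
package ships a first-class synthetic generator that emulates the
measurement design, so the entire chain is exercised and tested end to
end without any external data.

## Spectra and band integration

Spectra are stored on their measured grid as photon spectral irradiance
(µmol m⁻² s⁻¹ nm⁻¹); energy spectra (W m⁻² nm⁻¹) are converted with
N(λ) = E(λ)·λ/(h·c·N_A) using CODATA constants.  Wavebands are
half-open `[lower, upper)` — UV-B [280, 315), UV-A [315, 400),
PAR [400, 700) — so adjacent bands partition the spectrum at the shared
315 and 400 nm boundaries.  Band integrals use the trapezoid rule with
virtual samples linearly interpolated exactly at the band edges; this
makes UV-B + UV-A equal the [280, 400) integral to rounding error and is
checkable against closed-form integrals of polynomial spectra.  Negative
ingest values are clipped to zero and counted rather than rejected:
calibrated field spectra routinely carry small negative UV-B noise.
The canonical analysis range is 280–900 nm; the generator uses a 0.5 nm
grid, a typical post-calibration array-spectroradiometer step.

## Weighting functions and doses

Biological spectral weighting functions (BSWFs) are normalised to
w = 1 at 300 nm (the community convention; the anchor is configurable)
and vanish outside their domain:

* **PG** (plant growth), the Flint–Caldwell exponential closed form,
  nonzero up to 390 nm;
* **GEN(G)** (generalised plant action spectrum, Green formulation),
  2.618·[1 − (λ/313.3)²]·exp(−(λ−300)/31.08), zero at and above
  313.3 nm;
* **FLAV** (flavonoid accumulation), a tabulated node table with linear
  interpolation.  The shipped node table is a **synthetic stand-in**
  with the literature's qualitative shape (monotone decline from the
  UV-B through the UV-A); swap in a transcribed table via the registry
  to reproduce a specific published spectrum.

An effective dose is the trapezoidal integral of w(λ)·E(λ) with the
weight evaluated on the spectrum's own grid — measured values are never
resampled.  Doses are reported in weighted-photon units (µmol m⁻² s⁻¹).
Internal consistency is tested against an independent 0.01 nm midpoint
Riemann sum (agreement to 1e-4 relative).  The red:far-red ratio uses
the conventional 10 nm bands, 655–665 over 725–735 nm.

## Thermal seasons and weather covariates

Season starts are defined from daily mean temperature: spring
continuously above 0 °C, summer above +10 °C, autumn below +10 °C,
winter below 0 °C.  "Continuously" is operationalised as a run of at
least N consecutive days (default N = 5; N is reported in the output).
Spring → summer → autumn form a strict sequence because the cold-side
thresholds are implied by the warm-side ones (a −5 °C day also
satisfies "below +10 °C"); winter is searched after the last assigned
start, or from the beginning of the series when no warm season ever
establishes, so a year that never thaws is winter throughout.

Covariates per DOY: days post snowmelt (first spring snow-free day
followed by ≥ K snow-free days; K = 7 default), days prior to the first
marked snowfall (≥ 1 cm persisting ≥ K days, searched from autumn),
days from the growing-season (spring) start, and the effective
temperature sum Σ max(0, t_mean − T_base) from the spring start.
T_base defaults to +5 °C, the standard Fennoscandian degree-day base;
both 0 and +5 °C are defensible, so it is a configuration knob.

## Community-weighted means and group tests

The CWM at a measurement point and date is Σ p̃_s · mean(I_flav of
species s), where species means are computed per point and date
(matching the design's "for each measurement point on each DOY") and
the abundances p̃_s are renormalised over the species actually measured
that day, keeping the CWM a proper mean bounded by the species means.
Stand contrasts per DOY use one-way fixed-effects ANOVA; leaf-side
style contrasts use Welch's t by default (stand-to-stand variance
heterogeneity is expected; pooled t by flag) or the Wilcoxon rank-sum
test (exact enumeration for n ≤ 20 without ties, tie-corrected normal
approximation otherwise).  A sample with all values tied returns p = 1
by convention.  No multiple-testing correction is applied across the
per-DOY ANOVA family — deliberately, to match the analysis convention
this pipeline mirrors; treat the per-day p values accordingly.

## Loess trends and CI overlap

Local regression uses tricube weights and a local polynomial of degree
2 (the default of the classical loess implementation).  For span α ≤ 1
the bandwidth at x₀ is the distance to the ⌈αn⌉-th nearest point; for
α > 1 every point is used with the bandwidth inflated to α times the
largest distance.  The fit at x₀ is a linear functional l(x₀)'y, so the
pointwise standard error is σ̂·‖l(x₀)‖ with σ̂² = RSS/δ₁ and
δ₁ = n − 2·tr(L) + tr(L'L) the trace-based residual degrees of freedom;
intervals use t quantiles on δ₁.  This equivalent-kernel construction
is one of several loess CI conventions; it was chosen because it is
reproducible from first principles and testable: simulated pointwise
coverage for a linear truth is 93–97% over 1000 replicates.  Two trends
"differ" at x when their 95% bands fail to overlap (strict
inequalities), evaluated on a shared integer-DOY grid; contiguous
non-overlap runs are reported as DOY intervals.  CI-overlap is a
conservative screen, not a formal test.

## Feasible GLS with compound symmetry

The irradiance–I_flav models use generalised least squares with a
compound-symmetry (CS) block covariance Σ_g = σ_k²[(1−ρ)I + ρJ] within
groups (e.g. the repeated DOYs at one measurement point) and residual
SDs σ_k optionally varying by stratum (e.g. stand).  Estimation is
moment-based feasible GLS rather than REML: alternate (i) the GLS solve
for β given (ρ, σ_k), using the closed-form CS inverse per block, and
(ii) moment updates — σ_k² from stratum residual mean squares, ρ from
the mean within-group cross-product of standardised residuals over
their pooled variance, clipped into (−1/(m−1)+ε, 1−ε).  Moment updates
are not guaranteed to increase the Gaussian likelihood, so an update
that would decrease it is rejected and iteration stops; the likelihood
path is therefore non-decreasing by construction.  Convergence is a
maximum parameter change below 1e-8 (at most 100 iterations; in
practice fewer than 20).  AIC = −2ℓ + 2(p + #σ + [CS]) at the final
parameters; model selection over candidate correlation/variance
structures takes the lowest AIC with ties broken toward fewer
parameters.  The reported pseudo-R² is corr(fitted, observed)² — a
descriptive quantity, not a variance decomposition.  The
independence/homoscedastic structure reduces exactly to OLS.

## The synthetic campaign

The generator's defaults are the study conditions: 5 stands (three
birch stands differing in canopy density and leaf-out timing, a
late-flushing oak stand, and an evergreen spruce stand with constant
PAI 4.2), 4 points per stand, campaign DOYs 115/144/156/202, three
understorey positions, a 35-species community with ~14 species per
stand, and 4 plants per species × point × day.

* **Solar template** — a smooth photon-irradiance envelope × an
  exponential UV decline × a logistic ozone cut-on whose midpoint
  shifts to longer wavelengths with slant path (so the UV-B:UV-A ratio
  falls as the sun drops).  The amplitude is calibrated so open-field
  midsummer-noon integrals sit at boreal magnitudes: PPFD ≈ 1.39 mmol,
  UV-B ≈ 0.1% of PPFD, UV-A ≈ 113 µmol m⁻² s⁻¹.  It is a parametric
  template, not radiative transfer: only band magnitudes and ratios are
  meant to be plausible, not spectral fine structure.
* **Canopy filters** — sunfleck: near-neutral exp(−0.06·PAI); shade:
  Beer–Lambert exp(−k(λ)·PAI) with k lowered in the UV (diffuse
  skylight is UV-rich) and above 690 nm (foliage transmits far-red), so
  shade is UV-enriched and R:FR-depressed; leaf: shade × a one-leaf
  transmittance (low UV/PAR, green bump, high NIR).  At PAI = 0
  sunfleck and shade are exactly the open spectrum.  Point-to-point
  spread is a neutral lognormal factor, much larger for sunflecks
  (σ = 0.45) than shade (σ = 0.10), reflecting sunfleck-size variation.
* **Weather** — sinusoidal daily mean (mean 3.5 °C, amplitude 13.5 °C,
  peak DOY 199) + AR(1) noise (φ = 0.7, sd 2.5 °C); fixed half-ranges
  give t_min/t_max; snowpack follows a deterministic
  accumulation/melt envelope driven by the deterministic temperature.
* **Response model** — I_flav = β₀(species) + β_UVA·D_UVA(shade, stand,
  DOY) + γ·max(0, T_cold − t_min) + b_point + ε, with β_UVA = 0.02 per
  µmol m⁻² s⁻¹ (keeping I_flav within the optical clip's 0–3 range
  across the planted dose range), γ = 0.012 °C⁻¹, T_cold = 5 °C,
  σ_point = 0.06, σ_e = 0.08 (point-level intraclass correlation
  ≈ 0.36).  Planted values are written to `truth.json` for recovery
  tests.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: penumbral sunfleck geometry and diurnal
sunfleck duration, canopy spectral fine structure, species-specific
dose responses or phenology, leaf-age and leaf-side structure (all
records are mature adaxial leaves), measurement-device error structure,
and year-to-year weather contrasts.  The generator's role is to give
every downstream statistic a known truth under the design's dimensions,
not to reproduce any particular field campaign's values.

## Problem sizes and numerics

Simulation-backed checks use sizes chosen to make Monte-Carlo error
comfortably smaller than the tolerance they check: loess coverage with
1000 replicates of n = 30; GLS recovery with 200 surveys of 20 groups
× 8 observations; structure selection over 100 replicates; the
campaign-level correlation ordering over 100 seeds.  Dose oracles use a
0.01 nm midpoint Riemann sum; degenerate inputs (zero variance, all
ties, empty band overlap, rank-deficient designs) return typed nulls or
raise with explicit messages as documented per function.
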