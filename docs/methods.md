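# Methods

This note documents the models, numerical choices and limitations behind
`costark`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic tests do and do not demonstrate.

## Spectral containers and file formats

A `Spectrum` stores absorbance on a strictly ascending, uniform wavenumber
grid (≥ 16 points, spacing jitter < 1e−6 relative) with electrode potential
(mV), reference-electrode label and optional temperature as metadata. A
`SpectralSeries` stacks spectra on one shared grid with strictly monotonic
potentials — the shape of a stepped titration (default emulation: 25 mV steps
from −500 to +550 mV, 2 cm⁻¹ resolution).

CSV files carry `#`-prefixed `potential_mV=`/`reference=`/`temperature_K=`
lines and two columns. The JCAMP-DX writer/reader supports only the
`XYDATA=(X++(Y..Y))` dialect with XFACTOR/YFACTOR scaling; the writer picks
YFACTOR = max|y|/1e8, so round trips are exact to ~5e−9 of the full scale
(the stated 1e−6 bound has a large margin for absorbance-scale data). Reads
normalize descending grids to ascending.

## Baseline filter

The baseline correction removes spectral components broader than a cutoff
width Γc (default 150 cm⁻¹). Realization: the spectrum is mean-detrended and
mirror-extended (to kill the wrap-around discontinuity), transformed by FFT,
and the baseline is rebuilt from the Fourier modes whose half-wavelength on
the extended grid exceeds Γc; subtracting it leaves the narrow-band content.

This is an orthogonal projection, chosen deliberately over a soft
(exponentially weighted) roll-off: a projection is exactly linear, exactly
idempotent and removes a constant to machine precision, which makes the
filter's interaction with downstream linear fits predictable. The trade-off
of any such filter is fundamental: for a Lorentzian of FWHM Γ the fraction of
peak amplitude carried by the low-order modes scales like π·Γ/(2·Γc), so an
8 cm⁻¹ band on an 800 cm⁻¹ window retains ≈ 92–93 % of its amplitude while a
300 cm⁻¹ background is suppressed to ≈ 5 %. One can show (the retained
fraction is linear in the mode weights, so the optimum is a hard cutoff) that
no Fourier-weighting filter can simultaneously keep ≥ 95 % of an 8 cm⁻¹ band
and ≤ 10 % of a 300 cm⁻¹ band; the projection here sits at the Pareto corner
favoring background rejection. Because the filter is linear, the uniform
few-percent amplitude loss rescales fitted band areas but leaves band centers
and all midpoint potentials unchanged.

## Difference → absolute transformation

Titration spectra are recorded against a fully reduced background, so CO
bands appear as depletions. Subtracting the mean of the spectra inside an
oxidizing window (+500…+550 mV by default, where CO has dissociated and the
bands are absent) re-references the series to the oxidized state and makes
band areas track species populations directly. Window membership compares
potentials rounded to 0.1 mV, inclusive on both ends; potentials are discrete
set points, not ranges.

## Band model and shared-shape fit

Bands are pseudo-Voigt: η·Lorentzian + (1−η)·Gaussian of equal FWHM, unit
area, η = 0.2 by default (a 20/80 Lorentzian/Gaussian mixture). The "Voigtian
percentage" reading as an η-mixture is the standard pseudo-Voigt
parameterization; true Voigt convolution is out of scope.

The series fit has two phases. Phase 1 optimizes one (center, FWHM) per band
jointly over all spectra in the window (default 1950–1980 cm⁻¹) with bounded
trust-region least squares; the per-spectrum areas are eliminated at every
objective evaluation by non-negative linear least squares (variable
projection), so the optimizer sees only 2 parameters per band and is
deterministic — no random restarts. η is held at its seeded value. Phase 2
freezes the shapes and refits non-negative areas per spectrum; standard
errors come from σ²(AᵀA)⁻¹ with σ² the per-spectrum residual variance.
Initialization comes from `peak_pick` (local maxima above 3× a robust MAD
noise estimate, FWHM from the half-height crossing); bands ~3.5 cm⁻¹ apart
with ~4 cm⁻¹ FWHM sit at the resolution limit and may merge into one seed,
so manual seeding is supported everywhere. Bands whose fitted centers
approach within 0.1×FWHM are flagged as collapsed. Areas are parameterized
directly (the traces of interest are integrals, not heights). A per-spectrum
linear baseline can be co-fit but is off by default, since the Fourier filter
normally precedes fitting.

## Redox model and fits

The reduced fraction of one couple is 1/(1 + exp(n F (E − E_m)/RT)) with
RT/F = 25.693 mV at 298.15 K. The three-state populations are
Boltzmann-weighted sequential equilibria, x ∝ (1, a₁, a₁a₂) with
aᵢ = exp(nᵢF(E−E_m,i)/RT), computed as a log-domain softmax so they sum to 1
to machine precision at any potential. The apparent electron number n is a
free parameter bounded to [0.5, 4]: measured transitions convolve
multi-electron steps, so the fitted slope is not forced to a physical
electron count. Potentials are stored against the declared reference
electrode (Ag/AgCl in the emulated experiment); conversion to SHE
(+210 mV, configurable) is applied only on explicit request.

Trace fits are weighted least squares (inverse variance when band-fit
standard errors are available) of amplitude × population + offset, with
asymptotic standard errors from the Jacobian covariance and an optional
seeded residual bootstrap (off by default; 100–500 resamples are typical) as
a cross-check. Each trace is fit independently by default. A single-sigmoid
fit of the first transition on a three-state trace carries a small (~0.1 mV
at midpoints 135 mV apart) structural bias from the second transition; the
`transient` two-transition fit of the intermediate trace is exact on
noiseless data.

`global_fit` is alternating least squares on the whole series: given
midpoints, species spectra are the linear least-squares solution of
data ≈ populations × spectra; given spectra, the midpoint/slope parameters
are refit with bounded least squares (ordering E_m,1 < E_m,2 enforced by
parameterizing the second midpoint as an offset ≥ 0); iterate until the
relative residual change is < 1e−8 or 200 iterations. Convergence is linear
(rate ≈ 0.8 on the default synthetic series, well inside the iteration cap).
Default initialization seeds the midpoints at the 25th/75th percentile
potentials. A population-matrix condition number above 1e8 aborts with advice
to widen the potential range. Any constant-in-potential background (e.g. the
synthetic baseline drift) is absorbed equally into all species spectra
because populations sum to one; midpoints are unaffected.

## Vibrational Stark conversion

ΔE = Δν·f/|Δμ|₀ with |Δμ|₀ = 2.4 cm⁻¹/(MV/cm) for heme-bound CO and local
field correction f = 2.0 by default; both are parameters with provenance
recorded in CLI output, since f in particular is an approximate literature
value. A blueshift maps to a positive field change along the C→O axis — the
sign convention is declared (not inferred) and stated in all outputs. The
conversion is exactly linear; |Δν| > 20 cm⁻¹ triggers a warning because the
single-parameter linear regime is no longer trustworthy there.

## Electrostatics

Unit system: charges in e, distances in Å, fields in MV/cm, with
k = e/(4πε₀) = 14.39964 V·Å, i.e. 1439.964 MV·Å²/(cm·e). The dielectric is
homogeneous (ε_r = 4.0 by default) — appropriate when the probe sits deep in
the protein/membrane interior far from bulk water — with no
distance-dependent screening. The evaluation point is the geometric C–O
midpoint; the projection axis p runs from C to O. Field changes between
charge states equal, by superposition, the field of the charge-difference
distribution; the transition report exploits this so that sums of disjoint
transition rows reproduce the combined transition to numerical precision.

CO placement: idealized linear geometry (Fe–C–O 180°, d(Fe–C) = 1.70 Å) or
bent (169°, d(Fe–C) = 1.67 Å, bend direction given by an in-plane vector);
d(C–O) = 1.13 Å by default (a standard bound-CO bond length; configurable).
PDB files are read with gemmi (first altloc kept, dropped count logged,
insertion codes preserved); PQR files (whitespace dialect, with or without a
chain column) also supply a base charge state. Crystal waters present in the
input are treated as ordinary atoms and never re-optimized.

The worked-example transition table used in tests and in the acceptance
script is a *calibrated synthetic* charge set: per transition group, one
charge site per probe geometry, with site charges solved from a small linear
system so the group's projected field change equals a given target value at
every probe. This exercises the full engine (placement, fields, projections,
superposition, sums) against externally specified per-group values without
requiring the unpublished per-atom charge sets of the original structures.

## Synthetic generator: what it does and does not emulate

The generator produces the study conditions: two pseudo-Voigt CO bands at
1963.7 and 1967.2 cm⁻¹ (FWHM 4.0 cm⁻¹, η = 0.2, maximum area 0.1 AU·cm⁻¹)
whose areas follow the R₄CO and R₂CO populations of a three-state model with
midpoints +102/+237 mV (n = 1), on a 25 mV grid from −500 to +550 mV and a
2 cm⁻¹ wavenumber grid spanning 1800–2100 cm⁻¹. Noise is additive i.i.d.
Gaussian per point, sd 4.4e−4 AU (peak SNR ≈ 50, matching visually clean
experimental bands); the baseline drift is a broad Lorentzian (amplitude
2e−3 AU, FWHM 300 cm⁻¹) identical in every spectrum. Difference series share
one noise realization for the background, mimicking a single measured
reference. Generation is fully reproducible from the scenario seed.

Not emulated: the protein fingerprint region and its band assignments,
H₂O/D₂O differences, CO binding/unbinding kinetics, electrode double-layer
or mediator effects, potential-dependent band-shape changes within a
species, and correlated (1/f, fringe) instrument noise. Consequently,
passing recovery tests demonstrates that the estimators are unbiased and
consistent under the stated noise model at the stated SNR — not that real
spectra with structured backgrounds would yield the same uncertainties.
Measured midpoint uncertainties (±11/±6 mV scale) derive from instrument
data and are not reproduction targets; the suite instead checks |bias| <
3 mV over 20 seeded replicates and sub-mV agreement between the sigmoid and
global fits on noiseless data.

## Numerical choices and degenerate inputs

- NNLS enforces area ≥ 0 exactly; standard errors use the unconstrained
  covariance, which is accurate whenever no area sits on the bound.
- Sigmoid fits refuse constant traces (< 1e−12 relative span) and warn when
  a fitted midpoint falls outside the sampled potential range.
- Population evaluation clips exponents at ±700 to avoid overflow; the
  softmax keeps the sum at 1 to < 1e−12 even at ±2 V.
- Field evaluation raises (naming the atom) if the probe point lies within
  1e−6 Å of a charged atom.
- The probe constructor verifies the achieved Fe–C–O angle to 0.01°, and the
  bent path at 180° reproduces the idealized placement to < 1e−9 Å.

## Known limitations

- The dielectric is a single constant; no Poisson–Boltzmann screening,
  polarizability or explicit-solvent response. Computed field changes are
  therefore first-order Coulomb estimates.
- Hydrogen placement and charge-state-specific geometry optimization of real
  structures are out of scope; the electrostatics operates on whatever
  coordinates and charges are supplied.
- The pseudo-Voigt approximation and the shared-shape constraint assume
  potential-independent band shapes within a species.
- The baseline filter's narrow-band amplitude loss (few percent at
  8 cm⁻¹/150 cm⁻¹ cutoff) is uniform but not zero; quantitative absolute
  areas should be corrected or fitted with the filter response in mind.
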