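# costark

Analysis toolkit for quantifying local electric-field changes at a heme-bound
CO probe from FTIR spectroelectrochemical titrations, with point-charge
electrostatics to attribute those changes to redox and protonation events.

## Who this is for

Spectroscopists running *operando* ATR/FTIR redox titrations of heme–copper
oxidases (or any heme protein with a bound CO reporter), and modelers who want
to compare the measured vibrational Stark response with Coulomb field changes
computed from charged structures. The package covers the desk side of that
workflow end to end:

1. **Spectra** — read/write two-column CSV and JCAMP-DX `(X++(Y..Y))` spectra,
   remove broad baseline undulations with a Fourier low-pass baseline filter
   (cutoff 150 cm⁻¹ by default), and convert potential-resolved *difference*
   spectra into absolute species spectra by re-referencing against the
   oxidized-window mean (+500…+550 mV).
2. **Band deconvolution** — pseudo-Voigt components (20 % Lorentzian / 80 %
   Gaussian by default) with one shared center/FWHM/η per band across the
   whole series and free non-negative per-spectrum areas, giving
   area-vs-potential traces with standard errors.
3. **Redox titration** — Nernst sigmoids and a sequential three-state model
   (R₄CO → R₂CO → O) fitted to the traces, or a global alternating
   least-squares fit of the whole series, yielding midpoint potentials with
   uncertainties.
4. **Vibrational Stark effect** — the linear relation Δν = |Δμ|·ΔE with
   |Δμ| = 2.4/f cm⁻¹/(MV/cm) for heme-bound CO and local-field correction
   f ≈ 2 converts the fitted band shift into a field change along the C→O
   axis (and back).
5. **Electrostatics** — Coulomb fields `E(r) = k/ε_r · Σ qᵢ (r−rᵢ)/|r−rᵢ|³`
   (charges in e, distances in Å, fields in MV/cm, k = 1439.964 MV·Å²/(cm·e),
   ε_r = 4) evaluated at the C–O bond midpoint and projected on the C→O unit
   vector; CO probe placement in idealized linear (180°, d(Fe–C) = 1.70 Å) or
   bent (169°, d(Fe–C) = 1.67 Å) geometry; per-transition field-change tables
   with combined sums.
6. **Synthetic data** — a seeded generator producing titration series and toy
   charged structures with exact ground truth, so every stage above is
   testable without instrument data.

## The model in brief

Populations of the three enzyme states follow sequential Boltzmann equilibria

    x ∝ (1, a₁, a₁a₂),   aᵢ = exp(nᵢ F (E − E_m,i) / RT),

so a single couple is half-reduced at its midpoint E_m and the intermediate
R₂CO peaks between the two midpoints. Band areas are proportional to species
populations (Beer–Lambert), so fitted area traces are amplitude-scaled
population curves. The C≡O frequency reports the local field through the
linear vibrational Stark effect, and the computed counterpart of that field
change is the projected Coulomb field of the charge differences between the
named redox/protonation states.

## Worked example

```python
import costark as ck

scenario = ck.TitrationScenario(rng_seed=7)           # noisy synthetic titration
series = ck.generate_absolute_series(scenario)
series = series.map(lambda s: ck.fourier_baseline_filter(s, 150.0))
series = ck.difference_to_absolute(series, (500.0, 550.0))

seeds = [ck.PseudoVoigtBand(1963.0, 4.0, 0.2), ck.PseudoVoigtBand(1968.0, 4.0, 0.2)]
fit = ck.fit_shared_shape(series, seeds, window=(1950.0, 1980.0))
print(f"fitted centers: {fit.centers[0]:.2f}, {fit.centers[1]:.2f} cm^-1")

t1, t2 = ck.fit_sigmoid_trace(fit.trace(1), "transient")
print(f"E_m(R4CO->R2CO) = {t1.midpoint_mV:+.1f} +/- {t1.midpoint_se_mV:.1f} mV")
print(f"E_m(R2CO->O)    = {t2.midpoint_mV:+.1f} +/- {t2.midpoint_se_mV:.1f} mV")

delta_nu = fit.centers[1] - fit.centers[0]
field = ck.field_from_shift(delta_nu, ck.StarkProbe(2.4, 2.0))
print(f"blueshift {delta_nu:+.2f} cm^-1  ->  delta_E = {field:+.2f} MV/cm")
```

prints

```
fitted centers: 1963.69, 1967.16 cm^-1
E_m(R4CO->R2CO) = +97.4 +/- 1.1 mV
E_m(R2CO->O)    = +239.7 +/- 1.1 mV
blueshift +3.47 cm^-1  ->  delta_E = +2.89 MV/cm
```

The generator's ground truth is bands at 1963.7/1967.2 cm⁻¹ and midpoints
+102/+237 mV (vs Ag/AgCl): the pipeline recovers the band centers to a few
hundredths of a cm⁻¹ and the midpoints to a few mV at the default noise
level, and the 3.5 cm⁻¹ blueshift converts to a ≈ +2.9 MV/cm field increase
along the CO bond.

The same pipeline is available from the shell:

```
costark simulate --config scenario.yaml --out raw/
costark preprocess --in raw/ --out prep/ --filter-fwhm 150 --oxidized-window 500:550
costark fitbands --in prep/ --out fits/ --window 1950:1980 --bands 1963,1968
costark titrate --areas fits/areas.csv --mode sigmoid --out report/
costark stark --shift 3.5 --f 2.0
costark efield --structure model.pqr --states states.yaml --transition red:ox \
        --fe A/412/FE --axis 0,0,1 --angle 169 --eps 4.0
```

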