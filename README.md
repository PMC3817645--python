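# duospec

Dual-wavelength UV spectrophotometric quantification of
**5-hydroxymethylfurfural (HMF)** and **levulinic acid (LA)** in glucose acid
hydrolysate — for biorefinery researchers who want to follow HMF/LA formation
without chromatography.

Acid-catalyzed dehydration of glucose yields HMF, which rehydrates to LA.
Both absorb in the UV (HMF peaks at 284 nm, LA at 266 nm) and follow Beer's
law, so one spectrum determines both concentrations — once the colored
hydrolysis byproducts (a broad 350–450 nm band) are removed by boiling the
sample with activated charcoal. The package implements the full computational
chain:

1. **Calibration** — OLS fit A = a + s·C per analyte/wavelength; the slope is
   the molar absorptivity ε, and LOQ = (a + 10·|Δa|)/s with Δa the intercept
   standard error.
2. **Charcoal correction** — K = A_before/A_after compensates for analyte
   lost to the adsorbent (defaults K_HMF = 69.3, K_LA = 1.62).
3. **Dual-wavelength deconvolution** — exact solve of the 2×2 Beer's-law
   system A_λ = l·(ε_HMF^λ·C_HMF + ε_LA^λ·C_LA) at λ ∈ {266, 284} nm.
4. **Contents** — W = C·M·K·R (mg/L) in the original hydrolysate, with M the
   molecular weight and R the dilution factor.
5. **Validation** — spiked recovery (%) and relative standard deviation.

Because no instrument data ship with the method, a fully seeded **synthetic
spectra generator** (Gaussian analyte bands derived from the reference ε
values, a byproduct band, a charcoal adsorption model, and demo reaction
kinetics) stands in for the spectrophotometer; every inverse step is tested
against its forward model.

## Worked example

Simulate a hydrolysate spectrum from known concentrations (0.06 mmol/L HMF,
40 mmol/L LA, with byproduct band and photometric noise), apply the charcoal
treatment, and quantify the treated spectrum with the default constants:

```sh
duospec simulate spectrum --seed 7 --c-hmf 0.06 --c-la 40 --out demo
duospec run --spectrum demo/treated.csv
```

```
dual-wavelength quantification report
spectrum: treated.csv (401 points, 200-600 nm)
wavelengths: 266 nm / 284 nm
path length: 1 cm; dilution R = 1
constants[HMF]: eps(266)=12.38, eps(284)=22.7 mmol-1.L.cm-1; K=69.3; M=126.11 g/mol; LOQ=0.017 mmol/L
constants[LA]: eps(266)=0.023, eps(284)=0.014 mmol-1.L.cm-1; K=1.62; M=116.12 g/mol; LOQ=4.68 mmol/L
result[HMF]: C = 0.000620371 mmol/L; W = 5.42168 mg/L
result[LA]: C = 25.0188 mmol/L; W = 4706.41 mg/L
flags: below_loq:HMF
```

Reading the output: the LA content comes back within ~1.3 % of the generating
truth (40 mmol/L × 116.12 g/mol = 4644.8 mg/L). The HMF estimate is flagged
`below_loq:HMF`: after the 69-fold charcoal attenuation its treated-solution
concentration (0.06/69.3 ≈ 0.0009 mmol/L) sits under the 0.017 mmol/L limit
of quantitation, so the reported 5.4 mg/L (truth 7.57 mg/L) is an
order-of-magnitude indication, not a quantitative value — exactly what the
flag is for. The report echoes every constant used (ε, K, M, R, LOQ) so a run
can be audited line by line.

The same steps are available as library calls
(`duospec.render_spectrum`, `charcoal_treat`, `quantify_sample`,
`fit_line`, `loq`, `recovery_table`, …); see the docstrings and
`docs/methods.md` for the model details and design choices.

Other subcommands: `duospec calibrate` (fit a calibration CSV),
`duospec validate` (recovery/RSD report), `duospec quantify`
(single-spectrum quantification with explicit constants),
`duospec simulate calibration|series`.

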