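# Methods

## The measurement problem

Acid hydrolysis of glucose (hot dilute H₂SO₄) produces 5-hydroxymethylfurfural
(HMF) as an intermediate and levulinic acid (LA) as the end product, alongside
colored condensation byproducts. Both analytes absorb in the UV — HMF peaks at
284 nm, LA at 266 nm — and each obeys Beer's law at both wavelengths, so a
single spectrum of the hydrolysate contains enough information to quantify the
pair simultaneously, provided the byproduct interference (a broad band between
350 and 450 nm that leaks into the analytical region) is first removed by
adsorption onto activated charcoal.

## Model and procedure

**Calibration.** For each analyte and wavelength, absorbance is regressed on
concentration by ordinary least squares with intercept, A = a + s·C. With a
1 cm cell the slope s is the molar absorptivity ε (mmol⁻¹·L·cm⁻¹). The
reference constants used throughout are ε_HMF = 12.38 / 22.7 and
ε_LA = 0.023 / 0.014 at 266 / 284 nm. Δa is taken to be the standard error of
the intercept; the source equations print "(±…)" without saying whether it is
an SE or a confidence half-width, and we adopt the conventional SE reading
(both readings reproduce the published LOQs after rounding). The limit of
quantitation is

    LOQ = (a + 10·|Δa|) / s ,

using the **signed** intercept exactly as the formula is written; taking |a|
instead would round to the same published values (0.017 mmol/L for HMF at
266 nm, 4.68 mmol/L for LA at 284 nm), so the choice is documented rather than
silently made. The published lines report n = 6 while only five standards are
listed (possibly a blank was included); the fitter accepts any n ≥ 3 and never
hard-codes n.

**Charcoal correction.** Charcoal removes the byproducts but also adsorbs part
of each analyte. The correction coefficient K = A_before / A_after, measured
on pure standards at each analyte's peak wavelength, compensates for that
loss; the reference values are K_HMF = 69.3 and K_LA = 1.62. K_HMF = 69.3
implies ≈98.6 % of the HMF is lost to the adsorbent, leaving a near-zero
signal; the magnitude is physically surprising but is taken at face value as
the default constant (it is config-overridable everywhere).

**Dual-wavelength solve.** The treated sample's absorbance at the two
analytical wavelengths is the classical-least-squares superposition

    A_λ = l · (ε_HMF^λ · C_HMF + ε_LA^λ · C_LA),  λ ∈ {266, 284} nm.

The published rendering of this system scrambles some sub/superscripts
(pairing an LA absorptivity with C_HMF and dividing by the wrong ε in the
back-substitution); those forms contradict Beer's law, and the system above is
the only physically consistent reading. The 2×2 system is solved exactly
(`numpy.linalg.solve`); singularity is guarded by a determinant check scaled
to the entry magnitudes (|det| > 1e-12 × largest entry product). Negative
solved concentrations — legitimate near the LOQ under noise — are clamped to
zero and flagged (`negative_clamped`) rather than treated as errors.

**Contents.** The concentration in the original hydrolysate is recovered as

    W = C · M · K · R   [mg/L],

with M the molecular weight (M_HMF = 126.11, M_LA = 116.12 g/mol — standard
constants, overridable) and R the dilution factor carried on the spectrum.

**Validation statistics.** Recovery = 100 × measured/added, reported to the
nearest integer percent as validation tables conventionally print it (full
precision is retained programmatically). RSD uses the sample (n−1) standard
deviation; the source does not specify the denominator.

## Synthetic data generator

No instrument data accompany the method, so the `synthetic` module is the
testbed: it renders spectra from known concentrations so every inverse step
can be checked against ground truth.

* **Analyte bands** are Gaussians ε(λ) = ε_peak·exp(−(λ−center)²/(2σ²)) — the
  minimal smooth two-parameter shape fixed by the two absorptivity constraints
  per analyte. The widths are derived, not tuned: σ_HMF = 18/√(2·ln(22.7/12.38))
  ≈ 16.35 nm and σ_LA = 18/√(2·ln(0.023/0.014)) ≈ 18.06 nm, so the default
  bands reproduce all four reference ε values at 266/284 nm to < 1 % relative.
* **Byproduct interferent**: one broad Gaussian centered at 400 nm with
  σ = 30 nm (covering the 350–450 nm window), default amplitude 0.5 AU — a
  mid-scale absorbance typical of a visibly colored hydrolysate.
* **Noise**: additive Gaussian with default sd 0.005 AU (a typical
  photometric noise floor of a scanning single-beam instrument), truncated so
  total absorbance stays nonnegative. No noise model was reported for the
  original instrument.
* **Charcoal model**: at dosage d (g/mL) the byproduct is scaled by
  max(0, 1 − d/0.1) — complete removal at and above the 0.1 g/mL operating
  dosage — and each analyte by the linear interpolation between factor 1 at
  d = 0 and 1/K at d ≥ 0.1. Only the endpoint behavior is established; the
  linear interior is the minimal assumption. The renderer stores each
  spectrum's per-species decomposition so treatment can act species-wise;
  measurement noise passes through treatment unchanged, making dosage 0 an
  exact identity.
* **Kinetics** (demo only): consecutive first-order glucose → HMF → LA in
  closed form, with the k1 = k2 limiting form handled explicitly. Defaults
  k1 = 0.10 min⁻¹, k2 = 0.012 min⁻¹ place the HMF maximum at
  t* = ln(k1/k2)/(k1−k2) ≈ 24 min for a 3 g / 50 mL glucose charge
  (G0 ≈ 333 mmol/L), matching the qualitative time-course profile. No rate
  constants were ever measured for the real system; this component exists
  only to drive demonstrations and stress tests and is never an assertion
  target.

What the generator does **not** emulate: wavelength-dependent stray light,
baseline drift, detector nonlinearity at high absorbance, charcoal dosage
dependence of K, or matrix effects of the acid. Passing tests therefore
demonstrate the correctness of the computational chain, not the field
performance of the wet-lab procedure.

## Numerical choices

* All randomness flows from a single integer seed per generator call
  (`numpy.random.default_rng`); identical configs give identical outputs.
* Spectrum CSVs are written with shortest exact float representation, so a
  read → write → read cycle is bit-identical.
* Single-wavelength readings use linear interpolation on the sampled grid
  with no extrapolation; exact grid hits return stored values.
* The 2×2 solve recovers forward-constructed concentrations to vector-relative
  error below 1e-9 over the calibrated ranges ([0, 0.1] mmol/L HMF,
  [0, 65] mmol/L LA); tests cross-check it against an iteratively refined
  grid-search least-squares oracle and hand-written Cramer's rule.
* An overdetermined (> 2 wavelengths) least-squares extension was considered
  and left out: the method is defined at exactly two wavelengths, and the
  2×2 exact solve keeps the error model transparent.
* Test problem sizes (1,000 round-trip pairs, 200 calibration replicates,
  12 pipeline replicates) were chosen as comfortably large for the statistics
  they support while keeping the default suite fast.

## Known limitations

* The published repeatability figures (RSD 4.47 % for HMF, 2.25 % for LA) and
  the reaction time-course table cannot be recomputed: the replicate
  measurements and raw instrument data behind them were never printed (the
  time-course is reported in grams per batch with an unstated conversion).
  The test suite covers the same machinery with synthetic surrogates instead.
* Two cells of the published recovery table are arithmetically inconsistent
  with their own added/measured columns (123→144 μmol prints 116 % where
  100·144/123 = 117.1; 165→173 μmol prints 104 % where the quotient gives
  104.8), and the stated LA recovery maximum of 105 % conflicts with the
  table row computing to 108 %. These are flagged in tests as documented
  discrepancies, not "fixed".
* With K_HMF = 69.3, the post-treatment HMF signal sits near the noise floor;
  quantification of HMF after full charcoal treatment is accordingly noisy
  (the pipeline flags it `below_loq` where appropriate), which is a property
  of the method's own constants, not of this implementation.
* The JCAMP-DX reader supports only single-block `XYDATA=(X++(Y..Y))` files
  with plain (AFFN) numbers — the common instrument export — not the full
  compressed format family.
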