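# Methods

`redoxscan` re-implements, as a tested pipeline, the analysis of
low-temperature two-channel fluorescence ("redox scanning") data: raster
scans of the oxidized-flavoprotein (Fp, including FAD) and NADH
autofluorescence of milled frozen-tissue surfaces, used to quantify the
mitochondrial redox state of tissue and its spatial heterogeneity.  This
note records the models, the numerical choices, and what the synthetic
phantom does and does not emulate.

## Calibration model

Raw counts are converted to *nominal concentrations* by a one-point linear
calibration against the in-scan reference standard of the matching
fluorophore:

    C(x) = C_ref · (counts(x) − I_bg) / (I_ref − I_bg)

with `I_ref` the mean count over the standard disk, `I_bg` the mean
background count, both re-estimated for every section (the standards are
scanned with each milled surface; nothing is pooled).  The calibration is
through-origin after offset removal: a two-point or nonlinear curve would
require instrument data that a single standard per channel cannot supply.
Whether the original analysis background-subtracted before ratioing is not
documented; the subtraction used here is recorded per section in the
calibration log so the choice is auditable.  Concentrations are clipped
below at zero.

Pixel signal-to-noise is defined the conventional imaging way,
`SNR = (counts − I_bg)/σ_bg` with `σ_bg` the background-region SD.  A
tissue pixel enters the region of interest only if `SNR ≥ 3.5` in *both*
channels (the exclusion rule is the strict `SNR < 3.5`, so a pixel exactly
at the threshold is retained).  Requiring both channels keeps all five
indices on an identical pixel set; the threshold is a configuration value,
not a literal.

## Redox indices and per-section statistics

Five indices are computed pixelwise on valid pixels: Fp (µM), NADH (µM),
the Fp redox ratio Fp/(Fp+NADH) ∈ [0,1] (higher = more oxidized), Fp/NADH
and NADH/Fp.  Pixels with a vanishing denominator are dropped from the
affected index only and tallied; dropped pixels are NaN sentinels, never
zeros.  Per-section statistics are the arithmetic mean and sample SD
(denominator n−1) of the pixelwise values.  They are deliberately *not*
ratios of channel means — the mean pixelwise ratio of a heterogeneous
section differs from mean(Fp)/(mean(Fp)+mean(NADH)), and the published
group tables are only mutually consistent under the pixelwise reading.

Fp-ratio histograms use a fixed [0, 1] support with 64 bins by default
(the bin count is a knob recorded in outputs) so histograms are comparable
across sections; other indices bin over their data range.

## Bi-Gaussian histogram decomposition

Heterogeneity is additionally quantified by fitting

    f(x) = a1·exp(−(x−b1)²/(2c1²)) + a2·exp(−(x−b2)²/(2c2²))

to each section's Fp-ratio histogram, with FWHM_i = 2√(2 ln 2)·c_i.  The
fit is nonlinear least squares on (bin center, count) pairs — unweighted by
default, since the original weighting is undocumented, with a Poisson
option — under bounds a ≥ 0, 0 ≤ b ≤ 1, 10⁻⁴ ≤ c ≤ 0.5.  Initialization
is multi-start from deterministic weighted-quantile pairs of the histogram
(plus one narrow/wide start sharing the bulk center, which catches heavily
overlapped components); the best-SSE solution wins, so fits are exactly
reproducible without a seed.  Components are reported ordered by center
(b1 ≤ b2, ties broken by width).  Fits in which one component carries
< 1% of the area or the centers coincide within 10⁻³ are flagged
degenerate, never silently merged.  Both the peak-height ratio a2/a1 (the
conventionally tabulated quantity) and the area ratio (a2c2)/(a1c1) are
exported, because tabulations are ambiguous between the two.

Interpreting the fitted curve as a two-component Gaussian mixture with
weights w_i ∝ a_i·c_i gives closed-form moments

    mean = Σ w_i b_i,   sd = √(Σ w_i (c_i² + b_i²) − mean²),

the bridge between fitted coefficients and ordinary per-section statistics.
These moments are verified against large Monte-Carlo draws from the same
mixture; individual comparisons use kurtosis-aware standard errors for the
sample SD, with a small tail allowance because ~100 three-sigma
comparisons are made in one test.

## Group comparison

**Method I (global averaging).**  Each per-section statistic is averaged
to one value per animal; groups are compared by a two-tailed unpaired
t-test on animal values.  Welch's test is the default — safest at three
animals per group — with a pooled-variance option for strict
reproducibility of either convention.  Averaging discards within-animal
heterogeneity and leaves ~4 degrees of freedom.

**Method II (depth covariate).**  Every section is one observation of the
OLS model `statistic ~ intercept + group + depth`, the one-factor
one-covariate ANCOVA; the group effect and its two-sided p-value come from
the group coefficient and the per-µm depth slope is reported.  Sections
are treated as independent samples — matching the original univariate-GLM
treatment — so no animal random effect is fitted; group SDs pool over
sections.  Designs in which all depth variation lies between groups are
flagged collinear but still computed.

No multiple-testing correction is applied anywhere (none was applied in
the original analysis); all raw p-values are reported and the 0.05
threshold is reported, never enforced.  The full comparison covers 2
methods × (5 index means + 5 index SDs + 6 coefficients + a2/a1) = 34
rows.

## The synthetic phantom

The phantom generates complete studies in the exact on-disk format the
pipeline reads, with known ground truth per section.  Defaults are the
study conditions the package targets:

- 3 animals per group; 9 control and 14 PTEN-null sections; 128 × 128
  matrix at a 100 µm step (reduced sizes are used in tests and
  simulations; statistics at the section level are size-independent).
- Milling depths inside 200–2340 µm with 100–400 µm spacing; the first
  section of an animal starts uniformly within 400 µm of the top of the
  range.
- Group Fp-ratio distributions are two-component Gaussian mixtures whose
  default coefficients are the published per-group fit means: control
  (54, 33, 0.31, 0.35, 0.032, 0.065), mixture SD ≈ 0.057; PTEN-null
  (39, 24, 0.32, 0.37, 0.071, 0.12), mixture SD ≈ 0.102.
- The upper (more-oxidized) component is painted into random contiguous
  disks covering exactly its area fraction, giving localized oxidized foci
  while preserving the per-pixel marginal mixture that all statistics use.
- Channel synthesis: per pixel, a total concentration T is drawn lognormal
  (σ_log 0.15) around the 900 µM combined scale and split Fp = r·T,
  NADH = (1−r)·T for drawn ratio r; counts are gain·C + background +
  Gaussian noise (gain 20 counts/µM, background 50 ± 8 counts, signal
  noise SD 20 counts), rounded to uint16.  Calibration therefore recovers
  r up to noise, and exactly when noise and quantization are disabled.
- Reference standards default to 500 µM per channel — an arbitrary but
  recorded value, since the original standard concentrations are not
  published — and the background region is below the 3.5-SNR rule by
  construction.
- Between-section biological variability: each section's mixture centers
  are shifted by N(0, 0.03) and its widths scaled by a common
  lognormal(σ 0.2) factor, i.i.d. across sections.  These defaults were
  chosen so that the between-section and between-animal scatter of section
  means and SDs is of the order the published group tables show (±0.02–0.04
  for the ratio mean, cv ~30% for the ratio SD); because the jitter is
  i.i.d. across sections, both comparison methods remain exactly calibrated
  under the null, which the type-I-error test exercises.
- An optional linear drift of the mean ratio with depth
  (`depth_slope_per_um`, default 0) creates the regime where the depth
  covariate matters.  The power scenario in the acceptance suite uses a
  0.06 group shift with slope 2×10⁻⁴ µm⁻¹, chosen so that the trend
  contributes noticeably to between-animal variance: under it, global
  averaging loses power while the depth-adjusted model retains it.

**What the phantom does not emulate:** optical physics (scattering,
depth-dependent attenuation, inner-filter effects), cryo-milling
artifacts, anatomically realistic pancreas morphology, between-animal
(as opposed to between-section) random effects, cystic/ductal voids, and
instrument drift.  Passing tests therefore show that the *analysis* is
correct and well calibrated under the stated generative assumptions, not
that those assumptions exhaust real tissue.

## Problem sizes in the test suite

Simulation-based tests run the full pipeline at reduced matrix sizes
(48 × 48 for power checks, 24 × 24 for the 200-replicate null
calibration); per-section statistics concentrate fast enough that the
section-level comparisons are unaffected, and the choices keep the whole
suite to a couple of minutes.  Fitter-recovery checks use 64-bin
histograms and 16 384-pixel samples.

## Known limitations

- The bi-Gaussian fit on near-unimodal sections is weakly identified; such
  fits converge but individual coefficients scatter (the degenerate flag
  marks the worst cases).  Group comparisons of coefficients inherit that
  noise, as they do in the original analysis.
- Method II's independence assumption ignores within-animal correlation;
  with animal-level random effects in real data its p-values would be
  anti-conservative.  A mixed model is a deliberate non-default extension.
- One-point calibration cannot detect detector nonlinearity.
- Ratio values are clipped to [0, 1] during generation; with the default
  coefficient sets the clipped mass is negligible (< 0.1%), but extreme
  custom mixtures would bias the realized moments.
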