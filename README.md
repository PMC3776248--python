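# redoxscan

Analysis of cryogenic two-channel autofluorescence ("redox scanning")
imaging data.  A redox scanner mills a snap-frozen specimen flat and
raster-scans each exposed surface in two fluorescence channels — oxidized
flavoproteins (Fp, including FAD) and NADH — alongside frozen reference
standards of known concentration.  From such multi-section scans the
package quantifies the mitochondrial redox state of tissue and, centrally,
its *spatial heterogeneity*, the feature that distinguishes premalignant
from normal tissue in models such as the pancreas-specific PTEN-null
mouse.

The pipeline:

1. **Calibration** — one-point linear conversion of raw counts to nominal
   concentrations, `C = C_ref (I − I_bg)/(I_ref − I_bg)`, per section and
   channel; pixels with `SNR = (I − I_bg)/σ_bg < 3.5` in either channel
   are excluded.
2. **Redox indices** — pixelwise Fp, NADH, Fp redox ratio
   `Fp/(Fp + NADH)` ∈ [0, 1] (higher = more oxidized), Fp/NADH and
   NADH/Fp; per-section means and sample SDs (the SD of the ratio is the
   primary heterogeneity statistic).
3. **Bi-Gaussian decomposition** — least-squares fit of
   `f(x) = a₁e^{−(x−b₁)²/2c₁²} + a₂e^{−(x−b₂)²/2c₂²}` to each section's
   Fp-ratio histogram; `FWHM_i = 2√(2 ln 2) c_i`; closed-form mixture
   moments (weights `w_i ∝ a_i c_i`) bridge the coefficients back to the
   ordinary mean/SD.
4. **Group comparison** — *Method I*: per-animal global averages compared
   by unpaired two-tailed t-tests (Welch default); *Method II*: every
   section as one observation of the ANCOVA-style OLS model
   `statistic ~ group + depth`, with milling depth as covariate.
5. **Phantom generator** — fully ground-truthed synthetic studies (two
   phenotype mixtures, contiguous oxidized foci, reference standards,
   low-SNR background) written in the exact on-disk format the pipeline
   reads, so every stage is testable without instrument data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from redoxscan import (PhantomConfig, make_phantom_study, write_study,
                       load_study, analyze_study, method_one, method_two)

cfg = PhantomConfig(seed=42)            # 3 animals/group, 9 + 14 sections
study = make_phantom_study(cfg)
manifest = write_study(study, "example_study")   # TIFFs + YAML manifest

sections, man = load_study(manifest)
summaries, fits, analyses = analyze_study(sections, man)

for stat in ("fp_ratio_mean", "fp_ratio_sd"):
    for m in (method_one(summaries, stat), method_two(summaries, stat)):
        c, p = m.group_estimates["control"], m.group_estimates["pten_null"]
        print(f"{stat:14s} method {m.method:3s} control {c[0]:.3f}+-{c[1]:.3f} "
              f"pten {p[0]:.3f}+-{p[1]:.3f}  p={m.p_value:.4g}")
```

prints

```
fp_ratio_mean  method I   control 0.340+-0.013 pten 0.353+-0.011  p=0.2767
fp_ratio_mean  method II  control 0.340+-0.024 pten 0.352+-0.038  p=0.04895
fp_ratio_sd    method I   control 0.052+-0.006 pten 0.096+-0.009  p=0.003184
fp_ratio_sd    method II  control 0.052+-0.009 pten 0.096+-0.020  p=2.74e-05
```

Read: the PTEN-like phenotype is far more *heterogeneous* (per-section SD
of the Fp ratio ≈ 0.10 vs ≈ 0.05, significant by both methods), while the
shift of the *mean* ratio is small and reaches significance only once the
depth covariate absorbs between-section variance — the characteristic
contrast between global averaging and depth-covariate modelling.
`analyses[0].fit.summary()` prints the section's bi-Gaussian fit
(centers, widths, FWHM, a₂/a₁, implied mixture moments).

The same pipeline runs from the shell:

```sh
redoxscan simulate --out study --seed 42
redoxscan analyze --manifest study/manifest.yaml --out results
redoxscan compare --results results
redoxscan report  --results results
```

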