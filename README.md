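# chemocal

Multivariate UV-Vis calibration for quantifying two spectrally overlapping
drugs in one scan — classical least squares (CLS), principal component
regression (PCR) and partial least squares (PLS) — together with the
experimental-design, cross-validation, method-validation and greenness
machinery that a complete chemometric assay needs.

## The problem

Two co-administered antivirals (favipiravir-like and remdesivir-like
compounds) absorb in overlapping UV regions, so neither can be quantified at
a single wavelength in a mixture. The chemometric answer is to calibrate on
the full spectrum: prepare a balanced set of mixtures spanning the working
range (here 1–17 µg/mL per drug via a five-level, two-factor 25-run design),
record each spectrum over 220–400 nm at 1 nm, and regress concentrations on
absorbances.

With concentration matrix **C** (n samples × m components) and absorbance
matrix **A** (n × p wavelengths):

- **CLS** fits the Beer–Lambert model directly, **A** = **C K**, estimating
  the pure-component absorptivities **K̂** = (**CᵀC**)⁻¹**CᵀA** and predicting
  by ĉ = a **K̂**ᵀ(**K̂K̂**ᵀ)⁻¹. It requires every absorbing species to be in
  the calibration — an unmodeled background biases it.
- **PCR** regresses mean-centered **C** on the leading principal-component
  scores of mean-centered **A**; extra components can absorb an interferent.
- **PLS** (NIPALS PLS2) extracts latent variables maximizing the covariance
  between the spectral and concentration blocks, deflating both per
  component; **B** = **W**(**PᵀW**)⁻¹**Qᵀ**.

The number of latent variables is chosen by leave-one-out cross-validation
(RMSECV versus latent-variable count), with either the global minimum or a
parsimony rule (smallest count within 25% of the minimum). Validation
figures of merit follow the usual conventions: %recovery = 100·ĉ/c with
mean ± RSD, RMSEC/RMSEP = √(Σ(ĉᵢ−cᵢ)²/n), LOD = 3.3·SD/slope and
LOQ = 10·SD/slope from the predicted-vs-nominal line, standard-addition
selectivity, and pooled-variance t / variance-ratio F comparison against a
reference method at P = 0.05. An analytical eco-scale module scores
procedure greenness (100 − penalty points; >75 excellent).

Because no instrument data ship with the package, a synthetic-spectra module
generates mixture spectra with the statistical structure the models assume:
Gaussian-band pure spectra with configurable overlap, Beer–Lambert
additivity, seeded homoscedastic noise, and an optional plasma-like
interferent background.

## Worked example

```python
import chemocal as cc

design = cc.split_design(cc.generate_design())          # 25 mixtures, 13 cal / 12 val
grid = cc.WavelengthGrid.default()                      # 220-400 nm, 1 nm
noise = cc.NoiseModel(seed=42, noise_sd=0.002)          # 0.002 AU instrument noise
spectra = cc.simulate_mixtures(design, cc.DEFAULT_COMPONENTS, noise, grid)

cal = design.role == "calibration"
C, A = design.conc[cal], spectra.absorbance[cal]

cv = cc.loo_rmsecv("pls", C, A, max_latent=6)
k = cc.select_n_latent(cv)
print(f"chosen latent variables: {k}  (pooled RMSECV {cv.pooled[k]:.4f} ug/mL)")

model = cc.fit_pls(C, A, k, wavelengths=grid.wavelengths,
                   component_names=["favipiravir", "remdesivir"])
pred = cc.predict(model, spectra.absorbance[~cal])
for j, name in enumerate(model.component_names):
    s = cc.recovery_summary(pred[:, j], design.conc[~cal][:, j])
    print(f"{name:12s} mean recovery {s.mean:6.2f}%  RSD {s.rsd:.3f}%  (n={s.n})")

mi = cc.linearity_merit(design.conc[~cal][:, 0], pred[:, 0])
lod, loq = cc.lod_loq(mi)
print(f"favipiravir LOD {lod:.3f} ug/mL, LOQ {loq:.3f} ug/mL")
```

prints

```
chosen latent variables: 2  (pooled RMSECV 0.0088 ug/mL)
favipiravir  mean recovery 100.05%  RSD 0.073%  (n=12)
remdesivir   mean recovery 100.00%  RSD 0.261%  (n=12)
favipiravir LOD 0.017 ug/mL, LOQ 0.053 ug/mL
```

Cross-validation correctly identifies the two chemical components; the
held-out 12 mixtures are recovered at ~100% with sub-percent RSD at the
default noise level, and the detection limit sits far below the 1 µg/mL
bottom of the calibrated range, as it must for the assay to cover plasma
peak levels of ~4.4 and ~3.0 µg/mL.

The same workflow is scriptable from the shell:

```sh
chemocal design --out design.csv
chemocal simulate --design design.csv --seed 42 --out spectra.csv
chemocal crossval --method pls --max-latent 6 --spectra spectra.csv \
    --design design.csv --out rmsecv.csv
chemocal fit --method pls --n-latent 2 --spectra spectra.csv \
    --design design.csv --out model.json
chemocal validate --model model.json --spectra spectra.csv --design design.csv
chemocal run --seed 42 --outdir results/   # full pipeline, one command
```

An annotated full-pipeline configuration is in `examples/config.yaml`.

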