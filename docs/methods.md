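# Methods

## Calibration design

The default design is the 25-run five-level two-factor multilevel layout:
a generator sequence over coded levels {−2,−1,0,1,2}, each appearing five
times and starting at 0, gives factor 1; factor 2 is the same sequence
rotated left by one position. Real concentrations are `center + step·coded`
with center 9 µg/mL and step 4 µg/mL, i.e. levels 1, 5, 9, 13, 17 µg/mL per
drug. The shipped generator is the constant `DEFAULT_GENERATOR`; with it the
two coded columns are balanced, zero-sum and mutually orthogonal. Note that
orthogonality is a property of this particular cyclic generator, not of
every balanced generator — `MixtureDesign.is_orthogonal` checks it
explicitly rather than assuming it. Odd sample ids (1-based) form the
13-sample calibration set, even ids the 12-sample validation set; an
explicit id list may replace the odd/even rule. Non-default level counts
are supported only when the user supplies a generator; we make no attempt
to derive generators for other sizes.

## Spectral data and masking

Spectra live on a strictly increasing wavelength grid, by default 220–400 nm
at 1 nm (181 points), stored as real numbers so other instruments' grids
work unchanged. The file format is plain CSV (wavelength column plus one
column per sample) — no vendor binary. Wavelength masking keeps closed
intervals `[lo, hi]` nm and is how a noise-dominated spectral region is
excluded before modeling. The default mask keeps the full range: the
literature on this assay does not state which wavelengths its authors
discarded, and inventing an exclusion window would be arbitrary, so the
noise region is user configuration. Masking is idempotent and commutes with
sample subsetting; a mask that empties the grid is an error.

## Synthetic spectra

Pure-component spectra are Gaussian band sums
a(λ) = Σ h·exp(−(λ−c)²/2σ²) in AU·mL/µg. The defaults place the two drugs'
maxima near 323 nm and 246 nm with secondary bands making them overlap over
230–280 nm — chosen to mimic the qualitative overlap of the real pair, since
no absorptivities are tabulated anywhere we could use. Only the
linear-mixture structure matters to the calibration models; all shape
parameters are configuration, not constants of the method. Mixtures obey
Beer–Lambert additivity exactly before noise; instrument noise is
homoscedastic Gaussian with default sd 0.002 AU, roughly the short-term
photometric noise of a benchtop UV-Vis instrument at moderate absorbance.
Optional linear baselines and a broad "plasma" interferent band (with
per-sample level jitter, default ±20%) emulate, respectively, instrument
drift and an endogenous matrix background that the calibration model does
not know about. Every stochastic call takes an explicit seed; there is no
hidden global randomness.

What the generator does **not** emulate: wavelength-correlated
(pink/drift) noise, stray light, detector saturation, absorbance
nonlinearity at high optical density, and real plasma's variable fine
structure. Passing tests therefore demonstrate the correctness of the
algorithms and their qualitative behaviour (exactness on in-span data,
degradation of CLS under unmodeled interferents, CV curve shapes), not
instrument-specific figures such as absolute RMSEP or LOD on real extracts.

## Calibration models

Standard textbook forms are used:

- **CLS** — K̂ = (CᵀC)⁻¹CᵀA, prediction ĉ = aK̂ᵀ(K̂K̂ᵀ)⁻¹. No centering; an
  optional intercept row (default off) absorbs a constant background.
  A rank-deficient C raises an error naming the collinear columns.
- **PCR** — both blocks column-centered; truncated SVD of centered A;
  regression of centered C on the scores. A request at (or above) the
  numerical rank reproduces the minimum-norm least-squares solution.
- **PLS2** — NIPALS with both blocks centered: per latent variable, weight
  w (unit norm), scores t = A_def·w, loadings p = A_defᵀt/tᵀt,
  q = C_defᵀt/tᵀt, deflation of both blocks; B = W(PᵀW)⁻¹Qᵀ. The inner
  u↔t loop converges at relative tolerance 1e-12 with a 500-iteration cap
  (non-convergence raises, reporting the latent-variable index). PLS1 is
  not provided; PLS2 covers the two-component use and the single-response
  case reduces to it in one inner pass.

Autoscaling is off by default because all channels share absorbance units.
Whether the original workflow centered its blocks or gave CLS a background
term is not stated anywhere; the defaults above are declared choices.
Numerical rank uses a relative singular-value threshold of 1e-10. Sign
indeterminacy of singular/weight vectors is resolved by making each
vector's largest-magnitude element positive, so repeated fits are
bit-identical.

## Model selection and error metrics

Leave-one-out cross-validation refits the model with each calibration
sample held out, for every candidate latent-variable count 1..max, and
reports RMSECV(a) per component plus the 0-LV baseline (training-fold mean
prediction). RMSE uses divisor n throughout (the common chemometric
convention; the printed errors we could compare against imply no single
consistent alternative divisor). Two selection rules: `global_min`
(smallest argmin of pooled RMSECV) and the default `one_se_like_fratio`
(smallest count whose pooled RMSECV is within 1.25× the minimum — a
Haaland–Thomas-style parsimony rule; the original study never states its
rule, so both are provided and the chosen rule is recorded with the
model). CLS has no latent-variable axis: it is excluded from the RMSECV
curve but `loo_rmsecv_cls` gives its single LOO error number, and it
participates fully in RMSEC/RMSEP.

## Figures of merit

Recoveries are 100·predicted/nominal; summaries report the mean, sample SD
(n−1) and RSD = 100·SD/mean. LOD/LOQ use 3.3·SD/|slope| and 10·SD/|slope|
where SD is the residual standard deviation s_{y/x} (divisor n−2) of the
ordinary least-squares line of predicted versus nominal concentration over
the 1–17 µg/mL range — the ICH convention. The accuracy protocol simulates
triplicate determinations at 4, 8 and 16 µg/mL (both drugs at the level)
and pools nine recoveries per component; the precision protocol repeats it
per day (one seed per day) for repeatability (day 1, n = 9) and
intermediate precision (three days, n = 27), with an optional between-day
baseline offset drawn once per day. Standard addition reports %R =
100·pure_found/pure_added per spike row plus mean ± RSD. Method comparison
uses the pooled-variance two-sample t (df n1+n2−2, two-sided critical) and
the variance-ratio F (larger/smaller, df ordered accordingly, upper-tail
critical) at α = 0.05, with criticals from the scipy t and F quantile
functions. One documented quirk: the spiked-plasma summary table this
workflow mirrors labels its dispersion column "RSD" while the values equal
the plain sample SD; the package computes and labels it as SD.

## Greenness

The analytical eco-scale subtracts itemized penalty points from 100;
score > 75 is "excellent", 50–75 "acceptable", < 50 "inadequate" (75 itself
is acceptable, per the "more than 75" rule). Penalty itemizations are user
configuration; `EXAMPLE_PENALTIES` ships plausible reconstructions
totalling 21/19/22 points (scores 79/81/78) for the three workflows as
documentation, since no published itemization exists. The GAPI and AGREE
pictogram tools are external published software and are out of scope; only
the eco-scale arithmetic is implemented.

## Pipeline

`run_pipeline` composes the stages (design → simulate → mask → CV → fit →
predict → merit → plasma stress → greenness) as a pure function of a
validated YAML config; every stochastic stage derives its seed from the
config seed, so identical configs give byte-identical outputs. Files are
written to a temporary name then atomically renamed. The CLI subcommands
(`design`, `simulate`, `fit`, `crossval`, `validate`, `assay`,
`greenness`, `run`) are thin wrappers over the same library calls.

## Problem sizes and numerical checks

The test suite and acceptance script work at the assay's native scale —
25 mixtures × 181 wavelengths, LOO CV over 13 calibration samples with up
to 8 latent-variable candidates — which runs in seconds. Stress tests use
200 replicates (noise monotonicity of RMSEP over sd ∈ {0.001, 0.002,
0.004}) and 50 replicates (RMSEC ≤ RMSECV as a ≥45/50 majority property).
Independent oracles: brute-force normal equations for CLS, the Moore–
Penrose pseudoinverse for full-rank PCR, a closed-form univariate
regression for 1-LV/1-component PLS, and scikit-learn's PCA regression and
NIPALS PLS2 as external cross-checks.

## Known limitations

- Gaussian-band surrogates cannot reproduce instrument-specific published
  values (absolute RMSEC/RMSEP, LOD/LOQ, accuracy/precision of the real
  extracts); those depend on the undeposited raw spectra.
- The 25-run design generator is shipped as a constant recovered from the
  published layout; its construction rule (cyclic rotation) is inferred,
  and other design sizes require a user-supplied generator.
- CLS assumes all absorbers are modeled; the package demonstrates (rather
  than fixes) its failure under unmodeled backgrounds — use PCR/PLS with
  an extra latent variable there.
- A valid `DesignSpec` requires all real concentrations positive
  (center − 2·step > 0); degenerate centered-at-zero designs are rejected
  by construction.
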