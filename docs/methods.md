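# Methods

This note documents the models, conventions, parameter choices and known
limitations of `nirscal`, in the spirit of a model-description appendix.

## Pretreatment

**Order of operations.** `apply_recipe` restricts the wavelength range,
then applies the scatter correction, then the derivative.  Scatter models
(SNV, MSC, WMSC, detrend) describe raw absorbance — a multiplicative
path-length factor and an additive baseline — so they are applied before
differentiation.  The recipe token (e.g. `"2,5,5,2 | SNVD | 1108-2492"`)
is appended to the dataset provenance so alternative orders can be compared
explicitly if ever needed.

**Scatter corrections.** SNV centres each spectrum and scales it to unit
sample SD (n−1 denominator, as everywhere in the package).  DET removes a
per-spectrum quadratic (configurable order) in wavelength by OLS.  MSC
regresses each spectrum on a reference — by default the population's
column-mean spectrum — and returns `(x − a)/b`.  WMSC does the same fit by
weighted least squares; the weighting scheme is not standardized across
vendors, so the package's default is inverse across-sample variance per
wavelength (down-weighting unstable regions), exposed as a parameter.
MSC/WMSC are population-dependent: the fitted reference (and weights) are
captured in a `PreprocessState` and must be reused when pretreating
prediction samples, otherwise the correction target silently drifts.  Note
the MSC idempotence property (correcting twice changes nothing) holds
exactly only when spectra follow the affine scatter model exactly; with
additive noise it is approximate.

**Gap-segment derivatives.** The `d,g,s1,s2` code means: running-mean
smooth with segment `s1`, then `d` successive differences over gap `g`,
then a second running-mean smooth with segment `s2`; `0,0,1,1` is the
identity.  For odd gaps the difference uses offsets (⌈g/2⌉, ⌊g/2⌋).  Edges
without full support are truncated — no padding or extrapolation — and the
wavelength positions are propagated through every step (averaged under
smoothing, midpointed under differencing), so the returned grid reports
the true effective positions, including half-step shifts.  Derivatives are
reported in raw difference units (not divided by the wavelength step);
calibration is scale-invariant to this choice.

## Outlier screening

The spectral population is decomposed by PCA (SVD of the centred matrix;
deterministic sign convention: the largest-magnitude element of each
loading is positive).  Components are retained up to a cumulative
explained-variance target, default 0.9981, capped at `min(n − 1, 63)`.
The global H statistic is

GH_i = (1/k) · Σ_j (t_ij − t̄_j)² / s_j²,

the Mahalanobis distance in retained score space divided by the component
count k, with score variances on an n−1 denominator.  Division by k makes
the conventional cutoff GH > 3.0 scale-free; the in-population mean GH is
exactly (n−1)/n.  Elimination is single-pass — one PCA, one cutoff, no
iteration.  NH (the per-component-mean squared standardized distance to the
nearest other sample) is reported as a redundancy diagnostic only; no
elimination rule is attached to it.

**Known limitation — self-masking.** An extreme sample inflates the
variance of its own direction, so its standardized score is at most about
√n and its GH at most about n/k.  With the default variance target the
retained count often reaches the 63-component cap, so GH screening resolves
gross spectral outliers reliably only when n/k is comfortably above the
cutoff (true at the default n = 247); for populations of ≲ 150 samples a
lower variance target (fewer retained components) is needed, and the CLI
exposes it.

## MPLS calibration

Single-response NIPALS PLS1 with per-factor residual standardization.  Per
factor: covariance weight w ∝ Xᵀy (unit norm), score t = Xw, loadings
p = Xᵀt/tᵀt and q = yᵀt/tᵀt, deflation of both X and y — and then the
modification: every wavelength's residual column is divided by its sample
SD, the SDs being stored so prediction can replay them factor by factor.
Only the wavelength residuals are rescaled; response residuals are not.
With `standardize_residuals=False` the algorithm is plain PLS1 and its
predictions match `sklearn.cross_decomposition.PLSRegression(scale=False)`
to 1e−8 (asserted in the tests; sklearn is used only as an independent
oracle, never as the implementation).

Predictor columns are not autoscaled before the first factor (the scatter
corrections already normalize the spectra); a zero residual SD at some
wavelength is replaced by 1 with a warning.  Prediction replays the stored
per-factor scalings rather than folding them into one coefficient vector,
because the scalings are factor-indexed; `regression_vector()` collapses
the affine map exactly, for inspection only.  Models serialize to a
versioned JSON embedding recipe provenance.

## Validation statistics

* SEC = √(SSE/(n − Terms − 1)) — calibration degrees of freedom;
* SECV = √(SSE_cv/n), SEP = √(SSE_val/n_val) — plain RMS errors of pooled
  out-of-fold / external predictions (this denominator split reproduces
  the conventional SEC < SECV pattern);
* R² = 1 − SSE/SST in every flavour (equal to the squared correlation for
  calibration fits with intercept, but defined this way throughout);
* RPD = SD/SECV (externally SD_val/SEP), SDs with n−1.

Cross validation partitions the calibration set into seeded random groups
(default 4), pools out-of-fold predictions for every candidate factor
count, and picks the optimal Terms as the smallest count whose SECV is
within 2% of the minimum — a parsimony window chosen because the SECV
curve is typically flat past its minimum; the 2% value is a package
convention.  With n groups = n the scheme reduces exactly to
leave-one-out (verified against a brute-force oracle).  A single random
partition is used by default; a repeats parameter exists.

The grid search evaluates every recipe in the configured grid (default
8 derivative codes × 6 scatter methods × 3 ranges = 144) with the same
fold seed, ranks rows by SECV, and reports them in the conventional
calibration-table column order (N, Terms, DT, SCM, range, Mean, SD, SEC,
R², SECV, R²cv, RPD).  Failing combinations (e.g. a wide gap on a narrow
range) are recorded as failed rows, not fatal errors.

## Correlation panels

Spearman's rho is the Pearson correlation of mean-ranked data (ties get
their mean rank).  P-values default to the two-sided t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df — adequate at the package's default
population sizes — with a seeded permutation test (add-one smoothing)
available for exactness at small n.  Significance tiers are per-pair at
0.05/0.01; no multiple-testing correction is applied, matching how such
panels are conventionally reported.

## Synthetic-data generator

The generator emulates the statistical structure of a transgenic rice
straw population; its defaults live in `data/default_generator.yaml`.

**Traits.**  Seven wall-polymer features are drawn from a multivariate
normal matched to published means/SDs (cellulose 25.11/4.45% dry matter,
Ara 13.22/1.37%, Xyl 75.08/2.63%, X/A 5.75/0.77, ASL 3.13/0.41%, AIL
8.20/1.40%, total lignin 11.33/1.55%) with a synthetic correlation matrix
(X/A strongly negative with Ara; total lignin nearly collinear with AIL).
X/A and total lignin are generated as first-class coordinates rather than
derived ratios/sums, so their marginals hit the printed targets exactly;
the arithmetic identities X/A = Xyl/Ara and total = ASL + AIL therefore
hold only approximately — a deliberate synthetic artifact.  Ten
saccharification yields are linear in the standardized polymer features
plus independent noise, with signed loadings that force the known
correlation structure (cellulose and lignin depress hexose yields, Ara
raises them, X/A depresses them, cellulose raises pentose yields) by
construction, and noise scaled so each marginal SD hits its printed
target; the explained-variance fractions (0.90–0.96) put the default
population in the strong-calibration regime that the published models
occupy.  Bounds: fermentable hexoses are confined to the printed observed
range 52.8–95.9% of total hexoses; all other traits default to mean ± 4 SD.
Using observed ranges as hard bounds for every trait would truncate the
marginal SDs several percent below their targets, so the wide default was
chosen and the printed ranges are treated as descriptive.  Rejection is
staged (redraw a polymer vector violating polymer bounds; redraw a yield's
noise; redraw the whole row only if that fails) precisely so the polymer
moments and correlations stay undistorted by yield bounds; draws are
rejected, never clipped, to avoid boundary spikes.

**Spectra.**  A Beer–Lambert surrogate on a 408–2492 nm grid at 2 nm steps
(1043 points; the step size is a package choice — published work states
only the endpoints): absorbance = m·Σ c_k e_k(λ) + b + s·(λ−λ_min) + ε,
with per-sample multiplicative factor m (SD 0.05), offset b (SD 0.02 AU),
slope s (SD 1e−5 AU/nm), and i.i.d. noise ε (SD 5e−4 AU).  The component
library assigns each concentration-bearing trait (cellulose, Ara, Xyl,
ASL, AIL) 4–6 Gaussian bands whose positions loosely follow common NIR
overtone/combination assignments, with deliberate overlap between
components for realistic collinearity; band heights are synthetic, chosen
to give total absorbances of order 1 AU.  Since no absorbance scale is
published for the emulated instrument, these amplitudes are free
parameters.  X/A and total lignin carry no bands of their own and are
recoverable from spectra only through their correlations — which caps
their attainable calibration R² below 1 by construction.

**Outliers.**  `inject_outliers` adds to each chosen spectrum a sum of
three random-sign Gaussian bumps, normalized to unit RMS and scaled by a
magnitude times the population's mean per-wavelength SD.  Shape (not
offset/slope) perturbations are used deliberately: pure affine artifacts
would be removed by SNV/MSC and would not represent the anomalous samples
screening is meant to catch.

**What passing tests do and do not show.**  The generator reproduces the
published trait moments, the correlation sign structure, and a
strong-calibration spectral regime; it does not model reflectance physics,
instrument line shapes, wavelength-dependent noise, moisture/particle-size
effects, or reference-method error in the trait values.  Success on
synthetic data demonstrates that the algorithms are implemented correctly
and behave as the published workflow describes at the published population
sizes — not that any particular real instrument/population would achieve
the same statistics.

## Pipeline

`run_full` executes simulate (or load) → screen → split → per-trait grid
search → calibrate → external validation → correlation panel, writing
plain CSV/JSON artifacts and a manifest with the config hash, per-stage
seeds (spawned deterministically from the master seed) and artifact
SHA-256 hashes; a rerun from the same config is byte-identical.
`integrative_recalibrate` pools a prior run's calibration and validation
sets and repeats the grid search and CV (no external stage remains).  The
default problem size (247 samples × 1043 wavelengths × 17 traits, 144-recipe
grid per trait) runs the per-trait search in ~10 s, the full 17-trait
pipeline in a few minutes, on one CPU.

## Acceptance quantities

`scripts/acceptance.py` recomputes, from a single seed: the RPD printing
identity over the bundled published calibration rows (each printed
statistic has two decimals, so the identity is checked by rounding-interval
overlap); the MPLS/PLS1 oracle agreement and noiseless parameter recovery;
outlier recovery at the 247/7 study scale; grid-searched cross- and
external-validation power for the hexose-yield trait at the published
147/93 split sizes; and the Spearman sign structure.  Nothing in the JSON
is stored — every value is computed at run time.
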