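# Methods

This note documents the models, algorithms and design choices behind
`nirwood`, in the order data flows through the package.

## Data model and metrics

Spectra are stored as a samples × wavelengths matrix on a strictly
increasing nm grid (standard configuration 350–2397 nm at 1 nm, 2048
variables), flagged as reflectance R ∈ (0, 1] or absorbance A = log10(1/R).
Replicate scans (three per sample by default) are averaged **in reflectance
space first**, then converted; the two operations do not commute and the
averaged reflectance spectrum is defined as the raw spectrum.

Model quality is reported as R², RMSE, RPD and RSD. RPD is defined with the
**population** standard deviation (denominator n), which makes
RPD = (1 − R²)^(−1/2) an exact identity on any one dataset; this convention
reproduces tabulated (R², RPD) pairs in the chemometric literature to three
decimals, which the n−1 convention does not at small n. RSD = 100·RMSE/ȳ.
Tables print all four to three decimals, RSD with a percent sign.

The calibration/prediction split is random, stratified per species with
floor(n·fraction) calibration samples (fraction 0.7 by default; at least one
prediction sample per species). If the prediction-set density range is not
contained in the calibration range a warning (not an error) is raised, since
predictions there are extrapolations.

## Synthetic spectra generator

No public wood Vis-NIR dataset accompanies this problem class, so the
generator emulates the structure every method in the pipeline is designed to
act on:

* **Chemistry.** Three latent components (hemicellulose, cellulose, lignin
  in spirit) with concentrations drawn from zero-truncated normals.
  Clean absorbance follows Beer–Lambert mixing with unit path length:
  A(λ) = Σ_bands g(λ; center, width)·(loadings·c). The default band library
  places eight bands at 1157, 1171, 1370, 1597, 1811, 1830, 2200 and
  2353 nm with widths of 20–60 nm.
* **Band shape.** Profiles are Gaussians truncated at ±2σ and shifted to
  zero at the cut, so each band has compact support exactly on its ±2·width
  window. Outside all windows the clean signal is identically zero, giving
  selection-recovery tests a sharp oracle; the ~13% amplitude that plain
  Gaussians carry past 2σ is sacrificed for that sharpness.
* **Physics.** Per-sample multiplicative slope and additive offset
  (defaults 0.95–1.05 and ±0.02 — the distortion MSC removes), a random
  degree-2 polynomial baseline scaled by `baseline_amplitude` (default
  0.01), and white noise per replicate (default sd 0.005 absorbance units).
  Replicates share everything except the noise. Reflectance is
  R = 10^(−A_observed), clipped into (1e-6, 1] so log(1/R) is always
  defined.
* **Density.** density = intercept + slopes·c + γ·(Σc)² g/cm³. Defaults
  (intercept 0.30, slopes 0.55/0.50/0.60, γ = 0.12, concentration means
  0.35/0.30/0.25 with spreads 0.06/0.05/0.05) were calibrated once so that
  500 simulated densities span roughly 0.65–1.08 g/cm³, inside the
  0.50–1.20 window that brackets published temperate-species ranges. With
  γ = 0 and no noise the density is exactly linear in the clean spectra, so
  PLS attains training R² > 0.999 (a solvability oracle). The nonlinear
  test regime instead uses slopes = −2γ·E[Σc] so the linear term cancels at
  the mean and density is a curved function of total composition — the
  cleanest setting in which kernel models must beat linear ones.

What the generator does **not** emulate: quantitative wood chemistry,
instrument line shape, water-vapor bands, or temperature/moisture effects.
Passing tests therefore demonstrate algorithmic correctness and the expected
qualitative orderings, not field performance on real wood.

## Lifting wavelet transform

The LWT is implemented as true lifting: split into even/odd polyphase
channels, then a sequence of elementary steps each adding a filtered version
of one channel to the other, then a diagonal normalization. The steps for
any registered wavelet (haar, db2–db8, sym2–sym8, bior1.1/1.3/1.5) are
derived at first use by reducing the wavelet's 2×2 Laurent-polynomial
polyphase matrix to diagonal monomials with the Euclidean algorithm; the
recorded row operations are the lifting steps. Laurent division is
non-unique, and some elimination paths are numerically degenerate, so the
factorization searches over quotient-end choices and accepts the first path
whose single-level output matches the direct filter bank to 1e-9. Haar is
hand-coded with the classic steps d = odd − even, a = even + d/2.

Boundary handling: signals are padded symmetrically to a multiple of 2^level
and the lifting convolutions wrap circularly inside the padded signal;
because every lifting step is exactly invertible on circular signals, the
round trip is exact to machine precision for every wavelet and level. With
`normalize=True` the diagonal is applied, giving orthonormal filter-bank
coefficients (energy-preserving for orthogonal families); the unnormalized
convention keeps Haar's pairwise means/differences.

Denoising thresholds all detail levels with λⱼ = scale·σ̂·√(2 ln nⱼ),
σ̂ = median(|d₁|)/0.6745 estimated from the finest level, soft rule by
default (both exposed). Coefficients are taken in the normalized convention
so one σ̂ applies at every level. The classical-WT baseline uses the same
padding and threshold so haar-LWT and haar-WT denoising agree to 1e-6.

At coarse sampling (e.g. an 8 nm grid) genuine signal detail reaches the
finest scale and soft universal thresholding can over-shrink it; at the
native 1 nm grid, where signal and noise scales separate, denoising reduces
both the RMS error to the clean spectrum and the PLS cross-validation error
for noise sd ≥ 0.01. Tests of the denoising *gain* therefore run on the
native grid.

The parameter search is greedy, as is conventional: stage 1 fixes
(order, level) = (3, 8) and compares haar/db3/sym3/bior1.3 by PLS
cross-validation RMSE (R² is recorded too; RMSE is primary when they
disagree); stage 2 scans orders 2–8 for the winning family (haar has no
order; bior is restricted to registered bior1.{1,3,5}); stage 3 scans levels
1–8. Ties keep the earlier candidate.

## MSC and SNV

MSC regresses each spectrum on a reference (x ≈ a + b·ref) and returns
(x − a)/b; the reference defaults to the calibration-set mean and is stored
so prediction spectra are corrected against the same reference. Note a
structural limit: MSC projects every spectrum onto span{1, ref}, so it can
reconstruct clean spectra exactly only when the underlying composition is
fixed and samples differ by scatter alone — the regime its oracle test uses.
With compositional variation MSC necessarily conflates chemical and physical
multiplicative effects. SNV standardizes each spectrum to mean 0, sd 1
(denominator n − 1).

## Wavelength selection

All four selectors share a PLS core whose latent-variable count is chosen by
inner 5-fold cross-validation capped at 15, and all are deterministic under
their seed; weight ties break toward the lower index.

* **UVE**: append p uniform-noise variables (scale 1e-10 — the reliability
  statistic is scale-free), leave-one-out PLS, reliability
  cⱼ = mean(bⱼ)/sd(bⱼ); keep real variables whose |c| exceeds the 0.99
  quantile of |c| over the noise block.
* **CARS**: N = 50 Monte-Carlo runs, 80% sample draws, forced retention
  rᵢ = a·e^(−k·i) with r₁ = 1 and ⌈r_N·p⌉ = 2 (endpoint computed with a
  small tolerance so floating point cannot push it to 3), adaptive
  reweighted sampling by |coefficient|, 5-fold RMSECV per iteration, return
  the subset minimizing RMSECV.
* **SPA**: forward chains maximizing the residual norm after projection onto
  the orthogonal complement of the chosen set; chain prefixes of
  min_vars..max_vars scored by validation-set RMSE of a linear regression.
  With large p an evenly spaced subset of start columns (default cap 64) is
  scanned; duplicated/collinear columns are never selected twice because
  their residual projection vanishes.
* **IRIV**: rounds of binary-matrix sampling (inclusion probability 0.5,
  default 500 rows — pipeline and tests use 50–100 rows at desk scale),
  per-variable DMEAN = mean(RMSECV | excluded) − mean(RMSECV | included)
  with a Welch t-test; DMEAN > 0 keeps (strong if p < α = 0.05),
  DMEAN ≤ 0 drops; iterate until stable, then backward elimination of
  single survivors whose removal lowers RMSECV. At p = 2048 the pipeline
  downsamples the grid (every 4th wavelength by default, flag to disable)
  before IRIV, which is the compute-heavy selector.

## Calibration models

PLS (NIPALS, column-centered only, matching the common chemometric
default) and PCR stand on scikit-learn; both collapse onto ordinary least
squares at full rank, which the tests use as an oracle. GRNN is
Nadaraya–Watson kernel regression — the network formulation computes
exactly this — with predictors standardized by the training mean/sd
(distances are otherwise dominated by high-variance bands). SVR standardizes
predictors and the target; ε defaults to 0.01 on the standardized target.
All scaling parameters are learned on calibration data and frozen, so a
query's prediction cannot depend on what else is in its batch; a dedicated
test corrupts prediction-set targets and checks that no calibration or
cross-validation number moves.

Cross-validation assigns folds deterministically from the seed; when sample
identifiers are supplied the assignment is derived from the sorted
identifiers, making CVmse invariant to row order. CVmse is the mean over
folds of the fold MSE; RMSECV = √CVmse.

## Optimizers

* **FOA** (GRNN spread): canonical 2-D swarm, candidate S = 1/√(X²+Y²) — 
  positive by construction — with defaults 20 flies, 100 iterations, axis
  init uniform [0,1], steps uniform [−1,1]. Elitist, so the best-score trace
  is non-increasing; tested to land within 20% of a 200-point grid scan.
* **PSO** (SVR C, g): canonical inertia/cognitive/social updates
  (w = 0.8, c1 = 1.5, c2 = 1.7) in log10 coordinates over C ∈ [2⁻⁵, 2¹⁰],
  g ∈ [2⁻¹⁰, 2⁵], positions clamped to the box. The conventional default
  point (C = 1, g = 1/p) is always evaluated, so the returned model never
  loses to it.
* **RSM over PSO meta-parameters**: a three-factor Box-Behnken design — the
  12 edge points with two coordinates at ±1 plus 5 center replicates
  (17 runs, the common commercial-software default) — over cross-validation
  number (5/10/15), maximum generation (50/75/100) and population size
  (20/40/60). Each run executes a full PSO-SVM training; the swarm seed
  varies per run while the CV fold assignment stays fixed, so responses are
  comparable experiments and center replicates measure search noise. A full
  quadratic surface is fitted by least squares (per-term t-tests supply the
  significance report), minimized on a 41³ lattice over the coded cube, and
  the optimum snapped to the nearest feasible integers (all three factors
  are counts). A final PSO-SVM training at the optimum yields the model.
  Desk-scale tests shrink the factor levels, not the design geometry.

## Pipeline

`run_single_species` chains the stages per species and reports: the
wavelet-search table, a selection-comparison table with Full-spectrum and
LWT-denoised PLS baselines plus the four selectors, calibration-model
metrics with the prediction set evaluated both raw and identically denoised
(models are always trained on denoised calibration spectra), and the
dimensionality-reduction summary. Rather than hard-coding a winning selector
per species, the pipeline picks the selector with the best cross-validation
RMSECV and records the full comparison. A failing species branch logs its
diagnostic and does not abort the others.

`run_combined` contrasts "signal" models (one species at one location)
against pooled models (per location, same species across locations, and all
data) for PLS and PCR on raw absorbance spectra, with one global split
stratified by (species, location) so memberships are consistent across
groupings. Pooled models are additionally evaluated on each member species'
prediction subset; negative R² values are reported as-is. Groups with fewer
than 8 samples are skipped with a warning.

Default problem sizes in the pipeline, tests and acceptance script (60–120
samples, 256-point grids, 50 CARS runs, 50–100 IRIV rows) are desk-scale
choices that keep a full run in the minutes range; all are configuration
fields, and the synthetic generator accepts the full 2048-point grid
unchanged.

The run configuration is a plain dataclass; the CLI accepts the same fields
as a JSON file. Reports are delimited text plus a JSON manifest recording
config and seeds for reproducibility.

## Known limitations

* The lifting factorization covers the wavelet families the search uses
  (haar, db, sym, bior1.x); other registered families work if a stable
  elimination path exists, but are not exercised.
* IRIV's cost grows as rows × p per round; at full 2048-variable scale it
  relies on the grid downsampling documented above.
* SVR training uses an iterative solver, so row-order invariance holds to
  the solver tolerance (~1e-6 with the tightened default), not exactly.
* The synthetic generator's realism limits are listed above; none of the
  reported numbers should be read as field accuracy for real wood.
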