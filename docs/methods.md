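# Methods

## Signals and regions

The pipeline operates on two representative region signals per subject.
When starting from a 4D NIfTI volume, a region signal is the arithmetic
mean over all voxels whose centers lie within a sphere defined in world
(mm) coordinates — membership is decided by voxel-center distance, with
no partial-volume weighting, and the volume's affine is authoritative
(no RAS/LPS assumption). Defaults are 7.5 mm spheres at the PCC
(−5, −49, 40) and dACC (8, 7, 38) in MNI space. Signals are
z-normalized with the population (1/T) variance, so "mean 0, variance
1" holds exactly as a property of the output rather than approximately
via an estimator convention. Tabular (TSV) input bypasses imaging
entirely. Inputs are assumed already preprocessed (motion correction,
normalization, filtering are out of scope).

## Parametric spectral coherence

The coupling feature is magnitude-squared coherence estimated through a
bivariate VAR(p) rather than a windowed periodogram: at T ≈ 200 samples
a parametric spectrum is substantially less variable than Welch
averaging, and the VAR model class matches the generator used for
validation.

* **Autocovariances** use the biased 1/T divisor, which guarantees a
  positive-semidefinite block-Toeplitz system.
* **Yule-Walker:** coefficients solve Γ(k) = Σ_m B_m Γ(k−m), k = 1..p;
  Σ = Γ(0) − Σ_k B_k Γ(k)ᵀ, symmetrized. Singular systems raise with a
  suggestion to lower the order; unstable fits (companion spectral
  radius ≥ 1) warn but do not fail, and stability is recorded per
  subject in the orders sidecar.
* **Order selection:** AIC in the ranking-equivalent form
  T·log det Σ̂ + 2pd² (d = 2) over candidates 1–10, independently per
  subject; ties go to the smaller order.
* **Spectrum:** S(f) = A(f)⁻¹ Σ A(f)⁻ᴴ with
  A(f) = I − Σ_k B_k e^(−i2πf·dt·k). The 1/(2π) density convention and
  dt factors are omitted — they cancel in coherence, the only exported
  quantity.
* **Grid:** f_j = j·f_Nyq/n for j = 1..n (default n = 125), i.e. the
  grid excludes 0 Hz and includes Nyquist. After z-normalization (and
  high-pass preprocessing of real data) the DC point carries no
  information; "up to the Nyquist band edge" is read as the spanned
  range. At dt = 2 s this gives 0.002, 0.004, …, 0.250 Hz.
* **Convention:** coherence is magnitude-*squared* (range [0,1], the
  range the downstream kernel analysis assumes); an unsquared-magnitude
  variant is available behind the `coherence: magnitude` config switch.

The independent cross-check is the Welch estimator
(`welch_coherence_oracle`, Hann window): on long VAR simulations the
two estimators agree to mean absolute deviation < 0.05, which is
asserted in the test suite.

## Abnormality index

A ν-one-class SVM with RBF kernel k(u,v) = exp(−γ‖u−v‖²) is trained on
the pooled feature matrix of the two groups being contrasted. The dual
(minimize ½αᵀKα subject to 0 ≤ α_i ≤ 1/(νn), Σα_i = 1) is solved by
libsvm via scikit-learn with tolerance 1e-6 and no randomness; dual
coefficients are rescaled from libsvm's Σα = νn convention to Σα = 1,
and the offset ρ follows libsvm's convention (any standard ρ choice
moves indices only within solver tolerance). Scoring uses the package's
own kernel arithmetic over the stored support vectors. The abnormality
index is the negated decision score; positive values lie outside the
learned boundary.

Defaults: ν = 0.5 (with two equal-size groups pooled, at most half the
sample can be flagged) and γ = 1/d — the standard heuristic, which
equals 1/125 on the default grid. γ is re-applied as 1/d′ when the
relevance analysis drops a column; a fixed numeric `gamma` in the
config freezes it instead. ν-properties (outlier fraction ≤ ν, support
fraction ≥ ν, within 1/n) are asserted in tests, and a brute-force
SLSQP solve of the same dual serves as an independent oracle on small
instances.

Indices are computed **in-sample** on the mixed training set. This is
deliberate: pooling the groups and scoring everyone with the same model
is symmetric in the groups, so the procedure cannot be biased toward
declaring either group abnormal.

## Relevance curve

With the classifier unsupervised, per-frequency relevance is measured
by ablation: drop frequency j's column from both groups, retrain,
recompute indices, and record the between-group median separation
Δ_(−j) = median(case) − median(control). The default relevance
convention is the **drop** Δ_full − Δ_(−j) (large positive values mark
frequencies whose presence drives the separation); the raw Δ_(−j)
values are always exported too and can be selected as the convention
(`relevance: raw`), since for a pure ablation measure either reading is
defensible. Exclusion is strictly one column at a time.

Because mixed-group training ignores labels, the full and ablated index
sets are sufficient statistics for the curve under any relabelling of
subjects; label-permutation nulls therefore reuse the d + 1 trainings
and recompute only medians (exact, not approximate).

## Group statistics

The case-vs-control hypothesis is directional — case subjects are
expected to be *more* abnormal, hence greater indices — so the
Mann-Whitney U test is one-tailed in that direction. Exact enumeration
is used when the pooled sample is ≤ 12 without ties; otherwise the
tie-corrected normal approximation with continuity correction
(midranks). Confound checks: two-tailed Mann-Whitney on indices by sex,
and an OLS fit index = β₀ + β₁·age + β₂·age² with the overall F-test
for (β₁, β₂) = 0. Calibration (type-I error within Monte-Carlo bounds
of 5% at n = 21 + 21 for the rank test, and for the quadratic F-test
over 1,000 null replicates) is asserted in the test suite.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: two
groups of 21 subjects, T = 197 samples at dt = 2 s. Each subject is

    x_t = Σ_b √λ_b s_b(t) + noise·√(1 − Σλ_b)·η_x(t)
    y_t = Σ_b √λ_b s_b(t) + noise·√(1 − Σλ_b)·η_y(t)

where each s_b is a shared band-limited latent (order-8 Butterworth
filtered white noise, applied forward-backward, standardized) and η_x,
η_y are independent unit-variance AR(1) processes (φ = 0.4). The
colored private noise gives channels broadband autocorrelation like
regional BOLD signals and keeps VAR fits of strongly coupled subjects
well-conditioned. True coherence rises monotonically with λ_b inside
band b and is near zero well outside all bands. Per-subject seeds
derive from the master seed via `SeedSequence.spawn`, so cohorts are
bit-reproducible and subjects independent.

Coupling strengths are drawn **per subject**. This is the load-bearing
design choice: with two equal-size groups pooled for one-class
training, a pure location shift of one group's features is symmetric
between the groups and produces no median index difference — the
detectable signature of a clinical group under this protocol is
*dispersion*, not location. The case group therefore draws λ from a
wide U-shaped distribution (Beta(0.3, 0.3) stretched over
strength ± spread), placing subjects at both coupling extremes, while
controls draw from a narrow uniform band. This matches the clinical
picture the analysis is designed for: a patient group that is more
heterogeneous than controls, with individuals overlapping the control
range as well as falling far outside it.

Two cohort flavors are provided:

* **Default cohort** (`CohortSpec()`): coupling in 0.00–0.05 Hz
  (control λ ~ U(0.48, 0.62); case U-shaped over [0, 0.64]) and
  0.18–0.22 Hz (control λ ~ U(0.16, 0.24); case U-shaped over
  [0, 0.20]) — the two bands where group differences of interest
  concentrate.
* **Single-band contrast** (`single_band_contrast()`): the validation
  workhorse. Groups differ *only* within 0.01–0.05 Hz: control
  λ ~ U(0.5, 0.65), case U-shaped over [0, 0.9]. The case cap at 0.9
  matters — a subject with λ → 1 has almost no private signal, making
  the two channels nearly identical and hence coherent at *all*
  frequencies, which would leak the group difference outside the band.
  The source band is inset to 0.024–0.04 Hz within the nominal
  0.01–0.05 Hz window because the VAR estimator at T = 197 smears
  spectral structure by roughly ±0.01–0.02 Hz; a source band flush with
  the window edges would push the apparent difference (and the
  relevance peak) just outside it.

Ages (uniform over 20–50) and sexes (Bernoulli 1/2) are drawn
independently of the signals, so confound tests are exercised under
their null.

What the generator does **not** emulate: hemodynamic response shapes,
1/f physiological noise spectra, scanner drift and motion artifacts,
spatial structure within regions, or any relation between demographics
and coupling. Passing the synthetic end-to-end tests therefore shows
that the estimator-classifier-test chain behaves correctly under known
band-limited group structure of realistic size and length — not that
effects of this size exist in, or would survive the noise structure of,
real fMRI data.

## Numerical choices and edge cases

* OC-SVM solver tolerance 1e-6; training is deterministic given row
  order, and index invariance under row permutation is asserted to
  1e-6.
* Coherence values are clipped to [0, 1] against roundoff; a
  numerically singular A(f) (near unit root) raises rather than
  returning garbage.
* AIC ties select the smaller order; orders whose Σ̂ is not positive
  definite are excluded via log-det sign.
* Constant series (zero variance) are rejected at normalization with
  the subject and region named; empty ROI masks name the offending ROI.
* Mann-Whitney falls back to the tie-corrected asymptotic path whenever
  ties occur, so tied indices never crash the exact path.
* Decision-score sign tests use a 1e-9 tolerance so margin support
  vectors (score numerically zero) are not counted as outliers.

## Known limitations

* Exactly two regions; extending to more ROIs would square the feature
  count and degrade the one-class SVM at typical sample sizes.
* The relevance measure inherits the redundancy of neighboring
  frequencies: VAR-smoothed coherence columns are strongly correlated,
  so single-column ablation effects are small relative to median
  sampling noise at n = 21 + 21, and the *location* of the curve's
  maximum has appreciable seed-to-seed variability even for large
  effects. The magnitude of in-band versus out-of-band relevance is the
  more stable summary.
* In-sample indices are comparative, not diagnostic: they rank subjects
  within the pooled cohort and are not calibrated scores for new,
  unseen subjects.
* The directional Mann-Whitney presumes the case group is the more
  heterogeneous/atypical one; under a tight case group and diffuse
  controls the expected direction reverses.
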