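# Methods

## The model

An epigenetic clock is a linear predictor over CpG methylation
fractions (beta values, in [0, 1]).  For sample *i* with beta vector
β<sub>i</sub> and a clock with weights w and intercept a, the
transformed score is

    m_i = a + Σ_j w_j β_ij .

Horvath-style clocks map the score to years through the inverse of the
log-linear age transform

    F(t) = log(t + 1) − log(A + 1)      t ≤ A
    F(t) = (t − A) / (A + 1)            t > A

with adult age A (20 y by default; natural logarithm).  F is continuous,
strictly increasing, zero at A, and invertible on all reals, so
DNAm age = F⁻¹(m).  Hannum-style clocks use the identity transform: the
score is already years.

The package never ships real clock coefficients; clock tables are user
data (`probe_id,weight` CSV with an `(Intercept)` row) or synthetic.

## Probe masking and the deviation identity

Newer array generations lack some clock probes: the EPIC (850k) array is
missing 17 of the 353 Horvath CpGs (4.8%) and 6 of the 71 Hannum CpGs
(8.5%); the bundled lists in `methclock/data/` name them.  Scoring a
matrix from which probes have been masked requires imputation.  Under
reference-mean imputation (fill probe j with a constant r_j), the
transformed-score deviation between the full and reduced runs is exactly

    m_full,i − m_reduced,i = Σ_{j ∈ dropped} w_j (β_ij − r_j) .

This identity is the analytic oracle for the whole comparison analysis
and is asserted to 1e−10 in the tests.

## Imputation

* **reference_mean** — constant fill from a gold-standard cohort's mean
  betas (the behaviour of the widely used online calculator); the only
  method that can resolve probes with no observed values.
* **cohort_mean** — per-probe observed mean; resolves missing cells, not
  fully absent probes.
* **knn** (default k = 10) — for each incomplete probe row, the k
  nearest *fully observed* probe rows by Euclidean distance over the
  target's observed columns; missing cells are filled with the
  unweighted mean of the neighbours.  Distance ties are broken by
  probe-ID lexicographic order, making the procedure deterministic.
  Restricting candidates to complete rows gives the clean limit case
  (k = all complete rows → per-column mean of complete rows) and mirrors
  the classical impute workflow; rows with no eligible neighbour fall
  back to the cohort mean.  The published descriptions of clock
  pipelines do not state k, the metric, or the orientation; these
  defaults are declared assumptions, surfaced in logs.
* **constant** — fixed value; mainly for tests.

All methods are idempotent and keep imputed values inside the range of
the values they average.

## Comparison statistics

Deviation is defined as full − reduced, so a positive mean means the
reduced probe set underestimates DNAm age.  Summaries: overall and
per-dataset mean/SD, per-age-bin mean/SD in closed-open bins
([0,5), [5,10), …), Pearson correlations, and a paired t-test.
Regressions of DNAm age on chronological age are stratified at the
transform's adult age (below / at-or-above 20 y); slopes and intercepts
from independent fits are compared with

    t = (b_a − b_b) / √(SE_a² + SE_b²),   df = n_a + n_b − 4 ,

two-sided.  Age acceleration is the residual of DNAm age regressed on
chronological age (the inverted direction is available via a flag, since
both appear in the literature).  The cross-platform offset is the
indicator coefficient in OLS of DNAm age on platform + chronological
age.  All fits are ordinary least squares via statsmodels, 95% CIs from
the t distribution, α = 0.05, no multiplicity correction.  Samples with
unknown age are excluded from age-dependent outputs but retained in
paired summaries.

## Synthetic cohorts

The generator draws ages uniformly on [0, 100] (or resamples a supplied
pool) and sets β_ij = clip(μ_j + s_j·F(age_i) + ε_ij, 0.001, 0.999) with
ε ~ N(0, σ²), σ = 0.01 by default.  Any clock with Σ w_j s_j = 1 and
intercept −Σ w_j μ_j recovers chronological age *exactly* on noiseless
data; `construct_consistent_clock` builds one with w ∝ s, and permits
explicit weights on zero-slope probes (their baseline is absorbed by the
intercept, so consistency is untouched).  Closed forms used in the
tests: masking probes carrying signal fraction ρ = Σ_dropped w_j s_j and
imputing at the baselines leaves m = (1−ρ)·F(age); the score error
variance under noise is σ²·Σ w_j².

Two scenarios emulate the cross-array study designs:

* **horvath_like_scenario** (353 probes, 17 dropped, n = 1000).  The
  dropped probes have zero net age slope but carry clock weight, and
  their imputation reference means are offset from the cohort baselines
  — a reference cohort whose baseline methylation differs from the study
  population, which is what constant-mean imputation against an external
  gold standard actually encounters.  The deviation is then a constant
  δ in score units, hence δ·(A+1) years in adults and
  (A+1)·e^{F(t)}(1−e^{−δ}) below A: rising through childhood, flat
  (~3.5 y) thereafter, with the below-cutoff slope ratio e^{−δ} ≈ 0.85
  and an adult intercept shift of δ·(A+1).  Calibration: δ = 3.46/21
  (≈3.5-y adult underestimation, the magnitude reported for the Horvath
  clock on EPIC-restricted data) and dropped-probe weight magnitude
  1.13/((A+1)·σ·√17) so the adult deviation SD is ≈1.1 y at σ = 0.01.
  A by-product is the increasing deviation SD across child age bins that
  cross-array comparisons report, driven by the transform's Jacobian.
* **hannum_like_scenario** (71 probes, 6 dropped, identity transform).
  The dropped probes carry ρ = 0.10 of the age signal and are imputed at
  cohort-mean reference values, so the deviation is ρ·(age − mean age):
  the reduced set overestimates the young and underestimates the old —
  the sign-changing misestimation pattern reported for the Hannum clock.

What the generator does **not** emulate: probe-type I/II chemistry,
batch and plate effects, cell-composition structure, non-Gaussian beta
distributions (no beta-distributed noise in v1), and dataset-level
heterogeneity.  Passing tests therefore demonstrate correctness of the
algorithms and the masking/imputation arithmetic, not biological
validity of any particular clock on real arrays.

## Numerical choices

* Beta values beyond [0, 1] by more than 1e−6 are rejected; within
  tolerance they are clipped (GEO matrices contain rounding spill).
* Transform round trip is exact to 1e−9 over [0, 150]; the masking
  identity holds to 1e−10; OLS agrees with closed-form normal equations
  to 1e−8.
* Slope/intercept comparisons treat differences within 1e−10 (relative)
  as zero so that noiseless exact fits compare as equal.
* Strata with fewer than 3 aged samples are omitted from regressions
  with a warning; constant covariates are a hard error.
* CSV readers parse floats in round-trip mode and writers emit %.17g, so
  clock tables and beta matrices round-trip bit-exactly.

## Problem sizes

The test suite and the acceptance script use synthetic cohorts of
n = 500–1000 samples and 50–200 replicate seeds for the simulation-based
checks — large enough that Monte-Carlo error is well below the asserted
tolerances (e.g. SE of the adult mean deviation at n ≈ 800 is
~0.04 y), while the whole suite runs in seconds.

## Known limitations

* No idat-level preprocessing, normalization (BMIQ/quantile), or cell
  deconvolution: beta matrices are taken as provided.
* kNN cannot resolve probes absent from the matrix entirely unless a
  reference-mean fallback is supplied; this mirrors reality (a probe the
  array lacks has no within-cohort information).
* The paired deviation analysis assumes the same samples in both runs;
  cross-platform comparisons of independent cohorts go through the
  offset regression instead.
* Published clock coefficient sets must be supplied by the user; the
  package validates and applies them but does not distribute them.
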