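# Methods

This note documents the models, the numerical choices, and the design
decisions behind `nacmap`, and what the synthetic cohort does and does
not show about real data.

## Pipeline overview

Per subject: motion QC drops sessions whose displacement relative to the
first volume reaches 2 mm translation or 0.02 rad rotation (inclusive);
surviving sessions are band-pass filtered to 0.01–0.1 Hz; each session
yields a region × region Z matrix; session Z matrices are averaged and
binarized at Z > 1.96 (strict) into the adjacency matrix; normalized
α-centrality gives nAC₀ and nAC₁ per region; controls define a per
(region, sex, measure) normative band and every subject is compared
against mean + 2 SD at their age.

## Band-pass filter

The filter is the orthogonal projection onto the intersection of two
subspaces of R^T: signals whose discrete Fourier coefficients vanish
outside [0.01, 0.1] Hz, and signals orthogonal to constant offset and
linear trend.  A single "detrend, then mask" pass is *not* idempotent
(masking reintroduces the in-band component of the removed trend; the
one-pass discrepancy on white noise is a few percent), so the projector
onto the intersection is built explicitly: with B an orthonormal basis
of in-band cosine/sine modes and L = span{1, t}, the projector is
B N Nᵀ Bᵀ where N spans the null space of LᵀB.  It is symmetric,
exactly idempotent, removes DC and linear trends, and is cached per
(T, TR, band).  Consequences match intuition: an in-band sinusoid keeps
essentially all of its variance, an out-of-band sinusoid is removed
exactly, a constant maps to zero.

## Connectivity significance

Pearson correlations between filtered series are converted to t values
using an effective sample size that discounts temporal autocorrelation.
The default is the lag-1 form

    N_eff = n (1 − ρ̂ᵢ ρ̂ⱼ) / (1 + ρ̂ᵢ ρ̂ⱼ),

with ρ̂ the per-region lag-1 sample autocorrelation; a full-lag variant
N_eff = n / (1 + 2 Σₖ ρ̂ᵢ(k) ρ̂ⱼ(k)) (lags up to n/4, denominator
floored at 0.05) is available via `ess_mode="full"`, and the mode used
is recorded in every report.  N_eff is floored at 4 so the t
distribution keeps ≥ 2 degrees of freedom.  t is mapped to Z by quantile
matching on the signed tail — Z = Φ⁻¹ applied to the t tail probability
computed in log space (`t.logsf` + `ndtri_exp`) — which preserves
sign, keeps the p < 0.05 ↔ Z > 1.96 correspondence, and does not
overflow for |t| into the thousands; |Z| saturates at a configurable cap
(default 40, also returned for |r| = 1 with a warning).  Under
white-noise input this calibration puts the strict Z > 1.96 edge rate at
the one-sided normal tail, 2.5% (tested).

## Normalized α-centrality

The series C_αn is evaluated exactly by iterated multiplication
(P ← αPA, 21 terms at the default order n = 20).  The per-region score
is the row sum of C_αn / ΣC_αn — the unique reduction for which the
α = 0 score is exactly proportional to degree.  At α = 1/λ the terms do
not decay, but the normalization cancels the linear growth of the
dominant term; the normalized profile converges to the dominant
eigenvector profile v/Σv at rate O(1/n), because the sub-dominant part
of the series saturates at a constant while the dominant term grows
linearly.  Quantitatively, on 50-node random graphs the order-20 profile
sits within ~10⁻³ of the eigenvector limit and moves by a comparable
amount when the order is doubled; at 388 nodes and realistic density the
residual is ~10⁻⁵.  This O(1/n) tail is an intrinsic property of the
normalized partial sum, not of the implementation; tolerances in the
tests reflect it.  Two scales are emitted: the canonical sum-to-1 scale
(used by all statistics and the normative model) and a max-rescaled
scale in (0, 1] used only for distribution histograms.  Disconnected
graphs are flagged but not treated per component; λ comes from the full
spectrum.

## Normative model

Controls are split by sex; per region and measure, score is OLS-
regressed on age (the mean line), and the scaled absolute residuals
|e|√(π/2) are OLS-regressed on age (the SD line; for Gaussian residuals
E|e| = σ√(2/π), so the fitted line estimates σ at each age).  A pooled
homoscedastic SD is available via `sd_mode="pooled"`.  Predicted SDs are
floored at 10% of the pooled residual SD so noiseless fixtures cannot
create zero-width bands.  Age matching is continuous (prediction at the
subject's age), ages outside the fitted range are flagged as
extrapolation, and the abnormality rule is strict: score > mean + 2 SD.
Applied to subjects drawn from the fitted model itself, the per-region
flag rate is the one-sided 2 SD tail, 2.28% (tested to ±1 percentage
point).  Scores must arrive on one consistent scale: the fit records the
training profiles' score sums and both fitting and detection reject
inputs whose sums deviate by more than 25% from that reference, which
catches a max-rescaled profile slipped in among canonical ones.

## Downstream statistics

* Distribution χ²: subject's 388 max-rescaled scores histogrammed in
  width-0.05 bins on [0, 1] against the mean bin proportions of same-sex
  controls within ±5 years of age; when fewer than 10 controls match,
  the window is doubled until 10 do (or all same-sex controls are used),
  and the matched count is reported.  Adjacent bins are merged left to
  right until every expected count is ≥ 5 (the standard validity rule);
  df = merged bins − 1.
* Rank-sum comparison of abnormal-region counts: Wilcoxon rank-sum with
  tie-corrected normal approximation and no continuity correction;
  medians of both samples are reported.
* Spearman correlations via Pearson on mid-ranks with the
  t-approximation; partial Spearman rank-transforms all three variables
  and applies the first-order partial-correlation formula with df = n−3
  (used for duration of illness with age as nuisance covariate, since
  age and duration are confounded).
* Connection percentage: 100 × edges among the aR₀ set / C(n, 2);
  undefined (reported missing) when the set has fewer than 2 regions.
* Cohen's κ between the aR₀ and aR₁ indicator labelings; κ defined as 1
  when both labelings are constant and identical.
* DMN enrichment: goodness-of-fit χ² (df = 1) of the (in-DMN, out-DMN)
  split of an abnormal set against expected proportions 100/388 and
  288/388.  On small discrete sets the χ² approximation is slightly
  conservative (true level ≈ 3.6% at nominal 5% for sets of 10–80
  regions), which the calibration test measures precisely rather than
  hides.
* Edge-count ANCOVA: OLS `edges ~ group + age` with the partial F for
  group, and the interaction F from comparison against
  `edges ~ group * age` (statsmodels).
* No multiple-testing adjustment is applied; the cohort report counts
  the number of unadjusted tests it contains.

## Synthetic cohort generator

The generator emulates the features of real rs-fMRI cohorts that the
analysis depends on, with defaults frozen once at design time:

* 300 controls spanning ages 18–84 for both sexes (62% female) and 10
  patients; 3 sessions × 101 volumes at TR = 3 s; 388 regions, 100
  flagged as DMN.
* Latent correlation: 6 contiguous communities; within-community
  correlation 0.30 with an age slope of −0.001/yr and a +0.02 offset for
  females; between-community correlation 0.05.
* Between-subject variability: each subject draws per-region coupling
  offsets uᵢ ~ N(0, 0.06) that shift *within-community* correlations by
  uᵢ + uⱼ.  Placing the heterogeneity on the saturating within-community
  channel gives regional degree a left-skewed, light-upper-tailed
  distribution across subjects — so Gaussian normative bands flag very
  few control regions — while still producing the age- and sex-dependent
  dispersion the normative regression estimates.  (Heterogeneity on the
  sparse between-community channel instead produces heavy right tails
  and 6–9% control flag rates, destroying the patient-control contrast;
  this alternative was examined and rejected at design time.)
* Temporal structure: AR(1) with φ = 0.3, innovations drawn with the
  latent covariance and the process started from its stationary law, so
  the session's population correlation equals the latent correlation for
  any φ.
* Patients: 5 hub regions each, whose latent correlation to every other
  region is boosted by +0.3 (clipped at 0.95, nearest-positive-definite
  repair by eigenvalue clipping at 1e-8 plus re-normalization to unit
  diagonal).  Hubs are the ground truth for recovery tests.
* Motion: Gaussian random walks well under the exclusion limits, with an
  optional injected violating session for QC tests.
* Determinism: one cohort seed drives everything through
  `SeedSequence`-derived per-subject seeds; regeneration is
  bit-identical.

What the generator does **not** emulate: physiological noise, scanner
drift and site effects, epileptiform discharges, spatially continuous
(voxel-level) signals, realistic edge-density profiles (the synthetic
graphs are denser than typical thresholded connectomes), and the heavy
between-subject tails of real normalized centrality — real controls show
many more normative outliers than the synthetic ones (whose flag counts
sit near zero).  Passing tests therefore demonstrate the correctness and
calibration of the machinery, not clinical effect sizes; the patient
abnormality model (uniform hub injection) is a deliberately simple
stand-in chosen to make parameter recovery testable, not a model of
epileptic network pathology.

## Numerical and interface conventions

Region ids are 0-based everywhere on disk and the atlas row order is the
canonical region order, asserted at every read.  Z matrices and profiles
round-trip through TSV at 1e-12; binary adjacencies round-trip through
Matrix Market.  The pipeline writes a manifest (config, version, modes,
exclusions) sufficient to re-run any subject identically, and warnings
(SD floor in effect, extrapolated age, disconnected graph, dropped
sessions) are machine-readable in the cohort report.  Problem sizes in
the acceptance script — 300 + 10 subjects, 40 held-out controls, 400
model-drawn null subjects, 1000/5000 null draws, 200 random graphs — are
the package's chosen defaults for a single-CPU run of a few minutes.
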