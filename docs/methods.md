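# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators emulate (and what they do
not), and the numerical choices that matter.

## Chronology: weight → age → relative time

Within a species, embryo weight is a tight proxy for developmental age.
The calibration model is

  age = f(boxcox(weight, λ)) + ε,

with f monotone non-decreasing. f is a non-negative linear combination of
I-splines (integrated cubic B-splines, knots at quantiles of the
transformed weights) plus a free intercept, fitted by non-negative least
squares; since every I-spline is non-decreasing and the coefficients are
non-negative, monotonicity holds by construction rather than by post-hoc
check. The Box-Cox exponent λ is chosen on a grid (−1…2, step 0.05) by the
Gaussian profile likelihood of the fit; because the transform is applied to
the predictor, no Jacobian term is needed. Predictions outside the training
weight range raise an error rather than extrapolate — silent extrapolation
would systematically bias relative times at the ends of a series.

Ages are mapped onto a relative 0–10 timeline by an affine map anchored on
two morphological milestones per species (early cap stage → 0, crest stage
→ 10; mouse 14.6/18.0 dpc, hamster 12.3/14.6 dpc). The ratio is computed
before scaling so the anchors map to 0 and 10 exactly in floating point.
Values outside [0, 10] are returned (the sample predates/postdates the
anchors) and can be flagged. Litter effects and maternal covariates on
weight are out of scope.

## Staging: Erlang phase-type stage durations

Cusp patterning is an ordered, irreversible sequence of K stages; each
embryo contributes one cross-sectional observation (relative age, stage).
Stage k is expanded into m_k consecutive exponential substates sharing rate
λ_{c(k)}, so its sojourn is Erlang(m_k, λ) with a mode away from zero —
a realistic stage-length distribution, unlike a plain exponential. The
default m_k = 5 for all non-terminal stages balances realism against state
space size; the terminal stage is absorbing (m_K = 1). Stages may share
rates through rate classes c(k), giving a nested family from one common
rate up to one rate per stage.

The likelihood of an observation (t, s) is the occupancy probability
P(stage = s at t), conditional on the embryo's age — ages enter as known
covariates, not as random sampling times. Occupancies are computed by
uniformization: P(t) = Σ_n Poisson(n; Λτ) · v_n with v_n = e₁ᵀMⁿ,
M = I + Q/Λ, truncated at 1e−14 of Poisson mass. This is exact to the
truncation level (verified against the closed-form Erlang survival at
≤1e−8... in practice machine precision) and far faster than repeated
matrix exponentials, which matters for the simulation studies.

Fitting maximizes the log-likelihood over log-rates (L-BFGS-B, relative
tolerance 1e−8, 5 seeded random restarts, first-found maximum on ties).
Observations before the process start are excluded with a logged count;
observations with probability exactly zero (staging noise) contribute a
−1e10 floor with a warning instead of aborting. Expected durations are
m_k/λ_{c(k)}; relative durations are normalized to sum to 1, which removes
the overall time-scale and makes estimates comparable across species.
Nested rate-class structures are compared by forward LRT along the chain
(χ² with df = difference in free rates, α = 0.05): the simplest structure
not rejected against the next fuller one is retained.

The process origin (start_time) is anchored at the chronology milestone by
default and is configurable; with cross-sectional data the origin and the
absolute rates trade off, which is another reason relative durations are
the primary output.

## Expression profiles: nested NB spline models

Counts y_gs are modelled as NB(μ_gs, α_g) with
log μ_gs = x_sᵀβ_g + log(size factor_s). Size factors are median-of-ratios
(per-gene geometric-mean reference over genes positive everywhere),
rescaled to geometric mean 1. Mean curves are cubic B-splines with 2
interior knots at the 33/67% quantiles of the observed relative times
(6 basis functions per curve); with fewer distinct timepoints than basis
functions the basis auto-reduces (interior knots first, then degree), so a
3-timepoint limb design yields a quadratic polynomial.

The four model classes are: `simple` (one shared curve + species baseline
offset, 7 df), `species` (one curve per species, 12 df), `tooth` (one curve
per organ + species offset, 13 df), `complex` (one curve per species×organ,
24 df). Species baselines are single additive log-scale intercept shifts —
the comparisons target regulation over development, not absolute level
differences, which can also carry cross-species quantification artifacts.
All column spaces nest (simple ⊂ species, tooth ⊂ complex), verified
numerically in the tests.

**Dispersion.** α_g is estimated once per gene under the complex design by
Cox-Reid adjusted profile likelihood (the −½ log det(XᵀWX) adjustment; plain
ML is severely biased downward when 24 parameters are fitted to 32
samples — we measured median α̂ ≈ 0.004 for a true 0.05, which inflates
every LRT). The per-gene CR estimates, still noisy on ~8 residual df, are
then moderated: empirical-Bayes shrinkage of log α_g toward the
cohort-common CR dispersion (the maximizer of the summed adjusted profile
likelihood), with per-gene weights from the curvature of the adjusted
profile. The moderated α_g is held fixed across all nested fits of the
gene, as a valid LRT requires. With this scheme the null rejection rate of
the four tests is 4–7% at nominal 5% and the null p-values are
KS-uniform; without it they reach 13–20%. Genes whose profile is flat in α
(Poisson-like) shrink fully to the common value, which errs conservative.

**Fitting.** NB GLMs with fixed α are fitted by IRLS with step-halving,
convergence on the coefficient step (1e−8 relative) — the likelihood
flattens long before coefficients reach full precision. For near-Poisson
dispersions (1/α ≥ 1e7) the gammaln difference in the log-likelihood is
evaluated by its series in y·α, and the r·log(r/(r+μ)) term via log1p;
both direct evaluations lose ~1e−6 of absolute precision to cancellation,
enough to destabilize step acceptance. Fits agree with statsmodels GLM
(NegativeBinomial family) to ≤1e−5 in coefficients, which the tests check
as an independent oracle.

**Selection.** Four LRTs per gene — t1: species vs simple, t2: tooth vs
simple, t3: complex vs tooth, t4: complex vs species — each BH-adjusted
across genes within its own family (the family structure keeps the four
tests' error rates separately controlled). Significance is strict
(adjusted p < 0.05). Decision tree: neither t1 nor t2 → `simple`; t1 only →
`species`, escalated to `complex` if t4; t2 only → `tooth`, escalated if
t3; both → `complex` if t3 or t4, otherwise the better-likelihood two-curve
model. The escalation is symmetric in t3/t4 by design. Genes with total
count < 10 (configurable) or failing fits are reported untested.

The coevolution index is count(species)/(count(species)+count(tooth)+
count(complex)) among tested genes, optionally within a supplied gene list.
Per-organ divergence uses the same machinery restricted to one organ:
`divergent` (curve per species) vs `non-divergent` (shared curve), both
with species offsets; the reported proportion is divergent/tested.
Two divergence proportions are compared by a two-sided two-proportion
z-test.

**Distances.** For complex-class fits, curves are evaluated at 100 equally
spaced points on the timeline, split into 10 windows of 10; each window
reports ‖Δ‖₂/√10 (per-point RMS), so values are comparable across window
widths and a constant log-scale offset c yields c in every window.
Distances are computed on the log-scale linear predictor including species
baselines by default (`include_baseline=False` to exclude). The variance
decomposition runs PCA on log1p normalized counts and reports, per factor,
the between-group share of score variance weighted by component variance.

## Deconvolution

Markers are selected per gene by an NB Wald test of the two-tissue effect
(dispersion per gene as above; Wald rather than LRT for speed), BH-adjusted
p < 0.05 and |log2FC| strictly above the threshold (3 for
epithelium/mesenchyme-like contrasts, 1 for subtler buccal/lingual-like
ones). The signature is the mean normalized expression of each marker in
each pure tissue. Bulk samples are decomposed on the normalized linear
scale (mixtures of counts are linear; log scale would break that) by
exactly solving min ‖b − Sp‖₂ s.t. p ≥ 0, Σp = 1 via support enumeration:
the optimum restricted to its active support solves the equality-
constrained problem, so for small k enumerating the 2^k − 1 supports and
keeping the best feasible candidate is the exact QP solution. An
NNLS-then-normalize fallback is provided but differs in general; the QP
result is authoritative. Near-collinear signatures (condition number >
1e10) raise a conditioning error. Uncertainty comes from resampling the
marker list with replacement (B = 1000), rebuilding the signature and
re-deconvolving; 2.5–97.5% percentile intervals are clamped to contain the
point estimate. Only k = 2 is exercised; the solver accepts k ≥ 2.

## Synthetic data

Generators are pure functions of (config, seed); one pipeline seed fans out
into independent named streams (SeedSequence spawn keys from CRC32 of the
stream name), so enlarging one simulation never shifts another's draws.

The rodent preset mirrors the study design this package addresses: 8
timepoints × 2 organs × 2 species, one replicate (32 samples); a 9-stage
cusp sequence (PEK, 1-SEK…7-SEK, crest) with m = 5 substates and preset
relative durations; 100-marker two-tissue signatures and mixtures with 20%
CV multiplicative gamma noise; weight/age pairs from
age = 11.4 + 0.39·w^0.4 (a curve through mouse-like anchor points,
~14.6 dpc at 200 mg and ~18 dpc at 1200 mg) with σ = 0.1 d Gaussian noise
and log-uniform weights over 150–1300 mg. A bat-like preset gives the
sparse 3-timepoint × 2-organ limb design with 3 replicates.

Expression effect sizes: per-gene base curves are spline coefficient
vectors ~ N(log 200 baseline, 0.7² shape variation); class structure is
imposed by sharing or perturbing coefficients with N(0, effect²) draws,
effect = 1 by default (an e-fold curve difference, a realistic strong
regulatory change); species offsets ~ N(0, 0.5²); NB dispersion 0.05
(typical for clean bulk RNA-seq); library sizes log-uniform on 0.5–2.
Because perturbations are random draws, some "informative" genes carry
near-zero realized effects; classification accuracy on the benchmark is
therefore bounded away from 1 by design, not by the fitter.

What the generators do *not* emulate: mean-dispersion trends and outlier
genes, count-level correlation between orthologues, mappability/length
biases, batch effects, staging errors in the (age, stage) observations, and
compositional interference between non-marker genes in mixtures. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to those real-data violations.

## Pipeline and formats

All tables are TSV (UTF-8, '.' decimal, 'NA' missing); results are written
with a fixed float format so reruns are byte-identical. `run_pipeline`
executes chronology → staging → profiles → deconvolution on the synthetic
preset and writes a manifest (package version, seed, config, SHA-256 of
every output; declared input checksums are verified before any computation).
The pipeline preset uses 100 genes per class — enough for stable
coevolution and divergence summaries while keeping a full run under a
minute — and the benchmark experiments use the sizes stated in their
docstrings (e.g. 500 genes/class for the classification benchmark, 200
replicates for LRT calibration).

## Known limitations

- The chronology smoother is not the same smoother as any particular GAM
  implementation; only the monotone weight→age contract is reproduced.
- Erlang shapes m_k are not identifiable from cross-sectional data at these
  sample sizes and are fixed by configuration, so absolute durations from
  differently-shaped fits are not comparable; relative durations are.
- The LRT χ² reference is asymptotic; at 32 samples the moderated-dispersion
  tests are close to nominal (4–7% at 5%) but not exact.
- BH is applied per test family; no hierarchical correction across the four
  families is attempted.
- The deconvolution bootstrap resamples markers only; it quantifies
  signature-choice uncertainty, not biological replicate variance.
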