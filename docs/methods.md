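# Methods

This note documents the models, conventions and numerical choices behind
`carescreen`, in the order the pipeline applies them.

## Data model and scoring conventions

A survey blueprint (`SurveyDesign`) fixes the presentation order of
items, their factor membership, the reverse-worded subset, the
instructed-response item with its required category, and the integer
response bounds. The instructed item is stored with the responses
(screening needs it) but is structurally excluded from every reliability,
factor-analytic and scoring computation.

Scale scores are **sums** of reverse-recoded items, not means. Sums keep
the arithmetic exact on integer data and make permutation-test mean
differences interpretable in raw score points; the scoring functions also
accept a mean convention for cross-checks against data scored elsewhere.
Reverse recoding reflects a response x to `(scale_min + scale_max) − x`;
it is an involution, which the test suite asserts on random matrices.

Missing or out-of-range values are handled by a complete-case policy at
read time: offending rows are excluded and itemized in a rejection
report, never imputed.

## The synthetic-data generator

Attentive respondents follow a graded (categorical) factor model. Factor
scores θ are multivariate normal with unit variances and correlation
matrix Φ (default: 0.5 everywhere off-diagonal). Each item's latent
response is

    y_j = μ_j + λ_j θ_f(j) + ε_j,   Var(ε_j) = 1 − λ_j²,

discretized at fixed thresholds into categories. Defaults, with reasons:

* **Thresholds** at the normal quantiles of cumulative (0.1, 0.3, 0.7,
  0.9) for 5 categories — symmetric, mildly peaked middle categories.
* **Item intercepts** μ_j = +0.5 sd in the keyed direction (sign-flipped
  on the presentation scale for reverse-worded items). Attitude items are
  endorsement-skewed in practice: attentive means sit above the scale
  midpoint. This skew is not cosmetic — it is the mechanism that makes
  reverse-worded items the large-mean-shift items under acquiescent
  contamination. With zero intercepts the attentive means sit exactly at
  the midpoint and acquiescent careless responding shifts standard and
  recoded-reverse items symmetrically, which no real attitude battery
  shows.
* **Loadings** average ≈ 0.57: standard items ramp over 0.55–0.70 within
  each factor; reverse items load weakly (0.25–0.35), matching the
  well-documented signature of reverse-worded attitude items.
* **Careless prevalence** 0.1133 of n = 1112 (126 respondents), the
  default study size.
* **Archetype mix** 70% acquiescent, 15% uniform-random, 10% fixed
  straightliner, 5% late-onset. The acquiescent archetype draws each
  response from the top two categories with probabilities 0.52/0.48. The
  late-onset archetype answers attentively up to presentation position 19
  and acquiescently afterwards (the dominant failure mode is the natural
  choice for the post-onset process). Archetypes govern the instructed
  item too — careless responding is content-blind, so the check is not
  special-cased. Consequently acquiescent responders always fail it while
  uniform responders pass with probability 1/#categories: the flagged
  prevalence under the default mix is slightly *below* the planted
  prevalence, which is the single-indicator blind spot the extended
  definition addresses.
* **Criterion scales** (19 items on 0–10; 9 items on 1–7) hang off
  criterion latents whose correlation with the *equally weighted
  composite* of the focal factors is the configured value (default 0.40);
  criterion latents intercorrelate at 0.60 and their items load at 0.65
  with equal-probability thresholds. Defining the correlation against the
  composite (rather than against each factor separately) keeps the
  configured number interpretable: score-level correlations then land
  around 0.3–0.37 after categorical attenuation, the range typical of
  attitude–criterion correlations.

Randomness is counter-based: respondent *i* draws from
`default_rng([seed, i])`, so changing the row count never perturbs other
rows' draws, and archetype assignment uses the same per-row substream.

**What the generator does not emulate.** Real careless respondents are
only *partially* inattentive; archetypes here are fully content-blind.
Two visible consequences. First, a *mixture* of archetypes induces a
spurious "response elevation" factor in the careless group (acquiescent
rows high everywhere, straightliner rows constant, uniform rows mid) with
negative loadings on recoded reverse items; a multigroup model that
constrains loadings equal across attentive and mixed-careless groups then
genuinely misfits, and metric invariance fails. A homogeneous acquiescent
careless group — which is what instructed-item failers overwhelmingly are
in real batteries — shows the classic pattern instead: metric holds,
scalar fails. The invariance examples and replicate tests therefore
compare attentive vs acquiescent-careless groups. Second, because
acquiescent archetypes answer high on focal *and* criterion items, shared
method variance *inflates* unscreened criterion correlations here,
whereas partially attentive humans more often attenuate them; the
correlation-comparison machinery (Fisher z, Cohen's q) is indifferent to
the direction. Passing tests on this generator demonstrate that the
pipeline detects and quantifies the planted structure, not that real data
behave identically.

## Screening indices

* **Longstring** is computed over the full concatenated battery in
  presentation order on raw (non-recoded) values — identical-response
  runs should be counted as the respondent produced them.
* **Even–odd consistency** uses the reverse-recoded focal items, needs at
  least three factors, and is `1 − r_sb` where r is the respondent's
  Pearson correlation between odd- and even-position half-scale means
  across factors and r_sb its Spearman–Brown step-up. r is clipped below
  at −0.999 (the step-up degenerates at −1); the upper end is left at 1
  so a perfectly consistent respondent scores exactly 0. Zero-variance
  half-mean vectors (pure straightliners) receive the maximal score 2:
  an undefined correlation must not reward the behavior the index exists
  to catch.
* **Cut-offs** for the extended definition are mean + 2 SD (n − 1
  denominator) of each index *in the unscreened sample*.
* The **outlier pre-screen** (|z| > 4 of the recoded total, n − 1 SD)
  runs before careless screening; extreme-but-consistent responding and
  content-blind responding are different threats.

## Reliability

Alpha uses the classical variance decomposition with n − 1 variances; its
95% interval is the Feldt F interval with (n − 1) and (n − 1)(k − 1)
degrees of freedom. Omega comes from the higher-order route: the
first-order CFA's standardized loadings and factor correlations, a
one-general-factor solution for the factor correlations (closed form for
three factors, a shared loading for two, iterated least squares
otherwise), and the Schmid–Leiman split g_j = λ_j γ_f(j),
s_j = λ_j √(1 − γ²). ω_h = (Σg)²/V and ω_t = [(Σg)² + Σ_f (Σs)²]/V with
V including the standardized residuals. Subscales get a congeneric
(one-factor) ω_t only; a hierarchical decomposition of a single subscale
is not meaningful.

## Confirmatory factor analysis and invariance

Estimation is plain normal-theory ML on the unbiased sample covariance
(and means, when a mean structure is requested):
F = ln|Σ| + tr(SΣ⁻¹) + (x̄−μ)′Σ⁻¹(x̄−μ) − ln|S| − p, with
χ² = Σ_g (n_g − 1) F_g. Robust (sandwich/scaled) corrections are out of
scope; on ordinal data the plain-ML fit statistics are mildly optimistic,
which is why decision *rules* and parameter estimates, not raw index
values, are the quantities this package treats as reportable.

Identification fixes the first indicator loading of each factor at 1.
Factor covariances are parameterized through a Cholesky factor (the
optimizer cannot leave the positive-definite cone); residual variances
are bounded below at 0.001 and a Heywood diagnostic is recorded when any
sits on that bound. The Cholesky diagonal is floored at 0.05 × the
typical item sd: a group whose factor variance collapses to zero leaves
its loadings on a flat manifold where any gradient method stalls, and the
floor (implying minimum common variance of ~0.25% of an item variance,
negligible for fit statistics) removes the degeneracy. Optimization is
L-BFGS-B with analytic gradients (verified against finite differences in
the suite), start values λ_j = sd_j/sd_marker, φ_ff = 0.49 var_marker,
factor covariances at 0.3, ψ_j = 0.5 var_j, up to three jittered restarts
under a fixed jitter seed, and Hessian-resetting polish passes.
Convergence means projected gradient ≤ 1e-5; a plateaued function with
projected gradient ≤ 5e-3 at a bound is reported as a (converged)
boundary solution.

Fit indices: CFI and TLI against an independence baseline with free
variances and means per group (closed form); RMSEA with n − 1 (one group)
or N − #groups (multigroup) in the denominator and a 90% interval from
inverting the noncentral χ²; SRMR as the root mean square of
(S − Σ̂)/√(s_ii s_jj) over the lower triangle *including* the diagonal.
These dialect choices (diagonal included, unbiased variances, no √G
factor in multigroup RMSEA) are fixed, not configurable, so that golden
values in the tests stay stable. CR and AVE come from the standardized
solution: CR_f = (Σλ)²/((Σλ)² + Σψ), AVE_f = Σλ²/k_f.

The invariance ladder is configural (all free; intercepts free, factor
means 0 in both groups), metric (loadings equal), scalar (loadings and
intercepts equal; the second group's factor means free). Each step is
supported iff ΔCFI ≥ −0.010 and ΔRMSEA ≤ 0.015 against the previous
step; Δχ² with Δdf is reported alongside. Groups below 100 respondents
are refused — multigroup estimation is unstable below that.

## Impact statistics

The nested permutation test reassigns the careless label to the same
number of respondents drawn without replacement; p is the plain
proportion of permuted |full-minus-subsample mean differences| at least
as large as the observed one — **no +1/(B+1) smoothing**, so exhaustive
enumeration (used automatically when C(N, k) is small enough) yields
exact, pinnable p-values. Default B = 10,000 with seed 2025.

Fisher's z for two correlations uses the independent-samples formula even
for the nested unscreened/screened comparison, exactly as applied
practice does; the docstring warns that overlap makes the p approximate.
Cohen's q = |atanh r₁ − atanh r₂| with bins 0.10/0.30/0.50 and d bins
0.20/0.50/0.80; boundary values fall in the lower bin. Cohen's d uses the
pooled n − 1 sd with a normal-approximation CI and a Welch t alongside.
The minimum detectable effect solves the two-sided noncentral-t power
equation (ncp = d√(n₁n₂/(n₁+n₂))) by bracketing.

CSI components are absolute differences, so the table is symmetric in
which sample is called "unscreened". Ranks break ties by presentation
position (earlier item first) for determinism. CSI-z requires nonzero
across-item variance in every component; a constant component is an
error, not a silent zero.

## Pipeline

One run executes: simulate (or load) → outlier pre-screen → indicator
computation and flagging → parallel reliability and CFA on unscreened and
screened samples → invariance between the attentive and careless groups
(independent-groups framing) → permutation, correlation, effect-size and
CSI analyses (nested framing). Identical configuration and seed yield a
byte-identical JSON report; stage counts (respondents in, outliers
removed, flagged, retained) are logged so the sample-flow diagram is
reconstructible from the log. Partial failures (e.g. a careless group too
small for invariance) become structured warnings, not crashes.

## Problem sizes in the test suite

The suite simulates at the default study size (n = 1112) for
replicate-level checks: 20 replicates each for CFA parameter recovery
(n = 2000 per fit, median loading error ≤ 0.05 — the tolerance absorbs
the small categorization attenuation), for the invariance pattern
(attentive 986 vs acquiescent 126), and for the reliability/CSI
contamination signatures; permutation-calibration uses 500 repetitions of
B = 2000 at n = 40. One-off large-n oracle values (e.g. the alpha of the
six-item λ = 0.7 model at n = 10⁶) were computed once with independent
implementations and frozen into the tests.

## Known limitations

* Ordinal data are analyzed with Pearson covariances and plain ML, not
  polychoric/WLSMV estimation; loadings are mildly attenuated relative to
  the latent-response metric.
* No partial-invariance search, modification indices, or bootstrap CIs
  for fit indices.
* The careless archetypes are fully content-blind; graded inattention,
  response-time information and person-fit mixtures are out of scope.
* The even–odd index's exact transform varies across software; the
  1 − r_sb convention here matches the reported range and direction of
  published values but other conventions exist.
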