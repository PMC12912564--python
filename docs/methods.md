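# Methods

## The mixture model

A continuous-report trial yields a signed angular error θ ∈ (−180°, 180°]
(response minus target, wrapped; the ±180° boundary is assigned to +180°
by convention, tested explicitly). Errors are modelled as

p(θ) = pT · vM(θ; 0, K) + (1 − pT) / 360,

with all densities expressed **per degree** (the uniform component is
1/360) so that log-likelihoods are comparable across estimators and
across the no-guessing alternative. pT ∈ [0, 1] is the probability a
memory is retrieved at all; K ≥ 0 is the von Mises concentration of the
retrieved-trace error, the precision measure. K maps one-to-one onto a
circular SD via SD = √(−2 ln(I₁(K)/I₀(K))); the inverse (`sd_to_k`) is
solved by bracketed root-finding on the exact Bessel-ratio expression
(relative tolerance ~1e-10) rather than by series approximation, using
exponentially scaled Bessel functions throughout. K is capped at 700,
where the circular SD is already below ~2.2° and I₀ would overflow in
unscaled form; SDs so wide that K would fall below 1e-6 return K = 0 with
a warning (the uniform limit).

### Maximum-likelihood fitting

The default estimator is deterministic multi-start MLE: EM updates run
from every point of a 5 × 5 grid (pT ∈ {.1, .3, .5, .7, .9} ×
K ∈ {1, 4, 16, 64, 256}); the E-step computes target-component
responsibilities, the M-step sets pT to the mean responsibility and K by
inverting the weighted mean resultant length (A(K) = I₁/I₀, solved by
bracketed root-finding). The best EM run is polished by bounded L-BFGS-B
with the analytic gradient. Convergence tolerance is 1e-8 on the
log-likelihood; the optimum is verified in tests against 101 × 101 brute
grids to within 1e-6. K is searched in [1e-3, 700]. Inside resampling
loops (permutation, bootstrap) refits warm-start from the relevant pooled
estimate with the polish step disabled — each permuted group is a blend
of the original groups, so the pooled parameters are an excellent start
and EM-level accuracy suffices for difference distributions.

A fit is flagged non-converged only if every start fails; such subjects
are dropped (with a log entry) from downstream analyses.

### Bayesian fitting

`fit_mixture_bayes` offers posterior summaries when interval estimates at
the subject level are wanted: random-walk Metropolis on (logit pT, log K)
with the change-of-variables Jacobian, a uniform prior on pT, and a
weakly informative LogNormal(ln 10, 1.5) prior on K (95% mass roughly
K ∈ [0.5, 190], covering the range plausible for this task class). Two
chains with overdispersed starts, 600 adaptation + 1500 kept draws each;
proposal scale adapts toward ~30% acceptance during warmup only.
Convergence is judged by the split-chain potential scale reduction
(R̂ < 1.05 per parameter); non-converged fits are flagged unusable, the
analogue of excluding subjects whose toolbox fits failed. These priors
and sampler settings are this package's defaults — reference toolboxes
do not document theirs, and no claim of equivalence is made.

### No-guessing alternative and model comparison

The one-parameter alternative fixes pT = 1 (pure von Mises); its K-MLE is
closed-form via the mean-resultant-length equation. `compare_models`
reports AIC = 2k − 2ℓ for both models (k = 2 vs 1) and prefers the lower;
|ΔAIC| > 2 is treated as a decisive margin, the same convention used for
model selection elsewhere in this analysis class. With realistic guessing
rates (pT ≈ 0.6–0.8) the two-parameter model wins decisively at n in the
low thousands; under a true pT = 1 the penalty usually favours the
simpler model, and tests assert only parsimony-or-tie there.

## Semi-parametric estimation

When subject-level fits are unreliable, the pipeline fits the mixture
once to pooled group data and derives a guessing threshold: the |θ| where
the posterior responsibility of the target component is 0.5, equivalently
where pT·vM(θ; K) = (1 − pT)/360, giving
cos θc = [ln((1 − pT)/pT) + ln I₀(K)] / K. If the target component
dominates everywhere the threshold is 180° (nothing is called a guess);
if the uniform component dominates everywhere the threshold is 0° with a
warning. The responsibility-0.5 rule is the standard construction for
threshold-based scoring; toolbox-specific variants are not reproduced.

Subject-level retrieval is then #{|θ| ≤ θc}/n, and precision is −1 × the
SD of within-threshold errors (sign-flipped so higher = more precise).
The within-threshold SD is the **linear** sample SD (n−1 denominator;
ddof is configurable): within a narrow threshold the circular correction
is negligible. Retrieval is upward-biased relative to pT because a
fraction θc/180 of guesses lands inside the threshold; for concentrated
von Mises components the inflation is ≈ (1 − pT)·θc/180, asserted in
tests at n = 10⁵. The estimator is monotone in the cutoff and tracks true
pT with Spearman ρ ≥ 0.8 at 75 trials/subject in recovery simulations.

## Permutation inference

Group differences in group-level parameters are tested by shuffling
subject labels (trials travel with their subject — within-subject trials
are not exchangeable), preserving group sizes, and refitting pooled
groups per iteration (default B = 1000). The p-value is two-tailed on
absolute differences with add-one correction, p = (#{|perm| ≥ |obs|} + 1)/(B + 1):
it is never exactly zero (floor 1/(B+1)) and counts ties as exceedances
(conservative). z-scores standardise the observed difference by the
permutation distribution's mean and SD (ddof = 1). The test aborts if
more than 5% of permutation fits fail to converge. Type-I error is
calibrated in the acceptance suite: 200 null simulations of 20 subjects ×
75 trials per group at B = 200 — sizes chosen to make the calibration a
routine part of the default test run — give rejection rates within
[0.02, 0.09] at nominal 0.05.

## Bayes factors

`jzs_ttest_bf` integrates the noncentral-t sampling density against a
Cauchy(0, r) prior on the standardised effect (default r = 0.707; one- or
two-sample via the effective n), normalised by the central-t density;
tests cross-check it against the independent Zellner–Siow g-prior
integral and against pingouin to ≤ 1e-4 relative error. `pearson_bf`
places a stretched Beta(1/w, 1/w) prior on ρ (width w = 1 is uniform on
(−1, 1)) and integrates the exact likelihood ratio of the observed r,
a Gauss hypergeometric expression whose argument stays inside the unit
interval for |r| < 1 (parameters satisfy c − a − b = n − 3/2 > 0, so the
series converges there and no separate near-|r|=1 branch is needed at the
sample sizes this package targets). Both are two-sided; BF01 = 1/BF10.

## Lifestyle scoring

Activity-frequency items are answered 0–5 (never … daily) for the
typical phase and the pandemic phase. The phase score is the unweighted
sum over non-excluded items, with a pluggable weight table as the
extension point for published weighting schemes; change = typical −
pandemic (positive = reduced engagement). Items incomparable across
phases (life-phase-cumulative counts such as places travelled) can be
excluded by name. Item-level change uses paired Wilcoxon tests at a
Bonferroni alpha of 0.05 divided by the actual item count (0.05/17 ≈
0.0029 for the default set); all-tied items are degenerate and never
flagged significant.

## Synthetic data

The generators define the simulated study conditions:

- **Displays**: 29 scenes × 3 objects, continuous positions in [0, 360),
  rejection-sampled to pairwise separations ≥ 62.04° (cap 10,000 attempts,
  then a loud failure); each target is paired with a similar lure, 174
  objects in total. Configurations that cannot fit on the circle are
  refused up front.
- **Cohort** (defaults): 59 subjects × 75 trials/timepoint; true
  pT ~ logit-Normal(0.90, 0.80) (mean ≈ 0.70, subject SD ≈ 0.15) and
  K ~ log-Normal(ln 14, 0.35), matching group-level means and
  subject-level spreads typical of older-adult samples on this task;
  lifestyle sums bivariate normal with means 33.37/28.90, SDs 7.39/7.53,
  correlation 0.86 (rounded, clipped to [0, 85]); age ~ N(72.98, 5.78²)
  truncated at 60, 39/59 female, 18/59 family history of dementia,
  depression ~ N(7.14, 4.21²) clipped to [0, 30], follow-up interval
  ~ N(2.76, 0.95²) years. The default lifestyle→memory effect is zero (a
  null design); `lifestyle_memory_effect` adds a slope on the logit/log
  scales per SD of lifestyle decline. Attrition is
  missing-completely-at-random by default, with an optional
  performance-dependent log-odds slope for exploring selective attrition.
- **Items**: 17 activities with per-item typical means and pandemic
  shifts; a shared per-subject engagement trait induces the between-phase
  correlation. The default item set was calibrated once so the summed
  scores land near the cohort targets above (typical ≈ 33.1 (7.5),
  decline ≈ 4.6, correlation ≈ 0.85 across seeds).

What the generators deliberately do **not** emulate: response-time
structure, swap/misbinding errors, set-size effects, practice effects at
T2, item-level missingness patterns, or non-normal covariate shapes.
Passing recovery tests therefore show the estimators work when the model
class is correct; they do not certify robustness to misspecification.

## Pipeline conventions

- Outlier screening: |value − mean|/SD > 3 (sample SD), computed once,
  non-iteratively, per outcome independently — so different subjects may
  be excluded from the retrieval and precision analyses; every exclusion
  is logged and every input subject appears in results or the log.
- z-scoring uses an explicit reference sample (the full T1 sample in the
  change analysis), so T2 scores are on the T1 scale.
- Change scores are T1 − T2 on z-scored outcomes: positive = decline,
  matching the sign convention of the lifestyle change score.
- Group-level CIs in the two-group report are percentile bootstrap over
  subjects (default 1000 resamples).
- The two-group report's guessing threshold comes from a single fit
  pooled over all trials, so both groups are scored against one cutoff.
- Subgroup correlations: family history yes/no and a median split on the
  depression score (the available dementia-risk proxy in the simulated
  cohort; dedicated risk indices are out of scope), each at a Bonferroni
  alpha of 0.05 / number of subgroup tests.
- Subject-level group tests report Mann-Whitney U alongside a JZS Bayes
  factor computed from the t statistic; rank-based Bayes factors are not
  implemented.
- Mixed-effects modelling, marginal-effects contrasts and influence
  screening are deliberately outside this package; the pipeline stops at
  difference-score correlations and paired tests.

## Numerical notes

- Internal angles in radians; every interface in degrees.
- Wrapping: θ mod 360, then values > 180 shifted by −360; ±180 → +180.
- EM with pT → 0 terminates early (likelihood is flat in K there).
- Mixture density underflow is floored at 1e-300 inside the gradient.
- Problem sizes in tests (e.g. 200 × B = 200 calibration, 10⁴-trial
  recovery, 50-sample grid checks) are the package's chosen defaults for
  routine validation; the same code paths scale to larger B and n.
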