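# Methods

## The conditional overlap model

Consider m features measured in two experiments, each analysed for
differential signal so that every feature has a p-value per experiment.
Let X_i ∈ {0, 1} record whether feature i was called significant in
experiment 1 and Y_i ∈ {0, 1} whether it is *truly* differential in
experiment 2. Conditioning on X splits experiment 2's features into
group 1 (X_i = 1, size n) and group 0 (size m − n), each with its own
proportion of truly differential features:

    P(Y_i = 1) = pi_{1|0} P(X_i = 0) + pi_{1|1} P(X_i = 1).

The hypothesis that experiment 1 is uninformative about experiment 2 is
H0: pi_{1|0} = pi_{1|1}. Under H0 an estimate of pi_{1|1} computed on
group 1 has the same distribution as pi1_hat(n), the estimated
differential proportion in a uniformly random n-feature sample of
experiment 2 — this exchangeability is what the resampling null
exploits, and it requires no model of the dependence between features.

Three quantities answer the three practical questions:

- **Is there overlap?** The empirical p-value of the observed
  pi1_hat_{1|1} against B resampled pi1_hat(n) values, computed with
  the pseudocount convention p = (1 + #{null ≥ observed}) / (B + 1) so
  it is never zero. B defaults to 1,000. Because a resampling null
  cannot resolve p below 1/(B + 1), an upper-tail Gaussian
  approximation using the null sample's mean and standard deviation is
  reported alongside; it extrapolates beyond the resampling resolution
  and should be read as an approximation, not an exact tail.
- **How big is it?** round(pi1_hat_{1|1} · n).
- **Which features?** Storey q-values computed on experiment 2
  *restricted to group 1*. Conditioning decouples estimation of the
  overlap size from identification of its members: the multiple-testing
  burden applies only to the n conditioned features rather than all m.

pi_{1|0}, estimated on the complement set, is reported as a diagnostic;
a large gap between pi_{1|1} and pi_{1|0} is the visual signature of an
informative experiment 1.

## pi0 estimation

Everything reduces to Storey's estimator of the proportion of true
nulls among a p-value collection:

    pi0_hat(lambda) = #{p_i > lambda} / (m (1 − lambda)),

with strict inequality, and p-values of exactly 0 or 1 accepted (they
arise with discrete tests). Three rules choose lambda:

- **bootstrap** (default): evaluate pi0_hat on the grid
  lambda = 0.05, 0.10, …, 0.95, take pi0_min as the minimum over the
  grid, draw 100 bootstrap resamples of the p-values, and select the
  lambda minimising the bootstrap mean squared error around pi0_min;
  report the full-data pi0_hat at that lambda. The bootstrap exceedance
  counts are drawn as multinomial bin counts over the partition the
  grid induces on [0, 1] — distributionally identical to resampling
  the p-values with replacement and counting, at a fraction of the
  cost. The resample count (100) and the grid are conventions of the
  standard implementation of this estimator; neither is prescribed by
  the estimator itself.
- **smoother**: fit a cubic smoothing spline to the
  (lambda, pi0_hat(lambda)) pairs and report the fitted value at the
  largest lambda. The fit is a penalized cubic B-spline whose roughness
  penalty is tuned by bisection so the trace of the hat matrix (the
  effective degrees of freedom) equals 3; the flexibility is fixed, not
  user-tunable, to keep behaviour reproducible.
- **fixed**: evaluate at a user-supplied lambda. This is the escape
  hatch for p-value histograms whose shape misleads the automatic
  rules — e.g. a bump in the middle of the distribution that is
  unlikely to come from truly differential features; assuming p > 0.5
  are null (lambda = 0.5) then gives a defensible estimate where the
  bootstrap and smoother disagree wildly with the histogram.

The reported pi0 is clamped to [0, 1]; the raw per-lambda curve is
retained unclamped in `pi0_at_lambda` so the lambda-sensitivity of an
estimate can always be inspected. Estimates from fewer than 200
p-values trigger a warning: pi0 estimation is known to be unreliable on
small sets, and the histogram should be examined directly. Both
automatic rules require at least two distinct p-values; degenerate
inputs raise an error directing the caller to the fixed rule (internal
resampling paths fall back to lambda = 0.5 automatically and log the
fallback, so one degenerate draw cannot abort a B = 1,000 null).

q-values follow the min-over-tail construction
q(i) = min_{j ≥ i} pi0 · m · p(j) / j on the ascending-sorted
p-values, mapped back to input order, with ties broken stably by
feature id; with pi0 = 1 they equal Benjamini–Hochberg adjusted
p-values, which the test suite asserts against an independent
implementation.

## Chaining and concordance

For three or more experiments the conditional step iterates: stage 1
conditions experiment 2 on experiment 1's significant set and
identifies the shared features; stage k conditions experiment k+1 on
the previous stage's identified set. Direction concordance (optional
per stage) retains only features whose log2 fold changes agree in sign;
from stage 2 onward the comparison sign is the mean fold change across
all prior experiments, since the conditioning set no longer belongs to
a single experiment. Fold changes of exactly 0 carry no direction and
are dropped with a warning. An empty conditioning set stops the chain;
partial results are returned with a status flag rather than an
exception, because a stopped chain is itself a scientific result.

Feature universes are harmonized by inner join before any computation,
with dropped counts reported — differential analyses of the same assay
routinely test slightly different feature sets after per-experiment
count filters.

## Rank scans, unique-top selection, quartile tables

The rank-threshold scan asks a graded version of the overlap question:
for each threshold K (default 1000 to 5000 in steps of 250), take the
top-K source features by p-value, map them to target features through a
user-supplied many-to-many map (e.g. promoter peak → downstream gene,
deduplicated at the target level so each gene contributes one p-value),
and estimate the differential proportion of the targets. K counts
source features, not targets. A declining curve indicates that the
association concentrates in the most confidently ranked features.
Per-target effect sizes are summarised as the median log2 fold change
across a target's source features (midpoint convention for even
counts).

The unique-top rule selects features in one experiment's top `top_k`
(by p-value, ties broken stably by id) that are neither in a supplied
shared set nor within any other experiment's top `exclusion_k`
(defaults 1000 and 5000) — isolating signal specific to one condition.

The quartile cross-table stratifies a gene set by p-value quartile in
one ranking (quartile edges computed within the set; boundary ties fall
to the lower quartile) and reports, per quartile, the fraction of genes
in the set's top 25% under a second ranking. Independent rankings give
~0.25 everywhere; concentration in the first quartile indicates
cross-experiment agreement at the top of the lists.

## Gene-set shift test

For a named gene set the observed statistic is the Wilcoxon rank-sum
(midranks for ties) of the set's p-values within the full universe; the
null is built from R (default 10,000) uniformly random same-size
subsets drawn from the whole universe, including the true set's
members. The empirical p-value is one-sided toward small p-values
(smaller rank-sum), because the scientific question is a collective
shift toward significance; the resampling is unrestricted because the
null being modelled is "an arbitrary gene set of this size".

## The simulation study

The generator emulates three two-group experiments with a known sharing
structure. Reference configuration: m = 10,000 features per experiment;
2,000 truly differential and 8,000 truly null each; 1,400 shared true
differentials between experiments 1 and 2; 1,000 shared across all
three; null features N(0, 1) in both groups; differential features
N(0, 1) versus N(0.5, 1); 75 samples per group; a Welch two-sample
t-test per feature; 10% FDR throughout. The log2-fold-change column is
the group-mean difference, with the shift always applied to group 2.

Truth placement is a deterministic block construction: the three-way
block first, then the extra 1∩2 block, then disjoint per-experiment
unique blocks. The configuration pins only the 1∩2 and 1∩2∩3 counts;
the pairwise overlaps with experiment 3 beyond the triple block are set
to zero, the simplest structure consistent with the stated counts.

Each repetition runs the conditional chain 1 → 2 → 3 and the naive
per-experiment threshold-and-intersect baseline, then scores the
identified three-way set against the truth labels: the false-discovery
proportion (FDP) is the fraction of identified features not truly
differential in all three experiments, with FDP defined as 0 when
nothing is identified. The chain in the simulation applies no
direction-concordance filtering, matching the procedure the method's
FDR behaviour is validated under (all simulated effects share one sign,
so concordance would act only on noise); the flag is available in
`SimulationConfig` for exploring its effect. The per-repetition overlap
null is skipped by default (`n_resamples = 0`) since the summary needs
only point estimates and FDP, not resampling p-values.

RNG streams are split per (repetition, experiment) from the single
config seed, so reducing the repetition count leaves earlier
repetitions bit-identical, and a fixed (seed, config) pair reproduces
the whole study exactly.

What the generator does *not* emulate: count-based (negative binomial)
noise, correlation between features, library-size or batch effects,
varying effect sizes, or sign heterogeneity. Passing the study
therefore demonstrates the statistical machinery's calibration under
independent Gaussian data of the stated dimensions, not robustness to
the correlation structure of real sequencing data.

## Problem sizes and numerical choices

The validation suite runs the study at 200 repetitions (the
acceptance script likewise), which puts the Monte-Carlo standard error
of the mean three-way FDP near 0.16 percentage points; parameter
recovery uses 50 repetitions, and null-calibration checks use 500
replicates at reduced dimensions (m = 1,500 and 300) with B = R = 199
resamples. Resampling index draws use a chunked random-key
argpartition, bounding memory at ~160 MB regardless of B and m.

Null calibration has one subtlety worth knowing: when experiment 2 is
*entirely* null, pi1 estimates clamp at 0, the resampled statistic ties
with the observed one, and the empirical p-value becomes conservative
(an atom at 1) rather than uniform — the test never anti-conservative.
Strict uniformity holds when the estimates stay interior, e.g. when
experiment 2 contains signal at positions independent of the
conditioning set, which still satisfies H0 exactly.

## Known limitations

- The resampling p-value cannot go below 1/(B + 1); the Gaussian
  approximation reported alongside is an extrapolation whose tail
  accuracy is not guaranteed.
- pi0 estimation on small conditioning sets (< 200) is noisy and can be
  badly biased by histogram artefacts; the fixed-lambda override exists
  for exactly this case, and estimates from small sets should always be
  sanity-checked against the histogram.
- The exchangeability argument treats features as interchangeable under
  H0; strong feature-feature correlation shortens the effective sample
  and makes the resampling null narrower than it should be.
- The estimated overlap pi1_hat_{1|1} · n counts only group-1 features
  — features truly shared but missed by experiment 1's FDR call are
  invisible to it, so it estimates the replicable overlap of the
  *called* set, not the population overlap count.
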