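# Methods

This note documents the statistical procedures `indelcal` implements, the
defaults it chooses where the literature leaves details open, and what the
synthetic-data test suites do and do not demonstrate.

## The evidence model

Clinical variant classification under the ACMG/AMP guidelines combines
evidence in signed integer points; the Bayesian adaptation requires the
combined posterior probability of pathogenicity to satisfy fixed floors
(≥ 0.99 pathogenic, ≥ 0.90 likely pathogenic, ≤ 0.10 likely benign,
≤ 0.01 benign).  Because evidence multiplies on the likelihood-ratio
scale, the system is fully determined by the per-point likelihood ratio
`s`, which `indelcal` anchors by the likely-pathogenic constraint at six
points:

    posterior(s^6, α) = 0.90   ⇔   s(α) = (9(1−α)/α)^(1/6)

where α is the prior probability of pathogenicity of the variant class.
All per-level bounds are computed from `s` (`s^k` for level k), never
stored as tables: at α = 0.046 this gives 2.39 / 5.72 / 13.66 / 32.66 for
+1…+4, and the framework's very-strong odds constant is `s^8` (≈ 350 at
the historical α = 0.10).  `s ≤ 1` for α ≥ 0.9; such scales are flagged
degenerate rather than rejected, since the degenerate regime is a property
of the prior, not an input error.

## Prior estimation

α is estimated from a labeled positive sample and an unlabeled reference
sample in predictor feature space.  Features are standardized by pooled
mean and standard deviation (constant columns dropped); distances are
Euclidean.  The distance curve consumes the unlabeled sample: draw a
positive uniformly at random with replacement, remove the nearest
remaining unlabeled point (ties to the lowest row index), record the
distance; the curve is the mean recorded sequence over `n_reps`
repetitions (default 100; the recovery test suites use 30, a runtime
scaling choice that leaves the mean curve amply smooth at n = 2,000).
The positive×unlabeled distance matrix is computed once and shared across
repetitions.

The published distance-curve method maps curves to priors with a trained
regressor.  `indelcal` instead uses a deterministic knee rule: smooth the
mean curve with a centred moving average (window 5% of curve length,
minimum 3, forced odd), take first differences, find the earliest point
reaching half the maximum difference, and compensate the moving-average
lag by the smoothing half-window.  The compensation makes the rule exact
on an ideal step (a step at 30% of the curve returns α̂ = 0.30 exactly) and
unbiased rather than systematically early on smeared steps.  A flat curve
returns α̂ = 1.0 with a degeneracy flag (no rise means the unlabeled sample
is indistinguishable from the positives).  Recovery simulations (planted
α ∈ {0.05, 0.2, 0.4}, 5 dimensions, component separation 3, n = 2,000 per
sample) recover α to well within ±0.05; accuracy degrades as separation
shrinks, which the suite checks explicitly at separations 3 and 0.25.

## Local posterior calibration

For one tool and one variant type, scores are first oriented so higher
means more pathogenic (declared per tool, never inferred; negation for
lower-is-pathogenic tools).  The local posterior at oriented score x is

    p̂(x) = α·(c_P/n_P) / (α·(c_P/n_P) + (1−α)·(c_B/n_B))

with c_P, c_B the class counts in the closed window [x−ε, x+ε], where ε is
the minimal symmetric half-width whose window holds at least `min_count`
pooled calibration variants (default 100).  This is the continuous limit
of an expanding half-width schedule; near the data extremes the window
simply grows until it spans all data.  Curves are evaluated on an even
grid over the pooled score range (default 1,001 points).  Window counting
uses sorted arrays with `searchsorted` prefix sums; for each grid point
the minimal covering window is found by scanning the `min_count` candidate
runs straddling its insertion position, vectorised over the grid, so a
full bootstrap is CPU-cheap.

Confidence bounds: each bootstrap replicate resamples both classes
independently with replacement at original sizes and recomputes the whole
curve, including window re-selection, on the original grid.  The default
is 10,000 replicates; the test suites use 1,000 (and less for smoke
tests), recorded in every output.  Bounds are pointwise 5th/95th
percentiles per grid point — the one-sided 95% interval is the lower bound
for pathogenic evidence and the upper bound for benign evidence.
Percentiles are taken per grid point rather than on the threshold
statistic, matching the per-score bound curves the procedure is defined
by.

Threshold extraction: the +k threshold is the least oriented grid score t
such that the stringent bound clears the level's posterior bar
`posterior(s^k, α)` at *every* grid point ≥ t (benign levels mirror this
on a leading prefix with the upper bound).  Because the bars are monotone
in k and the qualifying regions nested, attained levels are always
contiguous from ±1, and the same cancellation that makes the benign
condition equivalent to a pure likelihood-ratio condition guarantees that
lowering the prior can only make every threshold more extreme.  A level is
reported only when at least `min_support` pooled calibration variants
(default 10; configurable, the criterion used in the literature is
unstated) lie at or beyond its threshold; unsupported extremes are
excluded with an explicit reason rather than silently dropped.  Intervals
between consecutive thresholds are emitted with shared boundaries assigned
to the stronger level, and reported back in original score units.
Insertions and deletions are always calibrated independently, each with
its own prior.

## Evaluation

Assignment maps a score to the unique containing interval (0 between the
−1 and +1 regions, missing scores unscored and excluded from
denominators).  Bin likelihood ratios are `(c_P/n_P)/(c_B/n_B)` for
pathogenic bins and the reciprocal for benign bins (reported as inverse
LRs, so higher is better on both sides); a bin with members of one class
only is infinite, an empty bin is *undefined* and kept distinct from
infinite.  Length stratification splits at |net| = 3 nt (single vs multi
amino acid).  Per-proband summaries count assignments per level, with
zero-variant probands contributing zeros.

## Synthetic data and what the tests show

The generators emulate only the statistical shape the calibration
consumes: class-conditional score densities (Gaussian for unbounded
tools, Beta on a finite support for bounded ones, mixtures of either),
feature-space mixtures with planted mixing fractions, variant tables with
planted per-rule filter outcomes, and cohorts with planted per-level
counts.  They do not simulate genes, linkage, annotation error,
classification noise in archival labels, or predictor-specific score
artifacts (multimodality, discretisation, missing-score patterns).
Passing the oracle-equivalence suite therefore shows the estimator and
extractor are correct *given* the model, not that any particular real
predictor is well calibrated.

The oracle-equivalence conditions are equal-variance Gaussians
(f_B = N(0,1), f_P = N(2,1)), α = 0.046, n = 5,000 per class, grid 1,001,
1,000 bootstrap replicates, one fixed seed.  Two conventions are the
package's own: (i) the |p̂ − p| ≤ 0.05 accuracy band is evaluated on the
intersection of the per-class 5th–95th percentile ranges — outside the
minority class's support the minimal 100-count window contains expected
minority counts below 1, so the hard-count estimator is pinned near 0 or
1 and no sample size makes a uniform 0.05 band attainable there; (ii) the
±0.15 check of the extracted +1 threshold against the analytic crossing
(x* = 1 + ln s/2 for this score model) uses the point-estimate extraction,
because the stringent bound is conservatively offset by construction —
its relation to the estimate is verified separately (stringent thresholds
are never less extreme than estimate thresholds).

## Numerical choices and edge cases

* Window intervals are closed on both ends; a relative slack of 1e-12 on
  the half-width protects the defining boundary point from rounding.
* Bound comparisons in threshold extraction use a 1e-12 tolerance.
* Degenerate score ranges (all scores identical) give a single-point
  curve with a warning; degenerate class compositions propagate exactly
  (an all-pathogenic top window has a bound of exactly 1 under any
  resampling).
* Missing allele frequency passes the frequency filters (absent from the
  reference population); missing genotype fields are excluded via a
  dedicated audit step rather than an exception.
* Variant keys are compared exactly as given (no allele normalization);
  cross-assembly comparisons require an explicit flag.
* Protein window cropping uses a floored midpoint and a left-biased split
  of the even window (1023 residues before the centre, 1022 after),
  shifted minimally at the termini; the convention is deterministic and
  boundary-safe.
* All randomness flows from explicit per-call seeds; stochastic pipeline
  stages refuse to run without one.

## Known limitations

* The knee rule assumes the distance curve has a single dominant rise;
  heavily overlapping classes (separation → 0) or strongly non-spherical
  feature clusters can bias α̂, and the suite only bounds accuracy under
  the stated simulation conditions.
* The adaptive window trades bias for variance through a single pooled
  count; no bias correction (e.g. on the bootstrap percentile) is
  applied.
* Published per-tool threshold tables ship only as interval-convention
  fixtures; reproducing them requires the original databases, features
  and predictor scores, which are out of scope.
* Gene- or domain-specific recalibration and the combination of multiple
  evidence criteria are out of scope.
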