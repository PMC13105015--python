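# indelcal

Calibration of in-frame indel variant effect predictors for clinical
variant classification under the ACMG/AMP guidelines.

Short in-frame insertions and deletions (net length change a nonzero
multiple of 3, ≤ 50 bp) preserve the reading frame but are hard to
interpret clinically, and computational predictors for them ship with
default thresholds that are not aligned to clinical evidence standards.
`indelcal` implements the full statistical pipeline that converts a
predictor's continuous scores into ACMG/AMP PP3/BP4 *evidence-strength
intervals*, separately for insertions and deletions:

1. **Dataset construction** (`indelcal.filtering`) — clinical-archive,
   population-reference and proband-genotype filters with per-rule audit
   counts; net-length indel typing; training-overlap exclusion; protein
   window cropping for length-limited sequence models.
2. **Prior estimation** (`indelcal.prior`) — the prior probability of
   pathogenicity α estimated from positive-unlabeled feature data by a
   distance-curve procedure with a deterministic knee rule.
3. **Evidence framework** (`indelcal.evidence`) — the point-based Bayesian
   adaptation of ACMG/AMP: posterior odds update
   `post(lr, α) = lr·α / (lr·α + 1 − α)`, per-point likelihood ratio
   `s(α) = (9(1−α)/α)^(1/6)` anchored so six points reach the 0.90
   likely-pathogenic floor, and per-level bounds `s^k` for
   k ∈ {±1, ±2, ±3, ±4}.
4. **Calibration** (`indelcal.calibration`) — local posterior probability
   curves with an adaptive window (≥ 100 pooled calibration variants),
   one-sided 95% bootstrap confidence bounds (pointwise 5th/95th
   percentiles over replicate curves), and threshold extraction from the
   stringent side with exclusion of poorly supported extremes.
5. **Evaluation** (`indelcal.evaluation`) — per-variant evidence
   assignment, bin percentages, bin likelihood ratios (standard TPR/FPR
   for pathogenic bins, inverse FPR/TPR for benign bins) checked against
   the per-level minima, length stratification and per-proband summaries.
6. **Synthetic data** (`indelcal.synthetic`) — generators for every input
   with planted ground truth, including the analytic posterior oracle
   `α·f_P(s) / (α·f_P(s) + (1−α)·f_B(s))`.

A machine-readable transcription of published per-tool threshold tables
for eight predictors (CADD, ESM1b, FATHMM-indel, INDELpred, MutPred-Indel,
ProGen2, PROVEAN, VEST-Indel) ships as an interval-convention fixture
(`indelcal.load_published_thresholds`).

## Worked example

Calibrate a synthetic deletion predictor whose pathogenic and benign
scores are N(2, 1) and N(0, 1) with prior α = 0.046:

```python
from indelcal import (ScoreDistributionSpec, SyntheticTruth, gen_two_class_scores,
                      bootstrap_bounds, extract_thresholds, WindowRule, PointScale)

truth = SyntheticTruth(
    pathogenic_spec=ScoreDistributionSpec.gaussian(2.0, 1.0),
    benign_spec=ScoreDistributionSpec.gaussian(0.0, 1.0),
    prior=0.046, seed=7)
scores = gen_two_class_scores(truth, 2000, 2000, tool="demo", variant_type="deletion")
curve = bootstrap_bounds(scores, prior=0.046, rule=WindowRule(), B=1000, seed=7)
thr = extract_thresholds(curve, PointScale.from_prior(0.046))
print(thr.to_frame().to_string(index=False))
```

```
tool variant_type         direction  prior  level  interval_low  interval_high  low_inclusive  high_inclusive  support_n excluded_reason
demo     deletion higher_pathogenic  0.046     -4          -inf      -2.025678          False            True         39
demo     deletion higher_pathogenic  0.046     -3     -2.025678      -0.811250          False            True        435
demo     deletion higher_pathogenic  0.046     -2     -0.811250      -0.170301          False            True        912
demo     deletion higher_pathogenic  0.046     -1     -0.170301       0.344144          False            True       1403
demo     deletion higher_pathogenic  0.046      1      1.567006       2.241688           True           False       1419
demo     deletion higher_pathogenic  0.046      2      2.241688       2.798301           True           False        819
demo     deletion higher_pathogenic  0.046      3      2.798301            inf           True           False        436
```

Scores of at least 1.567 earn supporting (+1) pathogenic evidence, at
least 2.242 moderate (+2), and so on; scores between 0.344 and 1.567 are
indeterminate (level 0).  A shared boundary always belongs to the stronger
level, and `support_n` counts the calibration variants at or beyond each
threshold (levels with too few are excluded rather than reported).  The
stringent bootstrap bound makes these thresholds deliberately conservative
relative to the point estimate.

The evidence framework itself is available from the command line:

```sh
$ indelcal report --prior 0.046
prior alpha = 0.046
per-point likelihood ratio s = 2.3906 (prints as 2.39)
level   expected_lr     posterior_bound
-4      0.0306  0.001474
...
+1      2.3906  0.103356
```

i.e. at the deletion prior a predictor must achieve a likelihood ratio of
2.39 for supporting pathogenic evidence, and a local posterior of at least
0.103 defines the +1 score region.

The `indelcal` CLI also exposes `simulate`/`filter`/`prior`/`calibrate`/
`evaluate` stages and `indelcal run --config config.yaml --outdir out/`,
which writes a deterministic manifest with content digests for every
artifact.

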