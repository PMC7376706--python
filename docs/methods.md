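# Methods

## Problem and procedure

The package evaluates preoperative serum CA-125, FASN and GLS as predictors
of suboptimal cytoreductive surgery in epithelial ovarian cancer. The
positive class throughout is *suboptimal* cytoreduction (residual tumour
≥ 1 cm); higher marker levels indicate higher risk of a suboptimal outcome,
and a patient is test-positive when the marker or combined score is
**strictly greater** than the cut-off. The boundary convention is fixed by
the category coding used for the combined scores (1 if ≤ cut-off, 2 if
above): a value equal to the cut-off is test-negative.

The analysis is two-stage. Stage 1 treats each marker alone: group summary
statistics, a ROC-derived cut-off, the diagnostic rate panel at that
cut-off, the AUC with a confidence interval, and two-group tests. Stage 2
freezes the stage-1 cut-offs, builds the three multiplicative combined
panels, and repeats the identical metric block on the panel scores. There is
no joint optimization of cut-offs across markers and no holdout — panel
cut-offs are re-derived on the same cohort, mirroring the original
procedure's narrative order.

## Cut-off selection

The published analysis states only that cut-offs came from ROC curves; the
criterion is not named. We use **Youden's J = sensitivity + specificity − 1**,
the standard single-operating-point criterion and the only one consistent
with reporting a single sensitivity/specificity pair per marker. Candidate
cut-offs are the midpoints between consecutive distinct pooled values (the
published cut-offs such as 248.55 and 22.895 carry midpoint-style extra
decimals, supporting this convention), with ±∞ sentinels anchoring the
curve at (0,0) and (1,1). Ties in J are broken toward the smaller cut-off,
i.e. toward higher sensitivity — in a surgical-triage setting a missed
high-risk patient is the costlier error. Tie comparison uses exact integer
counts (`tp·n₀ + tn·n₁`) rather than floating-point J, so the tie-break is
immune to rounding jitter. A degenerate pooled sample with a single distinct
value falls back to that value as the cut-off with J = 0.

`run_study` accepts `pinned_cutoffs` to impose published cut-offs (e.g.
CA-125 248.55, GLS 22.895) when the goal is reproducing worked examples
rather than re-deriving cut-offs from synthetic data.

## AUC, interval, and the "correctly predicted" count

The AUC is computed as the trapezoidal area under the empirical curve and,
independently, as the normalized Mann–Whitney statistic U/(n₁n₀) with ties
counted ½; the two are algebraically identical and the identity is enforced
in tests to 1e-12. The confidence interval uses the Hanley–McNeil closed
form with z = Φ⁻¹(0.975) ≈ 1.959964 at the default 95% level, clipped to
[0, 1]. This reproduces the published CA-125 interval (67.8–85.6%) to three
decimals; the published FASN interval differs by ≈0.003 and the combined
panels' intervals by up to ≈0.2 percentage points, consistent with the
original software using a data-dependent (distribution-free) SE that cannot
be recomputed without the raw data. Only the CA-125 and FASN intervals are
part of the printed-cell verification, the former expected to agree, the
latter flagged.

Figure-legend counts of the form "predicts correctly in N of 109 patients"
are `round(AUC × 109)` half-up. Five of the six published legends satisfy
this; the CA-125+GLS legend prints 91 where the arithmetic gives 93, which
the package surfaces as a known inconsistency rather than absorbing.

## Rate panel, rounding, and reconstruction

Sensitivity, specificity, accuracy, PPV and NPV are exact ratios of integer
2×2 counts. PPV/NPV with a zero denominator are reported as undefined
(`None`), never coerced to 0 or 1. The reporting convention is percent
rounded **half-up** to one decimal. Four published cells (CA-125 accuracy
73.3, FASN accuracy 61.4, CA-125+GLS accuracy 77.9 and CA-125+GLS PPV 76.6)
are each exactly 0.1 below the half-up value of the corresponding exact
ratio — evidently truncated at the second decimal — and are carried as
known discrepancies.

`reconstruct_confusion` inverts published rates: it picks the integer count
in [0, n] whose rate is nearest the printed one (ties toward the larger
count, matching half-up rounding), guaranteeing agreement within half a
count. This is what lets every derivable published cell be verified without
the raw data.

## Combined scores

The combined score keeps one marker numeric and multiplies it by the other
markers' category values in {1, 2}. Which marker stays numeric is not stated
in the publication; it is forced by arithmetic on the published panel
ranges (the CA-125+GLS suboptimal maximum 75.00 = 37.50 × 2 identifies GLS
as numeric there; the triple panel's minima 0.22 = 0.11 × 2 × 1 and
0.03 = 0.03 × 1 × 1 identify FASN; likewise FASN in CA-125+FASN via
3.18 = 1.59 × 2). One published endpoint (CA-125+FASN suboptimal minimum
0.21) is not reachable from any printed FASN extreme times {1, 2} — likely
the product of an unprinted raw value — and is not used as a check.

## Synthetic cohort generator

The raw 109-patient dataset is not deposited, so the generator emulates the
two groups (n = 56 suboptimal, 53 optimal) from the published summaries:

- **CA-125 and FASN** have means well above their medians in both groups
  (e.g. suboptimal CA-125 mean 1157.62 vs median 600.00) — strong right
  skew — and are modelled as **lognormals** with `mu = ln(median)`,
  `sigma = sqrt(2·ln(mean/median))`, which matches both printed moments
  exactly before truncation.
- **GLS** has mean ≈ median and is modelled as a **normal** with the printed
  mean and SD.
- Every draw is rejection-truncated to the printed min–max range of its
  marker and group; a rejection rate above 99% raises an error. Truncation
  perturbs the matched moments slightly; recovery tolerances in the tests
  (median within 10% at n = 10,000/group, truncated-normal mean within 5% of
  a Monte-Carlo oracle) absorb this.
- Markers are drawn **independently within a group**: no correlation
  structure is published, so none is invented. Consequently synthetic
  combined panels need not improve on single markers the way the original
  (presumably correlated) data did, and synthetic per-marker AUCs can drift
  from the published ones — e.g. the lognormal fits imply a CA-125 AUC near
  0.84 rather than the observed 0.767. Passing tests on synthetic data
  therefore demonstrate the correctness of the machinery, not the clinical
  effect sizes.
- Stage and histology covariates are sampled from the published per-group
  frequencies, independent of markers. The published characteristics table
  includes stage II patients despite a stated stage III–IV eligibility
  criterion; the generator follows the table.
- The seed is a required argument; no global random state is touched.

## Between-group tests

Both the Mann–Whitney U (normal approximation with tie-corrected variance
and continuity correction; delegated to `scipy.stats.mannwhitneyu`) and the
unpaired t (Welch by default; `scipy.stats.ttest_ind`) are always reported,
labelled — no normality pre-test gates the choice, avoiding the pre-test's
known distortions. The publication prints two unlabelled p-value columns
per variable; no attempt is made to match them to specific tests.
Categorical tables use Pearson chi-square without continuity correction and
error loudly on zero expected counts (no Fisher fallback). U is defined by
pair counting for the first sample, so `U/(n₁n₀)` equals the AUC when the
first sample is the positive group — an identity shared with the ROC module
and enforced in tests.

## Numerical choices and edge cases

- Percent formatting: half-up at the stated decimal via
  `floor(x·10^d + 0.5)/10^d` (banker's rounding never matches printed
  clinical tables).
- Trapezoidal integration traverses the curve by descending threshold so
  that tied values' diagonal segments integrate correctly.
- Identical samples: Mann–Whitney returns U = n₁n₀/2, p = 1 before
  delegating (the asymptotic formula is 0/0 there); a two-constant-sample t
  with equal means returns t = 0, p = 1, with unequal means it errors.
- All validation errors name the offending row or cell.

## Problem sizes

Default cohorts are the study's 56 + 53. Distributional recovery checks use
10,000 patients per group (medians, ranges) and 50,000 draws (lognormal
parameter round-trip); AUC-route equivalence runs 1,000 small random
cohorts with heavy ties; null calibration of the two-group tests uses 2,000
replicates at n = 50 + 50, with the observed 5%-level rejection rate
required to lie in [0.03, 0.07].

## Known limitations

- No marker correlation, no joint marker–stage model, no model-based
  (e.g. logistic) combination — the multiplicative dichotomized score is
  implemented as specified, not endorsed as optimal.
- No exact small-sample Mann–Whitney p-values, no DeLong AUC comparisons,
  no partial or smoothed ROC, no confidence intervals on sensitivity or
  specificity (none are published to compare against).
- Published p-values cannot be reproduced without the raw data and are not
  targets anywhere.
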