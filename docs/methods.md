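# Methods

This note documents the statistical procedures, conventions, and design
choices behind `pneumorisk`, and what the synthetic-data experiments do and
do not demonstrate.

## Scores and conventions

Each score is a weighted integer sum over clinical categories (weights in
the README table).  Conventions that the published tabulations leave
ambiguous are fixed as follows:

- **Age windows** use completed months as half-open intervals: "0–24
  months" is [0, 25) (a child aged 24.9 months is inside month 24),
  "2–59" is [2, 60), "1–59" is [1, 60).  The RISC HIV-negative score can be
  switched to its supplementary 0–59-month application.
- **WAZ band edges** differ by score and are implemented literally: RISC
  uses severe ⇔ WAZ ≤ −3 and moderate ⇔ −3 < WAZ ≤ −2; RISC-Malawi and the
  adapted PERCH use severe ⇔ WAZ < −3 and moderate ⇔ −3 ≤ WAZ < −2, so
  WAZ = −3 is severe under RISC but moderate under the others, and
  WAZ = −2 scores 0 under the Malawi/PERCH convention.
- **SpO₂ bands** are evaluated on the raw recorded percent on the real
  line: the RISC-Malawi middle band is [90, 93), so a recorded 92.5 falls
  in "90–92%".  No rounding is applied before banding.
- **PERCH unresponsiveness** defaults to weight 0.  The external
  application could not observe "deep breathing", and its published
  maximum is 12; retaining the original +2 unresponsiveness weight would
  make the enumerated maximum 14, contradicting that maximum.  A config
  option restores weight 2 for sensitivity analyses.
- **PERCH duration categories** "3–5 d" and ">5 d" carry equal weight but
  are kept as distinct labeled components.
- **HIV status is not modeled**: the HIV-negative RISC score is applied to
  all records, mirroring how the score is used when HIV status is not
  reliably recorded.
- Score ranges are always computed by exhaustive enumeration over category
  representatives (the scoring functions are piecewise constant on those
  categories), never asserted.

## Eligibility

Validation is complete-case: a record is eligible for a score iff its age
is inside the window and every required field is non-null.  Age is tested
first, so a record failing both is tallied as an age exclusion; the
partition `n_input = n_eligible + n_excluded_age + n_excluded_missing` is
enforced.  The ordering is a documented choice — the source flow diagram
does not state one.

## Intervals and test characteristics

- **Proportions** (CFRs, sensitivity, specificity) get Clopper-Pearson
  exact intervals from beta quantiles.  This choice reproduces the
  published interval cells that depend only on printed counts (e.g. 6/83 →
  2.7–15.1, 508/4333 → 10.8–12.7 at one-decimal rounding), where Wilson
  intervals do not.
- **Likelihood ratios** use the log-variance method:
  `SE(ln LR⁺) = sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))`, symmetric for
  LR⁻, with normal bounds exponentiated.  Zero cells yield flagged
  `infinite`/`undefined` values rather than exceptions; an optional Haldane
  correction (+0.5 per cell) is available for the LR estimates.
- **Display rounding** is half-away-from-zero: percentages to one decimal,
  LRs and AUC to two.  Computation always uses full precision;
  rounding only happens in display helpers and band assignment.  (The
  source tables contain a few cells whose printed digit cannot be
  reproduced from their own printed counts — e.g. a stratum of 5/137
  displayed as 3.7% where the quotient is 3.65% → 3.6 — and one stratum
  percentage displayed as 21.9 where the counts give 20.9; tests assert
  the recomputed values.)
- **Cut-point sweeps** classify positive at `score ≥ c` for every integer
  `c` in the enumerated range.  Sensitivity is non-increasing and
  specificity non-decreasing in `c` by construction; both are tested as
  invariants.  "Correctly classified" is reported per row.  The
  recommendation rule selects rows with sensitivity in [60%, 80%] and
  specificity ≥ 40%, all bounds inclusive.

## Discrimination

The AUC is the Mann-Whitney probability (ties = ½), computed via midranks
and asserted equal (1e−12) to the trapezoidal area under the empirical ROC
— the two are mathematically identical, so the assertion guards the
implementations against each other.  The default CI is DeLong's
placement-value variance; a seeded stratified bootstrap is available
because the original analysis does not name its method.  Qualitative bands
are applied to the AUC rounded to two decimals (a computed 0.699 is
labeled by its displayed 0.70, fair).

Predictiveness curves use the raw empirical CFR at each exact score level
as the predicted risk, sort children by ascending risk, and plot risk
against cumulative population fraction (risk-percentile convention).  The
fraction-weighted mean of the curve equals the overall CFR identically; a
pool-adjacent-violators option monotonizes risk in score if desired.

## Synthetic cohort generator

The generator emulates the *structure* of the three validation cohorts,
whose patient-level data are not public.  Calibration targets are the
exact published count ratios (e.g. prevalence 917/3574, stratum CFR
20/917), not the rounded display percentages.

- **Covariates** are sampled independently: age from configurable month
  bins, sex and each sign as Bernoulli with the published marginal
  prevalence, SpO₂ and WAZ from band-categorical draws with within-band
  continuous values (SpO₂ uniform in 70–89.9 / 90–92.9 / 93–100; WAZ
  uniform in (−4.5,−3) and (−3,−2), triangular with mode −0.5 on (−2,1)),
  illness duration likewise banded at <3 / 3–5 / >5 days.
- **Mortality (stratum model)**: a child's death probability is
  `p = total_CFR × Π_d f_d(level)`, one factor per covariate dimension,
  with factors solved so that every dimension satisfies E[f] = 1 and
  `E[p | stratum] = published stratum CFR` under covariate independence.
  A dimension with one untargeted level absorbs the normalization; a
  fully targeted dimension (the SpO₂ and WAZ bands) is rescaled jointly,
  preserving CFR ratios.  The RISC "chest indrawing with SpO₂ > 90%"
  stratum is a conditional target and is solved against the SpO₂ > 90%
  factor.  This multiplicative form was chosen over assigning each child
  the CFR of its single highest-weighted stratum because the latter mixes
  high-risk strata into every lower-priority marginal (e.g. it pushes the
  expected moderate-WAZ stratum CFR of the 2–59-month cohort to ≈ 8.1%
  against a published 6.7%), while the multiplicative solution reproduces
  *every* published marginal in expectation simultaneously.  Joint CFRs
  over sign combinations are not published and are not claimed; products
  are clipped to [0, 1] (the defaults never reach the clip).
- **Mortality (logistic model)**: `P(death) = logistic(β₀ + β₁·score)` on
  a chosen score, for experiments with a fully known generating mechanism.
- **Missingness** is MCAR per field (never the outcome), applied after
  generation, so the complete-case filter can be exercised at known rates.
- Defaults the published tables do not determine, fixed once at realistic
  values: the 0–24-month cohort's SpO₂ 90–92 band share (0.22 — only the
  ≤ 90% marginal is published), its age mix (60% infants) and sex ratio
  (46.8% female, borrowed from the 2–59-month cohort); the 1–59-month
  cohort's SpO₂ band split (0.550/0.245/0.205, chosen so P(SpO₂<92)
  equals the published 526/732) and duration split (0.135/0.565/0.300,
  matching the published P(≥3 d) = 633/732); age bins for the 2–59-month
  cohort (half infants).

**What passing calibration shows — and does not.**  At n = 20 000 the
generated 2–59-month cohort recovers every published Table-style marginal
(prevalences and per-stratum CFRs) within three binomial standard
deviations, and the whole pipeline runs end-to-end with realistic output
(AUC ≈ 0.75, recommended cut-points 5–6, closely matching the published
external validation).  Because covariates are independent, the generator
does not reproduce sign-sign correlation, between-study heterogeneity, or
informative missingness of real pooled data; pipeline results on synthetic
cohorts validate the *software* and the *calibration targets*, not the
clinical performance of the scores on new populations.

## Problem sizes and numerical checks

The test suite exercises: worked-example CFRs and exact-CI cells recomputed
from published counts; score-range enumeration; AUC pair-count vs
trapezoid equivalence on 1000 random cohorts (n ≤ 200) at 1e−12;
monotonicity of 500 random cut-point sweeps; interval coverage on 10 000
binomial replicates per (p, n) setting; generator calibration at
n = 20 000; and logistic-model parameter recovery, where the pipeline AUC
(mean of three seeded cohorts of n = 20 000, β₀ = −3.0, β₁ = 0.35 giving
≈ 13% mortality) is compared within 0.01 against an exact enumeration of
the finite score distribution (72 covariate combinations), an oracle with
zero Monte-Carlo error.  All randomness is seeded; end-to-end report
bundles are byte-reproducible given cohort, config, and seed (timestamps
are confined to the run log).

## Known limitations

- Independent covariates (no latent-severity copula; an extension hook is
  the natural place for one).
- Per-stratum calibration is marginal, not joint; rare covariate
  combinations can receive risk products the source population may not
  exhibit.
- The mRISC score, the HIV-positive RISC score, and the RISC-Malawi MUAC
  variant are out of scope (their weights are not fully tabulated in the
  validation source this package follows).
- WAZ is an input; computing it from raw weight/age/sex against WHO growth
  standards is out of scope.
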