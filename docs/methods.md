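# Methods

## The case-finding model

The classifier is a deterministic rule set over a patient's claims inside a
fixed window around their index date (default ±90 days, inclusive). Claims
are mapped to clinical *concepts* (drugs, PET scan, lung resection) through
a user-supplied concept→code registry; concepts are combined into
*criteria*: single agents/procedures, or combination regimens whose
components must all appear within one chemotherapy cycle
(`combo_window_days`, default 21 — the conventional cycle length; the
source material does not state how regimen co-occurrence is recognised in
claims, so this is configurable per criterion). A combination matches when
some anchor date exists with every component dated in
`[anchor, anchor + window − 1]`; restricting anchors to observed component
dates is exact, since any qualifying window can be re-anchored at its
earliest member.

Two policies turn matches into a label:

- **exclusion_first** (case-finding algorithm): any matched SCLC-indicative
  regimen ⇒ SCLC; else any matched NSCLC-indicative criterion ⇒ NSCLC; else
  the default label. The precedence is a design choice — the source
  material does not specify the tie case — justified by the purpose of the
  exclusion list (removing SCLC-treated patients); the decisive branch is
  recorded per patient for audit.
- **inclusion_only** (control): any matched inclusion criterion ⇒ NSCLC,
  exclusion-role rows ignored.

The default label is SCLC, so output is binary (the published
cross-tabulations have no unclassified column); `UNCLASSIFIED` is available
via configuration. Single agents used for both subtypes (paclitaxel,
docetaxel, gemcitabine, etoposide, vinorelbine, irinotecan, pemetrexed)
appear only in the control algorithm's inclusion list. A matched
combination does not suppress its constituent single-agent rows: no
suppression rule is documented, and the precedence needed for
classification lives in the policy, not the matcher. Classification
depends only on which criteria matched, never on evidence multiplicity.
A `criterion_count_scores` helper (inclusion-minus-exclusion match count)
is exposed as a clearly-labelled extension for ROC experimentation; it
plays no role in classification.

## Eligibility

"3 months" of continuous enrollment before and after index is implemented
as 90 days (30-day months, configurable), windows inclusive at both ends —
the usual convention in claims research, avoiding calendar-month
ambiguity. The check passes when no single uncovered run inside the window
exceeds `gap_tolerance_days` (default 0; exposed because pharmacoepi
studies often allow short gaps; the check is monotone in the tolerance).
Exclusion order is fixed and logged — missing label → intake window →
minimum age → enrollment — since no attrition order is documented; the
tally always sums to the input count. Dates are ISO-8601 throughout;
claim lines are deduplicated on (patient, date, system, code) and
enrollment spans stored merged, with abutting spans (end = day before next
start) treated as continuous. The per-patient observation window is
exposed as configuration rather than hard-coding a variable-capture rule.

## Validation statistics

- Proportion CIs: Wilson score intervals (95%). Chosen over Wald for
  behaviour near the boundary; the source names no CI method.
- DOR: (tp·tn)/(fp·fn); CI via the Woolf log method,
  exp(log DOR ± z·√(Σ 1/cell)). With a zero cell the DOR is undefined
  unless the Haldane–Anscombe correction (+0.5 to every cell) is enabled;
  the correction is flagged in the result.
- AUC of a dichotomous test: (Se+Sp)/2 — the trapezoid under the
  single-operating-point ROC polygon, reproducible from a 2×2 alone. Its
  CI uses a normal approximation with var(AUC) = (var(Se)+var(Sp))/4,
  binomial variances, clipped to [0, 1].
- DeLong comparison: AUC via midranks (ties count ½), variance/covariance
  from placement values with sample covariances over positives and
  negatives; χ² = ΔAUC²/var(ΔAUC) with **1 df** for two curves (the
  standard choice; a 2-df variant reported elsewhere for a two-curve
  comparison is nonstandard and not reproduced — the df is surfaced in the
  result object rather than hidden). Identical score vectors short-circuit
  to p = 1; zero variance with unequal AUCs is flagged degenerate. The
  delete-one-within-class jackknife is the natural variance oracle for
  this two-sample U-statistic and is used as such in the tests.
- Hierarchical logistic: statsmodels ML fits; McFadden pseudo-R²
  (1 − ll/ll_null, the variant Stata reports by default; others could be
  added). Step 1 covariates, step 2 + algorithm indicator; interactions
  fitted one covariate block at a time and assessed by LR test.
  Complete-case analysis with the dropped count reported. Designs are
  reduced to full column rank (pivoted QR); under (quasi-)separation the
  fit falls back to an escalating ridge penalty and sets a flag —
  p-values from penalised fits are approximate. Degenerate (constant)
  interaction columns are skipped; an interaction block that cannot be
  fitted reports NaN rather than failing the analysis.

Reported percentages are conventionally rounded to one decimal in
summaries; full precision is retained on the result objects.

## Synthetic cohorts

The generator emulates a validation study of ~1,353 lung-cancer patients
with 80% NSCLC prevalence. Per patient, independently:

- subtype ~ Bernoulli(prevalence); index date uniform in the intake window
  (2014-06-01 … 2015-10-31);
- with probability `p_guideline_concordant` (default 0.75) one regimen is
  drawn uniformly from the *own*-subtype criterion pool; with probability
  `p_crossover[subtype]` one regimen is additionally drawn from the *other*
  pool. Crossover is per-subtype (`{NSCLC: 0.04, SCLC: 0.756}` by default)
  because a single shared probability cannot represent the observed
  asymmetric operating point — SCLC patients frequently receive
  NSCLC-style therapy, the reverse is rare;
- NSCLC patients additionally receive a PET-scan claim with probability
  0.90 and a resection claim with probability 0.50; regimen components are
  dated inside one cycle window starting 0–14 days after index, so every
  assigned regimen satisfies its own criterion by construction;
- demographics (age, gender, BMI, comorbidity score, stage, region,
  insurance) are sampled per subtype from the published cohort summary
  statistics; they never influence treatment assignment — mirroring the
  finding that covariates did not affect the algorithm — though the
  per-subtype stage distributions do differ, so stage carries some
  subtype signal under the default demographics (tests of the
  "no covariate effects" condition set both subtypes' demographics equal);
- enrollment covers index ±120 days except for a violation fraction
  (default 5%) whose coverage stops 0–59 days after index, guaranteeing
  failure of the 90-day post-index requirement at zero tolerance.

**Closed-form operating point.** Under exclusion-first with default label
SCLC: Se = (1−px_N)·(1−(1−pc)(1−p_pet)(1−p_surg)) and
Sp = 1−(1−pc)·px_S. These are exact for the sampling scheme: SCLC-regimen
agents (etoposide, irinotecan, topotecan, CAV, temozolomide, ifosfamide,
bendamustine) are disjoint from the NSCLC-pool agents, so incidental
cross-regimen matches can only involve roles already assigned and never
flip a classification. The defaults were solved from these expressions to
give Se = 0.948, Sp = 0.811 at prevalence 0.80 — the study conditions the
package validates against.

**What the generator does not emulate:** billing noise (reversals,
adjustments), real code dictionaries, dose/route/days-supply, regimen
frequency differences (sampling is uniform over each pool unless weights
are supplied), line-of-therapy sequencing, or correlation between
demographics and treatment. Passing tests therefore demonstrate the
correctness of the matching, policy and statistical machinery under the
stated generative assumptions — not the algorithm's field accuracy on real
claims, which depends on the fidelity of user-supplied code lists.

## Problem sizes and numerics

The test suite and the acceptance script run the round trip at 20,000
generated patients (Monte-Carlo SE ≈ 0.002 for Se, ≈ 0.006 for Sp —
comfortably resolving the calibrated operating point at a 3-SE band) and
fit the hierarchical regression on a 6,000-patient subsample, where the
pseudo-R² increment attributable to the algorithm (~0.46–0.47) is two
orders of magnitude above the covariate-only term. Brute-force oracles
(pair counting for AUC, exhaustive date-combination enumeration for
regimen matching, delete-one jackknife for the DeLong variance) run at
n ≤ 20. All randomness flows through a single numpy Generator per cohort,
seeded from configuration and recorded in run metadata; re-running any
stage with the same configuration is byte-identical.

## Known limitations

- The control algorithm is implemented exactly as described
  (inclusion-only); how the original comparison assigned SCLC labels under
  an inclusion-only rule set is not documented, so the control's published
  2×2 is treated as a fixed input to the statistics, not something the
  classifier reproduces from claims.
- The published control AUC of 0.53 is inconsistent with its 2×2 under any
  standard binary-AUC definition ((Se+Sp)/2 = 0.109) and is not targeted.
- A published covariates-only pseudo-R² on real data (0.007) cannot be
  reproduced without the raw cohort; the synthetic analogue under the
  no-covariate-effect condition is ~0.001 and the algorithm-step increment
  dominates, which is the property the validation design asserts.
- Eligibility iterates per patient in Python; adequate to ~10⁵ patients,
  not tuned for full-database scans.
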