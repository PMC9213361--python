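# Methods

## The score and its reference standard

The preoperative scale is a deterministic additive point system over eight
variables: age (<40 → 0, 40+ → 1), sex (female 0, male 1), ASA class (1→0,
2→1, 3→2, 4→7), primary diagnosis (pancreatitis/biliary colic 0,
choledocholithiasis 1, cholecystitis 4), gallbladder wall thickness (≥3 mm →
2), common bile duct diameter (>6 mm → 1), prior ERCP (1), and admission
type (elective 0, delayed 1, emergency 2). Totals span 0–19 (verified by
full enumeration) and stratify as low 0–1, intermediate 2–6, high 7–19, with
inclusive boundaries.

Boundary semantics follow the published point table literally: age exactly
40 scores 1 ("40+"), wall thickness exactly 3 mm scores 2 ("≥ 3 mm"), a duct
of exactly 6 mm scores 0 (the table prints "> 6 mm"; the looser "greater
than or equal to 6 mm" phrasing that appears in surrounding prose is treated
as imprecise). ASA 5 is scored as the ASA 4 row (7 points): the point table
stops at 4 while the cohort is described with a joint "4–5" stratum, and
mapping 5 upward preserves monotonicity of the score in physical status.

The reference standard is the four-grade intraoperative difficulty scale
(gallbladder state, cystic pedicle, adhesions). The scale's source states no
rule for combining the three descriptor levels into one grade; we default to
the **maximum** — any grade-4 feature makes the case grade 4, matching how
surgeons use "worst finding" scales — and expose the aggregation as a
callable for other conventions. Grades 1–2 are classed easy, 3–4 difficult.
(A conflicting narrative phrasing "1–2 easy and 2–3 difficult" elsewhere in
the source is an evident typo; the scale's own caption is authoritative.)

Eligibility mirrors the study's selection: planned open cholecystectomy,
then missing scored variables, then gallbladder malignancy, checked in that
fixed order with first-match tallying (the study states no precedence;
fixing one makes the tally reproducible). Incomplete records are refused by
the scorer rather than imputed — the study excluded such patients.

## Diagnostic accuracy

Positivity is **score ≥ cutoff**. This convention reproduces the published
sensitivity/specificity pairs at cutoffs 2 (0.98/0.20) and 7 (0.81/0.81)
from the stratum counts. Sensitivity, specificity, PPV and NPV are the usual
2×2 ratios; a metric whose denominator is zero is reported as undefined,
never as 0. The Youden index is computed in full precision from the exact
sensitivity and specificity (the published table appears to compute it from
already-truncated values, e.g. 0.62 where the exact value is 0.6303; we
report the exact arithmetic and leave truncation to the renderer). The
published NPV at cutoff 7 (0.82) is inconsistent with the value its own
stratum counts imply (126/157 = 0.8025 → 0.80); the derived value is
reported.

The ROC curve carries one operating point per integer threshold from
min(score) to max(score)+1, so it is anchored at (1,1) and (0,0) and the
trapezoidal area equals the tie-aware Mann–Whitney concordance statistic
exactly (a property test checks the identity against brute-force pair
counting). For grouped data (patients known only up to an ordered stratum)
the same pair-counting definition applies with all within-stratum pairs
tied; the published stratum counts give 21083/25410 ≈ 0.830, the printed-
data shadow of the patient-level AUC of 0.88.

AUC confidence intervals default to Hanley–McNeil (Q1 = A/(2−A),
Q2 = 2A²/(1+A), symmetric normal interval clipped to [0,1]); DeLong's
placement-value variance is available as an option. The source does not
state which method produced its interval (0.85–0.92 around 0.88); Hanley–
McNeil at the study's class sizes gives (0.842, 0.918) — close but not
identical, and no exact match is asserted. A degenerate empirical AUC of
exactly 0 or 1 has zero Hanley–McNeil variance and is reported with a point
interval.

The Youden-optimal cutoff breaks ties toward the smallest cutoff (favouring
sensitivity). Note that on the minimal-score expansion of the grouped counts
(all patients at scores 0/2/7) every cutoff in 3–7 is equivalent, so the
reported optimum there is 3; the published patient-level optimum of 8 is not
desk-reproducible and is not asserted anywhere.

## Bivariate comparisons

Binary factors use Pearson's chi-square without continuity correction (none
is mentioned in the source; a flag enables Yates). Ordered factors — ASA,
admission type, risk stratum, and by default primary diagnosis in its point
order (pancreatitis < biliary colic < choledocholithiasis < cholecystitis) —
use the two-sided Mann–Whitney test with midranks and tie-corrected normal
approximation. Whether diagnosis was analysed as ordered or nominal is
ambiguous in the source; both are exposed, ordered is default. When every
observation is tied the Mann–Whitney statistic is n₁n₂/2 and p = 1. Cell
percentages are shares of the whole cohort. No multiplicity adjustment is
applied (the source applies none).

## Sample-size design

n_cases = ⌈z²·Se(1−Se)/d²⌉ positive cases, n_total = ⌈n_cases/prevalence⌉,
inflated for loss by division by (1−loss) — the conservative convention;
multiplication by (1+loss) is available. At the study's inputs (Se 0.934,
prevalence 0.312, 95% confidence, d 0.05, 10% loss) this gives 95 cases, 305
patients, 339 with loss. The source prints no resulting n, so the formula
variant it used is unverifiable; no equality with its enrolment of 319 is
asserted.

## Synthetic cohort generator

The generator's defaults are the published cohort conditions: age
~ Normal(55.4, 18.2²) truncated at 18; P(female) = 185/319; ASA, diagnosis
and admission from their observed proportions (all ASA "4–5" mass on 4, as
the point table has no separate 5 row); wall thickness and duct diameter as
gammas moment-matched to 3.3 ± 1.7 mm and 4.9 ± 2.1 mm (positive support is
required and only mean ± SD are published); P(ERCP) = 63/319. Covariates are
drawn independently by default; an optional stylised coupling shifts the
wall-thickness mean up by 1.5 mm for cholecystitis and moves half of its
elective admission mass to delayed — a modelling choice, not an estimated
dependence, since no joint distribution is published. Independent marginals
cannot reproduce the published factor-difficulty associations; passing tests
on synthetic cohorts therefore demonstrate correctness of the computational
chain, not clinical validity on real data.

Difficulty is drawn from a logistic link P(difficult | score) =
expit(α + β·score) — an artifact of the generator, as the study fit no
model. The defaults α = −5.1973, β = 0.84375 come from running the
calibration once at n = 50 000, seed 0: bisection on β, re-solving α at each
step (Brent's method) to hold the expected prevalence at 165/319, with the
expected tie-aware AUC evaluated in closed form on the score histogram,
until it is within tolerance of the published 0.88. Difficult cases get
grade 3 or 4 with equal odds, easy ones 1 or 2 (the published grade
distribution is only available as a figure and is not digitised). Outcome
flags are Bernoulli per risk stratum at the published stratum rates;
optional exclusion injection adds planned-open / missing-variable /
malignancy records at given rates (missing records have one scored field
blanked at random). All draws flow from a single seeded generator; equal
seeds give byte-identical cohorts.

Parameter recovery uses an in-package IRLS logistic fit (Newton steps on the
Fisher information, convergence at step norm < 1e-10, standard errors from
the inverse information); divergence of the linear predictor beyond |η| > 40
or a singular information matrix raises a separation signal rather than
returning garbage. Tests check agreement with an independent maximum-
likelihood implementation to 1e-6 and recovery of the generating parameters
within three standard errors at n = 10⁵.

## Rendering and problem sizes

Published tables are consistent with truncation (floor) to two decimals
(e.g. 2/123 → 1.62%), so report renderers truncate while JSON carries full
precision. p-values below 0.001 render as "< 0.001".

Test and acceptance problem sizes were chosen as the smallest that make the
stochastic checks informative: 50 000 draws per calibration evaluation and
round-trip (Monte-Carlo error on the AUC ≈ 0.003), 10⁵ for marginal-fidelity
and recovery checks (3-SE bands), 100 random instances for the AUC identity.
The end-to-end fixture is the deterministic 334-record expansion of the
published aggregates.

## Known limitations

- The expansion cohort is synthetic: it reproduces every published
  aggregate exactly but carries minimal covariate variation (three score
  values), so statistics that need the full score distribution (the
  patient-level AUC 0.88, cutoff rows other than 2 and 7, the optimum at 8)
  cannot be reproduced from it and are only approached stochastically via
  the calibrated generator.
- The generator's covariate independence and its logistic link are
  conveniences, not estimates; the coupling option is stylised.
- Exact published p-values are not asserted (test-variant details such as
  corrections are not fully specified in the source); only their
  significance classifications are checked, plus the one printed
  non-significant value (ERCP, 0.467), which Pearson's uncorrected test
  reproduces to two decimals.
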