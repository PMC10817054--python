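# Methods

## Scoring systems

All five scores are additive checklists over binary risk factors; a
factor contributes its points when present and nothing otherwise, so a
total is an integer in `[0, max]` and is monotone in every factor.

| System | Max | Components (1 point each unless noted) |
|---|---|---|
| CT-RECTOR | 6 | multiple occlusions; blunt cap at entry **or** exit; severe calcification; bending > 45°; duration > 12 months or unknown; reattempt |
| KCCT | 8 | proximal blunt cap; proximal adjacent side branch; length ≥ 15 mm; bending > 45°; duration > 12 months or unknown; reattempt; calcification (severe peripheral 1 pt, central 2 pts) |
| J-CTO_CCTA | 5 | proximal blunt cap; length ≥ 20 mm; severe calcification; bending > 45°; reattempt |
| RECHARGE_CCTA | 6 | proximal blunt cap; length ≥ 20 mm; severe calcification; bending > 45°; diseased distal landing zone; prior bypass graft to the CTO vessel |
| J-CTO_CA (angiographic) | 5 | blunt stump; any calcification; bending > 45°; length ≥ 20 mm; reattempt |

Conventions that matter and are enforced bit-exactly:

* Length thresholds are **inclusive** (15.0 mm scores the KCCT point,
  14.999 does not); the bend threshold is **strict** (45.0° scores
  nothing, 45.01° scores).
* *Severe calcification* in CT-RECTOR, J-CTO_CCTA and RECHARGE_CCTA is
  the area criterion alone: calcified area ≥ 50% of the vessel
  cross-sectional area (CSA), with no arc requirement. KCCT grades
  calcification on an exclusive ordinal ladder — *central* (arc 360°
  and 100% of CSA, 2 points) else *severe peripheral* (arc ≥ 180° and
  ≥ 50% of CSA, 1 point) else 0; central does **not** additionally
  collect the peripheral point, reading the two grades as mutually
  exclusive alternatives.
* CT-RECTOR's blunt-cap factor fires on a blunt shape at either the
  entry or the exit of the occlusion and is stored separately from the
  proximal-only blunt cap used by the other scores.
* Scores are never imputed. A missing required field makes exactly that
  score uncomputable with a reason naming the field; `score_all`
  returns the computable subset.
* Tortuosity is stored as a continuous maximal bend angle; the > 45°
  flag is derived from it, so continuous summaries and score components
  come from one field.

## Endpoints

* **Time-efficient guidewire crossing**: successful crossing within
  30 minutes of first wire insertion. The bound is inclusive (≤ 30.0):
  "within" is read as including the boundary, and the boundary case is
  tested explicitly.
* **Final procedural success**: crossing at any time with restored
  flow — residual stenosis strictly < 50% and TIMI flow grade 3. A
  crossed lesion with a missing TIMI grade is rejected at validation,
  never assumed successful; a missing residual stenosis fails the flow
  criterion.
* **Any non-AW strategy**: ADR, RW or RDR was used. Derived quantities:
  *retrograde approach* = RW or RDR; *DART* (dissection and re-entry
  technique) = ADR or RDR.

Endpoint derivation is a pure function of the procedure record.

## Diagnostic-accuracy machinery

Direction is explicit everywhere: `"low"` means low predictor values
indicate the positive class (low complexity scores predict procedural
success; criteria render `<=k`), `"high"` the reverse (`>k`, used for
the need-for-non-AW endpoint). An AUC below 0.5 is reported as
computed — orientation is never silently flipped, since auto-flipping
hides coding errors.

* **AUC** is the Mann–Whitney probability `P(score_pos ranks before
  score_neg)` with ties counting one half, computed from placement
  values; it equals the trapezoidal area of the tie-grouped empirical
  ROC curve (asserted as a test invariant).
* **DeLong variance/covariance** comes from the per-subject structural
  components; the paired test uses
  `z = (AUC_a − AUC_b) / sqrt(var_a + var_b − 2 cov)` with a two-sided
  normal p-value. A zero-variance difference of zero yields p = 1 by
  convention. The single-AUC variance agrees with the leave-one-out
  jackknife to within a few percent at n ≈ 100.
* **95% CI** for a single AUC: normal interval on the logit scale with
  the DeLong standard error, which keeps the bounds inside [0, 1]; a
  degenerate AUC of exactly 0 or 1 collapses the interval to the point.
  `p (AUC = 0.5)` uses the DeLong-based z. Exact-binomial CI variants
  exist and will differ slightly in the tails.
* **Youden cut-off**: maximizes J = sensitivity + specificity − 1 over
  every achievable threshold. Ties in J break toward higher sensitivity
  (screening use), then toward the less extreme threshold (nearest the
  middle of the sweep), making the output deterministic. In the fully
  degenerate high-direction case (no discrimination anywhere) the
  all-positive rule can be selected and renders as `>-inf`.
* **Fisher exact (two-sided)**: probability-mass definition — the sum
  of hypergeometric probabilities of all tables with the observed
  margins not exceeding the observed table's probability (relative
  tolerance 1e−7 for floating-point ties). Mid-p and doubling variants
  differ; this is the common default. An empty margin returns p = 1.
* **Mann–Whitney U**: exact enumeration of the permutation distribution
  for combined n ≤ 12 (valid under ties; two-sided p doubles the
  smaller tail, capped at 1); otherwise the tie-corrected normal
  approximation with continuity correction.
* **Student's t**: pooled variance, n₁+n₂−2 df; zero pooled variance
  with equal means gives (0, 1), with unequal means a flagged infinite
  t.
* **Cohen's kappa**: `(p_o − p_e)/(1 − p_e)` with expected agreement
  from the marginal products; κ = 1 when both raters agree perfectly on
  a single category.
* **Multiple testing**: none. Group-comparison and pairwise DeLong
  p-values are reported unadjusted; the report carries the number of
  comparisons so readers can adjust if they wish.
* Report rounding: percentages to one decimal, AUCs to three.

## Synthetic cohort generator

A single latent difficulty factor `d ~ N(0, 1)` per lesion induces all
feature–outcome correlation. The additive checklist scores are proxies
for one underlying difficulty construct, and one factor is the simplest
structure that reproduces the characteristic group contrasts (harder
lesions are simultaneously longer, more calcified, more tortuous, and
slower to cross).

* Binary features: `P(f | d) = logistic(α_f + β_f d)` with α_f solved
  by root-finding over the Gauss–Hermite-integrated normal mixture so
  the **marginal** prevalence hits its target for any loading β_f.
  Defaults: blunt proximal cap 36.4%, proximal side branch 51.8%,
  multiple occlusions 14.5%, diseased landing zone 50%, duration > 12
  months or unknown 89.1%, reattempt 21.8%, grafted vessel 17.3%.
* Calcification: ordinal ladder cut from `c = κd + ε` at thresholds
  matched to the nested marginals (any 80.9%, ≥ 50% CSA 40.9%, 100%
  CSA 16.4%), so the nesting holds by construction. The arc category is
  derived from the grade; in generated data arc ≥ 180° coincides with
  the ≥ 50%-area flag, a deliberate simplification.
* Length and bend: lognormal with medians 15.6 mm and 27°, a fixed
  residual log-SD, and the difficulty loading added on the log scale —
  the median is invariant to the loading, so calibration never moves
  it.
* Angiographic view: the CCTA truth seen through reader noise —
  symmetric 10% misclassification for the blunt stump, a noisier
  threshold on the same calcium latent (marginal 15.5%; invasive
  angiography is far less sensitive to calcium than CT), and
  multiplicative lognormal noise with median ratios 11.3/15.6 (length)
  and 25/27 (bend).
* Outcome: `log T = log 20 + γd + σε` for crossing time; a never-cross
  event with marginal probability 9.1% and its own difficulty loading.
  Escalation to a non-AW strategy happens on never-cross, when T
  exceeds an independently drawn switch time, or with 3.6% probability
  as a primary retrograde choice; the escalated strategy set is sampled
  from a fixed mix of ADR/RW/RDR combinations derived from the
  reference cohort's usage pattern. TIMI 3 flow follows crossing with
  probability 0.98.
* Switch time: lognormal with **marginal** median 36 min. The published
  27 min (IQR 19–52) describes recorded strategy changes, i.e. is
  conditional on escalation, and escalation selects small switch draws;
  the marginal 36 min yields a conditional median of ≈ 27 min under the
  default configuration.
* The switch draw is independent of the crossing time. The real
  dependence between the moment operators abandon AW and eventual
  success is not characterized; independence is a modelling convenience
  and should not be over-interpreted in generated data.

All base random draws are made up front from one seeded generator in a
fixed, documented order, with parameters applied analytically
afterwards. Regeneration is therefore bit-identical, and changing only
strength parameters (loadings, γ) reuses the same random numbers —
common random numbers, which make `calibrate_discrimination` (bisection
on a fixed-inner-seed AUC estimate at n = 20 000, tolerance 0.01) and
the γ-monotonicity property deterministic.

### Reference fixture

`fixture_table2_cohort()` is a deterministic 110-lesion cohort whose
per-group strategy, crossing, TIMI-3 and feature **counts** are exact.
The joint strategy assignment was solved by inclusion–exclusion from
the per-group marginals; feature flags are assigned to the first k
lesions of each group, so the joint feature structure is intentionally
meaningless — the fixture certifies counts and percentages, not
correlations. Use `generate_cohort` when correlated data are needed.

### What passing tests do and do not show

The generator reproduces marginal prevalences, medians, outcome rates
and a tunable single-factor association structure. It does not attempt
the real joint feature distribution, per-operator or per-vessel
effects, or the real dependence between switch timing and success, so
recovery results on synthetic cohorts validate the *machinery*
(scoring, endpoint derivation, ROC/DeLong inference, calibration), not
clinical effect sizes. Real-cohort AUC point estimates are outside what
synthetic data can certify.

## Problem sizes and numerical choices

The test suite and the acceptance script use: exhaustive scoring over
4 096 binarised factor combinations; 300–1 000 random AUC instances
with `n_pos × n_neg ≤ 400`; 1 000 null replicates at n = 200 for the
DeLong uniformity screen; all 2×2 tables with margins ≤ 15 for Fisher
enumeration; 100 replicates of n = 2 000 for AUC-recovery coverage; and
n = 10⁴ cohorts for marginal fidelity (every binary prevalence within 3
binomial SE, medians within 5%). These sizes give Monte-Carlo error
comfortably below the asserted tolerances while keeping a full run in
well under a minute.

Known limitations: the kappa summary averages over whichever
categorical parameters both readers scored (the canonical parameter set
is the package's own choice); the exact Mann–Whitney enumerates up to
combined n = 12 (configurable) and switches to the corrected normal
beyond; DeLong inference needs at least two subjects per class, and
degenerate endpoints are reported as uncomputable rather than guessed.
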