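# ctoscores

Risk-score calculators and diagnostic-accuracy analysis for
percutaneous coronary intervention (PCI) of chronic total occlusions
(CTOs) performed with the hybrid algorithm.

A CTO is a completely occluded coronary artery (TIMI flow grade 0 of at
least three months' duration). Crossing one with a guidewire is the
hardest part of the procedure, and the hybrid algorithm escalates
through four strategies — antegrade wiring (AW), antegrade dissection
and re-entry (ADR), retrograde wiring (RW) and retrograde dissection
and re-entry (RDR) — to do it time-efficiently. Several additive
checklist scores grade the expected difficulty of a lesion from imaging
before the procedure. This package is for interventional cardiologists
and biostatisticians who want to compute those scores reproducibly and
evaluate how well they predict procedural outcome.

It provides:

* **Scores** — CT-RECTOR (0–6), KCCT (0–8), J-CTO_CCTA (0–5) and
  RECHARGE_CCTA (0–6) from coronary-CT-angiography lesion features, and
  the classical angiographic J-CTO score (0–5). Each score is a sum of
  one-point risk factors (KCCT awards 2 points for central
  calcification), e.g.

  J-CTO = [blunt stump] + [calcification] + [bending > 45°] +
  [length ≥ 20 mm] + [reattempt].

* **Endpoints** — time-efficient guidewire crossing (success within 30
  minutes of first wire insertion), final procedural success (crossing
  at any time with residual stenosis < 50% and TIMI 3 flow), and the
  need for any non-AW strategy.

* **Diagnostics** — ROC curves, the Mann–Whitney AUC with DeLong
  variance, paired DeLong comparisons between scores, Youden-index
  optimal cut-offs with sensitivity/specificity, Cohen's kappa for
  interobserver agreement, Fisher exact and Mann–Whitney/t tests for
  group-comparison tables.

* **Synthetic cohorts** — a latent-difficulty generator that emulates
  the feature prevalences, outcome rates and strategy-escalation
  structure of a real hybrid CTO-PCI cohort, plus a deterministic
  110-lesion reference cohort for exact regression testing.

## Worked example

Score a difficult lesion — long (34 mm), centrally calcified, bent,
with a blunt proximal cap and a diseased distal landing zone:

```python
from ctoscores import (CTLesionFeatures, AngioLesionFeatures,
                       ClinicalContext, score_all)

lesion = CTLesionFeatures(
    blunt_cap_proximal=True, blunt_cap_entry_or_exit=True,
    proximal_side_branch=True, occlusion_length_mm=34.0, max_bend_deg=58.0,
    any_calcification=True, calc_arc_max_deg="360",
    calc_area_frac_ge_50=True, calc_area_frac_100=True,
    multiple_occlusions=False, diseased_distal_landing_zone=True)
angio = AngioLesionFeatures(blunt_stump=True, any_calcification=True,
                            max_bend_deg=49.0, occlusion_length_mm=28.0)
clin = ClinicalContext(duration_gt_12mo_or_unknown=True, reattempt=False,
                       prior_cabg_to_cto_vessel=False)

for system, res in score_all(lesion, angio, clin).results.items():
    print(f"{system:14s} {res.total}")
```

```
CT-RECTOR      4
KCCT           7
J-CTO_CCTA     4
RECHARGE_CCTA  5
J-CTO_CA       4
```

Every score lands well above its typical "likely success" cut-off
(e.g. KCCT ≤ 3, J-CTO_CCTA ≤ 1 for time-efficient crossing): this
lesion is predicted to need long crossing times and probably a non-AW
strategy. The per-factor breakdown is in ``res.components``.

Aggregate endpoints over the packaged reference cohort:

```python
from ctoscores import fixture_table2_cohort, aggregate_endpoints

agg = aggregate_endpoints(fixture_table2_cohort().procedures)
print(agg.loc[["time_efficient_crossing", "final_procedural_success",
               "any_non_aw"], ["count", "pct"]])
```

```
                          count   pct
indicator
time_efficient_crossing      59  53.6
final_procedural_success     98  89.1
any_non_aw                   40  36.4
```

i.e. 53.6% of the 110 lesions crossed within 30 minutes, 89.1% ended in
full procedural success, and 36.4% needed a non-AW strategy.

The same pipeline is available from the shell:

```sh
cto fixture --out cohort/
cto analyze --lesions cohort/lesions.csv --procedures cohort/procedures.csv --out report/
cto simulate --n 2000 --seed 7 --out sim/
```

``report/`` then contains the endpoint prevalences, group-comparison
tables, the per-score accuracy table (AUC, 95% CI, Youden criterion,
sensitivity/specificity) and the pairwise DeLong matrix as CSVs.

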