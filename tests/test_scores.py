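"""Scoring-system unit and property tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctoscores.scores import (
    AngioLesionFeatures,
    CalcGrade,
    CTLesionFeatures,
    ClinicalContext,
    FeatureValidationError,
    MissingFeatureError,
    SYSTEM_MAX,
    compute_ct_rector,
    compute_jcto_angio,
    compute_jcto_ccta,
    compute_kcct,
    compute_recharge_ccta,
    grade_calcification,
    score_all,
    score_table,
)
from oracles import oracle_score_panel


def ct(**kw):
    base = dict(
        blunt_cap_proximal=False,
        blunt_cap_entry_or_exit=False,
        proximal_side_branch=False,
        occlusion_length_mm=10.0,
        max_bend_deg=20.0,
        any_calcification=False,
        calc_arc_max_deg="<180",
        calc_area_frac_ge_50=False,
        calc_area_frac_100=False,
        multiple_occlusions=False,
        diseased_distal_landing_zone=False,
    )
    base.update(kw)
    return CTLesionFeatures(**base)


def angio(**kw):
    base = dict(
        blunt_stump=False,
        any_calcification=False,
        max_bend_deg=20.0,
        occlusion_length_mm=10.0,
    )
    base.update(kw)
    return AngioLesionFeatures(**base)


def clin(**kw):
    base = dict(
        duration_gt_12mo_or_unknown=False,
        reattempt=False,
        prior_cabg_to_cto_vessel=False,
    )
    base.update(kw)
    return ClinicalContext(**base)


class TestCalcificationGrade:
    @pytest.mark.parametrize(
        "arc, ge50, full, any_calc, expected",
        [
            ("360", True, True, True, CalcGrade.CENTRAL),
            ("<180", False, False, False, CalcGrade.NONE),
            (">=180", True, False, True, CalcGrade.SEVERE_PERIPHERAL),
            ("360", True, False, True, CalcGrade.SEVERE_PERIPHERAL),
            ("<180", False, False, True, CalcGrade.PRESENT_NONSEVERE),
            (">=180", False, False, True, CalcGrade.PRESENT_NONSEVERE),
        ],
    )
    def test_grade_ladder(self, arc, ge50, full, any_calc, expected):
        lesion = ct(
            calc_arc_max_deg=arc,
            calc_area_frac_ge_50=ge50,
            calc_area_frac_100=full,
            any_calcification=any_calc,
        )
        assert grade_calcification(lesion) is expected

    def test_grades_totally_ordered(self):
        assert (
            CalcGrade.NONE
            < CalcGrade.PRESENT_NONSEVERE
            < CalcGrade.SEVERE_PERIPHERAL
            < CalcGrade.CENTRAL
        )

    def test_full_area_with_partial_arc_rejected(self):
        with pytest.raises(FeatureValidationError):
            ct(calc_arc_max_deg=">=180", calc_area_frac_100=True)

    def test_full_area_without_half_area_rejected(self):
        with pytest.raises(FeatureValidationError):
            ct(
                calc_arc_max_deg="360",
                calc_area_frac_100=True,
                calc_area_frac_ge_50=False,
            )


ALL_CT = ct(
    blunt_cap_proximal=True,
    blunt_cap_entry_or_exit=True,
    proximal_side_branch=True,
    occlusion_length_mm=25.0,
    max_bend_deg=50.0,
    any_calcification=True,
    calc_arc_max_deg="360",
    calc_area_frac_ge_50=True,
    calc_area_frac_100=True,
    multiple_occlusions=True,
    diseased_distal_landing_zone=True,
)
ALL_CLIN = clin(
    duration_gt_12mo_or_unknown=True, reattempt=True, prior_cabg_to_cto_vessel=True
)


class TestScoreExamples:
    def test_ct_rector_all_factors(self):
        assert compute_ct_rector(ALL_CT, ALL_CLIN).total == 6

    def test_ct_rector_empty(self):
        assert compute_ct_rector(ct(), clin()).total == 0

    def test_ct_rector_two_factors_breakdown(self):
        res = compute_ct_rector(ct(multiple_occlusions=True), clin(reattempt=True))
        assert res.total == 2
        assert res.components["multiple_occlusions"] == 1
        assert res.components["reattempt"] == 1

    def test_kcct_max_with_central_calc(self):
        assert compute_kcct(ALL_CT, ALL_CLIN).total == 8

    def test_kcct_length_threshold_inclusive(self):
        assert compute_kcct(ct(occlusion_length_mm=15.0), clin()).total == 1

    def test_kcct_central_calcification_two_points_exclusive(self):
        lesion = ct(
            any_calcification=True,
            calc_arc_max_deg="360",
            calc_area_frac_ge_50=True,
            calc_area_frac_100=True,
        )
        res = compute_kcct(lesion, clin())
        assert res.total == 2
        assert res.components["calcification"] == 2

    def test_jcto_ccta_below_length_threshold(self):
        assert compute_jcto_ccta(ct(occlusion_length_mm=19.9), clin()).total == 0

    def test_jcto_ccta_all(self):
        assert compute_jcto_ccta(ALL_CT, ALL_CLIN).total == 5

    def test_jcto_ccta_cap_plus_calc(self):
        lesion = ct(
            blunt_cap_proximal=True,
            any_calcification=True,
            calc_area_frac_ge_50=True,
            calc_arc_max_deg=">=180",
        )
        assert compute_jcto_ccta(lesion, clin()).total == 2

    def test_recharge_landing_zone_plus_graft(self):
        res = compute_recharge_ccta(
            ct(diseased_distal_landing_zone=True),
            clin(prior_cabg_to_cto_vessel=True),
        )
        assert res.total == 2

    @pytest.mark.parametrize("lesion, context, expected", [(ALL_CT, ALL_CLIN, 6), (ct(), clin(), 0)])
    def test_recharge_extremes(self, lesion, context, expected):
        assert compute_recharge_ccta(lesion, context).total == expected

    def test_jcto_angio_extremes(self):
        full = angio(
            blunt_stump=True,
            any_calcification=True,
            max_bend_deg=50.0,
            occlusion_length_mm=25.0,
        )
        assert compute_jcto_angio(full, ALL_CLIN).total == 5
        assert compute_jcto_angio(angio(), clin()).total == 0

    def test_jcto_angio_stump_plus_reattempt(self):
        res = compute_jcto_angio(angio(blunt_stump=True), clin(reattempt=True))
        assert res.total == 2


class TestThresholdBoundaries:
    """Printed thresholds: >=15/>=20 mm inclusive, >45 degrees strict."""

    @pytest.mark.parametrize(
        "length, expected", [(15.0, 1), (14.999, 0), (14.0, 0), (15.001, 1)]
    )
    def test_kcct_length_boundary(self, length, expected):
        assert compute_kcct(ct(occlusion_length_mm=length), clin()).total == expected

    @pytest.mark.parametrize("length, expected", [(20.0, 1), (19.999, 0)])
    def test_jcto_length_boundary(self, length, expected):
        assert compute_jcto_ccta(ct(occlusion_length_mm=length), clin()).total == expected

    @pytest.mark.parametrize("bend, expected", [(45.0, 0), (45.01, 1), (44.99, 0)])
    def test_bend_boundary_strict(self, bend, expected):
        assert compute_ct_rector(ct(max_bend_deg=bend), clin()).total == expected
        assert compute_kcct(ct(max_bend_deg=bend), clin()).total == expected


CALC_LEVELS = [
    # (any, arc, ge50, full)
    (False, "<180", False, False),
    (True, "<180", False, False),
    (True, ">=180", True, False),
    (True, "360", True, True),
]


def _exhaustive_cases():
    """All combinations of binarised risk factors (the 2^n sweep)."""
    flags = itertools.product([False, True], repeat=6)
    cases = []
    for (blunt_p, blunt_ee, sb, multi, landing, duration) in flags:
        for reattempt, cabg in itertools.product([False, True], repeat=2):
            for length in (9.0, 25.0):
                for bend in (30.0, 50.0):
                    for any_c, arc, ge50, full in CALC_LEVELS:
                        cases.append(
                            dict(
                                blunt_cap_proximal=blunt_p,
                                blunt_cap_entry_or_exit=blunt_ee,
                                proximal_side_branch=sb,
                                multiple_occlusions=multi,
                                diseased_distal_landing_zone=landing,
                                duration_gt_12mo_or_unknown=duration,
                                reattempt=reattempt,
                                prior_cabg_to_cto_vessel=cabg,
                                occlusion_length_mm=length,
                                max_bend_deg=bend,
                                any_calcification=any_c,
                                calc_arc_max_deg=arc,
                                calc_area_frac_ge_50=ge50,
                                calc_area_frac_100=full,
                                angio_blunt_stump=blunt_p,
                                angio_any_calcification=any_c,
                                angio_max_bend_deg=bend,
                                angio_occlusion_length_mm=length,
                            )
                        )
    return cases


class TestExhaustiveEnumeration:
    def test_all_systems_match_point_sum_oracle(self):
        """Every factor combination scores exactly as the literal point lists."""
        cases = _exhaustive_cases()
        frame = pd.DataFrame(cases)
        frame["lesion_id"] = [str(i) for i in range(len(frame))]
        table = score_table(frame)
        expected = pd.DataFrame([oracle_score_panel(c) for c in cases])
        for col in expected.columns:
            assert (table[col].to_numpy() == expected[col].to_numpy()).all(), col

    def test_dataclass_api_agrees_with_vectorised_table(self):
        rng = np.random.default_rng(5)
        cases = _exhaustive_cases()
        idx = rng.choice(len(cases), 100, replace=False)
        for i in idx:
            c = cases[i]
            lesion = ct(**{k: c[k] for k in (
                "blunt_cap_proximal", "blunt_cap_entry_or_exit",
                "proximal_side_branch", "occlusion_length_mm", "max_bend_deg",
                "any_calcification", "calc_arc_max_deg", "calc_area_frac_ge_50",
                "calc_area_frac_100", "multiple_occlusions",
                "diseased_distal_landing_zone")})
            ang = angio(
                blunt_stump=c["angio_blunt_stump"],
                any_calcification=c["angio_any_calcification"],
                max_bend_deg=c["angio_max_bend_deg"],
                occlusion_length_mm=c["angio_occlusion_length_mm"],
            )
            context = clin(**{k: c[k] for k in (
                "duration_gt_12mo_or_unknown", "reattempt",
                "prior_cabg_to_cto_vessel")})
            panel = score_all(lesion, ang, context)
            expected = oracle_score_panel(c)
            got = {
                "ct_rector": panel.results["CT-RECTOR"].total,
                "kcct": panel.results["KCCT"].total,
                "jcto_ccta": panel.results["J-CTO_CCTA"].total,
                "recharge_ccta": panel.results["RECHARGE_CCTA"].total,
                "jcto_ca": panel.results["J-CTO_CA"].total,
            }
            assert got == expected

    def test_totals_within_system_bounds(self):
        frame = pd.DataFrame(_exhaustive_cases())
        table = score_table(frame)
        for system, col in [
            ("CT-RECTOR", "ct_rector"),
            ("KCCT", "kcct"),
            ("J-CTO_CCTA", "jcto_ccta"),
            ("RECHARGE_CCTA", "recharge_ccta"),
            ("J-CTO_CA", "jcto_ca"),
        ]:
            assert table[col].between(0, SYSTEM_MAX[system]).all()
            assert table[col].max() == SYSTEM_MAX[system]


UPGRADES = {
    "blunt_cap_proximal": lambda c: {**c, "blunt_cap_proximal": True,
                                     "angio_blunt_stump": True},
    "blunt_cap_entry_or_exit": lambda c: {**c, "blunt_cap_entry_or_exit": True},
    "proximal_side_branch": lambda c: {**c, "proximal_side_branch": True},
    "multiple_occlusions": lambda c: {**c, "multiple_occlusions": True},
    "diseased_distal_landing_zone": lambda c: {
        **c, "diseased_distal_landing_zone": True},
    "duration_gt_12mo_or_unknown": lambda c: {
        **c, "duration_gt_12mo_or_unknown": True},
    "reattempt": lambda c: {**c, "reattempt": True},
    "prior_cabg_to_cto_vessel": lambda c: {**c, "prior_cabg_to_cto_vessel": True},
    "length": lambda c: {**c, "occlusion_length_mm": 25.0,
                         "angio_occlusion_length_mm": 25.0},
    "bend": lambda c: {**c, "max_bend_deg": 50.0, "angio_max_bend_deg": 50.0},
    "calcification": lambda c: {**c, "any_calcification": True,
                                "calc_arc_max_deg": "360",
                                "calc_area_frac_ge_50": True,
                                "calc_area_frac_100": True,
                                "angio_any_calcification": True},
}


class TestMonotonicity:
    @pytest.mark.parametrize("factor", sorted(UPGRADES))
    def test_adding_a_risk_factor_never_lowers_any_score(self, factor):
        cases = _exhaustive_cases()
        base = pd.DataFrame(cases)
        upgraded = pd.DataFrame([UPGRADES[factor](c) for c in cases])
        t0, t1 = score_table(base), score_table(upgraded)
        for col in ("ct_rector", "kcct", "jcto_ccta", "recharge_ccta", "jcto_ca"):
            assert (t1[col].to_numpy() >= t0[col].to_numpy()).all(), col


class TestMissingData:
    def test_missing_field_names_the_field(self):
        lesion = ct(max_bend_deg=None)
        with pytest.raises(MissingFeatureError, match="max_bend_deg"):
            compute_ct_rector(lesion, clin())

    def test_panel_marks_uncomputable_instead_of_failing(self):
        context = ClinicalContext(
            duration_gt_12mo_or_unknown=True, reattempt=None,
            prior_cabg_to_cto_vessel=False,
        )
        panel = score_all(ct(), angio(), context)
        # every system except RECHARGE needs the reattempt flag
        assert set(panel.uncomputable) == {
            "CT-RECTOR", "KCCT", "J-CTO_CCTA", "J-CTO_CA"}
        assert "reattempt" in panel.uncomputable["CT-RECTOR"]
        assert panel.results["RECHARGE_CCTA"].total == 0

    def test_missing_angio_block(self):
        panel = score_all(ALL_CT, None, ALL_CLIN)
        assert "J-CTO_CA" in panel.uncomputable
        assert len(panel.results) == 4

    def test_no_feature_block_at_all(self):
        with pytest.raises(ValueError):
            score_all(None, None, clin())


class TestComplexLesionPanel:
    def test_hard_lesion_exceeds_every_success_cutoff(self):
        """A long, severely calcified, bent reattempt lesion scores above
        the time-efficient-crossing cut-offs of every system."""
        panel = score_all(
            ALL_CT,
            angio(blunt_stump=True, any_calcification=True,
                  max_bend_deg=50.0, occlusion_length_mm=25.0),
            ALL_CLIN,
        )
        cutoffs = {"J-CTO_CA": 1, "CT-RECTOR": 2, "KCCT": 3,
                   "J-CTO_CCTA": 1, "RECHARGE_CCTA": 2}
        for system, cut in cutoffs.items():
            assert panel.results[system].total > cut

    def test_component_sum_invariant(self):
        for res in score_all(ALL_CT, angio(), ALL_CLIN).results.values():
            assert res.total == sum(res.components.values())


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"occlusion_length_mm": -1.0},
            {"occlusion_length_mm": float("nan")},
            {"max_bend_deg": 181.0},
            {"calc_arc_max_deg": "180"},
            {"blunt_cap_proximal": 2},
        ],
    )
    def test_invalid_ct_features_rejected(self, kw):
        with pytest.raises(FeatureValidationError):
            ct(**kw)

    def test_invalid_angio_features_rejected(self):
        with pytest.raises(FeatureValidationError):
            angio(max_bend_deg=-5.0)
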