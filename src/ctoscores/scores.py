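"""Lesion-complexity scores for chronic total occlusion (CTO) PCI.

Implements the four CCTA-derived scoring systems (CT-RECTOR, KCCT,
J-CTO_CCTA, RECHARGE_CCTA) and the angiography-based J-CTO score.  All
five are additive checklists: each risk factor present contributes one
point (KCCT's central calcification contributes two), so a total score
is an integer between 0 and the system maximum.

Two calling conventions are provided:

* per-lesion, via frozen dataclasses (:class:`CTLesionFeatures`,
  :class:`AngioLesionFeatures`, :class:`ClinicalContext`) and the
  ``compute_*`` functions, which return a :class:`ScoreResult` with a
  per-component breakdown;
* vectorised, via :func:`score_table`, which scores a whole lesion
  DataFrame (the CSV schema of :mod:`ctoscores.io`) in one pass.

Scores are never imputed: a missing required field raises
:class:`MissingFeatureError`, and :func:`score_all` converts that into
an explicit "uncomputable" entry on the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ARC_CATEGORIES",
    "SYSTEM_MAX",
    "SYSTEMS",
    "CalcGrade",
    "CTLesionFeatures",
    "AngioLesionFeatures",
    "ClinicalContext",
    "ScoreResult",
    "ScorePanel",
    "FeatureValidationError",
    "MissingFeatureError",
    "grade_calcification",
    "compute_ct_rector",
    "compute_kcct",
    "compute_jcto_ccta",
    "compute_recharge_ccta",
    "compute_jcto_angio",
    "score_all",
    "score_table",
]

#: Categories of the maximal calcium arc encircling the vessel.
ARC_CATEGORIES = ("<180", ">=180", "360")

#: Score systems and their maximal totals.
SYSTEM_MAX = {
    "CT-RECTOR": 6,
    "KCCT": 8,
    "J-CTO_CCTA": 5,
    "RECHARGE_CCTA": 6,
    "J-CTO_CA": 5,
}
SYSTEMS = tuple(SYSTEM_MAX)

#: Length thresholds (mm), inclusive; bend threshold (degrees), strict.
KCCT_LENGTH_MM = 15.0
JCTO_LENGTH_MM = 20.0
BEND_DEG = 45.0


class FeatureValidationError(ValueError):
    """A lesion feature record violates its internal consistency rules."""


class MissingFeatureError(ValueError):
    """A score requires a feature that was not provided."""

    def __init__(self, system: str, fields: list[str]):
        self.system = system
        self.fields = list(fields)
        super().__init__(
            f"{system} score uncomputable: missing field(s) {', '.join(fields)}"
        )


class CalcGrade(IntEnum):
    """Ordered calcification severity grade.

    ``none < present_nonsevere < severe_peripheral < central``.  Severe
    peripheral requires a maximal encircling arc >= 180 degrees with a
    calcified area >= 50% of the vessel cross-sectional area (CSA);
    central requires a 360-degree arc with 100% of the CSA calcified.
    """

    NONE = 0
    PRESENT_NONSEVERE = 1
    SEVERE_PERIPHERAL = 2
    CENTRAL = 3


def _check_flag(name: str, value) -> bool | None:
    if value is None:
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in (0, 1):
        return bool(value)
    raise FeatureValidationError(f"{name} must be boolean/0/1, got {value!r}")


@dataclass(frozen=True)
class CTLesionFeatures:
    """Per-lesion CCTA morphology.

    Any field may be ``None`` (not assessed); a score needing it is then
    uncomputable.  Lengths are millimetres, angles degrees.
    """

    blunt_cap_proximal: bool | None = None
    #: blunt cap shape at either the entry or the exit of the occlusion
    blunt_cap_entry_or_exit: bool | None = None
    proximal_side_branch: bool | None = None
    occlusion_length_mm: float | None = None
    max_bend_deg: float | None = None
    #: any calcium within the CTO segment (may be mild)
    any_calcification: bool | None = None
    #: maximal calcium arc category, one of ``ARC_CATEGORIES``
    calc_arc_max_deg: str | None = None
    #: calcified area >= 50% of vessel CSA anywhere in the CTO segment
    calc_area_frac_ge_50: bool | None = None
    #: calcified area equal to 100% of vessel CSA
    calc_area_frac_100: bool | None = None
    #: >=2 complete interruptions separated by an enhanced segment >=5 mm
    multiple_occlusions: bool | None = None
    #: stenosis >50% distal to the occlusion or distal lumen <2 mm
    diseased_distal_landing_zone: bool | None = None

    def __post_init__(self):
        for name in (
            "blunt_cap_proximal",
            "blunt_cap_entry_or_exit",
            "proximal_side_branch",
            "any_calcification",
            "calc_area_frac_ge_50",
            "calc_area_frac_100",
            "multiple_occlusions",
            "diseased_distal_landing_zone",
        ):
            object.__setattr__(self, name, _check_flag(name, getattr(self, name)))
        L = self.occlusion_length_mm
        if L is not None and not (math.isfinite(L) and L >= 0):
            raise FeatureValidationError(
                f"occlusion_length_mm must be finite and >=0, got {L!r}"
            )
        b = self.max_bend_deg
        if b is not None and not (math.isfinite(b) and 0 <= b <= 180):
            raise FeatureValidationError(
                f"max_bend_deg must be in [0, 180], got {b!r}"
            )
        arc = self.calc_arc_max_deg
        if arc is not None and arc not in ARC_CATEGORIES:
            raise FeatureValidationError(
                f"calc_arc_max_deg must be one of {ARC_CATEGORIES}, got {arc!r}"
            )
        if self.calc_area_frac_100:
            if arc is not None and arc != "360":
                raise FeatureValidationError(
                    "calc_area_frac_100 requires calc_arc_max_deg='360'"
                )
            if self.calc_area_frac_ge_50 is False:
                raise FeatureValidationError(
                    "calc_area_frac_100 implies calc_area_frac_ge_50"
                )
        for flag in ("calc_area_frac_ge_50", "calc_area_frac_100"):
            if getattr(self, flag) and self.any_calcification is False:
                raise FeatureValidationError(
                    f"{flag} set but any_calcification is False"
                )


@dataclass(frozen=True)
class AngioLesionFeatures:
    """Per-lesion invasive-angiography morphology (J-CTO components)."""

    blunt_stump: bool | None = None
    any_calcification: bool | None = None
    max_bend_deg: float | None = None
    occlusion_length_mm: float | None = None

    def __post_init__(self):
        for name in ("blunt_stump", "any_calcification"):
            object.__setattr__(self, name, _check_flag(name, getattr(self, name)))
        L = self.occlusion_length_mm
        if L is not None and not (math.isfinite(L) and L >= 0):
            raise FeatureValidationError(
                f"occlusion_length_mm must be finite and >=0, got {L!r}"
            )
        b = self.max_bend_deg
        if b is not None and not (math.isfinite(b) and 0 <= b <= 180):
            raise FeatureValidationError(
                f"max_bend_deg must be in [0, 180], got {b!r}"
            )


@dataclass(frozen=True)
class ClinicalContext:
    """Clinical flags entering the scores."""

    duration_gt_12mo_or_unknown: bool | None = None
    reattempt: bool | None = None
    prior_cabg_to_cto_vessel: bool | None = None

    def __post_init__(self):
        for name in (
            "duration_gt_12mo_or_unknown",
            "reattempt",
            "prior_cabg_to_cto_vessel",
        ):
            object.__setattr__(self, name, _check_flag(name, getattr(self, name)))


@dataclass(frozen=True)
class ScoreResult:
    """One score for one lesion, with the per-component point breakdown."""

    system: str
    total: int
    components: Mapping[str, int]

    def __post_init__(self):
        if self.system not in SYSTEM_MAX:
            raise ValueError(f"unknown score system {self.system!r}")
        if self.total != sum(self.components.values()):
            raise ValueError("total does not equal the component sum")
        if not 0 <= self.total <= SYSTEM_MAX[self.system]:
            raise ValueError(
                f"{self.system} total {self.total} outside "
                f"[0, {SYSTEM_MAX[self.system]}]"
            )


@dataclass(frozen=True)
class ScorePanel:
    """All five scores for one lesion.

    Systems that could not be computed appear in ``uncomputable`` with
    a human-readable reason instead of in ``results``.
    """

    lesion_id: str
    results: Mapping[str, ScoreResult] = field(default_factory=dict)
    uncomputable: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        covered = set(self.results) | set(self.uncomputable)
        if covered != set(SYSTEMS):
            raise ValueError(
                f"panel must cover all systems; missing {set(SYSTEMS) - covered}"
            )


def _require(system: str, **fields):
    missing = [name for name, value in fields.items() if value is None]
    if missing:
        raise MissingFeatureError(system, missing)


def grade_calcification(ct: CTLesionFeatures) -> CalcGrade:
    """Grade calcification on the ordered none/non-severe/peripheral/central ladder.

    Central: 360-degree arc and 100% of CSA calcified.  Severe
    peripheral: arc >= 180 degrees and >= 50% of CSA.  Anything else
    with calcium present is non-severe; no calcium field set is none.
    """
    _require(
        "KCCT",
        calc_arc_max_deg=ct.calc_arc_max_deg,
        calc_area_frac_ge_50=ct.calc_area_frac_ge_50,
        calc_area_frac_100=ct.calc_area_frac_100,
    )
    if ct.calc_arc_max_deg == "360" and ct.calc_area_frac_100:
        return CalcGrade.CENTRAL
    if ct.calc_arc_max_deg in (">=180", "360") and ct.calc_area_frac_ge_50:
        return CalcGrade.SEVERE_PERIPHERAL
    any_calc = (
        ct.any_calcification
        or ct.calc_area_frac_ge_50
        or ct.calc_area_frac_100
        or ct.calc_arc_max_deg in (">=180", "360")
    )
    return CalcGrade.PRESENT_NONSEVERE if any_calc else CalcGrade.NONE


def compute_ct_rector(
    ct: CTLesionFeatures, clin: ClinicalContext
) -> ScoreResult:
    """CT-RECTOR score (0-6): one point per factor present.

    Factors: multiple occlusions; blunt cap at the occlusion entry or
    exit; severe calcification (calcified area >= 50% of CSA); bending
    > 45 degrees; duration > 12 months or unknown; reattempt procedure.
    """
    _require(
        "CT-RECTOR",
        multiple_occlusions=ct.multiple_occlusions,
        blunt_cap_entry_or_exit=ct.blunt_cap_entry_or_exit,
        calc_area_frac_ge_50=ct.calc_area_frac_ge_50,
        max_bend_deg=ct.max_bend_deg,
        duration_gt_12mo_or_unknown=clin.duration_gt_12mo_or_unknown,
        reattempt=clin.reattempt,
    )
    components = {
        "multiple_occlusions": int(ct.multiple_occlusions),
        "blunt_cap_entry_or_exit": int(ct.blunt_cap_entry_or_exit),
        "severe_calcification": int(ct.calc_area_frac_ge_50),
        "bend_gt_45": int(ct.max_bend_deg > BEND_DEG),
        "duration_gt_12mo_or_unknown": int(clin.duration_gt_12mo_or_unknown),
        "reattempt": int(clin.reattempt),
    }
    return ScoreResult("CT-RECTOR", sum(components.values()), components)


def compute_kcct(ct: CTLesionFeatures, clin: ClinicalContext) -> ScoreResult:
    """KCCT score (0-8).

    One point each for proximal blunt cap, proximal adjacent side
    branch, occlusion length >= 15 mm, bending > 45 degrees, duration >
    12 months or unknown, and reattempt.  Calcification contributes on
    an exclusive ladder: 2 points for central, 1 for severe peripheral,
    0 otherwise.
    """
    _require(
        "KCCT",
        blunt_cap_proximal=ct.blunt_cap_proximal,
        proximal_side_branch=ct.proximal_side_branch,
        occlusion_length_mm=ct.occlusion_length_mm,
        max_bend_deg=ct.max_bend_deg,
        duration_gt_12mo_or_unknown=clin.duration_gt_12mo_or_unknown,
        reattempt=clin.reattempt,
    )
    grade = grade_calcification(ct)
    calc_points = {
        CalcGrade.CENTRAL: 2,
        CalcGrade.SEVERE_PERIPHERAL: 1,
    }.get(grade, 0)
    components = {
        "blunt_cap_proximal": int(ct.blunt_cap_proximal),
        "proximal_side_branch": int(ct.proximal_side_branch),
        "length_ge_15mm": int(ct.occlusion_length_mm >= KCCT_LENGTH_MM),
        "bend_gt_45": int(ct.max_bend_deg > BEND_DEG),
        "duration_gt_12mo_or_unknown": int(clin.duration_gt_12mo_or_unknown),
        "reattempt": int(clin.reattempt),
        "calcification": calc_points,
    }
    return ScoreResult("KCCT", sum(components.values()), components)


def compute_jcto_ccta(ct: CTLesionFeatures, clin: ClinicalContext) -> ScoreResult:
    """CCTA-adapted J-CTO score (0-5).

    One point each for proximal blunt cap, length >= 20 mm, severe
    calcification (>= 50% CSA), bending > 45 degrees, and reattempt.
    """
    _require(
        "J-CTO_CCTA",
        blunt_cap_proximal=ct.blunt_cap_proximal,
        occlusion_length_mm=ct.occlusion_length_mm,
        calc_area_frac_ge_50=ct.calc_area_frac_ge_50,
        max_bend_deg=ct.max_bend_deg,
        reattempt=clin.reattempt,
    )
    components = {
        "blunt_cap_proximal": int(ct.blunt_cap_proximal),
        "length_ge_20mm": int(ct.occlusion_length_mm >= JCTO_LENGTH_MM),
        "severe_calcification": int(ct.calc_area_frac_ge_50),
        "bend_gt_45": int(ct.max_bend_deg > BEND_DEG),
        "reattempt": int(clin.reattempt),
    }
    return ScoreResult("J-CTO_CCTA", sum(components.values()), components)


def compute_recharge_ccta(
    ct: CTLesionFeatures, clin: ClinicalContext
) -> ScoreResult:
    """CCTA-adapted RECHARGE score (0-6).

    One point each for proximal blunt cap, length >= 20 mm, severe
    calcification, bending > 45 degrees, diseased distal landing zone,
    and previous bypass grafting to the CTO vessel.
    """
    _require(
        "RECHARGE_CCTA",
        blunt_cap_proximal=ct.blunt_cap_proximal,
        occlusion_length_mm=ct.occlusion_length_mm,
        calc_area_frac_ge_50=ct.calc_area_frac_ge_50,
        max_bend_deg=ct.max_bend_deg,
        diseased_distal_landing_zone=ct.diseased_distal_landing_zone,
        prior_cabg_to_cto_vessel=clin.prior_cabg_to_cto_vessel,
    )
    components = {
        "blunt_cap_proximal": int(ct.blunt_cap_proximal),
        "length_ge_20mm": int(ct.occlusion_length_mm >= JCTO_LENGTH_MM),
        "severe_calcification": int(ct.calc_area_frac_ge_50),
        "bend_gt_45": int(ct.max_bend_deg > BEND_DEG),
        "diseased_distal_landing_zone": int(ct.diseased_distal_landing_zone),
        "prior_cabg_to_cto_vessel": int(clin.prior_cabg_to_cto_vessel),
    }
    return ScoreResult("RECHARGE_CCTA", sum(components.values()), components)


def compute_jcto_angio(
    angio: AngioLesionFeatures, clin: ClinicalContext
) -> ScoreResult:
    """Angiography-based J-CTO score (0-5).

    The standard five components: blunt stump, any calcification,
    bending > 45 degrees, length >= 20 mm, and reattempt (retry of a
    previously failed lesion).
    """
    _require(
        "J-CTO_CA",
        blunt_stump=angio.blunt_stump,
        any_calcification=angio.any_calcification,
        max_bend_deg=angio.max_bend_deg,
        occlusion_length_mm=angio.occlusion_length_mm,
        reattempt=clin.reattempt,
    )
    components = {
        "blunt_stump": int(angio.blunt_stump),
        "calcification": int(angio.any_calcification),
        "bend_gt_45": int(angio.max_bend_deg > BEND_DEG),
        "length_ge_20mm": int(angio.occlusion_length_mm >= JCTO_LENGTH_MM),
        "reattempt": int(clin.reattempt),
    }
    return ScoreResult("J-CTO_CA", sum(components.values()), components)


_COMPUTE = {
    "CT-RECTOR": lambda ct, angio, clin: compute_ct_rector(ct, clin),
    "KCCT": lambda ct, angio, clin: compute_kcct(ct, clin),
    "J-CTO_CCTA": lambda ct, angio, clin: compute_jcto_ccta(ct, clin),
    "RECHARGE_CCTA": lambda ct, angio, clin: compute_recharge_ccta(ct, clin),
    "J-CTO_CA": lambda ct, angio, clin: compute_jcto_angio(angio, clin),
}


def score_all(
    ct: CTLesionFeatures | None,
    angio: AngioLesionFeatures | None,
    clin: ClinicalContext,
    lesion_id: str = "lesion",
) -> ScorePanel:
    """Compute every computable score for one lesion.

    A missing feature block or field marks the affected system(s)
    uncomputable with the reason, rather than failing the whole panel.
    """
    if ct is None and angio is None:
        raise ValueError("at least one feature block (CT or angio) is required")
    results: dict[str, ScoreResult] = {}
    uncomputable: dict[str, str] = {}
    for system, fn in _COMPUTE.items():
        needs_ct = system != "J-CTO_CA"
        if needs_ct and ct is None:
            uncomputable[system] = "CCTA feature block not provided"
            continue
        if not needs_ct and angio is None:
            uncomputable[system] = "angiographic feature block not provided"
            continue
        try:
            results[system] = fn(ct, angio, clin)
        except MissingFeatureError as exc:
            uncomputable[system] = str(exc)
    return ScorePanel(lesion_id, results, uncomputable)


# -- vectorised scoring over the CSV schema ---------------------------------

#: output column per system, shared with the report writers
SCORE_COLUMNS = {
    "CT-RECTOR": "ct_rector",
    "KCCT": "kcct",
    "J-CTO_CCTA": "jcto_ccta",
    "RECHARGE_CCTA": "recharge_ccta",
    "J-CTO_CA": "jcto_ca",
}


def score_table(lesions: pd.DataFrame) -> pd.DataFrame:
    """Score every lesion of a table (columns per :mod:`ctoscores.io`).

    Returns a DataFrame indexed like ``lesions`` with one integer column
    per system plus ``lesion_id``.  No missing values are allowed here;
    use :func:`score_all` for per-lesion missing-data handling.
    """
    b = lambda col: lesions[col].to_numpy().astype(bool)  # noqa: E731
    f = lambda col: lesions[col].to_numpy().astype(float)  # noqa: E731
    arc = lesions["calc_arc_max_deg"].astype(str).to_numpy()

    bend = f("max_bend_deg") > BEND_DEG
    length = f("occlusion_length_mm")
    severe = b("calc_area_frac_ge_50")
    central = (arc == "360") & b("calc_area_frac_100")
    severe_peri = ~central & np.isin(arc, (">=180", "360")) & severe
    kcct_calc = np.where(central, 2, np.where(severe_peri, 1, 0))

    out = pd.DataFrame(index=lesions.index)
    if "lesion_id" in lesions.columns:
        out["lesion_id"] = lesions["lesion_id"]
    out["ct_rector"] = (
        b("multiple_occlusions").astype(int)
        + b("blunt_cap_entry_or_exit")
        + severe
        + bend
        + b("duration_gt_12mo_or_unknown")
        + b("reattempt")
    )
    out["kcct"] = (
        b("blunt_cap_proximal").astype(int)
        + b("proximal_side_branch")
        + (length >= KCCT_LENGTH_MM)
        + bend
        + b("duration_gt_12mo_or_unknown")
        + b("reattempt")
        + kcct_calc
    )
    out["jcto_ccta"] = (
        b("blunt_cap_proximal").astype(int)
        + (length >= JCTO_LENGTH_MM)
        + severe
        + bend
        + b("reattempt")
    )
    out["recharge_ccta"] = (
        b("blunt_cap_proximal").astype(int)
        + (length >= JCTO_LENGTH_MM)
        + severe
        + bend
        + b("diseased_distal_landing_zone")
        + b("prior_cabg_to_cto_vessel")
    )
    out["jcto_ca"] = (
        b("angio_blunt_stump").astype(int)
        + b("angio_any_calcification")
        + (f("angio_max_bend_deg") > BEND_DEG)
        + (f("angio_occlusion_length_mm") >= JCTO_LENGTH_MM)
        + b("reattempt")
    )
    return out
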