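"""Procedural endpoints of hybrid-algorithm CTO PCI.

The hybrid algorithm escalates among four crossing strategies —
antegrade wiring (AW), antegrade dissection and re-entry (ADR),
retrograde wiring (RW), retrograde dissection and re-entry (RDR) —
to cross the occlusion time-efficiently.  From a per-procedure record
this module derives:

* ``time_efficient_crossing`` — successful guidewire crossing within
  30 minutes of first wire insertion (primary endpoint; boundary
  inclusive);
* ``final_procedural_success`` — crossing at any time with restoration
  of flow, i.e. residual stenosis < 50% and TIMI flow grade 3;
* ``any_non_aw`` — any non-AW strategy (ADR, RW or RDR) was needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "STRATEGIES",
    "TIME_EFFICIENT_LIMIT_MIN",
    "ProcedureRecord",
    "EndpointSet",
    "ProcedureValidationError",
    "derive_endpoints",
    "strategy_profile",
    "aggregate_endpoints",
    "endpoint_table",
]

STRATEGIES = ("AW", "ADR", "RW", "RDR")

#: "within 30 min" — inclusive bound, minutes
TIME_EFFICIENT_LIMIT_MIN = 30.0

#: residual stenosis must be strictly below this for restored flow
RESIDUAL_STENOSIS_LIMIT_PCT = 50.0


class ProcedureValidationError(ValueError):
    """A procedure record is internally inconsistent."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ProcedureRecord:
    """What happened in the cath lab for one lesion.

    ``gw_crossing_time_min`` is the time from first guidewire insertion
    to successful crossing, absent (``None``) if the wire never
    crossed.  ``final_strategy`` is the strategy that achieved the
    crossing, ``"none"`` if none did.
    """

    lesion_id: str
    gw_crossing_time_min: float | None = None
    used_aw: bool = False
    used_adr: bool = False
    used_rw: bool = False
    used_rdr: bool = False
    final_strategy: str = "none"
    residual_stenosis_pct: float | None = None
    timi_flow: int | None = None
    switch_time_min: float | None = None

    def __post_init__(self):
        t = self.gw_crossing_time_min
        if t is not None and not (math.isfinite(t) and t >= 0):
            raise ProcedureValidationError(
                f"{self.lesion_id}: crossing time must be finite and >=0"
            )
        if self.final_strategy not in STRATEGIES + ("none",):
            raise ProcedureValidationError(
                f"{self.lesion_id}: unknown final_strategy "
                f"{self.final_strategy!r}"
            )
        crossed = t is not None
        if crossed and self.final_strategy == "none":
            raise ProcedureValidationError(
                f"{self.lesion_id}: crossing time present but "
                "final_strategy is 'none'"
            )
        if not crossed and self.final_strategy != "none":
            raise ProcedureValidationError(
                f"{self.lesion_id}: final_strategy set without a crossing time"
            )
        if self.final_strategy != "none":
            used = getattr(self, f"used_{self.final_strategy.lower()}")
            if not used:
                raise ProcedureValidationError(
                    f"{self.lesion_id}: final strategy "
                    f"{self.final_strategy} was not among the used strategies"
                )
        if crossed:
            if self.timi_flow is None:
                raise ProcedureValidationError(
                    f"{self.lesion_id}: crossed lesion requires a TIMI grade"
                )
        if self.timi_flow is not None and self.timi_flow not in (0, 1, 2, 3):
            raise ProcedureValidationError(
                f"{self.lesion_id}: TIMI flow must be 0-3, got {self.timi_flow}"
            )
        r = self.residual_stenosis_pct
        if r is not None and not (0 <= r <= 100):
            raise ProcedureValidationError(
                f"{self.lesion_id}: residual stenosis must be in [0, 100]"
            )


@dataclass(frozen=True)
class EndpointSet:
    """The three study endpoints for one procedure."""

    time_efficient_crossing: bool
    final_procedural_success: bool
    any_non_aw: bool


def derive_endpoints(proc: ProcedureRecord) -> EndpointSet:
    """Derive the three endpoints from one procedure record.

    Pure function: depends only on the record.  A crossed lesion with a
    missing residual stenosis is treated as not meeting the flow
    criterion (never assumed successful).
    """
    t = proc.gw_crossing_time_min
    crossed = t is not None
    time_efficient = crossed and t <= TIME_EFFICIENT_LIMIT_MIN
    resid = proc.residual_stenosis_pct
    flow_restored = (
        crossed
        and proc.timi_flow == 3
        and resid is not None
        and resid < RESIDUAL_STENOSIS_LIMIT_PCT
    )
    any_non_aw = proc.used_adr or proc.used_rw or proc.used_rdr
    return EndpointSet(time_efficient, crossed and flow_restored, any_non_aw)


def strategy_profile(proc: ProcedureRecord) -> dict:
    """Strategy usage summary for one procedure.

    ``retrograde`` is RW or RDR; ``dart`` (dissection and re-entry
    technique) is ADR or RDR; ``n_strategies`` counts distinct
    strategies applied.
    """
    flags = {
        "AW": proc.used_aw,
        "ADR": proc.used_adr,
        "RW": proc.used_rw,
        "RDR": proc.used_rdr,
    }
    return {
        **flags,
        "n_strategies": sum(flags.values()),
        "retrograde": flags["RW"] or flags["RDR"],
        "dart": flags["ADR"] or flags["RDR"],
        "any_non_aw": flags["ADR"] or flags["RW"] or flags["RDR"],
    }


def _records(cohort) -> list[ProcedureRecord]:
    if isinstance(cohort, pd.DataFrame):
        from .io import procedures_from_frame

        return procedures_from_frame(cohort)
    return list(cohort)


def endpoint_table(cohort: Iterable[ProcedureRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-procedure endpoint and strategy flags as a DataFrame."""
    records = _records(cohort)
    rows = []
    for proc in records:
        ep = derive_endpoints(proc)
        prof = strategy_profile(proc)
        rows.append(
            {
                "lesion_id": proc.lesion_id,
                "time_efficient_crossing": ep.time_efficient_crossing,
                "final_procedural_success": ep.final_procedural_success,
                "any_non_aw": ep.any_non_aw,
                "crossed_any_time": proc.gw_crossing_time_min is not None,
                "used_aw": prof["AW"],
                "used_adr": prof["ADR"],
                "used_rw": prof["RW"],
                "used_rdr": prof["RDR"],
                "retrograde": prof["retrograde"],
                "dart": prof["dart"],
                "n_strategies": prof["n_strategies"],
            }
        )
    return pd.DataFrame(rows)


def aggregate_endpoints(
    cohort: Iterable[ProcedureRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Cohort prevalence of each endpoint and strategy.

    Returns one row per indicator with columns ``count``, ``n`` and
    ``pct`` (= 100*count/n, rounded to one decimal as reported in
    clinical tables; the unrounded value is in ``pct_raw``).
    """
    table = endpoint_table(cohort)
    n = len(table)
    if n == 0:
        raise ValueError("empty cohort")
    indicators = [
        "time_efficient_crossing",
        "final_procedural_success",
        "any_non_aw",
        "crossed_any_time",
        "used_aw",
        "used_adr",
        "used_rw",
        "used_rdr",
        "retrograde",
        "dart",
    ]
    rows = []
    for name in indicators:
        count = int(table[name].sum())
        pct = 100.0 * count / n
        rows.append(
            {
                "indicator": name,
                "count": count,
                "n": n,
                "pct": round(pct, 1),
                "pct_raw": pct,
            }
        )
    return pd.DataFrame(rows).set_index("indicator")
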