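"""CSV input/output, validation, configuration and the analysis pipeline.

Interchange format is plain CSV (RFC-4180, UTF-8, ``.`` decimal):
one lesion-feature table and one procedure table, joinable 1:1 on
``lesion_id``.  Booleans are encoded 0/1, lengths are millimetres,
angles degrees, times minutes.  Report CSVs carry a single provenance
header line starting with ``#``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics
from .endpoints import ProcedureRecord, endpoint_table, aggregate_endpoints
from .scores import ARC_CATEGORIES, score_table
from .synthetic import ENDPOINT_DIRECTIONS, SyntheticCohort

log = logging.getLogger("ctoscores")

__all__ = [
    "LESION_COLUMNS",
    "PROCEDURE_COLUMNS",
    "CohortBundle",
    "AnalysisConfig",
    "AnalysisReport",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "procedures_from_frame",
    "kappa_report",
    "run_pipeline",
    "write_report",
    "read_report_csv",
    "parse_config",
]

SCHEMA_VERSION = "1"

LESION_FLAG_COLUMNS = [
    "blunt_cap_proximal",
    "blunt_cap_entry_or_exit",
    "proximal_side_branch",
    "any_calcification",
    "calc_area_frac_ge_50",
    "calc_area_frac_100",
    "multiple_occlusions",
    "diseased_distal_landing_zone",
    "angio_blunt_stump",
    "angio_any_calcification",
    "duration_gt_12mo_or_unknown",
    "reattempt",
    "prior_cabg_to_cto_vessel",
]

LESION_COLUMNS = [
    "lesion_id",
    "blunt_cap_proximal",
    "blunt_cap_entry_or_exit",
    "proximal_side_branch",
    "occlusion_length_mm",
    "max_bend_deg",
    "any_calcification",
    "calc_arc_max_deg",
    "calc_area_frac_ge_50",
    "calc_area_frac_100",
    "multiple_occlusions",
    "diseased_distal_landing_zone",
    "angio_blunt_stump",
    "angio_any_calcification",
    "angio_max_bend_deg",
    "angio_occlusion_length_mm",
    "duration_gt_12mo_or_unknown",
    "reattempt",
    "prior_cabg_to_cto_vessel",
]

PROCEDURE_COLUMNS = [
    "lesion_id",
    "gw_crossing_time_min",
    "used_aw",
    "used_adr",
    "used_rw",
    "used_rdr",
    "final_strategy",
    "residual_stenosis_pct",
    "timi_flow",
    "switch_time_min",
]


class CohortValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(self.errors)
        )


@dataclass
class CohortBundle:
    """Validated lesion + procedure tables with provenance metadata."""

    lesions: pd.DataFrame
    procedures: pd.DataFrame | None = None
    second_reader: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> list[str]:
    errors = []
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing:
        errors.append(f"{what}: missing column(s) {missing}")
    if unknown:
        errors.append(f"{what}: unknown column(s) {unknown}")
    return errors


def _flag_errors(df, cols, what):
    errors = []
    for col in cols:
        if col not in df.columns:
            continue
        bad = df.index[~df[col].isin([0, 1])].tolist()
        if bad:
            errors.append(f"{what}: column {col} not 0/1 at row(s) {bad}")
    return errors


def validate_lesions(df: pd.DataFrame) -> list[str]:
    errors = _check_columns(df, LESION_COLUMNS, "lesions")
    if errors:
        return errors
    errors += _flag_errors(df, LESION_FLAG_COLUMNS, "lesions")
    bad = df.index[~df["calc_arc_max_deg"].isin(ARC_CATEGORIES)].tolist()
    if bad:
        errors.append(
            f"lesions: calc_arc_max_deg outside {ARC_CATEGORIES} at row(s) {bad}"
        )
    for col, lo, hi in (
        ("occlusion_length_mm", 0, np.inf),
        ("max_bend_deg", 0, 180),
        ("angio_occlusion_length_mm", 0, np.inf),
        ("angio_max_bend_deg", 0, 180),
    ):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~(v.between(lo, hi))].tolist()
        if bad:
            errors.append(f"lesions: {col} outside [{lo}, {hi}] at row(s) {bad}")
    if not errors:
        incons = df.index[
            (df["calc_area_frac_100"] == 1)
            & ((df["calc_arc_max_deg"] != "360") | (df["calc_area_frac_ge_50"] != 1))
        ].tolist()
        if incons:
            errors.append(
                "lesions: calc_area_frac_100 without 360-degree arc and >=50% "
                f"area at row(s) {incons}"
            )
    if df["lesion_id"].duplicated().any():
        errors.append("lesions: duplicated lesion_id")
    return errors


def validate_procedures(df: pd.DataFrame) -> list[str]:
    errors = _check_columns(df, PROCEDURE_COLUMNS, "procedures")
    if errors:
        return errors
    errors += _flag_errors(
        df, ["used_aw", "used_adr", "used_rw", "used_rdr"], "procedures"
    )
    timi = pd.to_numeric(df["timi_flow"], errors="coerce")
    bad = df.index[~timi.isin([0, 1, 2, 3])].tolist()
    if bad:
        errors.append(f"procedures: timi_flow not in 0-3 at row(s) {bad}")
    bad = df.index[
        ~df["final_strategy"].isin(["AW", "ADR", "RW", "RDR", "none"])
    ].tolist()
    if bad:
        errors.append(f"procedures: unknown final_strategy at row(s) {bad}")
    t = pd.to_numeric(df["gw_crossing_time_min"], errors="coerce")
    crossed = t.notna()
    bad = df.index[crossed & (df["final_strategy"] == "none")].tolist()
    if bad:
        errors.append(
            f"procedures: crossing time without final strategy at row(s) {bad}"
        )
    bad = df.index[~crossed & (df["final_strategy"] != "none")].tolist()
    if bad:
        errors.append(
            f"procedures: final strategy without crossing time at row(s) {bad}"
        )
    resid = pd.to_numeric(df["residual_stenosis_pct"], errors="coerce")
    bad = df.index[resid.notna() & ~resid.between(0, 100)].tolist()
    if bad:
        errors.append(
            f"procedures: residual_stenosis_pct outside [0, 100] at row(s) {bad}"
        )
    return errors


def procedures_from_frame(df: pd.DataFrame) -> list[ProcedureRecord]:
    """Typed :class:`ProcedureRecord` objects from a procedure table."""

    def opt(x):
        return None if pd.isna(x) else float(x)

    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProcedureRecord(
                lesion_id=str(row.lesion_id),
                gw_crossing_time_min=opt(row.gw_crossing_time_min),
                used_aw=bool(row.used_aw),
                used_adr=bool(row.used_adr),
                used_rw=bool(row.used_rw),
                used_rdr=bool(row.used_rdr),
                final_strategy=str(row.final_strategy),
                residual_stenosis_pct=opt(row.residual_stenosis_pct),
                timi_flow=None if pd.isna(row.timi_flow) else int(row.timi_flow),
                switch_time_min=opt(row.switch_time_min),
            )
        )
    return records


def read_cohort(
    lesions_path,
    procedures_path=None,
    second_reader_path=None,
) -> CohortBundle:
    """Read and validate a cohort from CSV files.

    All row-level validation problems are collected and raised together
    as a :class:`CohortValidationError` naming the offending rows.
    """
    lesions = pd.read_csv(lesions_path, comment="#")
    errors = validate_lesions(lesions)
    procedures = None
    if procedures_path is not None:
        procedures = pd.read_csv(procedures_path, comment="#")
        errors += validate_procedures(procedures)
        if not errors:
            l_ids = set(lesions["lesion_id"].astype(str))
            p_ids = set(procedures["lesion_id"].astype(str))
            if l_ids != p_ids:
                errors.append(
                    "lesion/procedure tables do not join 1:1 on lesion_id "
                    f"({len(l_ids - p_ids)} lesion-only, "
                    f"{len(p_ids - l_ids)} procedure-only)"
                )
    second = None
    if second_reader_path is not None:
        second = pd.read_csv(second_reader_path, comment="#")
        errors += validate_lesions(second)
    if errors:
        raise CohortValidationError(errors)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "source": str(lesions_path),
        "n_lesions": len(lesions),
    }
    log.info("read cohort: %d lesions", len(lesions))
    return CohortBundle(lesions, procedures, second, meta)


def write_cohort(cohort: SyntheticCohort | CohortBundle, outdir) -> dict[str, Path]:
    """Write a cohort's tables to ``outdir`` as CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    lesions = cohort.lesions
    paths["lesions"] = outdir / "lesions.csv"
    lesions.to_csv(paths["lesions"], index=False)
    if cohort.procedures is not None:
        paths["procedures"] = outdir / "procedures.csv"
        cohort.procedures.to_csv(paths["procedures"], index=False)
    if isinstance(cohort, SyntheticCohort):
        truth = pd.DataFrame(
            {"lesion_id": lesions["lesion_id"], "difficulty": cohort.difficulty}
        )
        paths["truth"] = outdir / "truth.csv"
        truth.to_csv(paths["truth"], index=False)
    return paths


# -- interobserver agreement ------------------------------------------------

#: categorical lesion parameters entering the kappa summary
KAPPA_PARAMETERS = LESION_FLAG_COLUMNS + ["calc_arc_max_deg"]


def kappa_report(
    reader_a: pd.DataFrame,
    reader_b: pd.DataFrame,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Cohen's kappa per categorical parameter between two readers.

    Tables are joined on ``lesion_id`` (the second reader may cover a
    subset); kappa is computed for every shared categorical parameter,
    and summary rows give the mean and the IQR across parameters.
    """
    if parameters is None:
        parameters = [
            p
            for p in KAPPA_PARAMETERS
            if p in reader_a.columns and p in reader_b.columns
        ]
    merged = reader_a.merge(
        reader_b, on="lesion_id", suffixes=("_a", "_b"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("no overlapping lesion_id between readers")
    rows = []
    for p in parameters:
        k = diagnostics.cohens_kappa(
            merged[f"{p}_a"].to_numpy(), merged[f"{p}_b"].to_numpy()
        )
        rows.append({"parameter": p, "kappa": k, "n": len(merged)})
    table = pd.DataFrame(rows).set_index("parameter")
    kappas = table["kappa"].to_numpy()
    q1, q3 = np.percentile(kappas, [25, 75])
    summary = pd.DataFrame(
        [
            {"parameter": "mean", "kappa": float(np.mean(kappas)), "n": len(merged)},
            {"parameter": "iqr_low", "kappa": float(q1), "n": len(merged)},
            {"parameter": "iqr_high", "kappa": float(q3), "n": len(merged)},
        ]
    ).set_index("parameter")
    return pd.concat([table, summary])


# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Report and test conventions (plain key/value config file)."""

    continuous_test: str = "mannwhitney"
    mw_exact_max_n: int = 12
    pct_decimals: int = 1
    auc_decimals: int = 3
    grouping_endpoint: str = "time_efficient_crossing"


def parse_config(path) -> AnalysisConfig:
    """Parse ``key = value`` lines (``#`` comments) into a config."""
    values = {}
    fields = {f.name: f.type for f in dataclasses.fields(AnalysisConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
        if fields[key] == "int":
            values[key] = int(value)
        else:
            values[key] = value
    return AnalysisConfig(**values)


# -- pipeline ---------------------------------------------------------------

#: variable typing for the group-comparison tables
CT_COMPARISON_VARS = {
    "blunt_cap_proximal": "categorical",
    "proximal_side_branch": "categorical",
    "occlusion_length_mm": "continuous",
    "max_bend_deg": "continuous",
    "any_calcification": "categorical",
    "calc_area_frac_ge_50": "categorical",
    "calc_area_frac_100": "categorical",
    "multiple_occlusions": "categorical",
    "diseased_distal_landing_zone": "categorical",
}
ANGIO_COMPARISON_VARS = {
    "angio_blunt_stump": "categorical",
    "angio_any_calcification": "categorical",
    "angio_max_bend_deg": "continuous",
    "angio_occlusion_length_mm": "continuous",
}
CLINICAL_COMPARISON_VARS = {
    "duration_gt_12mo_or_unknown": "categorical",
    "reattempt": "categorical",
    "prior_cabg_to_cto_vessel": "categorical",
}


@dataclass
class AnalysisReport:
    """All tables of one full analysis run."""

    scores: pd.DataFrame
    endpoints: pd.DataFrame | None = None
    prevalence: pd.DataFrame | None = None
    group_comparisons: dict = field(default_factory=dict)
    accuracy: pd.DataFrame | None = None
    delong: pd.DataFrame | None = None
    kappa: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def run_pipeline(
    bundle: CohortBundle, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Score, derive endpoints, and run the full accuracy analysis.

    Deterministic for fixed inputs.  Without a procedure table the
    report degrades to scores only, with the endpoint-dependent tables
    left unset.
    """
    config = config or AnalysisConfig()
    scores = score_table(bundle.lesions)
    report = AnalysisReport(scores=scores, meta=dict(bundle.meta))
    report.meta["config"] = dataclasses.asdict(config)
    if bundle.second_reader is not None:
        report.kappa = kappa_report(bundle.lesions, bundle.second_reader)
    if bundle.procedures is None:
        log.warning("no procedure table: endpoint analyses unavailable")
        return report

    procs = bundle.procedures.set_index("lesion_id", drop=False)
    procs = procs.loc[bundle.lesions["lesion_id"]].reset_index(drop=True)
    eps = endpoint_table(procs)
    report.endpoints = eps
    report.prevalence = aggregate_endpoints(procs)

    merged = pd.concat(
        [bundle.lesions.reset_index(drop=True), eps.drop(columns="lesion_id")],
        axis=1,
    )
    group = config.grouping_endpoint
    if merged[group].nunique() == 2:
        for name, spec_vars in (
            ("clinical", CLINICAL_COMPARISON_VARS),
            ("angiographic", ANGIO_COMPARISON_VARS),
            ("ct", CT_COMPARISON_VARS),
        ):
            report.group_comparisons[name] = diagnostics.compare_groups(
                merged, group, spec_vars, config.continuous_test
            )
        score_vars = {
            c: "continuous" for c in scores.columns if c != "lesion_id"
        }
        report.group_comparisons["scores"] = diagnostics.compare_groups(
            pd.concat([scores.reset_index(drop=True), eps[[group]]], axis=1),
            group,
            score_vars,
            config.continuous_test,
        )
    else:
        log.warning("grouping endpoint %s is single-class; skipping "
                    "group comparisons", group)

    score_cols = scores.drop(columns="lesion_id", errors="ignore")
    report.accuracy = diagnostics.accuracy_table(
        score_cols, eps, ENDPOINT_DIRECTIONS
    )
    delong_parts = []
    for ep, direction in ENDPOINT_DIRECTIONS.items():
        y = eps[ep].to_numpy()
        if 0 < y.sum() < len(y):
            delong_parts.append(
                diagnostics.delong_pairwise(score_cols, y, direction, endpoint=ep)
            )
    if delong_parts:
        report.delong = pd.concat(delong_parts, ignore_index=True)
    log.info(
        "pipeline complete: %d lesions, %d accuracy rows",
        len(scores),
        len(report.accuracy),
    )
    return report


def _write_csv(df: pd.DataFrame, path: Path, meta: dict, index: bool):
    with open(path, "w") as fh:
        fh.write(
            f"# ctoscores report, schema {meta.get('schema_version', '?')}, "
            f"n={meta.get('n_lesions', '?')}\n"
        )
        df.to_csv(fh, index=index)


def write_report(report: AnalysisReport, outdir) -> dict[str, Path]:
    """Serialize every table of the report to CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name, df, index=False):
        if df is None:
            return
        paths[name] = outdir / f"{name}.csv"
        _write_csv(df, paths[name], report.meta, index)

    emit("scores", report.scores)
    emit("endpoints", report.endpoints)
    emit("prevalence", report.prevalence, index=True)
    for name, df in report.group_comparisons.items():
        emit(f"comparison_{name}", df, index=True)
    emit("accuracy", report.accuracy)
    emit("delong_pairwise", report.delong)
    emit("kappa", report.kappa, index=True)
    return paths


def read_report_csv(path, index_col=None) -> pd.DataFrame:
    """Read back a report CSV written by :func:`write_report`."""
    return pd.read_csv(path, comment="#", index_col=index_col)
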