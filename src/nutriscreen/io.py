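"""Cohort file readers/writers, run configuration, and the pipeline driver.

The cohort file is a UTF-8, comma-separated, header-mandatory CSV with one
patient per row: profile columns, canonical questionnaire tokens, 3-item
food amounts, and optional reference flags / paired intakes.  Reading is
validating: unknown columns warn, missing mandatory columns reject, bad
categorical tokens either flag the row (lenient) or abort (strict).
Writing then reading a cohort is lossless.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet import (
    DEFAULT_ENERGY_FACTOR,
    DEFAULT_PROTEIN_FACTOR,
    FoodCompositionTable,
    IntakeReport,
    estimate_intake,
    estimate_requirements,
    intake_gap,
)
from .errors import ValidationError
from .instruments import (
    AppetiteCategory,
    AppetiteResponse,
    DietTextureCategory,
    DietTextureResponse,
    DiseaseSelection,
    IntakeReductionCategory,
    IntakeReductionResponse,
    PatientProfile,
    ScoringConfig,
    ScreeningResponses,
    Sex,
    WeightChangeCategory,
    WeightChangeResponse,
    _canonical_hash,
    score_nrs2002,
    score_pgsgasf,
)
from .valstats import paired_agreement, diagnostic_report, table_from_pairs

logger = logging.getLogger("nutriscreen")

__all__ = [
    "MANDATORY_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CohortRecord",
    "RowError",
    "CohortFile",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "run_pipeline",
]

MANDATORY_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "weight_change",
    "weight_loss_timeframe_months",
    "intake_reduction",
    "diet_texture",
    "appetite",
    "diseases",
    "rice_g",
    "meat_g",
    "milk_ml",
)

OPTIONAL_COLUMNS = (
    "reference_at_risk",
    "index_at_risk",
    "ref_energy_kcal",
    "ref_protein_g",
    "app_energy_kcal",
    "app_protein_g",
)


@dataclass(frozen=True)
class CohortRecord:
    """One parsed cohort row; reference-arm fields are optional."""

    profile: PatientProfile
    responses: ScreeningResponses
    intake_report: IntakeReport
    reference_at_risk: Optional[bool] = None
    index_at_risk: Optional[bool] = None
    ref_energy_kcal: Optional[float] = None
    ref_protein_g: Optional[float] = None
    app_energy_kcal: Optional[float] = None
    app_protein_g: Optional[float] = None


@dataclass(frozen=True)
class RowError:
    row: int
    message: str


@dataclass
class CohortFile:
    """Raw frame plus the validated records and per-row error report."""

    frame: pd.DataFrame
    records: list[Optional[CohortRecord]]  # None where the row failed validation
    errors: list[RowError]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def valid_records(self) -> list[CohortRecord]:
        return [r for r in self.records if r is not None]


def _record_to_row(rec) -> dict:
    prof = rec.profile
    resp = rec.responses
    rep = rec.intake_report
    tf = resp.weight_change.timeframe_months
    row = {
        "patient_id": prof.name_id,
        "age_years": prof.age_years,
        "sex": prof.sex.value,
        "height_cm": prof.height_cm,
        "weight_kg": prof.weight_kg,
        "weight_change": resp.weight_change.category.value,
        "weight_loss_timeframe_months": "" if tf is None else tf,
        "intake_reduction": resp.intake_reduction.category.value,
        "diet_texture": resp.diet_texture.category.value,
        "appetite": resp.appetite.category.value,
        "diseases": ";".join(sorted(resp.diseases.diseases)),
        "rice_g": rep.rice_g,
        "meat_g": rep.meat_g,
        "milk_ml": rep.milk_ml,
    }
    for col in OPTIONAL_COLUMNS:
        val = getattr(rec, col, None)
        if val is None:
            row[col] = ""
        elif col in ("reference_at_risk", "index_at_risk"):
            row[col] = int(val)
        else:
            row[col] = val
    return row


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Serialize cohort/synthetic records to the canonical tabular schema."""
    return pd.DataFrame(
        [_record_to_row(r) for r in records],
        columns=list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS),
    )


def write_cohort(records: Sequence, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _parse_row(row: pd.Series) -> CohortRecord:
    profile = PatientProfile(
        name_id=str(row["patient_id"]),
        age_years=int(float(row["age_years"])),
        sex=Sex(row["sex"]),
        height_cm=float(row["height_cm"]),
        weight_kg=float(row["weight_kg"]),
    )
    tf_raw = str(row["weight_loss_timeframe_months"]).strip()
    timeframe = None if tf_raw in ("", "nan") else int(float(tf_raw))
    diseases_raw = str(row["diseases"]).strip()
    codes = tuple(c for c in diseases_raw.split(";") if c) if diseases_raw else ()
    responses = ScreeningResponses(
        weight_change=WeightChangeResponse(
            WeightChangeCategory(row["weight_change"]), timeframe
        ),
        intake_reduction=IntakeReductionResponse(
            IntakeReductionCategory(row["intake_reduction"])
        ),
        diet_texture=DietTextureResponse(DietTextureCategory(row["diet_texture"])),
        appetite=AppetiteResponse(AppetiteCategory(row["appetite"])),
        diseases=DiseaseSelection(codes),
    )
    report = IntakeReport(
        rice_g=float(row["rice_g"]),
        meat_g=float(row["meat_g"]),
        milk_ml=float(row["milk_ml"]),
    )

    def opt_bool(col: str) -> Optional[bool]:
        v = str(row.get(col, "")).strip()
        return None if v in ("", "nan") else bool(int(float(v)))

    def opt_float(col: str) -> Optional[float]:
        v = str(row.get(col, "")).strip()
        return None if v in ("", "nan") else float(v)

    return CohortRecord(
        profile=profile,
        responses=responses,
        intake_report=report,
        reference_at_risk=opt_bool("reference_at_risk"),
        index_at_risk=opt_bool("index_at_risk"),
        ref_energy_kcal=opt_float("ref_energy_kcal"),
        ref_protein_g=opt_float("ref_protein_g"),
        app_energy_kcal=opt_float("app_energy_kcal"),
        app_protein_g=opt_float("app_protein_g"),
    )


def read_cohort(path, strict: bool = False) -> CohortFile:
    """Read and validate a cohort CSV.

    Lenient mode (default) keeps every row in the frame and flags invalid
    ones in ``errors`` (their ``records`` slot is None); strict mode raises
    on the first invalid row.  Missing mandatory columns always reject.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort file missing mandatory columns: {missing}")
    unknown = [
        c
        for c in frame.columns
        if c not in MANDATORY_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", UserWarning)
    records: list[Optional[CohortRecord]] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_parse_row(row))
        except (ValidationError, ValueError, KeyError) as exc:
            if strict:
                raise ValidationError(f"row {i}: {exc}") from exc
            errors.append(RowError(row=i, message=str(exc)))
            records.append(None)
    return CohortFile(frame=frame, records=records, errors=errors)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort_path: str
    out_dir: str
    instrument: str = "nrs2002"
    scoring_config_path: Optional[str] = None
    composition_path: Optional[str] = None
    ci_method: str = "clopper-pearson"
    continuity_correction: bool = False
    energy_factor: float = DEFAULT_ENERGY_FACTOR
    protein_factor: float = DEFAULT_PROTEIN_FACTOR
    strict: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # analytic identity only: output location and verbosity excluded
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("log_level")
        return _canonical_hash(d)


def score_cohort(
    records: Sequence[CohortRecord],
    scoring_config: Optional[ScoringConfig] = None,
) -> pd.DataFrame:
    """Per-patient component scores, totals and risk flags, both instruments."""
    cfg = scoring_config or ScoringConfig.default()
    rows = []
    for rec in records:
        r = rec.responses
        nrs = score_nrs2002(
            rec.profile, r.weight_change, r.intake_reduction, r.diseases, cfg
        )
        pg = score_pgsgasf(
            r.weight_change, r.intake_reduction, r.diet_texture, r.appetite, cfg
        )
        rows.append(
            {
                "patient_id": rec.profile.name_id,
                "bmi": round(rec.profile.bmi, 1),
                "nrs2002_nutritional_status": nrs.components["nutritional_status"],
                "nrs2002_disease_severity": nrs.components["disease_severity"],
                "nrs2002_age": nrs.components["age"],
                "nrs2002_total": nrs.total,
                "nrs2002_at_risk": int(nrs.at_risk),
                "pgsgasf_weight_history": pg.components["weight_history"],
                "pgsgasf_food_intake": pg.components["food_intake"],
                "pgsgasf_symptoms": pg.components["symptoms"],
                "pgsgasf_total": pg.total,
                "pgsgasf_at_risk": int(pg.at_risk),
            }
        )
    return pd.DataFrame(rows)


def assess_cohort(
    records: Sequence[CohortRecord],
    composition: Optional[FoodCompositionTable] = None,
    energy_factor: float = DEFAULT_ENERGY_FACTOR,
    protein_factor: float = DEFAULT_PROTEIN_FACTOR,
) -> pd.DataFrame:
    """Per-patient intake estimates, requirements and gaps."""
    table = composition or FoodCompositionTable.default()
    rows = []
    for rec in records:
        est = estimate_intake(rec.intake_report, table)
        req = estimate_requirements(rec.profile, energy_factor, protein_factor)
        gap = intake_gap(est, req)
        rows.append(
            {
                "patient_id": rec.profile.name_id,
                "energy_intake_kcal": round(est.energy_kcal, 1),
                "protein_intake_g": round(est.protein_g, 1),
                "energy_requirement_kcal": round(req.energy_kcal, 1),
                "protein_requirement_g": round(req.protein_g, 1),
                "energy_gap_kcal": round(gap.energy_kcal, 1),
                "protein_gap_g": round(gap.protein_g, 1),
                "table_version": est.table_version,
            }
        )
    return pd.DataFrame(rows)


def validate_cohort(
    records: Sequence[CohortRecord],
    instrument: str = "nrs2002",
    scoring_config: Optional[ScoringConfig] = None,
    ci_method: str = "clopper-pearson",
    continuity_correction: bool = False,
) -> dict:
    """Index-vs-reference validation report for one instrument.

    The index flag is recomputed from each record's questionnaire answers;
    reference flags must be present.  Paired intake agreement is included
    when both app and reference intakes are available.
    """
    cfg = scoring_config or ScoringConfig.default()
    usable = [r for r in records if r.reference_at_risk is not None]
    if not usable:
        raise ValidationError("no records carry a reference risk flag")
    index_flags, index_scores, ref_flags = [], [], []
    for rec in usable:
        r = rec.responses
        if instrument == "nrs2002":
            score = score_nrs2002(
                rec.profile, r.weight_change, r.intake_reduction, r.diseases, cfg
            )
        elif instrument == "pgsgasf":
            score = score_pgsgasf(
                r.weight_change, r.intake_reduction, r.diet_texture, r.appetite, cfg
            )
        else:
            raise ValidationError(f"unknown instrument {instrument!r}")
        index_flags.append(score.at_risk)
        index_scores.append(score.total)
        ref_flags.append(rec.reference_at_risk)
    tab = table_from_pairs(index_flags, ref_flags)
    report = diagnostic_report(
        tab,
        ci_method=ci_method,
        continuity_correction=continuity_correction,
        index_scores=index_scores,
        reference_scores=[int(f) for f in ref_flags],
    )
    out = {"instrument": instrument, "diagnostic": report.to_dict()}
    paired = [
        r
        for r in usable
        if r.ref_energy_kcal is not None and r.app_energy_kcal is not None
    ]
    if len(paired) >= 2:
        out["energy_agreement"] = paired_agreement(
            [r.app_energy_kcal for r in paired],
            [r.ref_energy_kcal for r in paired],
        ).to_dict()
        if all(
            r.ref_protein_g is not None and r.app_protein_g is not None
            for r in paired
        ):
            out["protein_agreement"] = paired_agreement(
                [r.app_protein_g for r in paired],
                [r.ref_protein_g for r in paired],
            ).to_dict()
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Score → assess → validate on one cohort file; write CSV + JSON outputs.

    Returns the cohort-level report dict (also written to
    ``<out_dir>/report.json``).  Outputs embed the package version and the
    run-config hash; no timestamps, so reruns are byte-identical.
    """
    logging.basicConfig(level=config.log_level)
    scoring = (
        ScoringConfig.from_yaml(config.scoring_config_path)
        if config.scoring_config_path
        else ScoringConfig.default()
    )
    composition = (
        FoodCompositionTable.from_yaml(config.composition_path)
        if config.composition_path
        else FoodCompositionTable.default()
    )
    cohort = read_cohort(config.cohort_path, strict=config.strict)
    records = cohort.valid_records
    if not records:
        raise ValidationError("cohort contains no valid records")
    logger.info(
        "pipeline: %d records (%d flagged) config_hash=%s",
        cohort.n_rows,
        len(cohort.errors),
        config.config_hash,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = score_cohort(records, scoring)
    assessments = assess_cohort(
        records, composition, config.energy_factor, config.protein_factor
    )
    per_patient = scores.merge(assessments, on="patient_id")
    per_patient.to_csv(out_dir / "patients.csv", index=False)
    report: dict = {
        "package_version": __version__,
        "run_config_hash": config.config_hash,
        "scoring_config_version": scoring.version,
        "scoring_config_hash": scoring.config_hash,
        "composition_version": composition.version,
        "composition_hash": composition.config_hash,
        "seed": config.seed,
        "n_rows": cohort.n_rows,
        "n_valid": len(records),
        "n_flagged": len(cohort.errors),
    }
    if any(r.reference_at_risk is not None for r in records):
        report["validation"] = validate_cohort(
            records,
            instrument=config.instrument,
            scoring_config=scoring,
            ci_method=config.ci_method,
            continuity_correction=config.continuity_correction,
        )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
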