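"""Deterministic scoring engines for nutritional-risk screening.

Two instruments are implemented as they are typically embedded in
self-administered screening apps for hospitalized oncology patients:

* **NRS-2002 (final screening only)** — three components: impaired
  nutritional status (0–3, the worst of weight-loss, BMI and
  intake-reduction subscores), disease severity (0–3, the worst selected
  disease), and age (1 point at or above 70 years).  Total 0–7; a total of
  3 or more flags nutritional risk.
* **Reduced PG-SGA short form** — weight history, food intake (reduction
  and diet texture, combined by the worst box entry) and appetite symptoms.
  A total of 4 or more flags nutritional risk.  The activities-and-function
  box of the full short form is deliberately not part of this instrument.

All point mappings, cutoffs and the disease catalogue are configuration
(:class:`ScoringConfig`), shipped with documented defaults and overridable
from YAML.  Scoring itself is pure and deterministic.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Sex",
    "WeightChangeCategory",
    "IntakeReductionCategory",
    "DietTextureCategory",
    "AppetiteCategory",
    "ClinicalRangeWarning",
    "PatientProfile",
    "WeightChangeResponse",
    "IntakeReductionResponse",
    "DietTextureResponse",
    "AppetiteResponse",
    "DiseaseSelection",
    "ScreeningResponses",
    "RiskScore",
    "ScoringConfig",
    "compute_bmi",
    "weight_loss_display_thresholds",
    "score_nrs2002",
    "score_pgsgasf",
]


class ClinicalRangeWarning(UserWarning):
    """Value is clinically implausible but not structurally invalid."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class WeightChangeCategory(str, Enum):
    """Self-reported weight change over the past three months."""

    STABLE_OR_GAIN = "stable_or_gain"
    LOSS_5_TO_15PCT = "loss_5_to_15pct"
    LOSS_OVER_15PCT = "loss_over_15pct"


class IntakeReductionCategory(str, Enum):
    """Recent reduction in food intake, as a fraction of usual intake."""

    UNCHANGED = "unchanged"
    REDUCTION_25_50 = "reduction_25_50"
    REDUCTION_50_75 = "reduction_50_75"
    REDUCTION_75_100 = "reduction_75_100"


class DietTextureCategory(str, Enum):
    NORMAL = "normal"
    SOFT = "soft"
    LIQUID = "liquid"
    FASTING = "fasting"


class AppetiteCategory(str, Enum):
    NEVER = "never"
    OCCASIONALLY = "occasionally"
    FREQUENTLY = "frequently"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientProfile:
    """Demographics and anthropometrics entered at admission.

    Parameters
    ----------
    name_id:
        Opaque patient identifier.
    age_years:
        Age in whole years; must be positive.  Ages outside the usual
        adult eligibility band (18–80) are scored but trigger a
        :class:`ClinicalRangeWarning`.
    sex:
        ``Sex.MALE`` or ``Sex.FEMALE``.
    height_cm, weight_kg:
        Height in centimetres and weight in kilograms, both strictly
        positive.  A derived BMI outside (10, 60) kg/m² warns.
    """

    name_id: str
    age_years: int
    sex: Sex
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValidationError(f"age must be positive, got {self.age_years}")
        if not (self.height_cm > 0):
            raise ValidationError(f"height must be positive, got {self.height_cm}")
        if not (self.weight_kg > 0):
            raise ValidationError(f"weight must be positive, got {self.weight_kg}")
        if not (18 <= self.age_years <= 80):
            warnings.warn(
                f"age {self.age_years} outside usual adult eligibility (18-80); "
                "scored anyway",
                ClinicalRangeWarning,
                stacklevel=2,
            )
        bmi = self.weight_kg / (self.height_cm / 100.0) ** 2
        if not (10.0 < bmi < 60.0):
            warnings.warn(
                f"BMI {bmi:.1f} kg/m^2 outside plausible band (10, 60); check "
                "height/weight entry",
                ClinicalRangeWarning,
                stacklevel=2,
            )

    @property
    def bmi(self) -> float:
        return compute_bmi(self)


@dataclass(frozen=True)
class WeightChangeResponse:
    """Weight-change answer; timeframe accompanies any reported loss."""

    category: WeightChangeCategory
    timeframe_months: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category is WeightChangeCategory.STABLE_OR_GAIN:
            if self.timeframe_months is not None:
                raise ValidationError(
                    "timeframe_months must be absent when weight is stable"
                )
        else:
            if self.timeframe_months not in (1, 2, 3):
                raise ValidationError(
                    "weight loss reported but timeframe_months not in {1, 2, 3}: "
                    f"{self.timeframe_months!r}"
                )


@dataclass(frozen=True)
class IntakeReductionResponse:
    category: IntakeReductionCategory


@dataclass(frozen=True)
class DietTextureResponse:
    category: DietTextureCategory


@dataclass(frozen=True)
class AppetiteResponse:
    category: AppetiteCategory


@dataclass(frozen=True)
class DiseaseSelection:
    """Multiple-choice disease selection; codes must exist in the catalogue."""

    diseases: frozenset[str] = frozenset()

    def __init__(self, diseases=()):  # accept any iterable of codes
        object.__setattr__(self, "diseases", frozenset(diseases))

    def severity(self, catalogue: Mapping[str, int]) -> int:
        """Effective disease-severity score: worst selected disease, 0 if none."""
        unknown = self.diseases - set(catalogue)
        if unknown:
            raise ValidationError(
                f"disease codes not in catalogue: {sorted(unknown)}"
            )
        if not self.diseases:
            return 0
        return max(catalogue[code] for code in self.diseases)


@dataclass(frozen=True)
class ScreeningResponses:
    """Complete questionnaire answer set for one patient (both instruments)."""

    weight_change: WeightChangeResponse
    intake_reduction: IntakeReductionResponse
    diet_texture: DietTextureResponse
    appetite: AppetiteResponse
    diseases: DiseaseSelection = DiseaseSelection()


@dataclass(frozen=True)
class RiskScore:
    """Per-instrument component scores, total, and the binary risk flag."""

    instrument: str
    components: Mapping[str, int]
    total: int
    at_risk: bool
    cutoff: int

    def __post_init__(self) -> None:
        if self.total != sum(self.components.values()):
            raise ValidationError("total must equal the sum of components")
        if self.at_risk != (self.total >= self.cutoff):
            raise ValidationError("at_risk flag inconsistent with total/cutoff")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_REQUIRED_TOP_KEYS = ("version", "nrs2002", "pgsgasf", "disease_catalogue")


def _canonical_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ScoringConfig:
    """Instrument point mappings, cutoffs and disease catalogue.

    Use :meth:`default` for the shipped configuration or :meth:`from_yaml`
    to load an override.  The configuration hash is logged with every
    scoring run so results are attributable to an exact rule set.
    """

    version: str
    nrs2002: Mapping
    pgsgasf: Mapping
    disease_catalogue: Mapping[str, int]

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScoringConfig":
        missing = [k for k in _REQUIRED_TOP_KEYS if k not in raw]
        if missing:
            raise ConfigurationError(f"scoring config missing keys: {missing}")
        catalogue = dict(raw["disease_catalogue"])
        for code, sev in catalogue.items():
            if sev not in (0, 1, 2, 3):
                raise ConfigurationError(
                    f"disease severity for {code!r} must be 0-3, got {sev!r}"
                )
        for instr, needed in (
            ("nrs2002", ("cutoff", "age_threshold_years", "weight_loss_points",
                         "bmi_points", "intake_points")),
            ("pgsgasf", ("cutoff", "weight_points", "one_month_bonus",
                         "intake_points", "texture_points", "appetite_points")),
        ):
            for key in needed:
                if key not in raw[instr]:
                    raise ConfigurationError(f"{instr} config missing {key!r}")
        return cls(
            version=str(raw["version"]),
            nrs2002=dict(raw["nrs2002"]),
            pgsgasf=dict(raw["pgsgasf"]),
            disease_catalogue=catalogue,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoringConfig":
        global _DEFAULT_CONFIG
        if _DEFAULT_CONFIG is None:
            text = (
                resources.files("nutriscreen.data") / "default_scoring.yaml"
            ).read_text(encoding="utf-8")
            _DEFAULT_CONFIG = cls.from_dict(yaml.safe_load(text))
        return _DEFAULT_CONFIG

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "nrs2002": self.nrs2002,
            "pgsgasf": self.pgsgasf,
            "disease_catalogue": dict(self.disease_catalogue),
        }

    @property
    def config_hash(self) -> str:
        return _canonical_hash(self.to_dict())


_DEFAULT_CONFIG: Optional[ScoringConfig] = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_bmi(profile: PatientProfile) -> float:
    """Body mass index, weight(kg) / height(m)², at full precision.

    Display convention is one decimal place; rounding is left to callers.
    """
    if not (profile.height_cm > 0) or not (profile.weight_kg > 0):
        raise ValidationError("height and weight must be positive")
    return profile.weight_kg / (profile.height_cm / 100.0) ** 2


def weight_loss_display_thresholds(profile: PatientProfile) -> tuple[float, float]:
    """Kilogram equivalents of 5% and 15% of current weight, 1 d.p.

    Used to render the weight-change options with patient-specific numbers
    ("weight loss of X–Y kg") instead of bare percentages.
    """
    if not (profile.weight_kg > 0):
        raise ValidationError("weight must be positive")
    return (
        round(0.05 * profile.weight_kg, 1),
        round(0.15 * profile.weight_kg, 1),
    )


def _nrs_weight_loss_points(wt: WeightChangeResponse, mapping: Mapping) -> int:
    if wt.category is WeightChangeCategory.STABLE_OR_GAIN:
        return int(mapping[WeightChangeCategory.STABLE_OR_GAIN.value])
    by_timeframe = mapping[wt.category.value]
    return int(by_timeframe[wt.timeframe_months])


def _nrs_bmi_points(bmi: float, mapping: Mapping) -> int:
    if bmi < float(mapping["severe_below"]):
        return 3
    if bmi < float(mapping["moderate_below"]):
        return 2
    return 0


def score_nrs2002(
    profile: PatientProfile,
    weight_change: WeightChangeResponse,
    intake: IntakeReductionResponse,
    diseases: DiseaseSelection = DiseaseSelection(),
    config: Optional[ScoringConfig] = None,
) -> RiskScore:
    """Score the NRS-2002 final screening.

    Impaired nutritional status is the worst of the weight-loss, BMI and
    intake-reduction subscores ("worst category" rule of the published
    worksheet); disease severity is the worst selected catalogue entry;
    one age point accrues at the configured threshold (70 years).
    """
    cfg = (config or ScoringConfig.default()).nrs2002
    catalogue = (config or ScoringConfig.default()).disease_catalogue
    bmi = compute_bmi(profile)
    nutritional_status = max(
        _nrs_weight_loss_points(weight_change, cfg["weight_loss_points"]),
        _nrs_bmi_points(bmi, cfg["bmi_points"]),
        int(cfg["intake_points"][intake.category.value]),
    )
    disease_severity = diseases.severity(catalogue)
    age_points = 1 if profile.age_years >= int(cfg["age_threshold_years"]) else 0
    components = {
        "nutritional_status": nutritional_status,
        "disease_severity": disease_severity,
        "age": age_points,
    }
    total = sum(components.values())
    cutoff = int(cfg["cutoff"])
    return RiskScore(
        instrument="nrs2002",
        components=components,
        total=total,
        at_risk=total >= cutoff,
        cutoff=cutoff,
    )


def score_pgsgasf(
    weight_change: WeightChangeResponse,
    intake: IntakeReductionResponse,
    texture: DietTextureResponse,
    appetite: AppetiteResponse,
    config: Optional[ScoringConfig] = None,
) -> RiskScore:
    """Score the reduced PG-SGA short form (weight, food intake, appetite).

    The food-intake box combines the intake-reduction and diet-texture
    answers by their worst (highest) point value, mirroring the published
    "greatest box score" convention; weight history earns an extra point
    when the loss occurred within one month.
    """
    cfg = (config or ScoringConfig.default()).pgsgasf
    weight_points = int(cfg["weight_points"][weight_change.category.value])
    if (
        weight_change.category is not WeightChangeCategory.STABLE_OR_GAIN
        and weight_change.timeframe_months == 1
    ):
        weight_points += int(cfg["one_month_bonus"])
    food_intake = max(
        int(cfg["intake_points"][intake.category.value]),
        int(cfg["texture_points"][texture.category.value]),
    )
    symptom_points = int(cfg["appetite_points"][appetite.category.value])
    components = {
        "weight_history": weight_points,
        "food_intake": food_intake,
        "symptoms": symptom_points,
    }
    total = sum(components.values())
    cutoff = int(cfg["cutoff"])
    return RiskScore(
        instrument="pgsgasf",
        components=components,
        total=total,
        at_risk=total >= cutoff,
        cutoff=cutoff,
    )
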