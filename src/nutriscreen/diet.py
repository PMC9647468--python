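"""Shortened 3-item dietary assessment: energy/protein intake, requirements, gap.

The 3-item recall asks only for daily amounts of rice (g), meat (g) and milk
(mL) — the dominant energy and protein sources in the target population —
and converts them to daily energy (kcal) and protein (g) through a linear
calibration against a food-composition table:

    energy  = b0_E + sum_item  adj_item * amount_item/100 * energy_density_item
    protein = b0_P + sum_item  adj_item * amount_item/100 * protein_density_item

Requirements follow weight-proportional guideline factors (kcal/kg/day and
g protein/kg/day); the reported gap is intake minus requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import isfinite
from typing import Mapping, Optional

import yaml

from .errors import ConfigurationError, ValidationError
from .instruments import ClinicalRangeWarning, PatientProfile, _canonical_hash

__all__ = [
    "FoodItem",
    "FoodCompositionTable",
    "IntakeReport",
    "IntakeEstimate",
    "RequirementEstimate",
    "IntakeGap",
    "estimate_intake",
    "estimate_requirements",
    "intake_gap",
    "DEFAULT_ENERGY_FACTOR",
    "DEFAULT_PROTEIN_FACTOR",
]

#: Guideline requirement factors for hospitalized adult patients; a mid-range
#: default, overridable per call and per patient.
DEFAULT_ENERGY_FACTOR = 25.0  # kcal/kg/day
DEFAULT_PROTEIN_FACTOR = 1.2  # g/kg/day

_ITEMS = ("rice", "meat", "milk")
_PLAUSIBILITY_BOUND = 2000.0  # g or mL per day, per item


@dataclass(frozen=True)
class FoodItem:
    """Energy/protein density per 100 g (or 100 mL) plus a calibration factor."""

    energy_kcal_per_100: float
    protein_g_per_100: float
    adjustment: float = 1.0

    def __post_init__(self) -> None:
        if self.energy_kcal_per_100 < 0 or self.protein_g_per_100 < 0:
            raise ConfigurationError("densities must be non-negative")
        if not (self.adjustment > 0):
            raise ConfigurationError("adjustment must be positive")


@dataclass(frozen=True)
class FoodCompositionTable:
    """Versioned calibration table for the 3-item recall."""

    version: str
    items: Mapping[str, FoodItem]
    intercept_energy_kcal: float = 0.0
    intercept_protein_g: float = 0.0

    def __post_init__(self) -> None:
        if not self.version:
            raise ConfigurationError("composition table must carry a version string")
        if self.intercept_energy_kcal < 0 or self.intercept_protein_g < 0:
            raise ConfigurationError("intercepts must be non-negative")

    def item(self, name: str) -> FoodItem:
        try:
            return self.items[name]
        except KeyError:
            raise ConfigurationError(
                f"composition table {self.version!r} lacks item {name!r}"
            ) from None

    @classmethod
    def from_dict(cls, raw: Mapping) -> "FoodCompositionTable":
        if "version" not in raw or "items" not in raw:
            raise ConfigurationError("composition table needs 'version' and 'items'")
        items = {
            name: FoodItem(
                energy_kcal_per_100=float(spec["energy_kcal_per_100"]),
                protein_g_per_100=float(spec["protein_g_per_100"]),
                adjustment=float(spec.get("adjustment", 1.0)),
            )
            for name, spec in raw["items"].items()
        }
        return cls(
            version=str(raw["version"]),
            items=items,
            intercept_energy_kcal=float(raw.get("intercept_energy_kcal", 0.0)),
            intercept_protein_g=float(raw.get("intercept_protein_g", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "FoodCompositionTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FoodCompositionTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            text = (
                resources.files("nutriscreen.data") / "default_composition.yaml"
            ).read_text(encoding="utf-8")
            _DEFAULT_TABLE = cls.from_dict(yaml.safe_load(text))
        return _DEFAULT_TABLE

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "intercept_energy_kcal": self.intercept_energy_kcal,
            "intercept_protein_g": self.intercept_protein_g,
            "items": {
                name: {
                    "energy_kcal_per_100": it.energy_kcal_per_100,
                    "protein_g_per_100": it.protein_g_per_100,
                    "adjustment": it.adjustment,
                }
                for name, it in self.items.items()
            },
        }

    @property
    def config_hash(self) -> str:
        return _canonical_hash(self.to_dict())


_DEFAULT_TABLE: Optional[FoodCompositionTable] = None


@dataclass(frozen=True)
class IntakeReport:
    """Self-reported daily amounts: rice (g), meat (g), milk (mL)."""

    rice_g: float
    meat_g: float
    milk_ml: float

    def __post_init__(self) -> None:
        for name, amount in self.amounts.items():
            if not isfinite(amount) or amount < 0:
                raise ValidationError(
                    f"{name} amount must be finite and >= 0, got {amount!r}"
                )
            if amount > _PLAUSIBILITY_BOUND:
                warnings.warn(
                    f"{name} amount {amount:g} exceeds plausibility bound "
                    f"{_PLAUSIBILITY_BOUND:g}/day",
                    ClinicalRangeWarning,
                    stacklevel=2,
                )

    @property
    def amounts(self) -> dict[str, float]:
        return {"rice": self.rice_g, "meat": self.meat_g, "milk": self.milk_ml}


@dataclass(frozen=True)
class IntakeEstimate:
    energy_kcal: float
    protein_g: float
    table_version: str


@dataclass(frozen=True)
class RequirementEstimate:
    energy_kcal: float
    protein_g: float
    energy_factor: float
    protein_factor: float


@dataclass(frozen=True)
class IntakeGap:
    """Intake minus requirement, componentwise (negative = deficit)."""

    energy_kcal: float
    protein_g: float


def estimate_intake(
    report: IntakeReport, table: Optional[FoodCompositionTable] = None
) -> IntakeEstimate:
    """Convert a 3-item report to estimated daily energy and protein."""
    tab = table or FoodCompositionTable.default()
    energy = tab.intercept_energy_kcal
    protein = tab.intercept_protein_g
    for name in _ITEMS:
        item = tab.item(name)
        portion = report.amounts[name] / 100.0
        energy += item.adjustment * portion * item.energy_kcal_per_100
        protein += item.adjustment * portion * item.protein_g_per_100
    return IntakeEstimate(
        energy_kcal=energy, protein_g=protein, table_version=tab.version
    )


def estimate_requirements(
    profile: PatientProfile,
    energy_factor: float = DEFAULT_ENERGY_FACTOR,
    protein_factor: float = DEFAULT_PROTEIN_FACTOR,
) -> RequirementEstimate:
    """Weight-proportional energy/protein requirements from guideline factors."""
    if not (profile.weight_kg > 0):
        raise ValidationError("weight must be positive")
    if not (energy_factor > 0 and protein_factor > 0):
        raise ValidationError("requirement factors must be positive")
    return RequirementEstimate(
        energy_kcal=energy_factor * profile.weight_kg,
        protein_g=protein_factor * profile.weight_kg,
        energy_factor=energy_factor,
        protein_factor=protein_factor,
    )


def intake_gap(estimate: IntakeEstimate, requirement: RequirementEstimate) -> IntakeGap:
    """Gap between estimated intake and requirement (intake − requirement)."""
    return IntakeGap(
        energy_kcal=estimate.energy_kcal - requirement.energy_kcal,
        protein_g=estimate.protein_g - requirement.protein_g,
    )
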