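"""Synthetic validation-cohort generator.

Emulates the statistical structure a paired diagnostic-accuracy study of a
self-administered screening app assumes, so the whole pipeline
(scoring → pairing → validation statistics) is testable end to end without
patient data:

* reference risk flags ~ Bernoulli(prevalence); index (app) flags drawn
  conditionally on the reference with configured sensitivity/specificity
  (non-differential misclassification);
* demographics: age log-normal matched to a median/IQR (hospital cohorts
  skew old), weight and BMI normal with configured moments, height derived
  from weight and BMI so the triplet stays consistent, sex Bernoulli;
* questionnaire responses sampled uniformly from the set of answer
  combinations that the scoring engine maps to the record's index flag —
  round-trip consistency with :mod:`nutriscreen.instruments` holds by
  construction;
* paired energy intakes from a bivariate normal (app vs reference) with
  configured means, SDs and correlation; paired protein intakes log-normal
  matched to median/IQR with a Gaussian-copula correlation; 3-item food
  amounts back-solved from the app values (projected onto the nearest
  representable diet when the drawn energy/protein ratio falls outside
  what rice/meat/milk can realize, so the stored app values remain the
  exactly calibrated ones).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .diet import FoodCompositionTable, IntakeReport
from .errors import ValidationError
from .instruments import (
    AppetiteCategory,
    ClinicalRangeWarning,
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
    score_nrs2002,
    score_pgsgasf,
)
from .valstats import cohens_kappa, diagnostic_metrics, table_from_pairs

__all__ = [
    "CohortConfig",
    "SyntheticRecord",
    "generate_cohort",
    "responses_for_flag",
    "recovery_experiment",
    "RecoverySummary",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def _lognormal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to a printed median and IQR.

    sigma averages the upper- and lower-quartile estimates, which differ
    only through sampling noise in the matched summary.
    """
    q1, q3 = iqr
    if not (0 < q1 < median < q3):
        raise ValidationError(f"inconsistent median/IQR: {median}, {iqr}")
    mu = math.log(median)
    sigma = 0.5 * (math.log(q3 / median) + math.log(median / q1)) / _Z75
    return mu, sigma


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one validation arm.

    Defaults describe a 244-patient hospital oncology cohort screened with
    the NRS-2002 arm's operating characteristics; :meth:`pgsgasf_defaults`
    switches to the PG-SGA-SF arm.  Intake parameters are shared between
    arms (one dietary comparison per cohort).
    """

    n: int = 244
    instrument: str = "nrs2002"
    prevalence: float = 0.172
    sensitivity: float = 0.810
    specificity: float = 0.767
    # demographics
    age_median: float = 59.0
    age_iqr: tuple[float, float] = (51.0, 68.0)
    weight_mean: float = 58.6
    weight_sd: float = 8.9
    bmi_mean: float = 22.2
    bmi_sd: float = 2.9
    male_fraction: float = 0.639
    # paired intake model
    energy_ref_mean: float = 1434.1
    energy_ref_sd: float = 528.8
    energy_app_mean: float = 1578.3
    energy_app_sd: float = 468.4
    energy_corr: float = 0.59
    protein_ref_median: float = 61.7
    protein_ref_iqr: tuple[float, float] = (43.0, 82.8)
    protein_app_median: float = 79.0
    protein_app_iqr: tuple[float, float] = (62.7, 95.3)
    protein_corr: float = 0.47
    energy_protein_corr: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("cohort size must be >= 0")
        for name in ("prevalence", "sensitivity", "specificity", "male_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("weight_sd", "bmi_sd", "energy_ref_sd", "energy_app_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.instrument not in ("nrs2002", "pgsgasf"):
            raise ValidationError(f"unknown instrument {self.instrument!r}")
        for name in ("energy_corr", "protein_corr", "energy_protein_corr"):
            if not (-1.0 < getattr(self, name) < 1.0):
                raise ValidationError(f"{name} must be in (-1, 1)")

    @classmethod
    def nrs2002_defaults(cls, **overrides) -> "CohortConfig":
        return cls(**overrides)

    @classmethod
    def pgsgasf_defaults(cls, **overrides) -> "CohortConfig":
        base = dict(
            instrument="pgsgasf",
            prevalence=0.238,
            sensitivity=0.845,
            specificity=0.645,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SyntheticRecord:
    """One simulated patient: profile, answers, flags and paired intakes."""

    profile: PatientProfile
    responses: ScreeningResponses
    reference_at_risk: bool
    index_at_risk: bool
    intake_report: IntakeReport
    app_energy_kcal: float
    app_protein_g: float
    ref_energy_kcal: float
    ref_protein_g: float


# ---------------------------------------------------------------------------
# Response-space enumeration
# ---------------------------------------------------------------------------

_WT_OPTIONS: tuple[tuple[WeightChangeCategory, Optional[int]], ...] = (
    (WeightChangeCategory.STABLE_OR_GAIN, None),
    (WeightChangeCategory.LOSS_5_TO_15PCT, 3),
    (WeightChangeCategory.LOSS_5_TO_15PCT, 2),
    (WeightChangeCategory.LOSS_5_TO_15PCT, 1),
    (WeightChangeCategory.LOSS_OVER_15PCT, 3),
    (WeightChangeCategory.LOSS_OVER_15PCT, 2),
    (WeightChangeCategory.LOSS_OVER_15PCT, 1),
)

# representative anthropometrics realizing each NRS BMI subscore (0/2/3)
_BMI_REPRESENTATIVE = {0: 23.0, 2: 19.5, 3: 17.0}

_SET_CACHE: dict = {}


def _codes_by_severity(config: ScoringConfig) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {0: [], 1: [], 2: [], 3: []}
    for code, sev in sorted(config.disease_catalogue.items()):
        out[int(sev)].append(code)
    return out


def _nrs_bmi_subscore(bmi: float, config: ScoringConfig) -> int:
    mapping = config.nrs2002["bmi_points"]
    if bmi < float(mapping["severe_below"]):
        return 3
    if bmi < float(mapping["moderate_below"]):
        return 2
    return 0


def _nrs_satisfying_sets(
    bmi_sub: int, age_sub: int, config: ScoringConfig
) -> dict[bool, list[tuple]]:
    """Answer combos (wt_idx, intake_idx, severity) per flag, given the
    profile-fixed BMI and age subscores."""
    key = ("nrs2002", config.config_hash, bmi_sub, age_sub)
    if key in _SET_CACHE:
        return _SET_CACHE[key]
    bmi = _BMI_REPRESENTATIVE[bmi_sub]
    age = 75 if age_sub else 40
    height = 165.0
    weight = bmi * (height / 100.0) ** 2
    profile = PatientProfile("enum", age, Sex.FEMALE, height, weight)
    codes = _codes_by_severity(config)
    sets: dict[bool, list[tuple]] = {True: [], False: []}
    for wi, (cat, tf) in enumerate(_WT_OPTIONS):
        wt = WeightChangeResponse(cat, tf)
        for ii, icat in enumerate(IntakeReductionCategory):
            intake = IntakeReductionResponse(icat)
            for sev in (0, 1, 2, 3):
                if sev > 0 and not codes[sev]:
                    continue
                selection = DiseaseSelection(codes[sev][:1] if sev else ())
                score = score_nrs2002(profile, wt, intake, selection, config)
                sets[score.at_risk].append((wi, ii, sev))
    _SET_CACHE[key] = sets
    return sets


def _pg_satisfying_sets(config: ScoringConfig) -> dict[bool, list[tuple]]:
    key = ("pgsgasf", config.config_hash)
    if key in _SET_CACHE:
        return _SET_CACHE[key]
    sets: dict[bool, list[tuple]] = {True: [], False: []}
    for wi, (cat, tf) in enumerate(_WT_OPTIONS):
        wt = WeightChangeResponse(cat, tf)
        for ii, icat in enumerate(IntakeReductionCategory):
            for ti, tcat in enumerate(DietTextureCategory):
                for ai, acat in enumerate(AppetiteCategory):
                    score = score_pgsgasf(
                        wt,
                        IntakeReductionResponse(icat),
                        DietTextureResponse(tcat),
                        AppetiteResponse(acat),
                        config,
                    )
                    sets[score.at_risk].append((wi, ii, ti, ai))
    _SET_CACHE[key] = sets
    return sets


_INTAKE_CATS = tuple(IntakeReductionCategory)
_TEXTURE_CATS = tuple(DietTextureCategory)
_APPETITE_CATS = tuple(AppetiteCategory)


def responses_for_flag(
    flag: bool,
    profile: PatientProfile,
    rng: np.random.Generator,
    instrument: str = "nrs2002",
    config: Optional[ScoringConfig] = None,
) -> ScreeningResponses:
    """Sample a questionnaire answer set that the scoring engine maps to
    ``flag`` for this patient, uniformly over the satisfying combinations.

    Answer fields the chosen instrument does not score are sampled
    uniformly and independently.
    """
    cfg = config or ScoringConfig.default()
    codes = _codes_by_severity(cfg)
    if instrument == "nrs2002":
        bmi_sub = _nrs_bmi_subscore(profile.bmi, cfg)
        age_sub = 1 if profile.age_years >= int(cfg.nrs2002["age_threshold_years"]) else 0
        combos = _nrs_satisfying_sets(bmi_sub, age_sub, cfg)[bool(flag)]
        if not combos:
            raise ValidationError(
                f"no answer combination yields flag={flag} for BMI subscore "
                f"{bmi_sub} and age subscore {age_sub}"
            )
        wi, ii, sev = combos[int(rng.integers(len(combos)))]
        texture = DietTextureResponse(
            _TEXTURE_CATS[int(rng.integers(len(_TEXTURE_CATS)))]
        )
        appetite = AppetiteResponse(
            _APPETITE_CATS[int(rng.integers(len(_APPETITE_CATS)))]
        )
    elif instrument == "pgsgasf":
        combos = _pg_satisfying_sets(cfg)[bool(flag)]
        wi, ii, ti, ai = combos[int(rng.integers(len(combos)))]
        texture = DietTextureResponse(_TEXTURE_CATS[ti])
        appetite = AppetiteResponse(_APPETITE_CATS[ai])
        sev = int(rng.integers(4))
        while sev > 0 and not codes[sev]:
            sev -= 1
    else:
        raise ValidationError(f"unknown instrument {instrument!r}")
    cat, tf = _WT_OPTIONS[wi]
    diseases = DiseaseSelection(
        (codes[sev][int(rng.integers(len(codes[sev])))],) if sev else ()
    )
    return ScreeningResponses(
        weight_change=WeightChangeResponse(cat, tf),
        intake_reduction=IntakeReductionResponse(_INTAKE_CATS[ii]),
        diet_texture=texture,
        appetite=appetite,
        diseases=diseases,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _truncated(rng, draw, ok, n: int) -> np.ndarray:
    x = draw(n)
    bad = ~ok(x)
    while bad.any():
        x[bad] = draw(int(bad.sum()))
        bad = ~ok(x)
    return x


def generate_cohort(
    config: CohortConfig,
    scoring_config: Optional[ScoringConfig] = None,
    composition: Optional[FoodCompositionTable] = None,
) -> list[SyntheticRecord]:
    """Generate a synthetic validation cohort under the configured conditions."""
    cfg = config
    scfg = scoring_config or ScoringConfig.default()
    table = composition or FoodCompositionTable.default()
    n = cfg.n
    rng = np.random.default_rng(cfg.seed)
    if n == 0:
        return []

    ref = rng.random(n) < cfg.prevalence
    u = rng.random(n)
    index = np.where(ref, u < cfg.sensitivity, u < (1.0 - cfg.specificity))

    age_mu, age_sigma = _lognormal_from_median_iqr(cfg.age_median, cfg.age_iqr)
    ages = _truncated(
        rng,
        lambda k: np.exp(age_mu + age_sigma * rng.standard_normal(k)),
        lambda x: (x >= 18.0) & (x <= 80.0),
        n,
    )
    weights = _truncated(
        rng,
        lambda k: cfg.weight_mean + cfg.weight_sd * rng.standard_normal(k),
        lambda x: x > 30.0,
        n,
    )
    bmis = _truncated(
        rng,
        lambda k: cfg.bmi_mean + cfg.bmi_sd * rng.standard_normal(k),
        lambda x: (x > 13.0) & (x < 45.0),
        n,
    )
    sexes = rng.random(n) < cfg.male_fraction

    heights = np.sqrt(weights / bmis) * 100.0

    # Paired intakes through a structured Gaussian copula: app-vs-reference
    # correlations per nutrient, plus a within-person energy-protein link.
    rho_e, rho_p, epc = cfg.energy_corr, cfg.protein_corr, cfg.energy_protein_corr
    denom = math.sqrt(max(1e-12, (1 - rho_e**2) * (1 - rho_p**2)))
    r_e = float(np.clip(epc * (1 - rho_e * rho_p) / denom, -0.999, 0.999))
    p_ref_mu, p_ref_sigma = _lognormal_from_median_iqr(
        cfg.protein_ref_median, cfg.protein_ref_iqr
    )
    p_app_mu, p_app_sigma = _lognormal_from_median_iqr(
        cfg.protein_app_median, cfg.protein_app_iqr
    )

    def draw_intakes(k: int) -> np.ndarray:
        z_re = rng.standard_normal(k)
        z_rp = epc * z_re + math.sqrt(1 - epc**2) * rng.standard_normal(k)
        e1 = rng.standard_normal(k)
        e2 = r_e * e1 + math.sqrt(1 - r_e**2) * rng.standard_normal(k)
        z_ae = rho_e * z_re + math.sqrt(1 - rho_e**2) * e1
        z_ap = rho_p * z_rp + math.sqrt(1 - rho_p**2) * e2
        return np.column_stack(
            [
                cfg.energy_ref_mean + cfg.energy_ref_sd * z_re,
                cfg.energy_app_mean + cfg.energy_app_sd * z_ae,
                np.exp(p_ref_mu + p_ref_sigma * z_rp),
                np.exp(p_app_mu + p_app_sigma * z_ap),
            ]
        )

    intakes = _truncated(
        rng, draw_intakes, lambda m: (m[:, 0] > 0) & (m[:, 1] > 0), n
    )
    ref_energy, app_energy_target = intakes[:, 0], intakes[:, 1]
    ref_protein, app_protein_target = intakes[:, 2], intakes[:, 3]

    # Back-solve 3-item food amounts from the app's target energy/protein.
    it = {name: table.item(name) for name in ("rice", "meat", "milk")}
    e_r = it["rice"].adjustment * it["rice"].energy_kcal_per_100 / 100.0
    p_r = it["rice"].adjustment * it["rice"].protein_g_per_100 / 100.0
    e_m = it["meat"].adjustment * it["meat"].energy_kcal_per_100 / 100.0
    p_m = it["meat"].adjustment * it["meat"].protein_g_per_100 / 100.0
    e_k = it["milk"].adjustment * it["milk"].energy_kcal_per_100 / 100.0
    p_k = it["milk"].adjustment * it["milk"].protein_g_per_100 / 100.0
    det = e_r * p_m - e_m * p_r
    milk = rng.uniform(0.0, 300.0, size=n)

    age_thr = int(scfg.nrs2002["age_threshold_years"])

    def build_profile(i: int) -> PatientProfile:
        """Profile for record i; for the NRS arm an index-negative flag is
        unreachable when the (rounded) BMI/age subscores alone reach the
        cutoff, so such anthropometrics are redrawn."""
        while True:
            profile = PatientProfile(
                name_id=f"S{i:05d}",
                age_years=int(round(ages[i])),
                sex=Sex.MALE if sexes[i] else Sex.FEMALE,
                height_cm=round(float(heights[i]), 1),
                weight_kg=round(float(weights[i]), 1),
            )
            if cfg.instrument != "nrs2002":
                return profile
            bmi_sub = _nrs_bmi_subscore(profile.bmi, scfg)
            age_sub = 1 if profile.age_years >= age_thr else 0
            if _nrs_satisfying_sets(bmi_sub, age_sub, scfg)[bool(index[i])]:
                return profile
            ages[i] = _truncated(
                rng,
                lambda k: np.exp(age_mu + age_sigma * rng.standard_normal(k)),
                lambda x: (x >= 18.0) & (x <= 80.0),
                1,
            )[0]
            bmis[i] = _truncated(
                rng,
                lambda k: cfg.bmi_mean + cfg.bmi_sd * rng.standard_normal(k),
                lambda x: (x > 13.0) & (x < 45.0),
                1,
            )[0]
            heights[i] = math.sqrt(weights[i] / bmis[i]) * 100.0

    records: list[SyntheticRecord] = []
    for i in range(n):
        profile = build_profile(i)
        responses = responses_for_flag(
            bool(index[i]), profile, rng, instrument=cfg.instrument, config=scfg
        )
        e_target = app_energy_target[i] - table.intercept_energy_kcal - e_k * milk[i]
        p_target = app_protein_target[i] - table.intercept_protein_g - p_k * milk[i]
        if e_target < 0 or p_target < 0:
            milk_i = 0.0
            e_target = app_energy_target[i] - table.intercept_energy_kcal
            p_target = app_protein_target[i] - table.intercept_protein_g
        else:
            milk_i = milk[i]
        rice = (p_m * e_target - e_m * p_target) / det
        meat = (e_r * p_target - p_r * e_target) / det
        if rice < 0:
            rice, meat = 0.0, max(p_target / p_m, 0.0)
        elif meat < 0:
            meat, rice = 0.0, max(e_target / e_r, 0.0)
        with warnings.catch_warnings():
            # extreme back-solved amounts are a documented tail projection,
            # not a data-entry error
            warnings.simplefilter("ignore", ClinicalRangeWarning)
            report = IntakeReport(
                rice_g=round(rice, 1), meat_g=round(meat, 1), milk_ml=round(milk_i, 1)
            )
        records.append(
            SyntheticRecord(
                profile=profile,
                responses=responses,
                reference_at_risk=bool(ref[i]),
                index_at_risk=bool(index[i]),
                intake_report=report,
                app_energy_kcal=float(app_energy_target[i]),
                app_protein_g=float(app_protein_target[i]),
                ref_energy_kcal=float(ref_energy[i]),
                ref_protein_g=float(ref_protein[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Recovery experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate-wise estimates and their mean/SD per recovered quantity."""

    n_reps: int
    estimates: dict[str, np.ndarray] = field(repr=False)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "means": dict(self.means),
            "sds": dict(self.sds),
        }


def recovery_experiment(
    config: CohortConfig,
    n_reps: int,
    scoring_config: Optional[ScoringConfig] = None,
) -> RecoverySummary:
    """Run generate → validate over replicates and summarize the estimates.

    Per replicate: the 2×2 table of index vs reference flags yields
    sensitivity, specificity, accuracy and κ; the paired energy/protein
    intakes yield mean app-minus-reference differences.  Replicate seeds
    derive deterministically from ``config.seed``.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    names = (
        "sensitivity",
        "specificity",
        "accuracy",
        "kappa",
        "energy_bias",
        "protein_bias",
    )
    values: dict[str, list[float]] = {k: [] for k in names}
    for rep in range(n_reps):
        cohort = generate_cohort(
            replace(config, seed=int(seeds[rep])), scoring_config=scoring_config
        )
        idx = [r.index_at_risk for r in cohort]
        ref = [r.reference_at_risk for r in cohort]
        tab = table_from_pairs(idx, ref)
        metrics = diagnostic_metrics(tab)
        kappa = cohens_kappa(tab)
        values["sensitivity"].append(
            metrics["sensitivity"].value if metrics["sensitivity"].defined else np.nan
        )
        values["specificity"].append(
            metrics["specificity"].value if metrics["specificity"].defined else np.nan
        )
        values["accuracy"].append(metrics["accuracy"].value)
        values["kappa"].append(kappa.value if kappa.defined else np.nan)
        values["energy_bias"].append(
            float(np.mean([r.app_energy_kcal - r.ref_energy_kcal for r in cohort]))
        )
        values["protein_bias"].append(
            float(np.mean([r.app_protein_g - r.ref_protein_g for r in cohort]))
        )
    estimates = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    return RecoverySummary(
        n_reps=n_reps,
        estimates=estimates,
        means={k: float(np.nanmean(v)) for k, v in estimates.items()},
        sds={k: float(np.nanstd(v, ddof=1)) if n_reps > 1 else 0.0 for k, v in estimates.items()},
    )
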