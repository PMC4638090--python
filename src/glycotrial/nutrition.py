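"""Enteral-formula composition accounting and GI-complication rules.

Per-100-kcal composition is the canonical route: a day's energy from the
pump is volume (mL) x caloric density (kcal/mL), and each nutrient is
(kcal / 100) x its per-100-kcal amount.  Non-nutritional calories (propofol
2 %, intravenous glucose 5 %) enter the caloric balance only.  The volume
ratio VR (%) = administered / prescribed x 100 measures feeding efficacy;
caloric prescription defaults to 25 kcal/kg/day.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .model import ConfigError, DomainError

GI_LABELS = (
    "abdominal_distension",
    "high_grv",
    "vomiting",
    "regurgitation",
    "diarrhea",
)


@dataclass(frozen=True)
class FormulaComposition:
    """One enteral formula: caloric density plus per-100-kcal composition."""

    name: str
    caloric_density_kcal_per_ml: float
    protein_g: float
    carbohydrate_g: float
    fat_g: float
    fat_saturated_g: float = 0.0
    fat_mufa_g: float = 0.0
    fat_pufa_g: float = 0.0
    epa_dha_mg: float = 0.0
    fiber_g: float = 0.0
    fiber_soluble_g: float = 0.0
    fiber_insoluble_g: float = 0.0

    def __post_init__(self) -> None:
        if self.caloric_density_kcal_per_ml <= 0:
            raise ConfigError(f"{self.name}: caloric density must be > 0")
        comp = self.fat_saturated_g + self.fat_mufa_g + self.fat_pufa_g
        if comp > self.fat_g + 0.1:  # printed components may round slightly high
            raise ConfigError(
                f"{self.name}: fat components ({comp} g) exceed total fat "
                f"({self.fat_g} g)"
            )

    def per_100_ml(self, field: str) -> float:
        """Per-100-mL amount derived through the caloric density."""
        return getattr(self, field) * self.caloric_density_kcal_per_ml


def load_formulas(
    path: str | Path | None = None,
) -> tuple[dict[str, FormulaComposition], dict[str, str]]:
    """Load formula compositions and the arm->formula map.

    Defaults to the bundled three-formula file.  Returns
    ``(formulas_by_name, arm_formula_names)``.
    """
    if path is None:
        text = (resources.files("glycotrial.data") / "formulas.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "formulas" not in raw:
        raise ConfigError("formula file must contain a 'formulas' mapping")
    formulas = {
        name: FormulaComposition(name=name, **fields)
        for name, fields in raw["formulas"].items()
    }
    arm_map = {str(k): str(v) for k, v in raw.get("arm_formulas", {}).items()}
    for arm, fname in arm_map.items():
        if fname not in formulas:
            raise ConfigError(f"arm {arm} maps to unknown formula {fname!r}")
    return formulas, arm_map


def volume_ratio(administered_ml: float, prescribed_ml: float) -> float:
    """VR (%) = (volume administered / volume prescribed) x 100."""
    if prescribed_ml <= 0:
        raise DomainError(f"prescribed volume must be > 0, got {prescribed_ml}")
    if administered_ml < 0:
        raise DomainError(f"administered volume must be >= 0, got {administered_ml}")
    return administered_ml / prescribed_ml * 100.0


def prescribe_calories(weight_kg: float, kcal_per_kg: float = 25.0) -> float:
    """Prescribed daily energy, default 25 kcal/kg/day."""
    if weight_kg <= 0:
        raise DomainError(f"weight must be > 0 kg, got {weight_kg}")
    if kcal_per_kg <= 0:
        raise DomainError("kcal_per_kg must be > 0")
    return kcal_per_kg * weight_kg


@dataclass(frozen=True)
class DailyIntake:
    """Energy and macronutrients actually delivered in one patient-day."""

    kcal_en: float
    kcal_total: float  # EN plus non-nutritional (propofol, IV glucose)
    protein_g: float
    carbohydrate_g: float
    fat_g: float
    fiber_g: float


def daily_intake(
    volume_administered_ml: float,
    formula: FormulaComposition,
    extra_kcal: float = 0.0,
) -> DailyIntake:
    """Convert an infused volume into energy and nutrient amounts.

    ``extra_kcal`` (non-nutritional calories) is added to the energy total
    only; it carries no macronutrients.
    """
    if volume_administered_ml < 0:
        raise DomainError("volume must be >= 0 mL")
    if extra_kcal < 0:
        raise DomainError("extra_kcal must be >= 0")
    kcal = volume_administered_ml * formula.caloric_density_kcal_per_ml
    per = kcal / 100.0
    return DailyIntake(
        kcal_en=kcal,
        kcal_total=kcal + extra_kcal,
        protein_g=per * formula.protein_g,
        carbohydrate_g=per * formula.carbohydrate_g,
        fat_g=per * formula.fat_g,
        fiber_g=per * formula.fiber_g,
    )


@dataclass(frozen=True)
class GIObservation:
    """One day's structured gastrointestinal observation."""

    grv_ml: float = 0.0  # largest recovered gastric residual volume
    liquid_stools: int = 0
    stool_volume_ml: float = 0.0
    vomiting: bool = False
    regurgitation: bool = False
    abdominal_distension: bool = False

    def __post_init__(self) -> None:
        if min(self.grv_ml, self.liquid_stools, self.stool_volume_ml) < 0:
            raise DomainError("GI observation fields must be non-negative")


def classify_gi_complication(
    obs: GIObservation,
    grv_threshold_ml: float = 500.0,
    diarrhea_stools: int = 5,
    diarrhea_volume_ml: float = 2000.0,
) -> tuple[str, ...]:
    """Label a daily GI observation; empty tuple means no complication.

    Thresholds follow the trial definitions: high GRV at >=500 mL recovered
    volume, diarrhea at >=5 liquid stools/24 h or >=2000 mL estimated stool
    volume.  Distension, vomiting and regurgitation are direct observations.
    Several complications can co-occur on one day, so a tuple is returned.
    """
    labels = []
    if obs.abdominal_distension:
        labels.append("abdominal_distension")
    if obs.grv_ml >= grv_threshold_ml:
        labels.append("high_grv")
    if obs.vomiting:
        labels.append("vomiting")
    if obs.regurgitation:
        labels.append("regurgitation")
    if obs.liquid_stools >= diarrhea_stools or obs.stool_volume_ml >= diarrhea_volume_ml:
        labels.append("diarrhea")
    return tuple(labels)


def flag_closed_early(withholding_h: float, threshold_h: float = 48.0) -> bool:
    """A complication withholding the diet for more than 48 h closes the
    case early; the patient stays in the intention-to-treat analysis."""
    if withholding_h < 0:
        raise DomainError("withholding_h must be >= 0")
    return withholding_h > threshold_h
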