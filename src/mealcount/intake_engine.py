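"""Calorie-count engine: recorded NIAFs and food weights -> nutrient totals.

Converts percent-consumed entries into served and consumed nutrient totals
per meal or per day.  All totals are accumulated in exact rational
arithmetic (``fractions.Fraction``) so that linearity, additivity and
conservation hold bit-exactly; reports render energy to one decimal kcal.

The weighed-food path implements the reference-standard computation used in
rater training: percent consumed by weight is
``((original - leftover) / original) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .food_model import FoodDatabase, FoodItem, NIAF, NIAFLine, NutrientProfile

__all__ = [
    "WeighedRecord",
    "IntakeReport",
    "weighed_consumption_pct",
    "line_consumed_profile",
    "meal_report",
    "day_report",
    "weighed_meal_energy",
]

MACROS = ("energy_kcal", "protein_g", "fat_sat_g", "fat_unsat_g", "carb_g")


@dataclass(frozen=True)
class WeighedRecord:
    """Pre/post-meal weights for one food item on one tray."""

    item_id: str
    original_weight: float
    leftover_weight: float
    tray_id: str | None = None

    def __post_init__(self) -> None:
        if not self.original_weight > 0:
            raise ValueError("undefined consumption: original_weight must be > 0")
        if self.leftover_weight < 0 or self.leftover_weight > self.original_weight:
            raise ValueError("invalid weights: need 0 <= leftover_weight <= original_weight")


def weighed_consumption_pct(record: WeighedRecord) -> Fraction:
    """Percent of an item consumed, from its pre- and post-meal weights.

    Returns the exact rational ``((original - leftover)/original) * 100``;
    the caller chooses any rounding.
    """
    orig = Fraction(record.original_weight)
    left = Fraction(record.leftover_weight)
    return (orig - left) / orig * 100


@dataclass
class IntakeReport:
    """Served and consumed nutrient totals, per meal or per day.

    ``served`` treats every line as fully consumed, including mid-meal
    additions (they reached the patient); ``consumed`` scales each line by
    its recorded percentage.  Totals are exact Fractions; ``lines`` carries
    the per-line breakdown as (tray_id, item_id, nutrient -> (served,
    consumed)).
    """

    scope: str  # "meal" or "day"
    served: dict[str, Fraction] = field(default_factory=dict)
    consumed: dict[str, Fraction] = field(default_factory=dict)
    lines: list[tuple[str, str, dict[str, tuple[Fraction, Fraction]]]] = field(
        default_factory=list
    )

    @property
    def energy_served_kcal(self) -> float:
        return float(self.served.get("energy_kcal", 0))

    @property
    def energy_consumed_kcal(self) -> float:
        return float(self.consumed.get("energy_kcal", 0))

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "served": {k: round(float(v), 4) for k, v in self.served.items()},
            "consumed": {k: round(float(v), 4) for k, v in self.consumed.items()},
        }

    def text_table(self) -> str:
        rows = [f"{'nutrient':<22}{'served':>12}{'consumed':>12}"]
        for k in self.served:
            rows.append(
                f"{k:<22}{float(self.served[k]):>12.1f}{float(self.consumed.get(k, 0)):>12.1f}"
            )
        return "\n".join(rows)


def _profile_amounts(profile: NutrientProfile) -> dict[str, Fraction]:
    out = {m: Fraction(getattr(profile, m)) for m in MACROS}
    for k, v in profile.micronutrients.items():
        out[k] = Fraction(v)
    return out


def line_consumed_profile(line: NIAFLine, item: FoodItem) -> NutrientProfile:
    """Nutrients consumed on one line: profile x servings x pct/100."""
    if line.pct_consumed is None:
        raise ValueError(f"consumption not recorded for line {line.item_id!r}")
    f = Fraction(line.servings) * Fraction(line.pct_consumed, 100)
    p = item.profile
    return NutrientProfile(
        energy_kcal=float(Fraction(p.energy_kcal) * f),
        protein_g=float(Fraction(p.protein_g) * f),
        fat_sat_g=float(Fraction(p.fat_sat_g) * f),
        fat_unsat_g=float(Fraction(p.fat_unsat_g) * f),
        carb_g=float(Fraction(p.carb_g) * f),
        micronutrients={k: float(Fraction(v) * f) for k, v in p.micronutrients.items()},
    )


def _accumulate(totals: dict[str, Fraction], amounts: dict[str, Fraction], factor: Fraction):
    for k, v in amounts.items():
        totals[k] = totals.get(k, Fraction(0)) + v * factor


def meal_report(niaf: NIAF, db: FoodDatabase) -> IntakeReport:
    """Detailed calorie-count report for one meal.

    Requires every line to have a recorded percentage; raises otherwise.
    """
    unrecorded = [ln.item_id for ln in niaf.lines if ln.pct_consumed is None]
    if unrecorded:
        raise ValueError(f"incomplete NIAF: consumption not recorded for {unrecorded}")
    report = IntakeReport(scope="meal")
    for m in MACROS:
        report.served[m] = Fraction(0)
        report.consumed[m] = Fraction(0)
    for ln in niaf.lines:
        item = db.get(ln.item_id)
        amounts = _profile_amounts(item.profile)
        servings = Fraction(ln.servings)
        pct = Fraction(ln.pct_consumed, 100)
        _accumulate(report.served, amounts, servings)
        _accumulate(report.consumed, amounts, servings * pct)
        report.lines.append(
            (
                niaf.tray_id,
                ln.item_id,
                {k: (v * servings, v * servings * pct) for k, v in amounts.items()},
            )
        )
    return report


def day_report(niafs: list[NIAF], db: FoodDatabase) -> IntakeReport:
    """Whole-day report: exact sum of the constituent meal reports.

    All forms must belong to the same patient and date; snack or
    outside-food forms are ordinary constituents.
    """
    if not niafs:
        return IntakeReport(scope="day")
    scope_keys = {(n.patient_id, n.date) for n in niafs}
    if len(scope_keys) > 1:
        raise ValueError(f"inconsistent scope: mixed patients/dates {sorted(map(str, scope_keys))}")
    out = IntakeReport(scope="day")
    for niaf in niafs:
        rep = meal_report(niaf, db)
        _accumulate(out.served, rep.served, Fraction(1))
        _accumulate(out.consumed, rep.consumed, Fraction(1))
        out.lines.extend(rep.lines)
    return out


def weighed_meal_energy(records: list[WeighedRecord], db: FoodDatabase) -> Fraction:
    """Reference energy consumed (kcal) for a meal, from food weights.

    Each item needs ``serving_weight_g`` in the database so its per-serving
    energy has a gram basis; consumed energy per item is energy x fraction
    of the served weight eaten.  The served portion is taken to be the
    original (pre-meal) weight.
    """
    total = Fraction(0)
    for rec in records:
        item = db.get(rec.item_id)
        if item.serving_weight_g is None:
            raise ValueError(f"no gram basis for item {rec.item_id!r} (serving_weight_g missing)")
        pct = weighed_consumption_pct(rec)
        # energy in the served portion = per-serving energy x original/serving weight
        served_energy = (
            Fraction(item.profile.energy_kcal)
            * Fraction(rec.original_weight)
            / Fraction(item.serving_weight_g)
        )
        total += served_energy * pct / 100
    return total
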