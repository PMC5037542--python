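"""Hospital menu system and the Nutritional Intake Assessment Form (NIAF).

The NIAF is the per-tray checklist at the heart of bedside calorie counting:
it lists every food item scheduled for a patient-meal (drawn from the menu
cycle for the selected day, meal and diet), is edited at the bedside until it
matches the tray actually delivered, and finally records the percentage of
each item the patient consumed, as an integer on a 0-100 scale.

Forms move through a forward-only lifecycle::

    generated -> verified -> recorded -> finalized

``generated`` is the menu-derived draft, ``verified`` means the bedside check
against the physical tray is done, ``recorded`` means every line has a
percent-consumed entry, and ``finalized`` forms are immutable.  Every edit is
appended to an audit trail so the provenance of each line (menu, bedside
edit, outside food, mid-meal addition) is preserved.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "NutrientProfile",
    "FoodItem",
    "DietPlan",
    "MenuCycle",
    "NIAFLine",
    "NIAF",
    "FoodDatabase",
    "NIAF_STATUSES",
    "MEALS",
    "LINE_ORIGINS",
    "generate_niaf",
    "edit_niaf",
    "record_consumption",
]

MEALS = ("breakfast", "lunch", "dinner")
NIAF_STATUSES = ("generated", "verified", "recorded", "finalized")
LINE_ORIGINS = ("menu", "bedside_edit", "outside_food", "mid_meal_addition")


@dataclass(frozen=True)
class NutrientProfile:
    """Per-serving nutrient amounts; the engine's unit of accounting.

    All amounts are per one serving *as served*.  ``serving_weight_g`` is
    optional metadata required only by weighed-food workflows, where energy
    must be re-expressed per gram.
    """

    energy_kcal: float
    protein_g: float = 0.0
    fat_sat_g: float = 0.0
    fat_unsat_g: float = 0.0
    carb_g: float = 0.0
    micronutrients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("energy_kcal", "protein_g", "fat_sat_g", "fat_unsat_g", "carb_g"):
            v = getattr(self, name)
            if not (v >= 0) or v != v or v in (float("inf"),):
                raise ValueError(f"nutrient amount {name}={v!r} must be finite and >= 0")
        for k, v in self.micronutrients.items():
            if not v >= 0:
                raise ValueError(f"micronutrient {k}={v!r} must be >= 0")
        # freeze the mapping so profiles are safely shareable
        object.__setattr__(self, "micronutrients", dict(self.micronutrients))

    def macronutrients(self) -> dict[str, float]:
        return {
            "energy_kcal": self.energy_kcal,
            "protein_g": self.protein_g,
            "fat_sat_g": self.fat_sat_g,
            "fat_unsat_g": self.fat_unsat_g,
            "carb_g": self.carb_g,
        }


@dataclass(frozen=True)
class FoodItem:
    """One entry of the food-composition database."""

    item_id: str
    description: str
    serving_label: str
    profile: NutrientProfile
    serving_weight_g: float | None = None

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError("FoodItem description must be non-empty")
        if self.serving_weight_g is not None and not self.serving_weight_g > 0:
            raise ValueError("serving_weight_g must be > 0 when given")


@dataclass(frozen=True)
class DietPlan:
    diet_id: str
    name: str


class FoodDatabase:
    """In-memory food-composition database keyed by ``item_id``.

    Mirrors the hospital's institutional nutrient table: built once from the
    dietary service's menu items, and extended in place whenever an outside
    (non-institutional) food is entered — such items persist for future use.
    """

    def __init__(self, items: list[FoodItem] | None = None):
        self._items: dict[str, FoodItem] = {}
        for it in items or []:
            self.add(it)

    def add(self, item: FoodItem) -> None:
        if item.item_id in self._items:
            raise ValueError(f"duplicate item_id {item.item_id!r}")
        self._items[item.item_id] = item

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def get(self, item_id: str) -> FoodItem:
        try:
            return self._items[item_id]
        except KeyError:
            raise KeyError(f"unknown food item: {item_id!r}") from None


class MenuCycle:
    """Repeating menu schedule: (cycle_day, meal, diet_id) -> served items.

    Keyed by integer cycle day (>= 1) rather than calendar date; mapping a
    calendar date onto a cycle day is site configuration and lives outside
    this class.
    """

    def __init__(
        self,
        cycle_id: str,
        entries: Mapping[tuple[int, str, str], list[tuple[str, Fraction | float | int | str]]],
    ):
        self.cycle_id = cycle_id
        self.entries: dict[tuple[int, str, str], list[tuple[str, Fraction]]] = {}
        for (day, meal, diet), items in entries.items():
            if day < 1:
                raise ValueError("cycle_day must be >= 1")
            if meal not in MEALS:
                raise ValueError(f"unknown meal {meal!r}")
            out = []
            for item_id, servings in items:
                servings = Fraction(servings)
                if servings <= 0:
                    raise ValueError("servings must be > 0")
                out.append((item_id, servings))
            self.entries[(day, meal, diet)] = out

    def validate_against(self, db: FoodDatabase) -> None:
        for key, items in self.entries.items():
            for item_id, _ in items:
                if item_id not in db:
                    raise ValueError(f"unknown food item: {item_id!r} in menu entry {key}")


@dataclass
class NIAFLine:
    item_id: str
    servings: Fraction
    pct_consumed: int | None = None
    origin: str = "menu"

    def __post_init__(self) -> None:
        self.servings = Fraction(self.servings)
        if self.servings <= 0:
            raise ValueError("servings must be > 0")
        if self.origin not in LINE_ORIGINS:
            raise ValueError(f"unknown line origin {self.origin!r}")
        if self.pct_consumed is not None:
            _check_pct(self.pct_consumed)


def _check_pct(pct) -> int:
    # integer 0-100, strictly: fractional inputs are rejected, not rounded
    if isinstance(pct, bool) or not isinstance(pct, int):
        if isinstance(pct, float) and pct.is_integer():
            raise ValueError(f"invalid percentage: {pct!r} (must be an integer)")
        raise ValueError(f"invalid percentage: {pct!r} (must be an integer)")
    if not 0 <= pct <= 100:
        raise ValueError(f"invalid percentage: {pct} (must be in [0, 100])")
    return pct


@dataclass
class NIAF:
    """One Nutritional Intake Assessment Form for one patient-meal-tray."""

    tray_id: str
    patient_id: str
    date: _dt.date
    meal: str
    diet_id: str
    lines: list[NIAFLine] = field(default_factory=list)
    photo_pre: str | None = None
    photo_post: str | None = None
    status: str = "generated"
    audit_trail: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.meal not in MEALS:
            raise ValueError(f"unknown meal {self.meal!r}")
        if self.status not in NIAF_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        ids = [ln.item_id for ln in self.lines]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate line")

    def line(self, item_id: str) -> NIAFLine:
        for ln in self.lines:
            if ln.item_id == item_id:
                return ln
        raise KeyError(f"line not found: {item_id!r}")

    def advance_status(self, new_status: str) -> None:
        """Move the form forward in the lifecycle; backward moves are rejected."""
        if NIAF_STATUSES.index(new_status) < NIAF_STATUSES.index(self.status):
            raise ValueError(
                f"status may only move forward ({self.status!r} -> {new_status!r} rejected)"
            )
        self.status = new_status

    @property
    def fully_recorded(self) -> bool:
        return bool(self.lines) and all(ln.pct_consumed is not None for ln in self.lines)


def generate_niaf(
    db: FoodDatabase,
    cycle: MenuCycle,
    diet_id: str,
    cycle_day: int,
    meal: str,
    tray_id: str,
    patient_id: str,
    date: _dt.date | None = None,
) -> NIAF:
    """Generate the NIAF draft for a patient-meal from the menu cycle.

    One line per scheduled menu item, ``origin='menu'``, percent consumed
    unrecorded, status ``generated``.  Deterministic: the same menu inputs
    always yield the identical line set, in menu order.
    """
    key = (cycle_day, meal, diet_id)
    items = cycle.entries.get(key)
    if not items:
        raise ValueError(
            f"menu entry missing: no items for day={cycle_day}, meal={meal!r}, diet={diet_id!r}"
        )
    lines = []
    for item_id, servings in items:
        if item_id not in db:
            raise ValueError(f"unknown food item: {item_id!r}")
        lines.append(NIAFLine(item_id=item_id, servings=servings, origin="menu"))
    return NIAF(
        tray_id=tray_id,
        patient_id=patient_id,
        date=date or _dt.date.today(),
        meal=meal,
        diet_id=diet_id,
        lines=lines,
    )


def edit_niaf(niaf: NIAF, edit: str, payload: dict, db: FoodDatabase | None = None) -> NIAF:
    """Apply one bedside edit and return the updated form.

    ``edit`` is one of ``add_line``, ``remove_line``, ``change_servings``.
    ``add_line`` payloads name either an item already in ``db`` or an ad-hoc
    outside food carrying a complete :class:`NutrientProfile`; outside foods
    are persisted into ``db`` for future reuse.  The edit is appended to the
    audit trail.  Returns a new NIAF; the input is not mutated.
    """
    if niaf.status not in ("generated", "verified", "recorded"):
        raise ValueError(f"cannot edit a {niaf.status} NIAF")
    out = copy.deepcopy(niaf)
    if edit == "add_line":
        item_id = payload["item_id"]
        if any(ln.item_id == item_id for ln in out.lines):
            raise ValueError(f"duplicate line: {item_id!r}")
        origin = payload.get("origin", "bedside_edit")
        if "profile" in payload:
            # ad-hoc outside food: needs the full profile, persisted for reuse
            if db is not None and item_id not in db:
                db.add(
                    FoodItem(
                        item_id=item_id,
                        description=payload.get("description", item_id),
                        serving_label=payload.get("serving_label", "1 serving"),
                        profile=payload["profile"],
                        serving_weight_g=payload.get("serving_weight_g"),
                    )
                )
        elif db is None or item_id not in db:
            raise ValueError(f"unknown food item: {item_id!r}")
        out.lines.append(
            NIAFLine(
                item_id=item_id,
                servings=Fraction(payload.get("servings", 1)),
                origin=origin,
            )
        )
    elif edit == "remove_line":
        item_id = payload["item_id"]
        idx = [i for i, ln in enumerate(out.lines) if ln.item_id == item_id]
        if not idx:
            raise ValueError(f"line not found: {item_id!r}")
        del out.lines[idx[0]]
    elif edit == "change_servings":
        item_id = payload["item_id"]
        servings = Fraction(payload["servings"])
        if servings <= 0:
            raise ValueError("servings must be > 0")
        try:
            ln = out.line(item_id)
        except KeyError:
            raise ValueError(f"line not found: {item_id!r}") from None
        ln.servings = servings
    else:
        raise ValueError(f"unknown edit {edit!r}")
    out.audit_trail.append({"edit": edit, "payload": _audit_payload(payload)})
    return out


def _audit_payload(payload: dict) -> dict:
    out = {}
    for k, v in payload.items():
        if isinstance(v, NutrientProfile):
            out[k] = {**v.macronutrients(), "micronutrients": dict(v.micronutrients)}
        elif isinstance(v, Fraction):
            out[k] = str(v)
        else:
            out[k] = v
    return out


def record_consumption(niaf: NIAF, entries: Mapping[str, int]) -> NIAF:
    """Record percent-consumed entries on a form and return the update.

    Partial entry is allowed (a night-shift employee may start the count and
    a day-shift one finish it); the form reaches status ``recorded`` only
    once every line has a percentage.
    """
    if niaf.status == "finalized":
        raise ValueError("cannot edit a finalized NIAF")
    out = copy.deepcopy(niaf)
    for item_id, pct in entries.items():
        pct = _check_pct(pct)
        try:
            ln = out.line(item_id)
        except KeyError:
            raise ValueError(f"line not found: {item_id!r}") from None
        ln.pct_consumed = pct
    out.audit_trail.append(
        {"edit": "record_consumption", "payload": {k: int(v) for k, v in entries.items()}}
    )
    if out.fully_recorded and NIAF_STATUSES.index(out.status) < NIAF_STATUSES.index("recorded"):
        out.status = "recorded"
    return out
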