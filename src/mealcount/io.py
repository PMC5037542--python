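"""Readers, writers and bundled fixtures.

CSV dialect throughout: UTF-8, comma-separated, header row required, '.'
decimal separator, times in seconds.  NIAFs serialize to JSON (including
the audit trail, with servings kept as exact rational strings so round
trips are bit-exact) and export to a flat CSV for spreadsheets.

The packaged fixtures are the timing table of the time-savings exercise
(24 rows, transcribed cell for cell with the printed method labels — label
correction is an explicit opt-in step) and a small demonstration food
database and one-day menu cycle.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
from fractions import Fraction
from importlib import resources
from pathlib import Path

import pandas as pd

from .agreement import AssessmentRecord, TimeRecord
from .food_model import (
    FoodDatabase,
    FoodItem,
    MenuCycle,
    NIAF,
    NIAFLine,
    NutrientProfile,
)
from .intake_engine import WeighedRecord
from .qc import ReviewComparison

__all__ = [
    "load_table2_fixture",
    "load_demo_food_db",
    "load_demo_menu_cycle",
    "read_food_db_csv",
    "read_food_db_json",
    "write_food_db_csv",
    "read_menu_cycle_json",
    "niaf_to_json",
    "niaf_from_json",
    "write_niaf",
    "read_niaf",
    "niaf_to_csv",
    "read_time_records_csv",
    "write_time_records_csv",
    "read_assessment_records_csv",
    "write_assessment_records_csv",
    "read_weighed_records_csv",
    "read_review_comparisons_csv",
    "file_checksum",
]

_MACRO_COLS = ["energy_kcal", "protein_g", "fat_sat_g", "fat_unsat_g", "carb_g"]
_META_COLS = ["item_id", "description", "serving_label", "serving_weight_g"]


def _data_path(name: str):
    return resources.files("mealcount.data").joinpath(name)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# fixtures


def load_table2_fixture() -> list[TimeRecord]:
    """The 24 timing rows of the time-savings assignment matrix.

    Printed method labels are preserved verbatim; apply
    :func:`mealcount.agreement.resolve_method_labels` to enforce the stated
    balanced alternating design.
    """
    with resources.as_file(_data_path("table2.csv")) as p:
        return read_time_records_csv(p)


def load_demo_food_db() -> FoodDatabase:
    with resources.as_file(_data_path("food_db.csv")) as p:
        return read_food_db_csv(p)


def load_demo_menu_cycle() -> MenuCycle:
    with resources.as_file(_data_path("menu_cycle.json")) as p:
        return read_menu_cycle_json(p)


# ---------------------------------------------------------------------------
# food database


def read_food_db_csv(path) -> FoodDatabase:
    df = pd.read_csv(path)
    missing = [c for c in ("item_id", "description", "serving_label", "energy_kcal") if c not in df.columns]
    if missing:
        raise ValueError(f"food database schema error: missing columns {missing}")
    micro_cols = [c for c in df.columns if c not in _META_COLS + _MACRO_COLS]
    db = FoodDatabase()
    for i, row in df.iterrows():
        try:
            db.add(
                FoodItem(
                    item_id=str(row["item_id"]),
                    description=str(row["description"]),
                    serving_label=str(row["serving_label"]),
                    profile=NutrientProfile(
                        energy_kcal=float(row["energy_kcal"]),
                        protein_g=float(row.get("protein_g", 0) or 0),
                        fat_sat_g=float(row.get("fat_sat_g", 0) or 0),
                        fat_unsat_g=float(row.get("fat_unsat_g", 0) or 0),
                        carb_g=float(row.get("carb_g", 0) or 0),
                        micronutrients={
                            c: float(row[c]) for c in micro_cols if pd.notna(row[c])
                        },
                    ),
                    serving_weight_g=(
                        float(row["serving_weight_g"])
                        if "serving_weight_g" in df.columns and pd.notna(row["serving_weight_g"])
                        else None
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"food database schema error at row {i + 2}: {exc}") from exc
    return db


def read_food_db_json(path) -> FoodDatabase:
    data = json.loads(Path(path).read_text())
    db = FoodDatabase()
    for entry in data["items"]:
        prof = entry["profile"]
        db.add(
            FoodItem(
                item_id=entry["item_id"],
                description=entry["description"],
                serving_label=entry.get("serving_label", "1 serving"),
                profile=NutrientProfile(
                    energy_kcal=prof["energy_kcal"],
                    protein_g=prof.get("protein_g", 0.0),
                    fat_sat_g=prof.get("fat_sat_g", 0.0),
                    fat_unsat_g=prof.get("fat_unsat_g", 0.0),
                    carb_g=prof.get("carb_g", 0.0),
                    micronutrients=prof.get("micronutrients", {}),
                ),
                serving_weight_g=entry.get("serving_weight_g"),
            )
        )
    return db


def write_food_db_csv(db: FoodDatabase, path) -> None:
    micro_names = sorted({k for item in db for k in item.profile.micronutrients})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_META_COLS[:3] + _MACRO_COLS + ["serving_weight_g"] + micro_names)
        for item in db:
            p = item.profile
            w.writerow(
                [item.item_id, item.description, item.serving_label]
                + [p.energy_kcal, p.protein_g, p.fat_sat_g, p.fat_unsat_g, p.carb_g]
                + [item.serving_weight_g if item.serving_weight_g is not None else ""]
                + [p.micronutrients.get(m, "") for m in micro_names]
            )


# ---------------------------------------------------------------------------
# menu cycle


def read_menu_cycle_json(path) -> MenuCycle:
    data = json.loads(Path(path).read_text())
    entries = {}
    for day_str, meals in data["entries"].items():
        for meal, diets in meals.items():
            for diet_id, items in diets.items():
                entries[(int(day_str), meal, diet_id)] = [
                    (it["item_id"], Fraction(str(it["servings"]))) for it in items
                ]
    return MenuCycle(cycle_id=data["cycle_id"], entries=entries)


# ---------------------------------------------------------------------------
# NIAF


def niaf_to_json(niaf: NIAF) -> str:
    doc = {
        "tray_id": niaf.tray_id,
        "patient_id": niaf.patient_id,
        "date": niaf.date.isoformat(),
        "meal": niaf.meal,
        "diet_id": niaf.diet_id,
        "status": niaf.status,
        "photo_pre": niaf.photo_pre,
        "photo_post": niaf.photo_post,
        "lines": [
            {
                "item_id": ln.item_id,
                "servings": str(ln.servings),  # exact rational
                "pct_consumed": ln.pct_consumed,
                "origin": ln.origin,
            }
            for ln in niaf.lines
        ],
        "audit_trail": niaf.audit_trail,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def niaf_from_json(text: str) -> NIAF:
    doc = json.loads(text)
    return NIAF(
        tray_id=doc["tray_id"],
        patient_id=doc["patient_id"],
        date=_dt.date.fromisoformat(doc["date"]),
        meal=doc["meal"],
        diet_id=doc["diet_id"],
        status=doc["status"],
        photo_pre=doc.get("photo_pre"),
        photo_post=doc.get("photo_post"),
        lines=[
            NIAFLine(
                item_id=ln["item_id"],
                servings=Fraction(ln["servings"]),
                pct_consumed=ln["pct_consumed"],
                origin=ln["origin"],
            )
            for ln in doc["lines"]
        ],
        audit_trail=doc.get("audit_trail", []),
    )


def write_niaf(niaf: NIAF, path) -> None:
    Path(path).write_text(niaf_to_json(niaf))


def read_niaf(path) -> NIAF:
    return niaf_from_json(Path(path).read_text())


def niaf_to_csv(niaf: NIAF, path) -> None:
    """Flat one-row-per-line export for spreadsheets."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["tray_id", "patient_id", "date", "meal", "diet_id", "status",
             "item_id", "servings", "pct_consumed", "origin"]
        )
        for ln in niaf.lines:
            w.writerow(
                [niaf.tray_id, niaf.patient_id, niaf.date.isoformat(), niaf.meal,
                 niaf.diet_id, niaf.status, ln.item_id, float(ln.servings),
                 "" if ln.pct_consumed is None else ln.pct_consumed, ln.origin]
            )


# ---------------------------------------------------------------------------
# evaluation records


def read_time_records_csv(path) -> list[TimeRecord]:
    df = pd.read_csv(path)
    required = ["rater", "method", "day", "session", "meal", "t_pre_s", "t_post_s", "t_entry_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"time record schema error: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                TimeRecord(
                    rater_id=str(row["rater"]),
                    method=str(row["method"]),
                    day=int(row["day"]),
                    session=int(row["session"]),
                    meal=str(row["meal"]).lower(),
                    t_pre=float(row["t_pre_s"]),
                    t_post=float(row["t_post_s"]),
                    t_entry=float(row["t_entry_s"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"time record schema error at row {i + 2}: {exc}") from exc
    return out


def write_time_records_csv(records: list[TimeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rater", "method", "day", "session", "meal", "t_pre_s", "t_post_s", "t_entry_s"])
        for r in records:
            w.writerow(
                [r.rater_id, r.method, r.day, r.session, r.meal, r.t_pre, r.t_post, r.t_entry]
            )


def read_assessment_records_csv(path) -> list[AssessmentRecord]:
    df = pd.read_csv(path)
    required = ["tray_id", "rater_id", "day", "meal", "estimate_kcal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"assessment record schema error: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            tv = row["true_kcal"] if "true_kcal" in df.columns else None
            out.append(
                AssessmentRecord(
                    tray_id=str(row["tray_id"]),
                    rater_id=str(row["rater_id"]),
                    day=int(row["day"]),
                    meal=str(row["meal"]).lower(),
                    estimate=float(row["estimate_kcal"]),
                    true_value=None if tv is None or pd.isna(tv) else float(tv),
                )
            )
        except ValueError as exc:
            raise ValueError(f"assessment record schema error at row {i + 2}: {exc}") from exc
    return out


def write_assessment_records_csv(records: list[AssessmentRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tray_id", "rater_id", "day", "meal", "estimate_kcal", "true_kcal"])
        for r in records:
            w.writerow(
                [r.tray_id, r.rater_id, r.day, r.meal, r.estimate,
                 "" if r.true_value is None else r.true_value]
            )


def read_weighed_records_csv(path) -> list[WeighedRecord]:
    df = pd.read_csv(path)
    required = ["tray_id", "item_id", "original_g", "leftover_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weighed record schema error: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                WeighedRecord(
                    item_id=str(row["item_id"]),
                    original_weight=float(row["original_g"]),
                    leftover_weight=float(row["leftover_g"]),
                    tray_id=str(row["tray_id"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"weighed record schema error at row {i + 2}: {exc}") from exc
    return out


def read_review_comparisons_csv(path) -> list[ReviewComparison]:
    """Columns: tray_id, item_id, primary_pct, review_pct, reviewer_id."""
    df = pd.read_csv(path)
    required = ["tray_id", "item_id", "primary_pct", "review_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"review comparison schema error: missing columns {missing}")
    out = []
    key_cols = ["tray_id", "reviewer_id"] if "reviewer_id" in df.columns else ["tray_id"]
    for key, grp in df.groupby(key_cols, dropna=False):
        tray = key[0] if isinstance(key, tuple) else key
        reviewer = key[1] if isinstance(key, tuple) and len(key) > 1 else ""
        out.append(
            ReviewComparison(
                tray_id=str(tray),
                reviewer_id="" if pd.isna(reviewer) else str(reviewer),
                items=tuple(
                    (str(r.item_id), int(r.primary_pct), int(r.review_pct))
                    for r in grp.itertuples()
                ),
            )
        )
    return out
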