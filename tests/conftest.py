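import datetime

import pytest

from mealcount import (
    FoodDatabase,
    FoodItem,
    MenuCycle,
    NIAF,
    NIAFLine,
    NutrientProfile,
)


@pytest.fixture
def db():
    return FoodDatabase(
        [
            FoodItem(
                "soup",
                "Chicken soup",
                "1 cup",
                NutrientProfile(200, protein_g=10, carb_g=20, micronutrients={"sodium_mg": 800}),
                serving_weight_g=240,
            ),
            FoodItem(
                "bread",
                "Bread roll",
                "1 roll",
                NutrientProfile(300, protein_g=9, fat_sat_g=1, fat_unsat_g=3, carb_g=50),
                serving_weight_g=75,
            ),
            FoodItem(
                "juice",
                "Apple juice",
                "120 mL",
                NutrientProfile(60, carb_g=15, micronutrients={"vitamin_c_mg": 40}),
                serving_weight_g=125,
            ),
        ]
    )


@pytest.fixture
def cycle():
    return MenuCycle(
        "c1",
        {
            (1, "breakfast", "regular"): [("soup", 1), ("bread", 1)],
            (1, "lunch", "regular"): [("soup", 1), ("bread", 2), ("juice", 1)],
        },
    )


def make_niaf(lines, status="generated", **kw):
    defaults = dict(
        tray_id="t1",
        patient_id="p1",
        date=datetime.date(2016, 3, 1),
        meal="breakfast",
        diet_id="regular",
    )
    defaults.update(kw)
    return NIAF(lines=lines, status=status, **defaults)


@pytest.fixture
def recorded_niaf():
    return make_niaf(
        [
            NIAFLine("soup", 1, pct_consumed=50),
            NIAFLine("bread", 1, pct_consumed=100),
        ],
        status="recorded",
    )
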