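"""Synthetic meal trays, consumption, rater estimates and task times.

The evaluation strategies that this module emulates:

* Strategy B (laboratory accuracy/reliability): 3 raters independently
  score the same 30 trays (5 days x 3 meals x 2 diets), blinded to the
  trainer's pre/post food weights — 90 assessments with true values.
* Strategy C (ward reliability): 6 raters, each scoring 5 breakfast, 5
  lunch and 5 dinner trays alongside at least 2 other raters — an
  incomplete rater-by-tray design, 90 assessments.
* Strategy D (time savings): 4 raters x 3 days x 2 sessions, methods
  assigned half-and-half per session with each rater alternating methods
  within a day; per-count task times are lognormal with method, meal, day,
  session and rater effects.

A single master seed spawns independent named substreams (trays,
consumption, raters, timing), so adding a later stage never perturbs the
draws of an earlier one.  Identical configurations reproduce identical
outputs bit for bit.

True consumption of each item is a draw on [0, 100] from a mixture: point
masses at 0 (tray untouched) and 100 (plate cleaned) plus a Beta(1.2, 0.8)
bulk — hospitals see many cleaned plates and some refusals.  Weighed
records are constructed in exact rational arithmetic so that the weighed
percent-consumed formula inverts the draw exactly.  Rater estimates are the
true percentage plus bias and Gaussian noise, clipped to [0, 100] and
rounded to the integer scale the form uses.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .agreement import AssessmentRecord, TimeRecord, MEAL_ORDER
from .food_model import FoodDatabase, FoodItem, NIAF, NIAFLine, NutrientProfile
from .intake_engine import WeighedRecord, meal_report, weighed_meal_energy

__all__ = [
    "SimConfig",
    "TimingSpec",
    "ConsumptionSpec",
    "TrayEnergySpec",
    "SimTray",
    "substreams",
    "simulate_tray",
    "simulate_consumption",
    "simulate_rater_estimates",
    "simulate_strategy_b",
    "simulate_strategy_c",
    "simulate_strategy_d",
]

# rater noise in percent points; default calibrated so that Strategy B paired
# energy differences (rater minus weighed) have SD near 40 kcal, the scale of
# the laboratory agreement study
DEFAULT_RATER_NOISE_SD = 13.0


@dataclass(frozen=True)
class ConsumptionSpec:
    """Distribution of true percent consumed on [0, 100]."""

    alpha: float = 1.2
    beta: float = 0.8
    p_zero: float = 0.05
    p_full: float = 0.15

    def draw(self, rng: np.random.Generator) -> float:
        u = rng.random()
        if u < self.p_zero:
            return 0.0
        if u < self.p_zero + self.p_full:
            return 100.0
        return 100.0 * rng.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class TrayEnergySpec:
    """Total tray energy (kcal) and item count."""

    mean_kcal: float = 550.0
    sd_kcal: float = 120.0
    min_items: int = 3
    max_items: int = 8


@dataclass(frozen=True)
class TimingSpec:
    """Lognormal task-time generator for the time-savings exercise.

    ``tm_median_s`` is the median total time of a traditional-method count;
    ``method_ratio`` multiplies the median for the Multi-Component Method.
    Meal/day/session effects act on the log scale; ``task_props`` split the
    total into the three recorded tasks (pre-meal, post-meal, data entry).
    """

    tm_median_s: float = 1450.0
    method_ratio: float = 0.327
    sigma_log: float = 0.065
    rater_sd_log: float = 0.05
    meal_effects: tuple[float, float, float] = (-0.10, 0.0, 0.10)  # breakfast, lunch, dinner
    day_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    session2_effect: float = 0.0
    task_props: dict = field(
        default_factory=lambda: {"MCM": (0.34, 0.26, 0.40), "TM": (0.30, 0.10, 0.60)}
    )


@dataclass(frozen=True)
class SimConfig:
    """Master configuration for the synthetic evaluation studies."""

    seed: int = 0
    n_trays: int = 30
    n_raters: int = 3
    rater_noise_sd: float = DEFAULT_RATER_NOISE_SD
    rater_bias: float = 0.0
    consumption: ConsumptionSpec = ConsumptionSpec()
    tray_energy: TrayEnergySpec = TrayEnergySpec()
    timing: TimingSpec = TimingSpec()

    def __post_init__(self) -> None:
        if self.rater_noise_sd < 0 or self.timing.sigma_log < 0:
            raise ValueError("noise SDs must be >= 0")


_STREAMS = ("trays", "consumption", "raters", "timing")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent random streams spawned from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


@dataclass
class SimTray:
    """A simulated meal tray with known item weights and nutrient profiles."""

    tray_id: str
    day: int
    meal: str
    diet_id: str
    items: list[FoodItem]

    def database(self) -> FoodDatabase:
        return FoodDatabase(self.items)

    @property
    def total_energy_kcal(self) -> float:
        return float(sum(it.profile.energy_kcal for it in self.items))


def simulate_tray(
    config: SimConfig,
    rng: np.random.Generator,
    tray_id: str = "tray",
    day: int = 1,
    meal: str = "breakfast",
    diet_id: str = "regular",
) -> SimTray:
    spec = config.tray_energy
    k = int(rng.integers(spec.min_items, spec.max_items + 1))
    total = spec.mean_kcal if spec.sd_kcal == 0 else max(50.0, rng.normal(spec.mean_kcal, spec.sd_kcal))
    shares = rng.dirichlet(np.ones(k))
    items = []
    for j in range(k):
        energy = total * shares[j]
        weight = float(rng.uniform(60.0, 300.0))
        protein_frac = rng.uniform(0.08, 0.25)
        fat_frac = rng.uniform(0.15, 0.40)
        carb_frac = max(0.0, 1.0 - protein_frac - fat_frac)
        items.append(
            FoodItem(
                item_id=f"{tray_id}-i{j}",
                description=f"simulated item {j} of {tray_id}",
                serving_label="1 serving",
                profile=NutrientProfile(
                    energy_kcal=energy,
                    protein_g=energy * protein_frac / 4.0,
                    fat_sat_g=energy * fat_frac * 0.4 / 9.0,
                    fat_unsat_g=energy * fat_frac * 0.6 / 9.0,
                    carb_g=energy * carb_frac / 4.0,
                ),
                serving_weight_g=weight,
            )
        )
    return SimTray(tray_id=tray_id, day=day, meal=meal, diet_id=diet_id, items=items)


def simulate_consumption(
    tray: SimTray, config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, float], list[WeighedRecord]]:
    """Draw true percent consumed per item and the matching weighed records.

    Leftover weights are computed in exact rational arithmetic, so
    ``weighed_consumption_pct`` recovers each drawn percentage exactly.
    """
    if not tray.items:
        raise ValueError("tray has no items")
    true_pcts: dict[str, float] = {}
    records = []
    for item in tray.items:
        pct = config.consumption.draw(rng)
        true_pcts[item.item_id] = pct
        orig = Fraction(item.serving_weight_g)
        leftover = orig * (1 - Fraction(pct) / 100)
        records.append(
            WeighedRecord(
                item_id=item.item_id,
                original_weight=orig,
                leftover_weight=leftover,
                tray_id=tray.tray_id,
            )
        )
    return true_pcts, records


def simulate_rater_estimates(
    true_pcts: dict[str, float], config: SimConfig, rng: np.random.Generator
) -> dict[str, int]:
    """One rater's integer percent-consumed estimates for a tray."""
    out = {}
    for item_id, true in true_pcts.items():
        raw = true + config.rater_bias + rng.normal(0.0, config.rater_noise_sd)
        out[item_id] = int(np.rint(np.clip(raw, 0.0, 100.0)))
    return out


def _tray_grid(config: SimConfig, n_diets: int = 2, n_days: int = 5):
    """The laboratory tray grid: days x meals x diets, row-major."""
    grid = []
    for day in range(1, n_days + 1):
        for meal in MEAL_ORDER:
            for d in range(n_diets):
                grid.append((day, meal, f"diet{d + 1}"))
    return grid[: config.n_trays]


def _rater_estimate_energy(tray: SimTray, est_pcts: dict[str, int]) -> float:
    """Run one rater's percentages through the calorie-count engine."""
    niaf = NIAF(
        tray_id=tray.tray_id,
        patient_id="sim",
        date=_dt.date(2016, 1, tray.day),
        meal=tray.meal,
        diet_id=tray.diet_id,
        lines=[
            NIAFLine(item_id=it.item_id, servings=1, pct_consumed=est_pcts[it.item_id])
            for it in tray.items
        ],
        status="recorded",
    )
    return meal_report(niaf, tray.database()).energy_consumed_kcal


def _simulate_tray_set(config: SimConfig, streams) -> list[tuple[SimTray, dict, float]]:
    """Trays plus true pcts and weighed (true) energy for the lab grid."""
    out = []
    for t, (day, meal, diet) in enumerate(_tray_grid(config)):
        tray = simulate_tray(
            config, streams["trays"], tray_id=f"t{t:02d}", day=day, meal=meal, diet_id=diet
        )
        true_pcts, weighed = simulate_consumption(tray, config, streams["consumption"])
        true_energy = float(weighed_meal_energy(weighed, tray.database()))
        out.append((tray, true_pcts, true_energy))
    return out


def simulate_strategy_b(config: SimConfig) -> list[AssessmentRecord]:
    """Complete design: every rater scores every tray; true values attached."""
    streams = substreams(config.seed)
    trays = _simulate_tray_set(config, streams)
    records = []
    for rater in range(1, config.n_raters + 1):
        for tray, true_pcts, true_energy in trays:
            est_pcts = simulate_rater_estimates(true_pcts, config, streams["raters"])
            est_energy = _rater_estimate_energy(tray, est_pcts)
            records.append(
                AssessmentRecord(
                    tray_id=tray.tray_id,
                    rater_id=f"R{rater}",
                    day=tray.day,
                    meal=tray.meal,
                    estimate=est_energy,
                    true_value=true_energy,
                )
            )
    return records


def simulate_strategy_c(config: SimConfig, n_raters: int = 6, raters_per_tray: int = 3):
    """Incomplete ward design: rotating trios of raters per tray.

    Each (day, meal) slot has two trays; the raters are split into two
    groups of ``raters_per_tray`` (rotated by a seeded permutation each
    day), one group per tray.  With the default 30 trays this gives each of
    the 6 raters exactly 15 assessments and each tray 3 raters.
    """
    if n_raters != 2 * raters_per_tray:
        raise ValueError("design infeasible: need n_raters == 2 * raters_per_tray")
    streams = substreams(config.seed)
    trays = _simulate_tray_set(config, streams)
    records = []
    rater_ids = [f"R{r}" for r in range(1, n_raters + 1)]
    day_perm: dict[int, list[str]] = {}
    for tray, true_pcts, true_energy in trays:
        if tray.day not in day_perm:
            day_perm[tray.day] = list(streams["raters"].permutation(rater_ids))
        perm = day_perm[tray.day]
        # diet1 tray -> first half of the day's rater permutation, diet2 -> second
        group = perm[:raters_per_tray] if tray.diet_id == "diet1" else perm[raters_per_tray:]
        for rater in group:
            est_pcts = simulate_rater_estimates(true_pcts, config, streams["raters"])
            est_energy = _rater_estimate_energy(tray, est_pcts)
            records.append(
                AssessmentRecord(
                    tray_id=tray.tray_id,
                    rater_id=rater,
                    day=tray.day,
                    meal=tray.meal,
                    estimate=est_energy,
                    true_value=true_energy,
                )
            )
    return records


def _draw_meal_schedule(rng: np.random.Generator, n_days: int) -> list[list[str]]:
    """Two distinct meals per day, redrawn until meal effects are estimable.

    A random schedule can leave the meal factor collinear with day and
    session (e.g. every day pairing the same meals in the same order); such
    draws are rejected, mirroring how the real exercise spread meals over
    the grid.
    """
    for _ in range(100):
        schedule = [list(rng.choice(MEAL_ORDER, size=2, replace=False)) for _ in range(n_days)]
        cells = [
            (day, session, schedule[day][session])
            for day in range(n_days)
            for session in (0, 1)
        ]
        meals_used = [m for m in MEAL_ORDER if any(c[2] == m for c in cells)]
        X = np.column_stack(
            [np.ones(len(cells))]
            + [[1.0 if c[0] == d else 0.0 for c in cells] for d in range(1, n_days)]
            + [[1.0 if c[1] == 1 else 0.0 for c in cells]]
            + [[1.0 if c[2] == m else 0.0 for c in cells] for m in meals_used[1:]]
        )
        if np.linalg.matrix_rank(X) == X.shape[1]:
            return schedule
    raise ValueError("design infeasible: could not draw an estimable meal schedule")


def simulate_strategy_d(config: SimConfig, n_raters: int = 4, n_days: int = 3) -> list[TimeRecord]:
    """Time-savings design: alternating balanced method assignment.

    Each day has two sessions on different meals; within a day each rater
    uses each method once, and each session is half MCM / half TM.
    """
    if n_raters % 2 != 0:
        raise ValueError("design infeasible: need an even number of raters")
    spec = config.timing
    rng = substreams(config.seed)["timing"]
    rater_ids = [f"R{r}" for r in range(1, n_raters + 1)]
    rater_effects = {a: rng.normal(0.0, spec.rater_sd_log) for a in rater_ids}
    meal_schedule = _draw_meal_schedule(rng, n_days)
    records = []
    for day in range(1, n_days + 1):
        meals = meal_schedule[day - 1]
        mcm_first = set(rng.choice(rater_ids, size=n_raters // 2, replace=False))
        for session in (1, 2):
            meal = meals[session - 1]
            for rater in rater_ids:
                mcm = (rater in mcm_first) == (session == 1)
                mu = (
                    math.log(spec.tm_median_s)
                    + (math.log(spec.method_ratio) if mcm else 0.0)
                    + spec.meal_effects[MEAL_ORDER.index(meal)]
                    + (spec.day_effects[day - 1] if day - 1 < len(spec.day_effects) else 0.0)
                    + (spec.session2_effect if session == 2 else 0.0)
                    + rater_effects[rater]
                )
                total = math.exp(mu + rng.normal(0.0, spec.sigma_log))
                p = spec.task_props["MCM" if mcm else "TM"]
                records.append(
                    TimeRecord(
                        rater_id=rater,
                        method="MCM" if mcm else "TM",
                        day=day,
                        session=session,
                        meal=meal,
                        t_pre=total * p[0],
                        t_post=total * p[1],
                        t_entry=total * (1.0 - p[0] - p[1]),
                    )
                )
    return records
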