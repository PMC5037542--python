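"""Synthetic study generators: determinism, design shapes, inverse identities."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from mealcount import SimConfig, weighed_consumption_pct
from mealcount.simulate import (
    ConsumptionSpec,
    TimingSpec,
    TrayEnergySpec,
    simulate_consumption,
    simulate_rater_estimates,
    simulate_strategy_b,
    simulate_strategy_c,
    simulate_strategy_d,
    simulate_tray,
    substreams,
)


class TestTray:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_tray(SimConfig(seed=5), substreams(5)["trays"])
        b = simulate_tray(SimConfig(seed=5), substreams(5)["trays"])
        assert [(i.item_id, i.profile.energy_kcal, i.serving_weight_g) for i in a.items] == [
            (i.item_id, i.profile.energy_kcal, i.serving_weight_g) for i in b.items
        ]

    def test_degenerate_energy_distribution(self):
        cfg = SimConfig(seed=1, tray_energy=TrayEnergySpec(mean_kcal=500, sd_kcal=0))
        for s in range(5):
            tray = simulate_tray(cfg, substreams(s)["trays"])
            assert tray.total_energy_kcal == pytest.approx(500)

    def test_item_count_in_range(self):
        rng = substreams(9)["trays"]
        for _ in range(20):
            tray = simulate_tray(SimConfig(seed=9), rng)
            assert 3 <= len(tray.items) <= 8


class TestConsumption:
    def test_degenerate_full_consumption(self):
        cfg = SimConfig(seed=2, consumption=ConsumptionSpec(p_zero=0, p_full=1))
        tray = simulate_tray(cfg, substreams(2)["trays"])
        pcts, recs = simulate_consumption(tray, cfg, substreams(2)["consumption"])
        assert all(p == 100 for p in pcts.values())
        assert all(r.leftover_weight == 0 for r in recs)

    def test_degenerate_zero_consumption(self):
        cfg = SimConfig(seed=2, consumption=ConsumptionSpec(p_zero=1, p_full=0))
        tray = simulate_tray(cfg, substreams(2)["trays"])
        pcts, recs = simulate_consumption(tray, cfg, substreams(2)["consumption"])
        assert all(p == 0 for p in pcts.values())
        assert all(r.leftover_weight == r.original_weight for r in recs)

    def test_weighed_pct_inverts_draw_exactly(self):
        cfg = SimConfig(seed=3)
        tray = simulate_tray(cfg, substreams(3)["trays"])
        pcts, recs = simulate_consumption(tray, cfg, substreams(3)["consumption"])
        for rec in recs:
            assert weighed_consumption_pct(rec) == Fraction(pcts[rec.item_id])


class TestRaterEstimates:
    def test_noise_free_equals_rounded_truth(self):
        cfg = SimConfig(seed=4, rater_noise_sd=0)
        true = {"a": 33.4, "b": 66.6, "c": 100.0}
        est = simulate_rater_estimates(true, cfg, substreams(4)["raters"])
        assert est == {"a": 33, "b": 67, "c": 100}

    def test_bias_shifts_mean(self):
        cfg = SimConfig(seed=4, rater_noise_sd=5, rater_bias=10)
        rng = substreams(4)["raters"]
        true = {f"i{k}": 50.0 for k in range(2000)}
        est = simulate_rater_estimates(true, cfg, rng)
        assert np.mean(list(est.values())) == pytest.approx(60, abs=1)

    def test_clipping_bounds(self):
        cfg = SimConfig(seed=4, rater_noise_sd=30)
        est = simulate_rater_estimates({f"i{k}": 100.0 for k in range(200)}, cfg, substreams(4)["raters"])
        assert all(0 <= v <= 100 for v in est.values())


class TestStrategyB:
    def test_shape_and_grid(self):
        recs = simulate_strategy_b(SimConfig(seed=6))
        assert len(recs) == 90
        assert len({r.tray_id for r in recs}) == 30
        assert {r.day for r in recs} == set(range(1, 6))
        assert Counter(r.meal for r in recs) == {"breakfast": 30, "lunch": 30, "dinner": 30}

    def test_reproducible(self):
        assert simulate_strategy_b(SimConfig(seed=6)) == simulate_strategy_b(SimConfig(seed=6))

    def test_zero_noise_matches_truth_to_rounding(self):
        from mealcount import bland_altman

        recs = simulate_strategy_b(SimConfig(seed=7, rater_noise_sd=0))
        r = bland_altman([(x.estimate, x.true_value) for x in recs])
        # only integer-rounding error remains: well under 1% of a meal
        assert abs(r.mean_diff) < 3 and r.sd_diff < 5


class TestStrategyC:
    def test_incomplete_design_shape(self):
        recs = simulate_strategy_c(SimConfig(seed=8, n_raters=6))
        assert len(recs) == 90
        assert Counter(r.rater_id for r in recs) == {f"R{i}": 15 for i in range(1, 7)}
        per_tray = Counter(r.tray_id for r in recs)
        assert all(v >= 3 for v in per_tray.values())

    def test_infeasible_configuration(self):
        with pytest.raises(ValueError, match="design infeasible"):
            simulate_strategy_c(SimConfig(seed=8), n_raters=5)

    def test_high_signal_low_noise_gives_high_icc(self):
        from mealcount import ICCModel

        cfg = SimConfig(seed=9, n_raters=6, rater_noise_sd=1.0,
                        tray_energy=TrayEnergySpec(mean_kcal=600, sd_kcal=250))
        res = ICCModel(simulate_strategy_c(cfg)).fit(ci_method=None)
        assert res.icc > 0.95 and res.design == "incomplete"


class TestStrategyD:
    def test_design_constraints_hold(self):
        recs = simulate_strategy_d(SimConfig(seed=10))
        assert len(recs) == 24
        for day in (1, 2, 3):
            for session in (1, 2):
                sess = [r for r in recs if r.day == day and r.session == session]
                assert len(sess) == 4
                assert sum(r.method == "MCM" for r in sess) == 2
                assert len({r.meal for r in sess}) == 1
            day_meals = {r.meal for r in recs if r.day == day}
            assert len(day_meals) == 2  # different meal each session
            for rater in {r.rater_id for r in recs}:
                assert {r.method for r in recs if r.day == day and r.rater_id == rater} == {
                    "MCM",
                    "TM",
                }

    def test_total_is_task_sum(self):
        for r in simulate_strategy_d(SimConfig(seed=11)):
            assert r.total == pytest.approx(r.t_pre + r.t_post + r.t_entry)

    def test_identical_methods_ci_covers_100(self):
        """With identical timing for both methods, the CI covers 100% in the
        vast majority of runs (a 95% interval can legitimately miss)."""
        from mealcount import TimeEfficiencyModel

        covered = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, timing=TimingSpec(method_ratio=1.0))
            res = TimeEfficiencyModel(simulate_strategy_d(cfg)).fit()
            covered += res.ci[0] <= 100 <= res.ci[1]
        assert covered >= 8

    def test_meal_effect_ordering_recovered(self):
        from mealcount import TimeEfficiencyModel

        cfg = SimConfig(seed=13, timing=TimingSpec(sigma_log=0.03))
        # pool several days to see all three meals
        recs = simulate_strategy_d(cfg, n_days=6)
        res = TimeEfficiencyModel(recs).fit()
        effects = res.meal_effects()
        assert effects["breakfast"] < effects["lunch"] < effects["dinner"]


class TestStreams:
    def test_substreams_independent_of_stage_order(self):
        a = substreams(14)
        b = substreams(14)
        assert a["timing"].normal() == b["timing"].normal()
        b["trays"].normal()  # consuming one stream leaves the others untouched
        assert a["raters"].normal() == b["raters"].normal()
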