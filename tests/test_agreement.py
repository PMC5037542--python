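"""Agreement statistics: Bland-Altman, accuracy, ICC, time efficiency, label repair."""

import math

import numpy as np
import pytest

from mealcount import (
    AccuracyModel,
    AssessmentRecord,
    ICCModel,
    TimeEfficiencyModel,
    TimeRecord,
    bland_altman,
    load_table2_fixture,
    resolve_method_labels,
)
from mealcount.varcomp import RandomInterceptModel


def _assessments(estimates, truths=None, trays=None, raters=None, meals=None, days=None):
    n = len(estimates)
    return [
        AssessmentRecord(
            tray_id=trays[i] if trays else f"t{i % 10}",
            rater_id=raters[i] if raters else f"r{i % 3}",
            day=days[i] if days else 1 + (i % 5),
            meal=meals[i] if meals else ("breakfast", "lunch", "dinner")[i % 3],
            estimate=estimates[i],
            true_value=truths[i] if truths is not None else None,
        )
        for i in range(n)
    ]


class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman([(100, 100)] * 5)
        assert r.mean_diff == 0 and r.sd_diff == 0
        assert r.loa == (0, 0) and r.n_outside_loa == 0
        assert r.corr_diff_vs_mean is None

    def test_three_pair_hand_computation(self):
        # diffs {3, -3, 0}: mean 0, sample SD 3, LoA = 0 +/- 2*3
        r = bland_altman([(103, 100), (97, 100), (100, 100)])
        assert r.mean_diff == pytest.approx(0)
        assert r.sd_diff == pytest.approx(3)
        assert r.loa == pytest.approx((-6, 6))

    def test_mean_diff_identity_and_negation_symmetry(self):
        rng = np.random.default_rng(11)
        est = rng.uniform(200, 800, 40)
        ref = est + rng.normal(0, 30, 40)
        r = bland_altman(np.column_stack([est, ref]))
        assert r.mean_diff == pytest.approx(est.mean() - ref.mean())
        assert r.loa[0] + r.loa[1] == pytest.approx(2 * r.mean_diff)
        flipped = bland_altman(np.column_stack([ref, est]))
        assert flipped.mean_diff == pytest.approx(-r.mean_diff)
        assert flipped.loa == pytest.approx((-r.loa[1], -r.loa[0]))

    def test_ci_uses_t_distribution(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        est = rng.normal(500, 50, 12)
        ref = est + rng.normal(0, 20, 12)
        r = bland_altman(np.column_stack([est, ref]))
        half = stats.t.ppf(0.975, 11) * r.sd_diff / math.sqrt(12)
        assert r.ci_mean_diff == pytest.approx((r.mean_diff - half, r.mean_diff + half))

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError, match="insufficient pairs"):
            bland_altman([(1, 2), (3, 4)])

    def test_loa_halfwidth_recovery_normal_differences(self):
        """Differences ~ N(0, 40^2) at n=90 give LoA half-width near 80 kcal."""
        rng = np.random.default_rng(2016)
        halves = []
        for _ in range(100):
            ref = rng.uniform(200, 900, 90)
            est = ref + rng.normal(0, 40, 90)
            r = bland_altman(np.column_stack([est, ref]))
            halves.append((r.loa[1] - r.loa[0]) / 2)
        assert np.mean(halves) == pytest.approx(80, abs=10)


class TestAccuracyModel:
    def test_identity_data(self):
        truths = list(np.linspace(300, 900, 30)) * 3
        recs = _assessments(truths, truths, trays=[f"t{i % 30}" for i in range(90)])
        fit = AccuracyModel(recs).fit()
        assert fit.slope["estimate"] == pytest.approx(1)
        assert fit.intercept["estimate"] == pytest.approx(0, abs=1e-8)
        assert fit.slope["p"] == pytest.approx(1) and fit.intercept["p"] == pytest.approx(1)

    def test_slope_two_detected(self):
        """y = 2x + small noise: slope near 2, test vs 1 rejects; OLS-on-tray-means oracle."""
        rng = np.random.default_rng(9)
        truths = np.repeat(rng.uniform(300, 900, 30), 3)
        est = 2 * truths + rng.normal(0, 10, 90)
        recs = _assessments(est, truths, trays=[f"t{i // 3}" for i in range(90)])
        fit = AccuracyModel(recs).fit()
        assert fit.slope["estimate"] == pytest.approx(2, abs=0.02)
        assert fit.slope["p"] < 1e-6
        # oracle: OLS on tray means (equivalent fixed-effect estimate, balanced design)
        tm_true = truths.reshape(30, 3).mean(1)
        tm_est = est.reshape(30, 3).mean(1)
        beta = np.polyfit(tm_true, tm_est, 1)
        assert fit.slope["estimate"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.intercept["estimate"] == pytest.approx(beta[1], abs=1e-4)

    def test_lr_test_flag(self):
        rng = np.random.default_rng(10)
        truths = np.repeat(rng.uniform(300, 900, 20), 2)
        est = truths + rng.normal(0, 30, 40)
        recs = _assessments(est, truths, trays=[f"t{i // 2}" for i in range(40)])
        wald = AccuracyModel(recs).fit(test="wald")
        lr = AccuracyModel(recs).fit(test="lr")
        # same point estimates, broadly agreeing p-values for a true null
        assert lr.slope["estimate"] == wald.slope["estimate"]
        assert lr.slope["p"] > 0.05 and wald.slope["p"] > 0.05

    def test_constant_truth_unidentifiable(self):
        recs = _assessments([500.0] * 6, [400.0] * 6, trays=[f"t{i // 3}" for i in range(6)])
        with pytest.raises(ValueError, match="slope unidentifiable"):
            AccuracyModel(recs)

    def test_requires_true_values(self):
        with pytest.raises(ValueError, match="true"):
            AccuracyModel(_assessments([1.0, 2.0, 3.0]))


class TestICCModel:
    def _balanced(self, tray_sd, noise_sd, seed, n_trays=30, n_raters=3):
        rng = np.random.default_rng(seed)
        tray_means = 600 + rng.normal(0, tray_sd, n_trays)
        recs = []
        for t in range(n_trays):
            for r in range(n_raters):
                recs.append(
                    AssessmentRecord(
                        tray_id=f"t{t}",
                        rater_id=f"r{r}",
                        day=1 + t % 5,
                        meal=("breakfast", "lunch", "dinner")[t % 3],
                        estimate=max(0.0, tray_means[t] + rng.normal(0, noise_sd)),
                    )
                )
        return recs

    def test_perfect_agreement(self):
        recs = self._balanced(tray_sd=100, noise_sd=0, seed=1)
        res = ICCModel(recs).fit(ci_method=None)
        assert res.icc == pytest.approx(1)

    def test_no_tray_variance_gives_icc_near_zero(self):
        recs = self._balanced(tray_sd=0, noise_sd=50, seed=2)
        res = ICCModel(recs).fit(ci_method=None)
        assert res.icc < 0.15

    def test_equals_anova_estimator_balanced_no_covariates(self):
        """Intercept-only REML matches the one-way ANOVA estimator to 6 decimals."""
        recs = self._balanced(tray_sd=100, noise_sd=33, seed=3)
        res = ICCModel(recs, covariates=()).fit(ci_method=None)
        y = np.array([r.estimate for r in recs]).reshape(30, 3)
        k, n = y.shape
        msb = n * ((y.mean(1) - y.mean()) ** 2).sum() / (k - 1)
        msw = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (k * (n - 1))
        vg = max((msb - msw) / n, 0)
        assert res.icc == pytest.approx(vg / (vg + msw), abs=1e-6)

    def test_bootstrap_ci_contains_point_and_is_seeded(self):
        recs = self._balanced(tray_sd=100, noise_sd=33, seed=4)
        a = ICCModel(recs).fit(n_boot=80, seed=5)
        b = ICCModel(recs).fit(n_boot=80, seed=5)
        assert a.ci == b.ci
        assert a.ci[0] <= a.icc <= a.ci[1]
        assert 0 <= a.ci[0] <= a.ci[1] <= 1

    def test_incomplete_design_detected_and_fit(self):
        recs = self._balanced(tray_sd=100, noise_sd=20, seed=6)
        thinned = [r for i, r in enumerate(recs) if i % 9 != 0]
        res = ICCModel(thinned).fit(ci_method=None)
        assert res.design == "incomplete"
        assert res.icc > 0.9

    def test_unidentifiable_when_all_trays_single_rated(self):
        recs = self._balanced(tray_sd=10, noise_sd=10, seed=7, n_raters=1)
        with pytest.raises(ValueError, match="reliability unidentifiable"):
            ICCModel(recs)


def _timerec(rater, method, day, session, meal, total, props=(0.3, 0.2, 0.5)):
    return TimeRecord(
        rater_id=rater,
        method=method,
        day=day,
        session=session,
        meal=meal,
        t_pre=total * props[0],
        t_post=total * props[1],
        t_entry=total * props[2],
    )


def _balanced_times(ratio=0.5, base=1200.0):
    """2 raters x 3 days x 2 sessions, methods alternating and balanced."""
    recs = []
    for day, meals in [
        (1, ("breakfast", "lunch")),
        (2, ("lunch", "dinner")),
        (3, ("dinner", "breakfast")),
    ]:
        for session, meal in zip((1, 2), meals):
            for i, rater in enumerate(("A", "B")):
                mcm = (i == 0) == (session == 1)
                total = base * (1.1 if meal == "dinner" else 1.0) * (ratio if mcm else 1.0)
                recs.append(_timerec(rater, "MCM" if mcm else "TM", day, session, meal, total))
    return recs


class TestTimeEfficiencyModel:
    def test_equal_times_give_ratio_100(self):
        recs = _balanced_times(ratio=1.0)
        res = TimeEfficiencyModel(recs).fit()
        assert res.ratio_pct == pytest.approx(100)
        assert res.saving_pct == pytest.approx(0)

    def test_halved_times_give_ratio_50(self):
        res = TimeEfficiencyModel(_balanced_times(ratio=0.5)).fit()
        assert res.ratio_pct == pytest.approx(50)

    def test_scale_invariance_and_geometric_mean_identity(self):
        recs = load_table2_fixture()
        corrected, _ = resolve_method_labels(recs)
        res = TimeEfficiencyModel(corrected).fit()
        scaled = [
            _timerec(r.rater_id, r.method, r.day, r.session, r.meal, 3.7 * r.total)
            for r in corrected
        ]
        res_scaled = TimeEfficiencyModel(scaled).fit()
        assert res_scaled.ratio_pct == pytest.approx(res.ratio_pct, rel=1e-9)
        # fully balanced design: contrast equals the geometric-mean ratio exactly
        mcm = [math.log(r.total) for r in corrected if r.method == "MCM"]
        tm = [math.log(r.total) for r in corrected if r.method == "TM"]
        gm_ratio = 100 * math.exp(np.mean(mcm) - np.mean(tm))
        assert res.ratio_pct == pytest.approx(gm_ratio, rel=1e-9)

    def test_one_method_absent(self):
        recs = [r for r in _balanced_times() if r.method == "MCM"]
        with pytest.raises(ValueError, match="contrast unidentifiable"):
            TimeEfficiencyModel(recs)


class TestResolveMethodLabels:
    def test_consistent_labels_untouched(self):
        recs = _balanced_times()
        corrected, rep = resolve_method_labels(recs)
        assert rep.n_flips == 0 and corrected == recs

    def test_single_forced_flip_on_toy_grid(self):
        """One rater fails to alternate; exactly that label is flipped."""
        recs = [
            _timerec("A", "MCM", 1, 1, "lunch", 400),
            _timerec("B", "TM", 1, 1, "lunch", 1300),
            _timerec("A", "TM", 1, 2, "dinner", 1200),
            _timerec("B", "TM", 1, 2, "dinner", 390),  # should be MCM
        ]
        corrected, rep = resolve_method_labels(recs)
        assert rep.flips == [("B", 1, 2, "TM", "MCM")]
        assert corrected[3].method == "MCM"

    def test_printed_table_anomalies_repaired(self):
        """The printed assignment matrix violates the half-and-half rule in
        day 1 session 2 and per-rater alternation throughout day 3."""
        recs = load_table2_fixture()
        corrected, rep = resolve_method_labels(recs)
        flipped = {(f[0], f[1], f[2]) for f in rep.flips}
        assert ("4", 1, 2) in flipped
        assert {f for f in flipped if f[1] == 3} == {("1", 3, 1), ("2", 3, 1), ("3", 3, 1), ("4", 3, 1)}
        assert rep.n_flips == 5
        # corrected set satisfies both design constraints
        for day in (1, 2, 3):
            for session in (1, 2):
                sess = [r for r in corrected if r.day == day and r.session == session]
                assert sum(r.method == "MCM" for r in sess) == len(sess) // 2
            for rater in "1234":
                methods = {r.method for r in corrected if r.day == day and r.rater_id == rater}
                assert methods == {"MCM", "TM"}

    def test_duplicate_slot_is_inconsistent(self):
        recs = _balanced_times()
        with pytest.raises(ValueError, match="inconsistent design"):
            resolve_method_labels(recs + [recs[0]])
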