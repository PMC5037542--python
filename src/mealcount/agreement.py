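"""Method-agreement and efficiency statistics for calorie-count evaluation.

Four analyses, each exposed in the Model -> ``fit()`` -> Results idiom:

* :func:`bland_altman` — agreement between rater and weighed-food energy
  estimates: mean difference, its t-based CI, and limits of agreement
  defined literally as mean +/- 2 SD of the paired differences.
* :class:`AccuracyModel` — mixed-model regression of rater estimates on
  weighed true values (random tray intercept for the clustering of raters
  within tray), with Wald tests of intercept = 0 and slope = 1.
* :class:`ICCModel` — inter-rater reliability as the intraclass correlation
  var(tray) / (var(tray) + var(residual)) from a REML mixed model with
  day/meal fixed covariates; handles incomplete rater-by-tray designs.
  CI by seeded parametric bootstrap.
* :class:`TimeEfficiencyModel` — mixed model on log total task time with
  fixed method/day/session/meal effects and a random rater intercept; the
  anti-log of the method contrast is the percent of traditional-method time
  the Multi-Component Method requires.

:func:`resolve_method_labels` repairs printed method-assignment labels that
violate the stated design (half MCM / half TM per session; each rater
alternating methods between a day's two sessions).  The repair is an
explicit, logged operation — analyses can be run on printed or corrected
labels, never silently on a repaired set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .varcomp import RandomInterceptModel, RandomInterceptResults

__all__ = [
    "AssessmentRecord",
    "TimeRecord",
    "BAResult",
    "bland_altman",
    "AccuracyModel",
    "AccuracyFit",
    "ICCModel",
    "ICCResult",
    "TimeEfficiencyModel",
    "EfficiencyResult",
    "resolve_method_labels",
    "FlipReport",
]

MEAL_ORDER = ("breakfast", "lunch", "dinner")
METHODS = ("MCM", "TM")


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class AssessmentRecord:
    """One (tray, rater) energy estimate, optionally paired with the weighed value."""

    tray_id: str
    rater_id: str
    day: int
    meal: str
    estimate: float
    true_value: float | None = None

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ValueError("estimate must be >= 0 kcal")
        if self.true_value is not None and self.true_value < 0:
            raise ValueError("true_value must be >= 0 kcal")
        if self.meal not in MEAL_ORDER:
            raise ValueError(f"unknown meal {self.meal!r}")


@dataclass(frozen=True)
class TimeRecord:
    """One rater-session calorie count: method label plus the three task times."""

    rater_id: str
    method: str
    day: int
    session: int
    meal: str
    t_pre: float
    t_post: float
    t_entry: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        if self.meal not in MEAL_ORDER:
            raise ValueError(f"unknown meal {self.meal!r}")
        for t in (self.t_pre, self.t_post, self.t_entry):
            if not t > 0:
                raise ValueError("task times must be > 0 seconds")

    @property
    def total(self) -> float:
        return self.t_pre + self.t_post + self.t_entry


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BAResult:
    """Bland-Altman agreement between two estimates of the same quantity."""

    n: int
    mean_diff: float
    sd_diff: float
    ci_mean_diff: tuple[float, float]
    loa: tuple[float, float]
    n_outside_loa: int
    corr_diff_vs_mean: tuple[float, float] | None  # (r, p); None when undefined
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)

    def summary(self) -> str:
        r = (
            f"r = {self.corr_diff_vs_mean[0]:.3f} (p = {self.corr_diff_vs_mean[1]:.3f})"
            if self.corr_diff_vs_mean is not None
            else "r undefined (zero variance)"
        )
        return (
            f"Bland-Altman agreement (n = {self.n})\n"
            f"  mean difference: {self.mean_diff:.2f} kcal "
            f"(95% CI {self.ci_mean_diff[0]:.2f} to {self.ci_mean_diff[1]:.2f})\n"
            f"  limits of agreement (mean +/- 2 SD): "
            f"{self.loa[0]:.2f} to {self.loa[1]:.2f} kcal\n"
            f"  observations outside limits: {self.n_outside_loa}\n"
            f"  difference vs mean: {r}"
        )

    def plot(self, ax=None):
        """Difference-vs-mean scatter with the mean line and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.means, self.differences, s=18, alpha=0.8)
        ax.axhline(self.mean_diff, color="k")
        for y in self.loa:
            ax.axhline(y, color="k", linestyle=":")
        ax.set_xlabel("mean of the two estimates (kcal)")
        ax.set_ylabel("difference between estimates (kcal)")
        return ax

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "ci_mean_diff": list(self.ci_mean_diff),
            "loa": list(self.loa),
            "n_outside_loa": self.n_outside_loa,
            "corr_diff_vs_mean": (
                list(self.corr_diff_vs_mean) if self.corr_diff_vs_mean is not None else None
            ),
        }


def bland_altman(pairs, loa_sd_multiple: float = 2.0, alpha: float = 0.05) -> BAResult:
    """Bland-Altman analysis of paired (estimate, reference) measurements.

    Differences are estimate minus reference.  The SD uses the n-1
    denominator; the CI of the mean difference uses the t distribution; the
    limits of agreement are mean +/- ``loa_sd_multiple`` x SD (default the
    literal 2).  Clustering of pairs (e.g. raters within tray) is ignored.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (estimate, reference) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("insufficient pairs: need at least 3")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    half = tcrit * sd_diff / math.sqrt(n)
    loa = (mean_diff - loa_sd_multiple * sd_diff, mean_diff + loa_sd_multiple * sd_diff)
    outside = int(np.sum((diffs < loa[0]) | (diffs > loa[1])))
    if sd_diff == 0 or means.std() == 0:
        corr = None
    else:
        r, p = stats.pearsonr(diffs, means)
        corr = (float(r), float(p))
    return BAResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        ci_mean_diff=(mean_diff - half, mean_diff + half),
        loa=loa,
        n_outside_loa=outside,
        corr_diff_vs_mean=corr,
        differences=diffs,
        means=means,
    )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _dummies(values, levels, prefix) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies with the first level as reference."""
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append(np.asarray([1.0 if v == lev else 0.0 for v in values]))
        names.append(f"{prefix}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(list(values)), 0)), []


# ---------------------------------------------------------------------------
# accuracy


@dataclass
class AccuracyFit:
    """Regression of rater estimates on weighed true values.

    Perfect accuracy corresponds to the identity line: intercept 0, slope 1.
    """

    intercept: dict
    slope: dict
    var_tray: float
    var_resid: float
    n: int
    n_trays: int
    test: str
    results: RandomInterceptResults = field(repr=False)

    def summary(self) -> str:
        i, s = self.intercept, self.slope
        return (
            f"Accuracy mixed model (n = {self.n}, trays = {self.n_trays}, "
            f"random tray intercept, REML)\n"
            f"  intercept: {i['estimate']:.2f} kcal "
            f"(95% CI {i['ci'][0]:.2f} to {i['ci'][1]:.2f}), p vs 0 = {i['p']:.3f}\n"
            f"  slope:     {s['estimate']:.3f} "
            f"(95% CI {s['ci'][0]:.3f} to {s['ci'][1]:.3f}), p vs 1 = {s['p']:.3f}\n"
            f"  var(tray) = {self.var_tray:.1f}, var(resid) = {self.var_resid:.1f}"
        )

    def to_dict(self) -> dict:
        pick = lambda d: {"estimate": d["estimate"], "ci": list(d["ci"]), "p": d["p"]}
        return {
            "model": "estimate ~ 1 + true_value + (1 | tray), REML",
            "test": self.test,
            "intercept": pick(self.intercept),
            "slope": pick(self.slope),
            "var_tray": self.var_tray,
            "var_resid": self.var_resid,
            "n": self.n,
            "n_trays": self.n_trays,
        }


class AccuracyModel:
    """Mixed model ``estimate ~ true_value`` with a random tray intercept.

    The tray intercept accounts for the clustering of raters within tray.
    """

    def __init__(self, records: list[AssessmentRecord]):
        recs = [r for r in records]
        if any(r.true_value is None for r in recs):
            raise ValueError("accuracy analysis requires a true (weighed) value on every record")
        trays = {r.tray_id for r in recs}
        if len(trays) < 2:
            raise ValueError("need at least 2 trays")
        truths = {r.true_value for r in recs}
        if len(truths) < 2:
            raise ValueError("slope unidentifiable: all true values are equal")
        self.records = recs

    @classmethod
    def from_dataframe(cls, df) -> "AccuracyModel":
        return cls(_records_from_frame(df))

    def fit(self, test: str = "wald", alpha: float = 0.05) -> AccuracyFit:
        """Fit by REML; ``test`` is 'wald' (default) or 'lr' (ML likelihood ratio)."""
        y = np.array([r.estimate for r in self.records])
        x = np.array([r.true_value for r in self.records])
        X = np.column_stack([np.ones_like(x), x])
        groups = np.array([r.tray_id for r in self.records])
        res = RandomInterceptModel(y, X, groups, ["intercept", "true_value"]).fit()
        intercept = res.t_test_param("intercept", value=0.0, alpha=alpha)
        slope = res.t_test_param("true_value", value=1.0, alpha=alpha)
        if test == "lr":
            intercept["p"] = _lr_pvalue(y, X, groups, drop="intercept")
            slope["p"] = _lr_pvalue(y, X, groups, drop="slope1")
        elif test != "wald":
            raise ValueError("test must be 'wald' or 'lr'")
        return AccuracyFit(
            intercept=intercept,
            slope=slope,
            var_tray=res.sigma2_group,
            var_resid=res.sigma2_resid,
            n=len(self.records),
            n_trays=len(set(groups)),
            test=test,
            results=res,
        )


def _lr_pvalue(y, X, groups, drop: str) -> float:
    """Likelihood-ratio p (ML) for intercept = 0 or slope = 1 in y ~ 1 + x."""
    full = RandomInterceptModel(y, X, groups).fit_ml()
    if drop == "intercept":
        red = RandomInterceptModel(y, X[:, 1:], groups).fit_ml()
    else:  # slope fixed at 1: regress y - x on the intercept only
        red = RandomInterceptModel(y - X[:, 1], X[:, :1], groups).fit_ml()
    lr = max(red.neg2_loglik - full.neg2_loglik, 0.0)
    return float(stats.chi2.sf(lr, df=1))


# ---------------------------------------------------------------------------
# ICC


@dataclass
class ICCResult:
    """Intraclass correlation from REML variance components."""

    icc: float
    ci: tuple[float, float] | None
    var_tray: float
    var_resid: float
    design: str  # "complete" or "incomplete"
    n: int
    n_trays: int
    n_raters: int
    ci_method: str | None = None
    n_boot: int = 0
    seed: int | None = None
    results: RandomInterceptResults | None = field(default=None, repr=False)

    def summary(self) -> str:
        ci = (
            f"95% CI {self.ci[0]:.3f} to {self.ci[1]:.3f} ({self.ci_method})"
            if self.ci is not None
            else "no CI computed"
        )
        return (
            f"Inter-rater reliability ({self.design} design, n = {self.n}, "
            f"{self.n_trays} trays, {self.n_raters} raters)\n"
            f"  ICC = {self.icc:.3f} ({ci})\n"
            f"  var(tray) = {self.var_tray:.1f}, var(resid) = {self.var_resid:.1f}"
        )

    def to_dict(self) -> dict:
        return {
            "model": "estimate ~ covariates + (1 | tray), REML",
            "icc": self.icc,
            "ci": list(self.ci) if self.ci is not None else None,
            "ci_method": self.ci_method,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "var_tray": self.var_tray,
            "var_resid": self.var_resid,
            "design": self.design,
            "n": self.n,
        }


class ICCModel:
    """Inter-rater reliability via a mixed model with a random tray effect.

    ``ICC = var(tray) / (var(tray) + var(residual))`` after adjusting for
    the fixed covariates (by default day and meal).  The model places no
    requirement that every rater saw every tray, so incomplete ward designs
    fit the same way as the complete laboratory design.
    """

    def __init__(self, records: list[AssessmentRecord], covariates: tuple[str, ...] = ("day", "meal")):
        for c in covariates:
            if c not in ("day", "meal"):
                raise ValueError(f"unknown covariate {c!r}")
        counts: dict[str, int] = {}
        for r in records:
            counts[r.tray_id] = counts.get(r.tray_id, 0) + 1
        if not counts or max(counts.values()) < 2:
            raise ValueError("reliability unidentifiable: no tray has 2 or more ratings")
        self.records = list(records)
        self.covariates = tuple(covariates)

    @classmethod
    def from_dataframe(cls, df, covariates=("day", "meal")) -> "ICCModel":
        return cls(_records_from_frame(df), covariates=covariates)

    @property
    def design(self) -> str:
        trays = sorted({r.tray_id for r in self.records})
        raters = sorted({r.rater_id for r in self.records})
        seen = {(r.tray_id, r.rater_id) for r in self.records}
        complete = all((t, a) in seen for t in trays for a in raters)
        return "complete" if complete else "incomplete"

    def _design_matrix(self, records) -> tuple[np.ndarray, list[str]]:
        X = [np.ones(len(records))]
        names = ["intercept"]
        if "day" in self.covariates:
            days = sorted({r.day for r in records})
            cols, nm = _dummies([r.day for r in records], days, "day")
            X.append(cols)
            names += nm
        if "meal" in self.covariates:
            meals = [m for m in MEAL_ORDER if any(r.meal == m for r in records)]
            cols, nm = _dummies([r.meal for r in records], meals, "meal")
            X.append(cols)
            names += nm
        return np.column_stack(X), names

    def fit(
        self,
        ci_method: str | None = "bootstrap",
        n_boot: int = 1000,
        seed: int = 0,
        alpha: float = 0.05,
    ) -> ICCResult:
        y = np.array([r.estimate for r in self.records])
        groups = np.array([r.tray_id for r in self.records])
        X, names = self._design_matrix(self.records)
        res = RandomInterceptModel(y, X, groups, names).fit()
        icc = _icc_from(res)
        ci = None
        if ci_method == "bootstrap":
            ci = self._bootstrap_ci(res, X, groups, names, n_boot, seed, alpha)
        elif ci_method is not None:
            raise ValueError("ci_method must be 'bootstrap' or None")
        return ICCResult(
            icc=icc,
            ci=ci,
            var_tray=res.sigma2_group,
            var_resid=res.sigma2_resid,
            design=self.design,
            n=len(self.records),
            n_trays=len(set(groups)),
            n_raters=len({r.rater_id for r in self.records}),
            ci_method=ci_method,
            n_boot=n_boot if ci_method == "bootstrap" else 0,
            seed=seed if ci_method == "bootstrap" else None,
            results=res,
        )

    def _bootstrap_ci(self, res, X, groups, names, n_boot, seed, alpha):
        """Seeded parametric bootstrap: simulate from the fitted model, refit."""
        rng = np.random.default_rng(seed)
        labels = res.model.group_labels
        gindex = {g: i for i, g in enumerate(labels)}
        gi = np.array([gindex[g] for g in groups])
        mu = X @ res.params
        sg = math.sqrt(max(res.sigma2_group, 0.0))
        se = math.sqrt(max(res.sigma2_resid, 0.0))
        iccs = np.empty(n_boot)
        for b in range(n_boot):
            bg = rng.normal(0.0, sg, size=len(labels))
            ystar = mu + bg[gi] + rng.normal(0.0, se, size=len(groups))
            rstar = RandomInterceptModel(ystar, X, groups, names).fit()
            iccs[b] = _icc_from(rstar)
        lo, hi = np.quantile(iccs, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))


def _icc_from(res: RandomInterceptResults) -> float:
    tot = res.sigma2_group + res.sigma2_resid
    return float(res.sigma2_group / tot) if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# time efficiency


@dataclass
class EfficiencyResult:
    """Percent of traditional-method time required by the new method."""

    ratio_pct: float
    ci: tuple[float, float]
    p: float
    df: float
    method_contrast: dict
    covariate_effects: dict[str, float]
    var_rater: float
    var_resid: float
    n: int
    results: RandomInterceptResults = field(repr=False)

    @property
    def saving_pct(self) -> float:
        return 100.0 - self.ratio_pct

    def meal_effects(self) -> dict[str, float]:
        """Fitted log-time meal effects, reference level at 0."""
        out = {MEAL_ORDER[0]: 0.0}
        for name, coef in self.covariate_effects.items():
            if name.startswith("meal["):
                out[name[5:-1]] = coef
        return out

    def summary(self) -> str:
        lines = [
            f"Time efficiency mixed model on log total time (n = {self.n}, "
            f"random rater intercept, REML)",
            f"  new-method time = {self.ratio_pct:.1f}% of traditional "
            f"(95% CI {self.ci[0]:.1f}% to {self.ci[1]:.1f}%, p = {self.p:.2g}, "
            f"Satterthwaite df = {self.df:.1f})",
            f"  time saving = {self.saving_pct:.1f}%",
            f"  var(rater) = {self.var_rater:.4g}, var(resid) = {self.var_resid:.4g}",
            "  covariate effects (log seconds):",
        ]
        for name, coef in self.covariate_effects.items():
            lines.append(f"    {name:<14}{coef:+.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": "log(total_time) ~ method + day + session + meal + (1 | rater), REML",
            "ratio_pct": self.ratio_pct,
            "ci": list(self.ci),
            "p": self.p,
            "df": self.df,
            "saving_pct": self.saving_pct,
            "covariate_effects": self.covariate_effects,
            "var_rater": self.var_rater,
            "var_resid": self.var_resid,
            "n": self.n,
        }


class TimeEfficiencyModel:
    """Mixed model comparing calorie-count methods on log total task time.

    Fixed effects: method (MCM vs TM), day, session, meal — no interactions.
    Random effect: rater intercept.  Because the outcome is log time, the
    anti-log of the MCM - TM contrast estimates the ratio of median times.
    """

    def __init__(self, records: list[TimeRecord]):
        methods = {r.method for r in records}
        if methods != set(METHODS):
            raise ValueError("contrast unidentifiable: need both MCM and TM records")
        if len({r.rater_id for r in records}) < 2:
            raise ValueError("need at least 2 raters")
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df) -> "TimeEfficiencyModel":
        recs = [
            TimeRecord(
                rater_id=str(row.rater),
                method=str(row.method),
                day=int(row.day),
                session=int(row.session),
                meal=str(row.meal).lower(),
                t_pre=float(row.t_pre_s),
                t_post=float(row.t_post_s),
                t_entry=float(row.t_entry_s),
            )
            for row in df.itertuples()
        ]
        return cls(recs)

    def fit(self, alpha: float = 0.05) -> EfficiencyResult:
        recs = self.records
        y = np.log([r.total for r in recs])
        cols = [np.ones(len(recs)), np.array([1.0 if r.method == "MCM" else 0.0 for r in recs])]
        names = ["intercept", "method[MCM]"]
        days = sorted({r.day for r in recs})
        dcols, dnames = _dummies([r.day for r in recs], days, "day")
        sessions = sorted({r.session for r in recs})
        scols, snames = _dummies([r.session for r in recs], sessions, "session")
        meals = [m for m in MEAL_ORDER if any(r.meal == m for r in recs)]
        mcols, mnames = _dummies([r.meal for r in recs], meals, "meal")
        X = np.column_stack(cols + [dcols, scols, mcols])
        names += dnames + snames + mnames
        groups = np.array([r.rater_id for r in recs])
        res = RandomInterceptModel(y, X, groups, names).fit()
        tt = res.t_test_param("method[MCM]", value=0.0, alpha=alpha)
        covariate_effects = {
            nm: float(res.params[j]) for j, nm in enumerate(names) if nm not in ("intercept",)
        }
        return EfficiencyResult(
            ratio_pct=100.0 * math.exp(tt["estimate"]),
            ci=(100.0 * math.exp(tt["ci"][0]), 100.0 * math.exp(tt["ci"][1])),
            p=tt["p"],
            df=tt["df"],
            method_contrast=tt,
            covariate_effects=covariate_effects,
            var_rater=res.sigma2_group,
            var_resid=res.sigma2_resid,
            n=len(recs),
            results=res,
        )


# ---------------------------------------------------------------------------
# method-label repair


@dataclass
class FlipReport:
    """Record of which printed method labels were flipped and why."""

    flips: list[tuple[str, int, int, str, str]]  # (rater, day, session, printed, corrected)
    n_candidates_tied: int
    pooled_within_method_var: float

    @property
    def n_flips(self) -> int:
        return len(self.flips)


def resolve_method_labels(records: list[TimeRecord]) -> tuple[list[TimeRecord], FlipReport]:
    """Repair printed method labels against the stated assignment design.

    The design requires, within each day, (a) every rater to use different
    methods in the two sessions and (b) each session to be half MCM / half
    TM.  For each day, all assignments satisfying both constraints are
    enumerated; the one(s) needing the fewest label flips are kept, and any
    remaining tie is broken by minimising the pooled within-method variance
    of log total time over the whole corrected dataset.
    """
    by_day: dict[int, dict[tuple[str, int], TimeRecord]] = {}
    for r in records:
        slot = by_day.setdefault(r.day, {})
        if (r.rater_id, r.session) in slot:
            raise ValueError(
                f"inconsistent design: duplicate (rater, day, session) = "
                f"({r.rater_id}, {r.day}, {r.session})"
            )
        slot[(r.rater_id, r.session)] = r
    day_candidates: dict[int, list[frozenset]] = {}
    for day, slot in sorted(by_day.items()):
        raters = sorted({k[0] for k in slot})
        sessions = sorted({k[1] for k in slot})
        if sessions != [1, 2] or len(raters) % 2 != 0 or any(
            (a, s) not in slot for a in raters for s in sessions
        ):
            raise ValueError(f"inconsistent design: day {day} is not a full rater x session grid")
        half = len(raters) // 2
        candidates = []
        best = None
        for S in itertools.combinations(raters, half):
            S = frozenset(S)  # raters on MCM in session 1; complement in session 2
            flips = sum(
                1
                for a in raters
                for s in sessions
                if slot[(a, s)].method != _implied(S, a, s)
            )
            if best is None or flips < best:
                best = flips
                candidates = [S]
            elif flips == best:
                candidates.append(S)
        day_candidates[day] = candidates

    def corrected_for(assignment: dict[int, frozenset]) -> list[TimeRecord]:
        out = []
        for r in records:
            meth = _implied(assignment[r.day], r.rater_id, r.session)
            out.append(r if meth == r.method else replace(r, method=meth))
        return out

    combos = list(itertools.product(*(day_candidates[d] for d in sorted(day_candidates))))
    days = sorted(day_candidates)
    best_combo, best_var = None, None
    for combo in combos:
        assignment = dict(zip(days, combo))
        v = _pooled_within_method_var(corrected_for(assignment))
        if best_var is None or v < best_var - 1e-12:
            best_combo, best_var = assignment, v
    corrected = corrected_for(best_combo)
    flips = [
        (r.rater_id, r.day, r.session, r.method, c.method)
        for r, c in zip(records, corrected)
        if r.method != c.method
    ]
    return corrected, FlipReport(
        flips=flips, n_candidates_tied=len(combos), pooled_within_method_var=float(best_var)
    )


def _implied(S: frozenset, rater: str, session: int) -> str:
    in_s = rater in S
    if session == 2:
        in_s = not in_s
    return "MCM" if in_s else "TM"


def _pooled_within_method_var(records: list[TimeRecord]) -> float:
    ss = 0.0
    for meth in METHODS:
        x = np.log([r.total for r in records if r.method == meth])
        if len(x):
            ss += float(np.sum((x - x.mean()) ** 2))
    return ss


# ---------------------------------------------------------------------------
# shared


def _records_from_frame(df) -> list[AssessmentRecord]:
    recs = []
    has_true = "true_kcal" in df.columns
    for row in df.itertuples():
        tv = getattr(row, "true_kcal", None) if has_true else None
        recs.append(
            AssessmentRecord(
                tray_id=str(row.tray_id),
                rater_id=str(row.rater_id),
                day=int(row.day),
                meal=str(row.meal).lower(),
                estimate=float(row.estimate_kcal),
                true_value=None if tv is None or (tv != tv) else float(tv),
            )
        )
    return recs
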