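"""Quality control for rater estimates: photo review, proficiency, retraining.

Photographs taken before and after each meal let a second trained employee
re-estimate percent consumed and compare against the bedside entries.  An
item whose review estimate differs from the original by *more than* a set
threshold (default 15 percentage points, strict inequality) is flagged as a
potential error; when the rate of flagged items *reaches* a set threshold
(default 5%, inclusive) retraining is indicated.  Both readings are literal:
"greater than" and "reaches".

Proficiency of a rater during training is judged against weighed-food
reference values: estimates should generally fall within 15% (relative) of
the weighed energy.  "Generally" is operationalised as a configurable
quantile of trays, with a conservative default of 1.0 (every tray).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .food_model import _check_pct

__all__ = [
    "ReviewComparison",
    "QCReport",
    "flag_discrepancies",
    "resolve_disagreement",
    "proficiency_check",
    "ProficiencyResult",
]


@dataclass(frozen=True)
class ReviewComparison:
    """Photo-review comparison for one tray: per-item (primary, review) pcts."""

    tray_id: str
    items: tuple[tuple[str, int, int], ...]  # (item_id, primary_pct, review_pct)
    reviewer_id: str = ""

    def __post_init__(self) -> None:
        for _, primary, review in self.items:
            _check_pct(primary)
            _check_pct(review)


@dataclass
class QCReport:
    flags: list[tuple[str, str, int]]  # (tray_id, item_id, |difference|)
    n_items_reviewed: int
    potential_error_rate: float
    retraining_indicated: bool
    item_threshold: float = 15.0
    rate_threshold: float = 0.05

    def to_dict(self) -> dict:
        return {
            "flags": [list(f) for f in self.flags],
            "n_items_reviewed": self.n_items_reviewed,
            "potential_error_rate": self.potential_error_rate,
            "retraining_indicated": self.retraining_indicated,
            "item_threshold": self.item_threshold,
            "rate_threshold": self.rate_threshold,
        }


def flag_discrepancies(
    comparisons: list[ReviewComparison],
    item_threshold: float = 15,
    rate_threshold: float = 0.05,
) -> QCReport:
    """Flag photo-review discrepancies and decide whether to retrain.

    An item is flagged iff ``|primary - review| > item_threshold`` (strict);
    retraining is indicated iff ``flag rate >= rate_threshold``.
    """
    if item_threshold <= 0 or rate_threshold <= 0:
        raise ValueError("thresholds must be positive")
    n = sum(len(c.items) for c in comparisons)
    if n == 0:
        raise ValueError("nothing to review")
    flags = []
    for comp in comparisons:
        for item_id, primary, review in comp.items:
            diff = abs(primary - review)
            if diff > item_threshold:
                flags.append((comp.tray_id, item_id, diff))
    rate = len(flags) / n
    return QCReport(
        flags=flags,
        n_items_reviewed=n,
        potential_error_rate=rate,
        retraining_indicated=rate >= rate_threshold,
        item_threshold=item_threshold,
        rate_threshold=rate_threshold,
    )


def resolve_disagreement(primary_pct: int, review_pct: int, obvious_error: bool) -> int:
    """Resolve a primary-vs-photo disagreement on one item.

    The photo review wins only when it exposes an obvious error (a typo such
    as 100 entered for 10, or an omitted item); otherwise the default is to
    accept the estimate based on direct observation.
    """
    _check_pct(primary_pct)
    _check_pct(review_pct)
    return review_pct if obvious_error else primary_pct


@dataclass
class ProficiencyResult:
    passed: bool
    ratios: list[float]  # per-tray |estimate - weighed| / weighed
    proportion_within: float
    tolerance: float
    quantile: float
    n_excluded: int = 0


def proficiency_check(
    rater_estimates: list[float],
    weighed_values: list[float],
    tolerance: float = 0.15,
    quantile: float = 1.0,
) -> ProficiencyResult:
    """Check a trainee's energy estimates against weighed reference values.

    Passes iff the proportion of trays with relative error
    ``|estimate - weighed| / weighed <= tolerance`` is at least ``quantile``.
    Trays with a zero weighed value have no defined ratio and are excluded
    with a warning.
    """
    if len(rater_estimates) != len(weighed_values):
        raise ValueError("rater_estimates and weighed_values must be paired (equal length)")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    ratios = []
    n_excluded = 0
    for est, ref in zip(rater_estimates, weighed_values):
        if ref == 0:
            warnings.warn("weighed value 0: ratio undefined for that tray, excluded")
            n_excluded += 1
            continue
        ratios.append(abs(est - ref) / ref)
    if not ratios:
        raise ValueError("no trays with a defined ratio")
    within = sum(r <= tolerance for r in ratios) / len(ratios)
    return ProficiencyResult(
        passed=within >= quantile,
        ratios=ratios,
        proportion_within=within,
        tolerance=tolerance,
        quantile=quantile,
        n_excluded=n_excluded,
    )
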