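"""Odds-ratio contrasts between frequency-label groups.

Knowledge decline is the (1,0) pattern among examinee-system observations
that were proficient at time 1; knowledge improvement is the (0,1) pattern
among those non-proficient at time 1.  For a pair of label groups the odds
ratio is the cross-product ratio of the resulting 2x2 table, with a 95% Wald
interval on the log scale, ``exp(log OR +/- 1.96 * sqrt(sum 1/cell))``, and a
two-sided Wald p-value.  Zero cells receive the Haldane–Anscombe 0.5
correction (added to all four cells) and are flagged.

Observations pool persons across systems within a label; person-level
clustering is deliberately ignored (plain unadjusted odds ratios), which the
run report notes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .blueprint import FrequencyLabel
from .transitions import DECLINE, IMPROVEMENT, MAINTENANCE, AggregateRow, PATTERNS

#: ordering of labels by how frequently the knowledge is used in practice
USAGE_RANK = {
    FrequencyLabel.DOMINANT: 3,
    FrequencyLabel.REFERENCE: 2,
    FrequencyLabel.RELEVANT: 1,
    FrequencyLabel.DISTANT: 0,
}

EVENTS = ("decline", "improvement")


class InferenceError(ValueError):
    """Raised when a contrast has an empty group."""


def event_counts(
    patterns: Iterable[tuple[int, int]], event: str, conditional: bool = True
) -> tuple[int, int]:
    """(events, non_events) for one group.

    Conditional (default): decline = #(1,0) vs #(1,1) among the initially
    proficient; improvement = #(0,1) vs #(0,0) among the initially
    non-proficient.  Unconditional: event pattern vs all other patterns.
    """
    if event not in EVENTS:
        raise ValueError(f"event must be one of {EVENTS}")
    counts = {p: 0 for p in PATTERNS}
    for p in patterns:
        counts[p] += 1
    if event == "decline":
        events = counts[DECLINE]
        non_events = counts[MAINTENANCE] if conditional else sum(counts.values()) - events
    else:
        events = counts[IMPROVEMENT]
        non_events = counts[(0, 0)] if conditional else sum(counts.values()) - events
    return events, non_events


@dataclass(frozen=True)
class ComparisonResult:
    """One odds-ratio contrast between two groups for one event type."""

    event: str
    group_a: FrequencyLabel
    group_b: FrequencyLabel
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: tuple[int, int, int, int]  # a_events, a_nonevents, b_events, b_nonevents
    corrected: bool


def odds_ratio_test(
    a_events: int,
    a_nonevents: int,
    b_events: int,
    b_nonevents: int,
    event: str = "decline",
    group_a: FrequencyLabel | None = None,
    group_b: FrequencyLabel | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Wald odds-ratio test on a 2x2 table of event vs non-event counts."""
    cells = (a_events, a_nonevents, b_events, b_nonevents)
    if any(c < 0 for c in cells):
        raise InferenceError("counts must be nonnegative")
    if a_events + a_nonevents == 0 or b_events + b_nonevents == 0:
        raise InferenceError("each group needs at least one observation")
    corrected = any(c == 0 for c in cells)
    work = tuple(c + 0.5 for c in cells) if corrected else tuple(float(c) for c in cells)
    ae, an, be, bn = work
    odds_ratio = (ae * bn) / (an * be)
    log_or = math.log(odds_ratio)
    se = math.sqrt(sum(1.0 / c for c in work))
    z = norm.ppf(1.0 - alpha / 2.0)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p_value = 2.0 * norm.sf(abs(log_or) / se)
    return ComparisonResult(
        event=event,
        group_a=group_a,
        group_b=group_b,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        counts=cells,
        corrected=corrected,
    )


def comparison_table(
    patterns_by_label: Mapping[FrequencyLabel, Sequence[tuple[int, int]]],
    conditional: bool = True,
) -> tuple[list[ComparisonResult], list[str]]:
    """All pairwise label contrasts for decline and improvement.

    With all four labels present this yields 6 pairs x 2 events = 12 results.
    Each pair is oriented with the less frequently used label as group a (the
    numerator), so a decline OR above 1 means less-used knowledge declines
    more.  Pairs whose contrast cannot be computed are reported as failures,
    not raised.
    """
    labels = sorted(patterns_by_label, key=lambda lab: USAGE_RANK[lab])
    results: list[ComparisonResult] = []
    failures: list[str] = []
    for lab_a, lab_b in itertools.combinations(labels, 2):
        # lab_a has the lower usage rank (less frequently used)
        for event in EVENTS:
            a = event_counts(patterns_by_label[lab_a], event, conditional)
            b = event_counts(patterns_by_label[lab_b], event, conditional)
            try:
                results.append(
                    odds_ratio_test(*a, *b, event=event, group_a=lab_a, group_b=lab_b)
                )
            except InferenceError as exc:
                failures.append(
                    f"{event} {lab_a.name.lower()} vs {lab_b.name.lower()}: {exc}"
                )
    return results, failures


@dataclass(frozen=True)
class OrderingCheck:
    """One pairwise comparison within the hypothesized ordering chain."""

    pattern: tuple[int, int]
    left: FrequencyLabel
    right: FrequencyLabel
    relation: str  # expected relation: '>', '<', or '~'
    left_value: float | None
    right_value: float | None
    status: str  # 'satisfied', 'tie', 'violated', or 'unavailable'


@dataclass(frozen=True)
class OrderingReport:
    """Hypothesis-ordering check over the per-label aggregate rows.

    The usage hypothesis implies maintenance (1,1) ordered
    dominant > reference > relevant >= distant and decline (1,0) ordered
    dominant < reference < relevant ~ distant (the relevant/distant contrast
    is expected to be a near-tie).
    """

    checks: tuple[OrderingCheck, ...]

    @property
    def violations(self) -> list[OrderingCheck]:
        return [c for c in self.checks if c.status == "violated"]

    @property
    def ties(self) -> list[OrderingCheck]:
        return [c for c in self.checks if c.status == "tie"]

    @property
    def satisfied(self) -> bool:
        return all(c.status in ("satisfied", "tie") for c in self.checks)


_MAINTENANCE_CHAIN = [
    (FrequencyLabel.DOMINANT, ">", FrequencyLabel.REFERENCE),
    (FrequencyLabel.REFERENCE, ">", FrequencyLabel.RELEVANT),
    (FrequencyLabel.RELEVANT, ">", FrequencyLabel.DISTANT),
]
_DECLINE_CHAIN = [
    (FrequencyLabel.DOMINANT, "<", FrequencyLabel.REFERENCE),
    (FrequencyLabel.REFERENCE, "<", FrequencyLabel.RELEVANT),
    (FrequencyLabel.RELEVANT, "~", FrequencyLabel.DISTANT),
]


def check_hypothesis_ordering(
    rows: Mapping[FrequencyLabel, AggregateRow], tie_tol: float = 0.005
) -> OrderingReport:
    """Compare per-label mean proportions against the hypothesized orderings.

    ``tie_tol`` is the proportion difference below which two labels are
    reported as tied; a '~' relation is satisfied regardless of direction and
    recorded as a tie when within tolerance.
    """
    checks: list[OrderingCheck] = []
    for pattern, chain in ((MAINTENANCE, _MAINTENANCE_CHAIN), (DECLINE, _DECLINE_CHAIN)):
        for left, relation, right in chain:
            lv = rows[left].means[pattern] if left in rows else None
            rv = rows[right].means[pattern] if right in rows else None
            if lv is None or rv is None:
                status = "unavailable"
            elif abs(lv - rv) <= tie_tol:
                status = "tie"
            elif relation == ">":
                status = "satisfied" if lv > rv else "violated"
            elif relation == "<":
                status = "satisfied" if lv < rv else "violated"
            else:  # '~': any direction acceptable, near-equality is a tie
                status = "satisfied"
            checks.append(
                OrderingCheck(pattern, left, right, relation, lv, rv, status)
            )
    return OrderingReport(tuple(checks))
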