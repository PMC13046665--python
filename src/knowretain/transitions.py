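"""Proficiency states, four-pattern transition tables, and label aggregation.

The classify-then-count transition analysis: within each system and time
point the top share (default 60%) of examinees by estimated proficiency is
labelled proficient, the rest non-proficient.  Crossing the two time points
yields four change patterns — (0,0) stayed non-proficient, (0,1) improvement,
(1,0) decline, (1,1) maintenance.  Pattern proportions are tabulated per
(specialty, system) stratum and aggregated by frequency-of-use label with an
across-system standard error, mirroring the study's summary table layout.

Estimates with a standard error above ``se_max`` (default 1.0, strictly
greater) are marked not-applicable for insufficient test information and drop
out of the pattern counts, as do persons missing either time point.
"""

from __future__ import annotations

import enum
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blueprint import FrequencyLabel, FrequencyLabelMap
from .irt import AbilityEstimate

PATTERNS: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))

DECLINE = (1, 0)
IMPROVEMENT = (0, 1)
MAINTENANCE = (1, 1)


class TransitionError(ValueError):
    """Raised for empty inputs or impossible pairings."""


class State(enum.Enum):
    PROFICIENT = "proficient"
    NON_PROFICIENT = "non_proficient"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ProficiencyState:
    """Dichotomized proficiency of one person/system/timepoint cell."""

    person_id: str
    system: str
    timepoint: int
    state: State


def apply_reliability_filter(
    estimates: Iterable[AbilityEstimate], se_max: float = 1.0
) -> tuple[list[AbilityEstimate], list[AbilityEstimate]]:
    """Split estimates into (kept, excluded) by the standard-error rule.

    An estimate is excluded when ``se > se_max`` (strictly greater): the cell
    carries insufficient test information and becomes not-applicable.
    """
    if se_max <= 0:
        raise ValueError("se_max must be positive")
    kept: list[AbilityEstimate] = []
    excluded: list[AbilityEstimate] = []
    for est in estimates:
        (excluded if est.se > se_max else kept).append(est)
    return kept, excluded


def proficient_count(n_kept: int, proficient_share: float = 0.60) -> int:
    """Number of proficient examinees: round(share * n), half to even."""
    return int(round(proficient_share * n_kept))


def classify_proficiency(
    estimates: Sequence[AbilityEstimate], proficient_share: float = 0.60
) -> list[ProficiencyState]:
    """Label the top ``proficient_share`` of one system+timepoint as proficient.

    Exactly ``round(share * n)`` persons with the highest theta are
    proficient.  Ties in theta are broken by ascending person id so the
    classification is deterministic and permutation-invariant.
    """
    if not 0 < proficient_share < 1:
        raise ValueError("proficient_share must be in (0, 1)")
    estimates = list(estimates)
    if not estimates:
        raise TransitionError("classify_proficiency requires at least one estimate")
    systems = {e.system for e in estimates}
    timepoints = {e.timepoint for e in estimates}
    if len(systems) > 1 or len(timepoints) > 1:
        raise TransitionError(
            "classification is per system per timepoint; got "
            f"systems={sorted(systems)} timepoints={sorted(timepoints)}"
        )
    n_prof = proficient_count(len(estimates), proficient_share)
    ranked = sorted(estimates, key=lambda e: (-e.theta, e.person_id))
    states = []
    for rank, est in enumerate(ranked):
        state = State.PROFICIENT if rank < n_prof else State.NON_PROFICIENT
        states.append(ProficiencyState(est.person_id, est.system, est.timepoint, state))
    return states


def assign_pattern(
    state_t1: ProficiencyState, state_t2: ProficiencyState
) -> tuple[int, int] | None:
    """Map a pair of states to a change pattern, or None when not applicable."""
    if state_t1.person_id != state_t2.person_id or state_t1.system != state_t2.system:
        raise TransitionError(
            f"mismatched pair: ({state_t1.person_id},{state_t1.system}) vs "
            f"({state_t2.person_id},{state_t2.system})"
        )
    if State.NOT_APPLICABLE in (state_t1.state, state_t2.state):
        return None
    code = (
        int(state_t1.state == State.PROFICIENT),
        int(state_t2.state == State.PROFICIENT),
    )
    return code


@dataclass(frozen=True)
class TransitionTable:
    """Counts and proportions of the four change patterns for one group."""

    key: object
    counts: Mapping[tuple[int, int], int]
    n_total: int

    @property
    def proportions(self) -> dict[tuple[int, int], float]:
        return {p: self.counts[p] / self.n_total for p in PATTERNS}


def estimate_transition_table(
    patterns: Iterable[tuple[int, int]], key: object = None
) -> TransitionTable:
    """Tally pattern occurrences into a transition table."""
    counter = Counter(patterns)
    bad = set(counter) - set(PATTERNS)
    if bad:
        raise TransitionError(f"unknown pattern codes {sorted(bad)}")
    n_total = sum(counter.values())
    if n_total == 0:
        raise TransitionError("estimate_transition_table requires a nonempty pattern list")
    counts = {p: counter.get(p, 0) for p in PATTERNS}
    return TransitionTable(key=key, counts=counts, n_total=n_total)


@dataclass(frozen=True)
class AggregateRow:
    """Per-label summary: mean pattern proportions with across-system SEs."""

    label: FrequencyLabel
    means: Mapping[tuple[int, int], float]
    standard_errors: Mapping[tuple[int, int], float] | None
    effective_system_count: int | None
    n_observations: int


def aggregate_by_label(
    tables: Mapping[tuple[str, str], TransitionTable],
    label_map: FrequencyLabelMap,
    min_n: int = 30,
    se_denominator: str = "sqrt_k",
) -> dict[FrequencyLabel, AggregateRow]:
    """Collapse (specialty, system) tables into one row per frequency label.

    For the dominant/relevant/distant labels, pattern counts are first pooled
    per system across the specialties sharing that label for the system; a
    system is *effective* when its pooled pattern count is at least ``min_n``.
    The row mean is the unweighted mean over effective systems and the SE is
    the across-system standard deviation divided by sqrt(K) (or by K with
    ``se_denominator="k"``).  The reference label pools all its observations
    into a single table and reports no across-system SE.
    """
    if se_denominator not in ("sqrt_k", "k"):
        raise ValueError("se_denominator must be 'sqrt_k' or 'k'")
    pooled: dict[FrequencyLabel, dict[str, Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for (spec_id, sys_id), table in tables.items():
        label = label_map.label_of(spec_id, sys_id)
        pooled[label][sys_id].update(table.counts)

    rows: dict[FrequencyLabel, AggregateRow] = {}
    for label, per_system in pooled.items():
        if label is FrequencyLabel.REFERENCE:
            total = Counter()
            for counts in per_system.values():
                total.update(counts)
            table = TransitionTable(
                key=label,
                counts={p: total.get(p, 0) for p in PATTERNS},
                n_total=sum(total.values()),
            )
            rows[label] = AggregateRow(
                label=label,
                means=table.proportions,
                standard_errors=None,
                effective_system_count=None,
                n_observations=table.n_total,
            )
            continue
        effective = {
            sys_id: counts
            for sys_id, counts in per_system.items()
            if sum(counts.values()) >= min_n
        }
        if not effective:
            raise TransitionError(
                f"label {label.name.lower()}: no system reaches min_n={min_n}"
            )
        props = np.array(
            [
                [counts.get(p, 0) / sum(counts.values()) for p in PATTERNS]
                for counts in effective.values()
            ]
        )
        k = props.shape[0]
        means = props.mean(axis=0)
        sd = props.std(axis=0, ddof=1) if k > 1 else np.zeros(len(PATTERNS))
        denom = math.sqrt(k) if se_denominator == "sqrt_k" else k
        ses = sd / denom
        rows[label] = AggregateRow(
            label=label,
            means=dict(zip(PATTERNS, means)),
            standard_errors=dict(zip(PATTERNS, ses)),
            effective_system_count=k,
            n_observations=int(sum(sum(c.values()) for c in effective.values())),
        )
    return rows


def aggregate_rows_frame(rows: Mapping[FrequencyLabel, AggregateRow]) -> pd.DataFrame:
    """Flatten aggregate rows into a tabular report (one row per label)."""
    records = []
    for label in FrequencyLabel:
        if label not in rows:
            continue
        row = rows[label]
        rec = {
            "label": label.name.lower(),
            "effective_system_count": row.effective_system_count,
            "n_observations": row.n_observations,
        }
        for p in PATTERNS:
            tag = f"{p[0]}{p[1]}"
            rec[f"p_{tag}"] = row.means[p]
            rec[f"se_{tag}"] = (
                row.standard_errors[p] if row.standard_errors is not None else np.nan
            )
        records.append(rec)
    return pd.DataFrame(records)
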