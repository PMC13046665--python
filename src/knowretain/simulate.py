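"""Synthetic two-timepoint certification cohorts with usage-dependent drift.

Emulates the statistical structure the transition analysis assumes: an item
bank over the 14 organ systems, exam forms shaped like the initial
certification exam (5 blocks x 60 items) and the longitudinal recertification
assessment (12 quarters x 25 items), examinee abilities drawn N(0,1) per
system at time 1, a between-timepoint ability drift whose mean depends on the
frequency-of-use label of the (specialty, system) pair, and Bernoulli Rasch
responses.

Defaults: each examinee answers 21 items per system at time 1 (300 initial
items spread over 14 systems) and 14 at time 2 (roughly eight 25-item
quarters of the longitudinal assessment spread over 14 systems), so time-2
scores carry visibly larger standard errors.  The default drift means
(+0.3 / 0.0 / -0.3 / -0.35 logits for dominant / reference / relevant /
distant) realize the usage hypothesis — the less the knowledge is used, the
larger the decline — with relevant and distant nearly tied; they are
configuration, not empirical claims.  The specialty mix places 48% of
examinees in multi-specialization (general practice) profiles.

All randomness flows from the configured seed; equal configurations produce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blueprint import (
    FrequencyLabel,
    FrequencyLabelMap,
    Specialty,
    SystemDomain,
    default_specialties,
    default_systems,
)
from .irt import Item, ResponseSet, rasch_prob


class DesignError(ValueError):
    """Raised for infeasible form designs or invalid simulator configs."""


DEFAULT_DRIFT_MEANS = {
    FrequencyLabel.DOMINANT: 0.30,
    FrequencyLabel.REFERENCE: 0.0,
    FrequencyLabel.RELEVANT: -0.30,
    FrequencyLabel.DISTANT: -0.35,
}


def default_specialty_mix(
    specialties: Mapping[str, Specialty] | None = None, multi_share: float = 0.48
) -> dict[str, float]:
    """Uniform within multi- and single-specialization groups; 48% multi."""
    specialties = default_specialties() if specialties is None else specialties
    multi = [s.id for s in specialties.values() if s.is_multi_specialization]
    single = [s.id for s in specialties.values() if not s.is_multi_specialization]
    mix: dict[str, float] = {}
    for sid in multi:
        mix[sid] = multi_share / len(multi)
    for sid in single:
        mix[sid] = (1.0 - multi_share) / len(single)
    return mix


@dataclass
class CohortConfig:
    """Generative settings for a synthetic two-timepoint cohort."""

    n_examinees: int = 2000
    specialty_mix: dict[str, float] | None = None
    drift_means: dict[FrequencyLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIFT_MEANS)
    )
    drift_sd: float = 0.30
    ability_sd_t1: float = 1.0
    items_per_system_t1: int = 21
    items_per_system_t2: int = 14
    bank_items_per_system: int = 30
    difficulty_mean: float = 0.0
    difficulty_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_examinees <= 0:
            raise DesignError("n_examinees must be positive")
        if self.drift_sd < 0 or self.ability_sd_t1 <= 0:
            raise DesignError("drift_sd must be >= 0 and ability_sd_t1 > 0")
        if min(self.items_per_system_t1, self.items_per_system_t2, 1) < 1:
            raise DesignError("items_per_system must be >= 1")
        if max(self.items_per_system_t1, self.items_per_system_t2) > self.bank_items_per_system:
            raise DesignError("item bank too small for the per-timepoint item counts")
        if self.specialty_mix is not None:
            total = sum(self.specialty_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise DesignError(f"specialty_mix sums to {total}, expected 1")


@dataclass(frozen=True)
class FormDesign:
    """Block structure of an exam form."""

    exam: str  # 'initial' or 'recertification'
    blocks: tuple[tuple[int, int], ...]  # (block index, items in block)

    def __post_init__(self):
        shapes = {b[1] for b in self.blocks}
        if self.exam == "initial":
            if len(self.blocks) != 5 or shapes != {60}:
                raise DesignError("initial form must be 5 blocks of 60 items")
        elif self.exam == "recertification":
            if len(self.blocks) != 12 or shapes != {25}:
                raise DesignError("recertification form must be 12 quarters of 25 items")
        else:
            raise DesignError(f"unknown exam kind {self.exam!r}")

    @property
    def total_items(self) -> int:
        return sum(n for _, n in self.blocks)

    @classmethod
    def initial(cls) -> "FormDesign":
        return cls("initial", tuple((i, 60) for i in range(1, 6)))

    @classmethod
    def recertification(cls) -> "FormDesign":
        return cls("recertification", tuple((q, 25) for q in range(1, 13)))


def build_item_bank(
    config: CohortConfig, systems: Mapping[str, SystemDomain] | None = None
) -> list[Item]:
    """Draw a bank with ``bank_items_per_system`` normal difficulties per system."""
    systems = default_systems() if systems is None else systems
    rng = np.random.default_rng(config.seed)
    items: list[Item] = []
    for sys_id in systems:
        diffs = rng.normal(
            config.difficulty_mean, config.difficulty_sd, config.bank_items_per_system
        )
        for j, d in enumerate(diffs, start=1):
            items.append(Item(f"{sys_id}_i{j:03d}", sys_id, float(d)))
    return items


def build_forms(
    bank: Sequence[Item], design: FormDesign, seed: int = 0
) -> list[list[str]]:
    """Assign bank items to the blocks of a form, balanced across systems.

    Items are sampled without replacement within the form; each system gets
    ``total // n_systems`` slots plus one of the remainder slots, as evenly
    as the bank allows.  Returns one item-id list per block.
    """
    rng = np.random.default_rng(seed)
    by_system: dict[str, list[str]] = {}
    for it in bank:
        by_system.setdefault(it.system, []).append(it.id)
    if len(bank) < design.total_items:
        raise DesignError(
            f"bank of {len(bank)} items cannot fill a {design.total_items}-item form"
        )
    n_sys = len(by_system)
    base, rem = divmod(design.total_items, n_sys)
    sys_ids = sorted(by_system)
    quotas = {s: base for s in sys_ids}
    for s in rng.permutation(sys_ids)[:rem]:
        quotas[s] += 1
    # rebalance quotas that exceed a system's bank onto systems with slack
    short = sum(max(0, quotas[s] - len(by_system[s])) for s in sys_ids)
    for s in sys_ids:
        quotas[s] = min(quotas[s], len(by_system[s]))
    while short:
        placed = False
        for s in sys_ids:
            if short and quotas[s] < len(by_system[s]):
                quotas[s] += 1
                short -= 1
                placed = True
        if not placed:
            raise DesignError("bank cannot fill the form under system balance")
    chosen: list[str] = []
    for s in sys_ids:
        chosen.extend(rng.choice(by_system[s], size=quotas[s], replace=False))
    order = rng.permutation(len(chosen))
    shuffled = [chosen[i] for i in order]
    blocks: list[list[str]] = []
    pos = 0
    for _, n in design.blocks:
        blocks.append(shuffled[pos : pos + n])
        pos += n
    return blocks


def _assign_items(
    bank: Sequence[Item], per_system: int, rng: np.random.Generator
) -> dict[str, list[Item]]:
    by_system: dict[str, list[Item]] = {}
    for it in bank:
        by_system.setdefault(it.system, []).append(it)
    out: dict[str, list[Item]] = {}
    for sys_id in sorted(by_system):
        pool = by_system[sys_id]
        if len(pool) < per_system:
            raise DesignError(f"system {sys_id}: bank has {len(pool)} < {per_system} items")
        idx = rng.choice(len(pool), size=per_system, replace=False)
        out[sys_id] = [pool[i] for i in idx]
    return out


def simulate_cohort(
    config: CohortConfig,
    label_map: FrequencyLabelMap,
    bank: Sequence[Item] | None = None,
) -> tuple[ResponseSet, pd.DataFrame]:
    """Generate responses and ground-truth abilities for a synthetic cohort.

    Per examinee: a specialty from the mix; per system, theta_t1 ~
    N(0, ability_sd_t1^2) and theta_t2 = theta_t1 + drift_mean[label] + eps,
    eps ~ N(0, drift_sd^2); Bernoulli Rasch responses to the per-timepoint
    item assignment.  Returns the long-format :class:`ResponseSet` and a
    truth table (person_id, specialty, system, label, theta_t1, theta_t2).
    """
    rng = np.random.default_rng(config.seed)
    systems = sorted(label_map.systems)
    if bank is None:
        bank = build_item_bank(config, label_map.systems)
    items_t1 = _assign_items(bank, config.items_per_system_t1, rng)
    items_t2 = _assign_items(bank, config.items_per_system_t2, rng)

    mix = config.specialty_mix or default_specialty_mix(label_map.specialties)
    spec_ids = sorted(mix)
    probs = np.array([mix[s] for s in spec_ids])
    n = config.n_examinees
    person_ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    chosen = rng.choice(len(spec_ids), size=n, p=probs)
    specialties = np.array([spec_ids[i] for i in chosen])

    drift_by_label = {lab: config.drift_means.get(lab, 0.0) for lab in FrequencyLabel}
    truth_rows = []
    resp_frames = []
    for sys_id in systems:
        theta1 = rng.normal(0.0, config.ability_sd_t1, n)
        labels = np.array(
            [label_map.label_of(spec, sys_id) for spec in specialties], dtype=object
        )
        drift_mu = np.array([drift_by_label[lab] for lab in labels])
        eps = rng.normal(0.0, config.drift_sd, n) if config.drift_sd > 0 else 0.0
        theta2 = theta1 + drift_mu + eps
        truth_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_ids,
                    "specialty": specialties,
                    "system": sys_id,
                    "label": [lab.name.lower() for lab in labels],
                    "theta_t1": theta1,
                    "theta_t2": theta2,
                }
            )
        )
        for timepoint, theta, assigned in ((1, theta1, items_t1), (2, theta2, items_t2)):
            its = assigned[sys_id]
            diffs = np.array([it.difficulty for it in its])
            p = rasch_prob(theta[:, None], diffs[None, :])
            x = (rng.random((n, len(its))) < p).astype(int)
            resp_frames.append(
                pd.DataFrame(
                    {
                        "person_id": np.repeat(person_ids, len(its)),
                        "item_id": np.tile([it.id for it in its], n),
                        "timepoint": timepoint,
                        "response": x.ravel(),
                    }
                )
            )
    responses = ResponseSet(pd.concat(resp_frames, ignore_index=True))
    truth = pd.concat(truth_rows, ignore_index=True)
    return responses, truth


def simulate_pattern_sequences(
    pattern_probs: Sequence[float], n: int, seed: int
) -> list[tuple[int, int]]:
    """Draw n iid change patterns from a four-category distribution.

    ``pattern_probs`` are the probabilities of (0,0), (0,1), (1,0), (1,1) in
    that order; they must be nonnegative and sum to 1 (within 1e-9).
    """
    probs = np.asarray(pattern_probs, dtype=float)
    if probs.shape != (4,):
        raise DesignError("pattern_probs must have exactly four entries")
    if (probs < 0).any():
        raise DesignError("pattern_probs must be nonnegative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise DesignError(f"pattern_probs sum to {probs.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    patterns = ((0, 0), (0, 1), (1, 0), (1, 1))
    idx = rng.choice(4, size=n, p=probs / probs.sum())
    return [patterns[i] for i in idx]
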