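"""Dichotomous Rasch measurement: calibration, scoring, and test information.

The Rasch (one-parameter logistic) model gives the probability of a correct
response as ``P(x=1 | theta, b) = logistic(theta - b)`` where ``theta`` is the
examinee's proficiency and ``b`` the item difficulty, both on the logit scale.

Calibration is marginal maximum likelihood under a standard-normal latent
distribution, computed by EM over a fixed quadrature grid (the classical
Bock–Aitkin scheme).  Person proficiency is scored as the expected a
posteriori (EAP) estimate under the same N(0,1) prior; the reported standard
error is the posterior standard deviation.  EAP stays finite for perfect and
zero raw scores, which routinely occur on short quarterly forms.

Identification: the latent distribution is fixed to N(0,1) and fitted item
difficulties are re-centered to mean zero.  Both time points are scored
against the same item-bank difficulties, so the two proficiency estimates are
on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm


class CalibrationError(RuntimeError):
    """Raised when item calibration cannot proceed or does not converge."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ScoringError(ValueError):
    """Raised when a person/system/timepoint cell has no usable responses."""


@dataclass(frozen=True)
class Item:
    """A calibrated dichotomous item."""

    id: str
    system: str
    difficulty: float

    def __post_init__(self):
        if not np.isfinite(self.difficulty):
            raise ValueError(f"item {self.id}: difficulty must be finite")


@dataclass(frozen=True)
class AbilityEstimate:
    """Latent proficiency of one person on one system at one time point."""

    person_id: str
    system: str
    timepoint: int
    theta: float
    se: float
    n_items: int


RESPONSE_COLUMNS = ["person_id", "item_id", "timepoint", "response"]


class ResponseSet:
    """Long-format dichotomous responses: one row per (person, item, timepoint).

    Wraps a validated :class:`pandas.DataFrame` with columns
    ``person_id, item_id, timepoint, response``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        frame = frame.loc[:, RESPONSE_COLUMNS].copy()
        frame["person_id"] = frame["person_id"].astype(str)
        frame["item_id"] = frame["item_id"].astype(str)
        frame["timepoint"] = frame["timepoint"].astype(int)
        frame["response"] = frame["response"].astype(int)
        if not frame["timepoint"].isin([1, 2]).all():
            raise ValueError("timepoint must be 1 or 2")
        if not frame["response"].isin([0, 1]).all():
            raise ValueError("responses must be strictly 0 or 1")
        if frame.duplicated(["person_id", "item_id", "timepoint"]).any():
            raise ValueError("duplicate (person, item, timepoint) records")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ResponseSet":
        return cls(pd.DataFrame(records, columns=RESPONSE_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResponseSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    def subset(self, *, person_id=None, timepoint=None, item_ids=None) -> pd.DataFrame:
        frame = self._frame
        if person_id is not None:
            frame = frame[frame["person_id"] == str(person_id)]
        if timepoint is not None:
            frame = frame[frame["timepoint"] == int(timepoint)]
        if item_ids is not None:
            frame = frame[frame["item_id"].isin(set(item_ids))]
        return frame


def read_item_bank(path: str | Path) -> list[Item]:
    """Read a ``item_id,system,difficulty`` CSV into a list of items."""
    frame = pd.read_csv(path)
    missing = [c for c in ("item_id", "system", "difficulty") if c not in frame.columns]
    if missing:
        raise ValueError(f"item bank missing columns {missing}")
    return [
        Item(str(r.item_id), str(r.system), float(r.difficulty))
        for r in frame.itertuples(index=False)
    ]


def write_item_bank(items: Sequence[Item], path: str | Path) -> None:
    pd.DataFrame(
        [(it.id, it.system, it.difficulty) for it in items],
        columns=["item_id", "system", "difficulty"],
    ).to_csv(path, index=False)


def rasch_prob(theta, difficulty):
    """P(correct) under the Rasch model; vectorized over both arguments."""
    theta = np.asarray(theta, dtype=float)
    difficulty = np.asarray(difficulty, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(difficulty))):
        raise ValueError("rasch_prob requires finite theta and difficulty")
    out = expit(theta - difficulty)
    return out if out.ndim else float(out)


def test_information(theta: float, items: Sequence[Item]) -> float:
    """Fisher information sum over items of p(1-p) at ``theta``."""
    if len(items) == 0:
        raise ValueError("test_information requires a nonempty item list")
    p = rasch_prob(theta, np.array([it.difficulty for it in items]))
    return float(np.sum(p * (1.0 - p)))


def quadrature_grid(n_nodes: int = 61, bound: float = 6.0):
    """Fixed grid with standard-normal weights used by calibration and EAP."""
    nodes = np.linspace(-bound, bound, n_nodes)
    weights = norm.pdf(nodes)
    return nodes, weights / weights.sum()


def _response_matrix(frame: pd.DataFrame):
    """Pivot long responses into (X, M, persons, items): data and mask."""
    wide = frame.pivot(index="person_id", columns="item_id", values="response")
    mask = wide.notna().to_numpy(dtype=float)
    data = wide.fillna(0).to_numpy(dtype=float)
    return data, mask, wide.index.to_numpy(), wide.columns.to_numpy()


def _posterior_weights(X, M, b, nodes, log_weights):
    """Log-posterior over quadrature nodes for each person; returns (post, N x Q)."""
    P = expit(nodes[:, None] - b[None, :])  # Q x J
    logP = np.log(P)
    log1mP = np.log1p(-P)
    # N x Q person-by-node log-likelihoods using the observation mask
    loglik = X @ logP.T + (M - X) @ log1mP.T
    logpost = loglik + log_weights[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return post


@dataclass
class CalibrationResult:
    """MML-EM calibration output: items, exclusions, and convergence info."""

    items: list[Item]
    excluded: list[str]
    n_iterations: int
    converged: bool


def fit_item_difficulties(
    responses: ResponseSet | pd.DataFrame,
    system: str = "",
    tol: float = 1e-4,
    max_iter: int = 500,
    n_nodes: int = 61,
) -> CalibrationResult:
    """Calibrate Rasch item difficulties by marginal maximum likelihood EM.

    ``responses`` must be restricted to a single system and time point.
    Items answered all-correct or all-incorrect by their responders are not
    estimable (the likelihood is maximized at infinite difficulty) and are
    excluded with a warning.  After convergence difficulties are re-centered
    to mean zero.
    """
    frame = responses.frame if isinstance(responses, ResponseSet) else responses
    X, M, persons, item_ids = _response_matrix(frame)
    n_resp = M.sum(axis=0)
    n_correct = (X * M).sum(axis=0)
    estimable = (n_correct > 0) & (n_correct < n_resp)
    excluded = [str(i) for i in item_ids[~estimable]]
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} item(s) with degenerate score: {excluded}",
            stacklevel=2,
        )
        X, M, item_ids = X[:, estimable], M[:, estimable], item_ids[estimable]
    if X.shape[1] < 2:
        raise CalibrationError("calibration requires at least 2 estimable items")
    if X.shape[0] < 2:
        raise CalibrationError("calibration requires at least 2 persons")

    nodes, weights = quadrature_grid(n_nodes)
    log_weights = np.log(weights)
    # classical logit start from observed proportions
    p_obs = (X * M).sum(axis=0) / M.sum(axis=0)
    b = np.log((1.0 - p_obs) / p_obs)

    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        post = _posterior_weights(X, M, b, nodes, log_weights)
        # expected responder and correct counts at each node, per item (Q x J)
        N_qj = post.T @ M
        R_qj = post.T @ X
        b_new = b.copy()
        for _ in range(25):  # Newton steps for the M-step score equation
            P = expit(nodes[:, None] - b_new[None, :])
            grad = (N_qj * P - R_qj).sum(axis=0)
            hess = (N_qj * P * (1.0 - P)).sum(axis=0)
            step = grad / np.maximum(hess, 1e-12)
            b_new = b_new + np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < 0.1 * tol:
                break
        delta = np.max(np.abs(b_new - b))
        b = b_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise CalibrationError(
            f"MML-EM did not converge within {max_iter} iterations", last_iterate=b
        )
    b = b - b.mean()
    items = [Item(str(i), system, float(d)) for i, d in zip(item_ids, b)]
    return CalibrationResult(items, excluded, iteration, converged)


def score_group(
    frame: pd.DataFrame,
    items: Sequence[Item],
    n_nodes: int = 61,
) -> pd.DataFrame:
    """EAP-score every person in a single system+timepoint response block.

    Returns a frame with columns ``person_id, theta, se, n_items``.  Persons
    with no response to a calibrated item are absent from the output.
    """
    bank = {it.id: it.difficulty for it in items}
    frame = frame[frame["item_id"].isin(bank)]
    if frame.empty:
        return pd.DataFrame(columns=["person_id", "theta", "se", "n_items"])
    X, M, persons, item_ids = _response_matrix(frame)
    b = np.array([bank[str(i)] for i in item_ids])
    nodes, weights = quadrature_grid(n_nodes)
    post = _posterior_weights(X, M, b, nodes, np.log(weights))
    theta = post @ nodes
    var = np.einsum("nq,qn->n", post, (nodes[:, None] - theta[None, :]) ** 2)
    return pd.DataFrame(
        {
            "person_id": persons,
            "theta": theta,
            "se": np.sqrt(var),
            "n_items": M.sum(axis=1).astype(int),
        }
    )


def score_person(
    responses: ResponseSet | pd.DataFrame,
    items: Sequence[Item],
    system: str = "",
    timepoint: int | None = None,
    n_nodes: int = 61,
) -> AbilityEstimate:
    """EAP ability estimate for one person's responses on one system+timepoint.

    ``se`` is the posterior standard deviation under the N(0,1) prior; with
    very few items it approaches the prior SD, signalling low information.
    """
    frame = responses.frame if isinstance(responses, ResponseSet) else responses
    if timepoint is not None:
        frame = frame[frame["timepoint"] == int(timepoint)]
    person_ids = frame["person_id"].unique()
    if len(person_ids) > 1:
        raise ScoringError(f"score_person got responses for {len(person_ids)} persons")
    scored = score_group(frame, items, n_nodes=n_nodes)
    if scored.empty:
        raise ScoringError("no usable responses for this person/system/timepoint")
    row = scored.iloc[0]
    tp = int(frame["timepoint"].iloc[0]) if timepoint is None else int(timepoint)
    return AbilityEstimate(
        person_id=str(row["person_id"]),
        system=system,
        timepoint=tp,
        theta=float(row["theta"]),
        se=float(row["se"]),
        n_items=int(row["n_items"]),
    )
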