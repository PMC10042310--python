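"""Response-probability models for the five experimental tasks.

Each task presents a forced choice whose success probability is a function
of a child's sensitivity parameters:

* mutual exclusivity (ME): choose the novel object given a novel word, with
  equal prior over the two objects — the rational-integration listener with
  a flat common-ground prior; informed by ``alpha`` and ``theta``.
* discourse novelty: choose the object that is new to the speaker; the
  choice probability *is* the common-ground sensitivity ``rho``.
* word comprehension: pick the named object among six pictures; a child who
  has acquired the word (prob ``theta``) is always correct, otherwise
  guesses at 1/6.
* word production: name the object; requires both acquisition (``theta``)
  and successful retrieval/articulation (shared probability ``gamma``).
* combination: the discourse-novelty scene with one familiar object, so
  mutual-exclusivity and common-ground cues are both present; the prior is
  set by ``rho`` and the condition (congruent: the novel object is
  discourse-new; incongruent: the familiar one is).

Responses are coded from the mutual-exclusivity perspective (1 = novel /
discourse-new / correct).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .rsa import (
    Utterance,
    lesion_no_common_ground,
    lesion_no_speaker_informativeness,
    p_novel_pragmatic,
    pragmatic_listener,
)

__all__ = [
    "Task",
    "Condition",
    "ListenerModel",
    "ChildParams",
    "TrialRecord",
    "p_mutual_exclusivity",
    "p_discourse_novelty",
    "p_comprehension",
    "p_production",
    "combination_prior",
    "p_combination",
    "trial_loglik",
    "TRIAL_COLUMNS",
    "N_ITEMS",
]

N_ITEMS = 16

TRIAL_COLUMNS = ["child_id", "task", "item_id", "condition", "response"]


class Task(enum.Enum):
    ME = "me"
    DISCOURSE = "discourse"
    COMPREHENSION = "comprehension"
    PRODUCTION = "production"
    COMBINATION = "combination"


class Condition(enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"
    NA = "na"


class ListenerModel(enum.Enum):
    """Which listener generates combination-task predictions."""

    RATIONAL = "rational"
    NO_CG = "no_cg"  # ignores common ground (uniform prior)
    NO_SI = "no_si"  # ignores speaker informativeness (prior only)


@dataclass
class ChildParams:
    """Realized sensitivity parameters for one child.

    theta is a vector over the 16 familiar items (degree of acquisition of
    each word); alpha and rho are scalar per child.
    """

    child_id: str
    theta: np.ndarray
    alpha: float
    rho: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta values must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class TrialRecord:
    child_id: str
    task: Task
    item_id: int | None
    condition: Condition
    response: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        if (self.condition is not Condition.NA) != (self.task is Task.COMBINATION):
            raise ValueError("condition is set iff task is COMBINATION")
        if self.task is Task.DISCOURSE:
            if self.item_id is not None:
                raise ValueError("discourse trials carry no item")
        elif self.item_id is None:
            raise ValueError(f"{self.task} trial requires an item_id")


def p_mutual_exclusivity(alpha, theta):
    """P(choose novel object) in the ME task: rational listener, flat prior."""
    return p_novel_pragmatic(alpha, theta, 0.5)


def p_discourse_novelty(rho):
    """P(choose discourse-new object): the common-ground sensitivity itself."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    return rho


def p_comprehension(theta):
    """P(correct picture among six): know it, or guess at chance 1/6."""
    theta = np.asarray(theta, dtype=float)
    return theta + (1.0 - theta) / 6.0


def p_production(theta, gamma):
    """P(produce an acceptable label): acquired and successfully retrieved."""
    return np.asarray(theta, dtype=float) * gamma


def combination_prior(rho, condition: Condition):
    """Common-ground prior over the novel object in the combination task.

    Congruent: the novel object is new to discourse, so the prior on it is
    rho.  Incongruent: the familiar object is discourse-new, so the prior
    on the novel object is 1 - rho.
    """
    rho = np.asarray(rho, dtype=float)
    if condition is Condition.CONGRUENT:
        return rho
    if condition is Condition.INCONGRUENT:
        return 1.0 - rho
    raise ValueError(f"combination condition must be congruent/incongruent, got {condition}")


def p_combination(
    params: ChildParams,
    item_id: int,
    condition: Condition,
    model: ListenerModel = ListenerModel.RATIONAL,
) -> float:
    """P(choose novel object) on one combination trial, under one listener."""
    if not 0 <= item_id < len(params.theta):
        raise ValueError(f"item_id {item_id} outside the item roster")
    theta = float(params.theta[item_id])
    prior = float(combination_prior(params.rho, condition))
    if model is ListenerModel.RATIONAL:
        return pragmatic_listener(Utterance.NOVEL_WORD, params.alpha, theta, prior).p_novel
    if model is ListenerModel.NO_SI:
        return lesion_no_speaker_informativeness(prior).p_novel
    if model is ListenerModel.NO_CG:
        return lesion_no_common_ground(Utterance.NOVEL_WORD, params.alpha, theta).p_novel
    raise ValueError(f"unknown listener model {model}")


def _bernoulli_loglik(p: float, response: int) -> float:
    p = float(p)
    if response == 1:
        return float(np.log(p)) if p > 0 else -np.inf
    return float(np.log1p(-p)) if p < 1 else -np.inf


def trial_loglik(
    trial: TrialRecord,
    params: ChildParams,
    gamma: float,
    model: ListenerModel = ListenerModel.RATIONAL,
) -> float:
    """Log Bernoulli probability of one recorded response.

    A predicted probability of exactly 0 or 1 contradicted by the response
    yields -inf (a flag, not an exception), so impossible data are visible
    in sums rather than raising mid-likelihood.
    """
    t = trial.task
    if t is Task.ME:
        p = float(p_mutual_exclusivity(params.alpha, params.theta[trial.item_id]))
    elif t is Task.DISCOURSE:
        p = float(params.rho)
    elif t is Task.COMPREHENSION:
        p = float(p_comprehension(params.theta[trial.item_id]))
    elif t is Task.PRODUCTION:
        p = float(p_production(params.theta[trial.item_id], gamma))
    elif t is Task.COMBINATION:
        p = p_combination(params, trial.item_id, trial.condition, model)
    else:  # pragma: no cover
        raise ValueError(f"unknown task {t}")
    return _bernoulli_loglik(p, trial.response)
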