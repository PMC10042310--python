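"""Synthetic five-task datasets generated from known ground truth.

The generator mirrors the study design: N children (default 60) aged 3-5
years complete 16 mutual-exclusivity trials (one per familiar item), 12
discourse-novelty trials, 16 comprehension and 16 production trials, and a
16-trial combination task (8 congruent + 8 incongruent, items fixed to
conditions identically for every child).  Responses are Bernoulli draws
from the task models under parameters realized from the hierarchy, so every
stage of the pipeline can be exercised — and validated by parameter
recovery — without the original study data.

Default population-trajectory values are the study's reported posterior
modes; the dispersions and gamma are not reported and default to plausible
placeholder values chosen to produce visible individual differences at the
study's trial counts (see ``NON_REPORTED_DEFAULTS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hierarchy import (
    ChildLatents,
    ChildRoster,
    Hyperparams,
    ItemEffects,
    realize_arrays,
)
from .rsa import p_novel_pragmatic
from .tasks import N_ITEMS, Condition, ListenerModel, Task

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_truth",
    "simulate",
    "scenario_library",
    "NON_REPORTED_DEFAULTS",
]

# Dispersions and gamma are placeholders, not study-reported quantities.
NON_REPORTED_DEFAULTS = {
    "sigma0_theta": 0.5,
    "sigma1_theta": 0.25,
    "sigma_i_alpha": 0.5,
    "sigma_i_rho": 0.5,
    "gamma": 0.8,
}


def default_truth() -> Hyperparams:
    """Ground-truth hyperparameters for simulation.

    Trajectory intercepts and slopes are the study-scale posterior modes:
    speaker informativeness (1.56, 1.18), common ground (1.96, -0.43) —
    logistic(1.96) = 0.88 at the youngest age — and vocabulary development
    (-1.21, 1.10) — logistic(-1.21) = 0.23.  Dispersions and gamma use the
    non-reported placeholder defaults.
    """
    return Hyperparams(
        mu0_theta=-1.21,
        mu1_theta=1.10,
        b0_alpha=1.56,
        b1_alpha=1.18,
        b0_rho=1.96,
        b1_rho=-0.43,
        **NON_REPORTED_DEFAULTS,
    )


@dataclass
class SimConfig:
    """Study-design knobs for the generator; defaults match the study."""

    n_children: int = 60
    age_range: tuple[float, float] = (3.06, 4.93)
    n_items: int = N_ITEMS
    n_me: int = 16
    n_discourse: int = 12
    n_comprehension: int = 16
    n_production: int = 16
    n_combination_per_condition: int = 8
    truth: Hyperparams = field(default_factory=default_truth)
    generating_model: ListenerModel = ListenerModel.RATIONAL
    latent_mode: str = "joint_me"
    sigma_theta_latent: float = 0.5  # only used with latent_mode="separate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children <= 0 or min(
            self.n_me, self.n_discourse, self.n_comprehension, self.n_production
        ) <= 0:
            raise ValueError("counts must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age range must be increasing")
        for nm in ("sigma0_theta", "sigma1_theta", "sigma_i_alpha", "sigma_i_rho"):
            if getattr(self.truth, nm) <= 0:
                raise ValueError(f"degenerate {nm} <= 0 in truth")
        if self.n_me > self.n_items or self.n_comprehension > self.n_items:
            raise ValueError("per-item tasks cannot exceed the item roster")


@dataclass
class SimTruth:
    """Everything the generator realized; regenerable from (config, seed)."""

    hyper: Hyperparams
    items: ItemEffects
    latents: ChildLatents
    theta: np.ndarray  # (N, J)
    alpha: np.ndarray  # (N,)
    rho: np.ndarray  # (N,)


def _combination_items(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed item->condition assignment, identical for every child.

    Even-indexed items are congruent, odd-indexed incongruent (stand-in for
    the study's matched pairs).
    """
    items = np.arange(cfg.n_items)
    return items[items % 2 == 0][: cfg.n_combination_per_condition], items[items % 2 == 1][
        : cfg.n_combination_per_condition
    ]


def simulate(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (trials, roster, truth) from the hierarchical model.

    Ages are uniform over the configured range; latent developmental ages
    are Gaussian around standardized age with the family dispersions (the
    theta family shares the ME latent under the default ``joint_me``
    layout); item trajectories are Gaussian around the population moments.
    Responses are Bernoulli from the task models, with combination-task
    responses generated by ``cfg.generating_model``.  Fully deterministic
    given the config (including its seed).
    """
    rng = np.random.default_rng([cfg.seed, 515])
    tr = cfg.truth
    n, j = cfg.n_children, cfg.n_items

    ages = np.sort(rng.uniform(*cfg.age_range, size=n))
    roster = ChildRoster(child_id=[f"c{i:03d}" for i in range(n)], age_years=ages)
    k = roster.age_std

    items = ItemEffects(
        b0_theta=rng.normal(tr.mu0_theta, tr.sigma0_theta, size=j),
        b1_theta=rng.normal(tr.mu1_theta, tr.sigma1_theta, size=j),
    )
    lat_me = rng.normal(k, tr.sigma_i_alpha)
    lat_rho = rng.normal(k, tr.sigma_i_rho)
    if cfg.latent_mode == "joint_me":
        latents = ChildLatents(lat_me, lat_me, lat_rho)
    elif cfg.latent_mode == "separate":
        lat_theta = rng.normal(k, cfg.sigma_theta_latent)
        latents = ChildLatents(lat_theta, lat_me, lat_rho)
    elif cfg.latent_mode == "single":
        latents = ChildLatents(lat_me, lat_me, lat_me)
    else:
        raise ValueError(f"unknown latent_mode {cfg.latent_mode!r}")

    theta, alpha, rho = realize_arrays(tr, items, latents)
    truth = SimTruth(tr, items, latents, theta, alpha, rho)

    rows: list[tuple] = []

    def emit(i: int, task: Task, item_id, condition: Condition, p: float) -> None:
        rows.append(
            (
                roster.child_id[i],
                task.value,
                item_id,
                condition.value,
                int(rng.uniform() < p),
            )
        )

    for i in range(n):
        for item in range(cfg.n_me):
            emit(i, Task.ME, item, Condition.NA, p_novel_pragmatic(alpha[i], theta[i, item], 0.5))
        for _ in range(cfg.n_discourse):
            emit(i, Task.DISCOURSE, None, Condition.NA, rho[i])
        for item in range(cfg.n_comprehension):
            emit(i, Task.COMPREHENSION, item, Condition.NA, theta[i, item] + (1 - theta[i, item]) / 6)
        for item in range(cfg.n_production):
            emit(i, Task.PRODUCTION, item, Condition.NA, theta[i, item] * tr.gamma)
        cong_items, incong_items = _combination_items(cfg)
        for cond, cond_items in (
            (Condition.CONGRUENT, cong_items),
            (Condition.INCONGRUENT, incong_items),
        ):
            prior = rho[i] if cond is Condition.CONGRUENT else 1.0 - rho[i]
            for item in cond_items:
                if cfg.generating_model is ListenerModel.RATIONAL:
                    p = p_novel_pragmatic(alpha[i], theta[i, item], prior)
                elif cfg.generating_model is ListenerModel.NO_CG:
                    p = p_novel_pragmatic(alpha[i], theta[i, item], 0.5)
                else:  # NO_SI
                    p = prior
                emit(i, Task.COMBINATION, int(item), cond, float(p))

    trials = pd.DataFrame(rows, columns=["child_id", "task", "item_id", "condition", "response"])
    roster_df = pd.DataFrame(
        {"child_id": roster.child_id, "age_years": roster.age_years, "age_std": roster.age_std}
    )
    return trials, roster_df, truth


def scenario_library() -> dict[str, SimConfig]:
    """Named study conditions used throughout the tests and examples."""
    return {
        # full study design with the reported trajectory modes as truth
        "paper_scale": SimConfig(n_children=60, seed=1),
        # minimal end-to-end smoke scenario
        "tiny": SimConfig(n_children=4, seed=2),
        # combination responses generated by each lesioned listener,
        # for model-comparison sign-recovery checks
        "no_cg_world": SimConfig(n_children=60, generating_model=ListenerModel.NO_CG, seed=3),
        "no_si_world": SimConfig(n_children=60, generating_model=ListenerModel.NO_SI, seed=4),
    }
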