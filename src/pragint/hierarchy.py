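"""Hierarchical model tying children's ages to their sensitivity parameters.

Each sensitivity parameter follows a developmental trajectory — a regression
on a child-specific latent developmental age ``i`` that is anchored at the
child's chronological age ``k`` (standardized so the youngest child is 0)::

    theta_ij = logistic(b0_theta[j] + i * b1_theta[j])     per familiar item j
    alpha_i  = max(0, b0_alpha + i * b1_alpha)
    rho_i    = logistic(b0_rho + i * b1_rho)

Item trajectories are themselves exchangeable draws from population moments
(mu0_theta, sigma0_theta) and (mu1_theta, sigma1_theta).  Latent ages are
Gaussian around chronological age with family-specific dispersions: one
latent shared by the jointly-estimated theta/alpha families (informed by
the mutual-exclusivity, comprehension and production tasks) and a second
for the common-ground family (informed by discourse novelty); alternative
latent layouts are available via ``latent_mode``.

This module holds the types, the realized-parameter map, the log prior and
the (vectorized) Part-1 joint log likelihood.  Posterior sampling lives in
:mod:`pragint.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy

from .rsa import p_novel_pragmatic
from .tasks import N_ITEMS, ChildParams, Task

__all__ = [
    "HYPER_NAMES",
    "Hyperparams",
    "ItemEffects",
    "ChildLatents",
    "ChildRoster",
    "Part1Data",
    "HyperpriorConfig",
    "realize_params",
    "realize_arrays",
    "joint_loglik_part1",
    "log_prior",
]

HYPER_NAMES = [
    "mu0_theta",
    "mu1_theta",
    "sigma0_theta",
    "sigma1_theta",
    "b0_alpha",
    "b1_alpha",
    "sigma_i_alpha",
    "b0_rho",
    "b1_rho",
    "sigma_i_rho",
    "gamma",
]

LATENT_MODES = ("joint_me", "separate", "single")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class Hyperparams:
    """Population-level trajectory coefficients, dispersions, and gamma.

    Locations are on the logit scale for theta/rho and the natural scale
    for alpha; dispersions are standard deviations (same scales); gamma is
    the shared successful-production probability.
    """

    mu0_theta: float
    mu1_theta: float
    sigma0_theta: float
    sigma1_theta: float
    b0_alpha: float
    b1_alpha: float
    sigma_i_alpha: float
    b0_rho: float
    b1_rho: float
    sigma_i_rho: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("sigma0_theta", "sigma1_theta", "sigma_i_alpha", "sigma_i_rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HYPER_NAMES], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Hyperparams":
        return Hyperparams(**{n: float(v) for n, v in zip(HYPER_NAMES, a)})


@dataclass
class ItemEffects:
    """Per-item trajectory coefficients for the 16 familiar words."""

    b0_theta: np.ndarray  # (n_items,)
    b1_theta: np.ndarray  # (n_items,)

    def __post_init__(self) -> None:
        self.b0_theta = np.asarray(self.b0_theta, dtype=float)
        self.b1_theta = np.asarray(self.b1_theta, dtype=float)
        if self.b0_theta.shape != self.b1_theta.shape:
            raise ValueError("item intercepts and slopes must align")
        if not (np.all(np.isfinite(self.b0_theta)) and np.all(np.isfinite(self.b1_theta))):
            raise ValueError("item effects must be finite")


@dataclass
class ChildLatents:
    """Latent developmental ages per child, one per parameter family."""

    dev_age_theta: np.ndarray
    dev_age_alpha: np.ndarray
    dev_age_rho: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dev_age_theta", "dev_age_alpha", "dev_age_rho"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")


@dataclass
class ChildRoster:
    """Child identifiers and ages; age_std is min-referenced (youngest = 0)."""

    child_id: list
    age_years: np.ndarray
    age_ref: float = None  # reference minimum age; defaults to sample min

    def __post_init__(self) -> None:
        self.age_years = np.asarray(self.age_years, dtype=float)
        if len(self.child_id) != len(self.age_years):
            raise ValueError("roster ids and ages must align")
        if self.age_ref is None:
            self.age_ref = float(np.min(self.age_years))

    @property
    def age_std(self) -> np.ndarray:
        return self.age_years - self.age_ref

    @property
    def n_children(self) -> int:
        return len(self.child_id)

    @staticmethod
    def from_frame(df: pd.DataFrame, age_ref: float | None = None) -> "ChildRoster":
        df = df.sort_values("child_id").reset_index(drop=True)
        return ChildRoster(
            child_id=list(df["child_id"]),
            age_years=df["age_years"].to_numpy(dtype=float),
            age_ref=age_ref,
        )


@dataclass
class HyperpriorConfig:
    """Weakly informative hyperpriors on the population-level parameters.

    Normal(0, loc_scale) on trajectory intercepts/slopes, half-Normal
    (sigma_scale) on dispersions, Uniform(0, 1) on gamma.
    """

    loc_scale: float = 2.0
    sigma_scale: float = 1.0


# ---------------------------------------------------------------------------
# Realized parameters


def realize_arrays(
    hyper: Hyperparams,
    items: ItemEffects,
    latents: ChildLatents,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map hierarchy state to realized (theta, alpha, rho) arrays.

    Returns theta with shape (n_children, n_items), alpha and rho with
    shape (n_children,).  Alpha is rectified at zero so the speaker
    exponent stays admissible for extreme latents.
    """
    theta = expit(items.b0_theta[None, :] + latents.dev_age_theta[:, None] * items.b1_theta[None, :])
    alpha = np.maximum(0.0, hyper.b0_alpha + latents.dev_age_alpha * hyper.b1_alpha)
    rho = expit(hyper.b0_rho + latents.dev_age_rho * hyper.b1_rho)
    return theta, alpha, rho


def realize_params(
    hyper: Hyperparams,
    items: ItemEffects,
    latents: ChildLatents,
    roster: ChildRoster,
) -> list[ChildParams]:
    """Realize one :class:`~pragint.tasks.ChildParams` per rostered child."""
    theta, alpha, rho = realize_arrays(hyper, items, latents)
    if theta.shape[0] != roster.n_children:
        raise ValueError("latent arrays do not match the roster")
    return [
        ChildParams(child_id=cid, theta=theta[i], alpha=float(alpha[i]), rho=float(rho[i]))
        for i, cid in enumerate(roster.child_id)
    ]


# ---------------------------------------------------------------------------
# Data container: trial table -> dense response matrices


@dataclass
class Part1Data:
    """Part-1 responses pivoted to child x item matrices for fast likelihoods.

    Missing trials are NaN in the matrices and masked out of every sum, so
    children with absent rows simply contribute fewer Bernoulli terms.
    """

    roster: ChildRoster
    me: np.ndarray  # (N, n_items) responses in {0,1}, NaN if absent
    comp: np.ndarray
    prod: np.ndarray
    disc_k: np.ndarray  # (N,) discourse-novel choices
    disc_n: np.ndarray  # (N,) discourse trials present
    n_items: int = N_ITEMS

    @staticmethod
    def from_frame(trials: pd.DataFrame, roster: ChildRoster, n_items: int = N_ITEMS) -> "Part1Data":
        idx = {cid: i for i, cid in enumerate(roster.child_id)}
        n = roster.n_children
        mats = {t: np.full((n, n_items), np.nan) for t in ("me", "comprehension", "production")}
        disc_k = np.zeros(n)
        disc_n = np.zeros(n)
        for row in trials.itertuples(index=False):
            if row.child_id not in idx:
                raise ValueError(f"trial references unrostered child {row.child_id!r}")
            i = idx[row.child_id]
            task = row.task
            if task == Task.COMBINATION.value:
                continue
            if task == Task.DISCOURSE.value:
                disc_k[i] += row.response
                disc_n[i] += 1
                continue
            if task not in mats:
                raise ValueError(f"unknown task {task!r}")
            j = int(row.item_id)
            if not 0 <= j < n_items:
                raise ValueError(f"item_id {j} outside the {n_items}-item roster")
            mats[task][i, j] = row.response
        return Part1Data(
            roster=roster,
            me=mats["me"],
            comp=mats["comprehension"],
            prod=mats["production"],
            disc_k=disc_k,
            disc_n=disc_n,
            n_items=n_items,
        )


def _masked_bernoulli_ll(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli log-likelihood; NaN responses contribute 0."""
    mask = ~np.isnan(y)
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y == 1, np.log(p), np.log1p(-p))
    return np.where(mask, ll, 0.0)


def loglik_matrices(
    data: Part1Data,
    theta: np.ndarray,
    alpha: np.ndarray,
    rho: np.ndarray,
    gamma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell ME+comprehension+production log-likelihood (N x J) and the
    per-child discourse log-likelihood vector (N,)."""
    p_me = p_novel_pragmatic(alpha[:, None], theta, 0.5)
    p_comp = theta + (1.0 - theta) / 6.0
    p_prod = theta * gamma
    cell = (
        _masked_bernoulli_ll(data.me, p_me)
        + _masked_bernoulli_ll(data.comp, p_comp)
        + _masked_bernoulli_ll(data.prod, p_prod)
    )
    rho = np.clip(rho, 0.0, 1.0)
    # xlogy gives 0 * log 0 = 0, so an impossible response flags -inf only
    # when the contradicted count is positive
    disc = xlogy(data.disc_k, rho) + xlogy(data.disc_n - data.disc_k, 1.0 - rho)
    return cell, disc


def joint_loglik_part1(
    data: Part1Data,
    hyper: Hyperparams,
    items: ItemEffects,
    latents: ChildLatents,
) -> float:
    """Joint Part-1 log likelihood: ME + comprehension + production + discourse."""
    theta, alpha, rho = realize_arrays(hyper, items, latents)
    cell, disc = loglik_matrices(data, theta, alpha, rho, hyper.gamma)
    return float(cell.sum() + disc.sum())


# ---------------------------------------------------------------------------
# Priors


def _normal_logpdf(x, mu, sigma):
    return -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.log(2.0) - _LOG_SQRT_2PI - np.log(scale) - 0.5 * (x / scale) ** 2
    return np.where(x >= 0, out, -np.inf)


def log_prior(
    hyper: Hyperparams,
    items: ItemEffects,
    latents: ChildLatents,
    roster: ChildRoster,
    latent_mode: str = "joint_me",
    sigma_theta_latent: float = 0.5,
    hyperprior: HyperpriorConfig | None = None,
) -> float:
    """Log density of the hierarchy above the likelihood.

    Item trajectory coefficients are Gaussian around the population
    moments; each latent developmental age is Gaussian around the child's
    standardized chronological age with the family dispersion; hyperpriors
    are Normal(0, 2) on locations, half-Normal(1) on dispersions and
    Uniform(0, 1) on gamma (see :class:`HyperpriorConfig`).

    In ``joint_me`` mode theta and alpha share one latent (with dispersion
    sigma_i_alpha) and only that latent plus the rho latent carry prior
    mass; ``separate`` gives the theta family its own latent with the
    fixed, non-sampled dispersion ``sigma_theta_latent``; ``single`` uses
    one latent for all three families (dispersion sigma_i_alpha).
    """
    if latent_mode not in LATENT_MODES:
        raise ValueError(f"latent_mode must be one of {LATENT_MODES}")
    hp = hyperprior or HyperpriorConfig()
    k = roster.age_std

    total = 0.0
    total += _normal_logpdf(items.b0_theta, hyper.mu0_theta, hyper.sigma0_theta).sum()
    total += _normal_logpdf(items.b1_theta, hyper.mu1_theta, hyper.sigma1_theta).sum()

    if latent_mode == "joint_me":
        total += _normal_logpdf(latents.dev_age_alpha, k, hyper.sigma_i_alpha).sum()
        total += _normal_logpdf(latents.dev_age_rho, k, hyper.sigma_i_rho).sum()
    elif latent_mode == "separate":
        total += _normal_logpdf(latents.dev_age_theta, k, sigma_theta_latent).sum()
        total += _normal_logpdf(latents.dev_age_alpha, k, hyper.sigma_i_alpha).sum()
        total += _normal_logpdf(latents.dev_age_rho, k, hyper.sigma_i_rho).sum()
    else:  # single
        total += _normal_logpdf(latents.dev_age_alpha, k, hyper.sigma_i_alpha).sum()

    for name in ("mu0_theta", "mu1_theta", "b0_alpha", "b1_alpha", "b0_rho", "b1_rho"):
        total += float(_normal_logpdf(getattr(hyper, name), 0.0, hp.loc_scale))
    for name in ("sigma0_theta", "sigma1_theta", "sigma_i_alpha", "sigma_i_rho"):
        total += float(_halfnormal_logpdf(getattr(hyper, name), hp.sigma_scale))
    # gamma ~ Uniform(0, 1): density 1 on the support
    if not 0.0 <= hyper.gamma <= 1.0:
        return -np.inf
    return float(total)
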