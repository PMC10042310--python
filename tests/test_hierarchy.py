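"""Hierarchical model: realized parameters, priors, joint likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import halfnorm, norm

from pragint.hierarchy import (
    ChildLatents,
    ChildRoster,
    Hyperparams,
    ItemEffects,
    Part1Data,
    joint_loglik_part1,
    log_prior,
    realize_arrays,
    realize_params,
)
from pragint.simulate import SimConfig, default_truth, simulate
from pragint.tasks import ChildParams, Condition, Task, TrialRecord, trial_loglik


def small_state(n=3, j=4, seed=0):
    rng = np.random.default_rng(seed)
    hyper = default_truth()
    items = ItemEffects(rng.normal(-1, 0.5, j), rng.normal(1, 0.3, j))
    roster = ChildRoster([f"c{i}" for i in range(n)], 3.0 + rng.uniform(0, 2, n))
    lat = rng.normal(roster.age_std, 0.5, (3, n))
    latents = ChildLatents(lat[0], lat[0], lat[2])
    return hyper, items, latents, roster


def test_realized_parameter_back_transforms():
    """Intercept-only back-transforms: logistic(1.96)=0.88 for common ground
    and logistic(-1.21)=0.23 for vocabulary, and alpha rectification."""
    hyper = default_truth()
    items = ItemEffects(np.array([-1.21]), np.array([1.10]))
    roster = ChildRoster(["c0"], np.array([3.0]))
    latents = ChildLatents(np.zeros(1), np.zeros(1), np.zeros(1))
    (child,) = realize_params(hyper, items, latents, roster)
    assert child.rho == pytest.approx(expit(1.96), abs=1e-12)
    assert round(child.rho, 2) == 0.88
    assert child.theta[0] == pytest.approx(expit(-1.21), abs=1e-12)
    assert round(float(child.theta[0]), 2) == 0.23
    assert child.alpha == pytest.approx(1.56)

    # strongly negative latent drives the linear alpha below zero -> clamp
    neg = ChildLatents(np.zeros(1), np.array([-10.0]), np.zeros(1))
    theta, alpha, rho = realize_arrays(hyper, items, neg)
    assert alpha[0] == 0.0


def test_joint_loglik_matches_per_trial_oracle():
    """Vectorized Part-1 likelihood equals naive per-trial Bernoulli sums."""
    trials, roster_df, truth = simulate(SimConfig(n_children=5, n_items=16, seed=3))
    roster = ChildRoster.from_frame(roster_df)
    data = Part1Data.from_frame(trials, roster)
    vec = joint_loglik_part1(data, truth.hyper, truth.items, truth.latents)

    by_child = {
        cid: ChildParams(cid, truth.theta[i], truth.alpha[i], truth.rho[i])
        for i, cid in enumerate(roster.child_id)
    }
    naive = 0.0
    for row in trials.itertuples(index=False):
        if row.task == Task.COMBINATION.value:
            continue
        rec = TrialRecord(
            row.child_id,
            Task(row.task),
            None if row.task == Task.DISCOURSE.value else int(row.item_id),
            Condition.NA,
            int(row.response),
        )
        naive += trial_loglik(rec, by_child[row.child_id], truth.hyper.gamma)
    assert vec == pytest.approx(naive, rel=1e-12)


def test_log_prior_matches_naive_oracle():
    hyper, items, latents, roster = small_state()
    got = log_prior(hyper, items, latents, roster, latent_mode="joint_me")

    expected = (
        norm.logpdf(items.b0_theta, hyper.mu0_theta, hyper.sigma0_theta).sum()
        + norm.logpdf(items.b1_theta, hyper.mu1_theta, hyper.sigma1_theta).sum()
        + norm.logpdf(latents.dev_age_alpha, roster.age_std, hyper.sigma_i_alpha).sum()
        + norm.logpdf(latents.dev_age_rho, roster.age_std, hyper.sigma_i_rho).sum()
        + sum(
            norm.logpdf(getattr(hyper, nm), 0, 2.0)
            for nm in ("mu0_theta", "mu1_theta", "b0_alpha", "b1_alpha", "b0_rho", "b1_rho")
        )
        + sum(
            halfnorm.logpdf(getattr(hyper, nm), scale=1.0)
            for nm in ("sigma0_theta", "sigma1_theta", "sigma_i_alpha", "sigma_i_rho")
        )
    )
    assert got == pytest.approx(float(expected), rel=1e-10)


def test_log_prior_peaks_at_chronological_age():
    hyper, items, latents, roster = small_state()
    base = log_prior(hyper, items, latents, roster)
    worse = ChildLatents(
        latents.dev_age_theta,
        latents.dev_age_alpha,
        roster.age_std + 3.0,  # move rho latents far from their ages
    )
    at_age = ChildLatents(latents.dev_age_theta, latents.dev_age_alpha, roster.age_std)
    assert log_prior(hyper, items, at_age, roster) > base or np.allclose(
        latents.dev_age_rho, roster.age_std
    )
    assert log_prior(hyper, items, worse, roster) < log_prior(hyper, items, at_age, roster)


def test_posterior_density_exchangeable_over_children():
    """Permuting children (data and latents together) leaves both the prior
    and the likelihood unchanged."""
    trials, roster_df, truth = simulate(SimConfig(n_children=6, seed=4))
    roster = ChildRoster.from_frame(roster_df)
    data = Part1Data.from_frame(trials, roster)
    base_ll = joint_loglik_part1(data, truth.hyper, truth.items, truth.latents)
    base_lp = log_prior(truth.hyper, truth.items, truth.latents, roster)

    perm = np.array([3, 1, 5, 0, 4, 2])
    roster_p = ChildRoster(
        [roster.child_id[i] for i in perm], roster.age_years[perm], age_ref=roster.age_ref
    )
    lat_p = ChildLatents(
        truth.latents.dev_age_theta[perm],
        truth.latents.dev_age_alpha[perm],
        truth.latents.dev_age_rho[perm],
    )
    data_p = Part1Data.from_frame(trials, roster_p)
    assert joint_loglik_part1(data_p, truth.hyper, truth.items, lat_p) == pytest.approx(
        base_ll, rel=1e-12
    )
    assert log_prior(truth.hyper, truth.items, lat_p, roster_p) == pytest.approx(
        base_lp, rel=1e-12
    )


def test_part1_data_rejects_bad_references():
    roster = ChildRoster(["c0"], np.array([3.5]))
    bad_child = pd.DataFrame(
        [("ghost", "me", 0, "na", 1)], columns=["child_id", "task", "item_id", "condition", "response"]
    )
    with pytest.raises(ValueError, match="unrostered|roster"):
        Part1Data.from_frame(bad_child, roster)
    bad_item = pd.DataFrame(
        [("c0", "me", 99, "na", 1)], columns=["child_id", "task", "item_id", "condition", "response"]
    )
    with pytest.raises(ValueError, match="item"):
        Part1Data.from_frame(bad_item, roster)


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        Hyperparams(0, 0, -1, 1, 0, 0, 1, 0, 0, 1, 0.5)
    with pytest.raises(ValueError):
        Hyperparams(0, 0, 1, 1, 0, 0, 1, 0, 0, 1, 1.5)
    h = default_truth()
    assert Hyperparams.from_array(h.to_array()) == h
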