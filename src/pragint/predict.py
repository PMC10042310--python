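"""Trial-level predictions for the combination task and their evaluation.

For every combination trial and posterior draw, the child's realized
parameters are pushed through the chosen listener (rational integration or
a lesion), giving a posterior distribution over the probability of choosing
the novel object.  That distribution is reduced to a point prediction by
its MAP (kernel-density mode), converted to a binary prediction by a
weighted coin flip, and scored as the proportion of trials matching the
child's actual responses.  Because the coin flip is stochastic, the
procedure is repeated (default 1000 runs) and the run distribution is
reported alongside the first-run headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import PosteriorDraws
from .rsa import p_novel_pragmatic
from .tasks import Condition, ListenerModel, Task

__all__ = [
    "CombinationPredictions",
    "EvalSummary",
    "predict_combination",
    "map_estimate",
    "binarize",
    "match_rate",
    "chance_comparison",
    "group_correlation",
]

_KDE_GRID = np.linspace(0.0, 1.0, 512)


@dataclass
class CombinationPredictions:
    """Per-trial prediction table plus the full per-draw distributions.

    ``table`` has one row per trial (child_id, trial, item_id, condition,
    model, p_map, response); ``p_novel_draws`` is aligned row-wise with
    shape (n_trials, n_draws).
    """

    model: ListenerModel
    table: pd.DataFrame
    p_novel_draws: np.ndarray


def predict_combination(
    draws: PosteriorDraws,
    trials: pd.DataFrame,
    model: ListenerModel,
    max_draws: int | None = 1000,
) -> CombinationPredictions:
    """Posterior-predictive choice probabilities for each combination trial.

    Every trial's child and item must appear in the fit; the age origin is
    the fit's, carried inside ``draws``.  ``max_draws`` strides the
    posterior down for speed (None keeps every draw).
    """
    comb = trials[trials["task"] == Task.COMBINATION.value].reset_index(drop=True)
    if comb.empty:
        raise ValueError("no combination trials to predict")
    child_index = {cid: i for i, cid in enumerate(draws.roster.child_id)}
    missing = set(comb["child_id"]) - set(child_index)
    if missing:
        raise ValueError(f"combination trials reference unfitted children: {sorted(missing)}")

    theta, alpha, rho, _ = draws.realize(max_draws=max_draws)
    ci = comb["child_id"].map(child_index).to_numpy()
    ji = comb["item_id"].to_numpy(dtype=int)
    if np.any((ji < 0) | (ji >= theta.shape[2])):
        raise ValueError("combination trial references an item outside the fit")
    cong = (comb["condition"] == Condition.CONGRUENT.value).to_numpy()

    th = theta[:, ci, ji]  # (S, T)
    al = alpha[:, ci]
    rh = rho[:, ci]
    prior = np.where(cong[None, :], rh, 1.0 - rh)
    if model is ListenerModel.RATIONAL:
        p = p_novel_pragmatic(al, th, prior)
    elif model is ListenerModel.NO_CG:
        p = p_novel_pragmatic(al, th, np.full_like(prior, 0.5))
    elif model is ListenerModel.NO_SI:
        p = prior
    else:
        raise ValueError(f"unknown listener model {model}")
    p = np.asarray(p).T  # (T, S)

    table = pd.DataFrame(
        {
            "child_id": comb["child_id"],
            "trial": comb.groupby("child_id").cumcount(),
            "item_id": ji,
            "condition": comb["condition"],
            "model": model.value,
            "p_map": [map_estimate(row) for row in p],
            "response": comb["response"].to_numpy(dtype=int),
        }
    )
    return CombinationPredictions(model=model, table=table, p_novel_draws=p)


def map_estimate(samples) -> float:
    """Mode of a Gaussian kernel density over posterior samples on [0, 1].

    Uses Silverman's bandwidth on a 512-point grid; degenerate samples
    (all equal) return that value, and grid ties are broken toward the
    posterior mean.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("map_estimate requires at least one sample")
    if np.any((samples < 0) | (samples > 1)):
        raise ValueError("samples must lie in [0, 1]")
    if samples.size == 1 or np.ptp(samples) < 1e-12:
        return float(samples.flat[0])
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    dens = kde(_KDE_GRID)
    top = np.flatnonzero(dens >= dens.max() - 1e-12)
    if top.size == 1:
        return float(_KDE_GRID[top[0]])
    mean = samples.mean()
    return float(_KDE_GRID[top[np.argmin(np.abs(_KDE_GRID[top] - mean))]])


def binarize(p_map: float, rng) -> int:
    """Weighted coin flip: 1 with probability ``p_map``.

    ``rng`` is a numpy Generator or an integer seed; seeded calls are
    reproducible.
    """
    if not 0.0 <= p_map <= 1.0:
        raise ValueError("p_map must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return int(rng.uniform() < p_map)


@dataclass
class EvalSummary:
    """Match-rate evaluation of one model's binarized predictions."""

    model: str
    proportion_matched: float  # first run of the coin-flip procedure
    n_trials: int
    run_proportions: np.ndarray  # one proportion per repetition
    per_child: pd.DataFrame = field(default=None, repr=False)  # first run, per child

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "proportion_matched": self.proportion_matched,
            "n_trials": self.n_trials,
            "runs": len(self.run_proportions),
            "run_mean": float(np.mean(self.run_proportions)),
            "run_sd": float(np.std(self.run_proportions)),
        }


def match_rate(
    predictions: CombinationPredictions,
    runs: int = 1000,
    seed: int = 0,
) -> EvalSummary:
    """Proportion of trials whose coin-flip prediction matches the response.

    The MAP coin flip is repeated ``runs`` times; the first run is the
    headline proportion and the whole run distribution is retained (the
    procedure is stochastic, so results vary slightly across runs).
    """
    tbl = predictions.table
    p_map = tbl["p_map"].to_numpy(dtype=float)
    resp = tbl["response"].to_numpy(dtype=int)
    rng = np.random.default_rng([seed, 8191])
    flips = (rng.uniform(size=(runs, p_map.size)) < p_map[None, :]).astype(int)
    matched = flips == resp[None, :]
    props = matched.mean(axis=1)
    per_child = (
        pd.DataFrame({"child_id": tbl["child_id"], "matched": matched[0]})
        .groupby("child_id", sort=True)["matched"]
        .mean()
        .reset_index()
    )
    return EvalSummary(
        model=predictions.model.value,
        proportion_matched=float(props[0]),
        n_trials=int(p_map.size),
        run_proportions=props,
        per_child=per_child,
    )


def chance_comparison(
    proportions,
    chance: float = 0.5,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Default-prior (JZS, r = 0.707) Bayes factor against a chance level.

    One-sample Bayesian t-test of the proportions against ``chance``, plus
    a bootstrap 95% CI of the mean.  BF10 > 1 favors a deviation from
    chance.
    """
    import pingouin

    x = np.asarray(proportions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two proportions")
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0:
        tstat = 0.0 if mean == chance else np.inf
    else:
        tstat = (mean - chance) / (sd / np.sqrt(x.size))
    bf10 = (
        np.inf
        if np.isinf(tstat)
        else float(pingouin.bayesfactor_ttest(tstat, x.size, paired=True, r=0.707))
    )
    rng = np.random.default_rng([seed, 4099])
    boots = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean": float(mean),
        "t": float(tstat),
        "n": int(x.size),
        "bf10": bf10,
        "ci95": (float(lo), float(hi)),
        "chance": chance,
    }


def group_correlation(
    predictions: CombinationPredictions,
    roster: pd.DataFrame,
    age_bin_years: float = 1.0,
) -> dict:
    """Correlation between aggregated predictions and aggregated data.

    Observed choice proportions and predicted MAP probabilities are
    averaged within (trial, age-bin) cells — a trial being one (item,
    condition) pair, identical across children — and correlated (Pearson).
    Constant predictions make r undefined; that is flagged rather than
    raised.
    """
    tbl = predictions.table.merge(roster[["child_id", "age_years"]], on="child_id")
    tbl["age_bin"] = np.floor(tbl["age_years"] / age_bin_years) * age_bin_years
    cells = (
        tbl.groupby(["item_id", "condition", "age_bin"])
        .agg(obs=("response", "mean"), pred=("p_map", "mean"))
        .reset_index()
    )
    if cells["pred"].nunique() == 1 or cells["obs"].nunique() == 1:
        return {"r": np.nan, "r2": np.nan, "n_cells": len(cells), "flag": "zero variance"}
    r, _ = stats.pearsonr(cells["pred"], cells["obs"])
    return {"r": float(r), "r2": float(r * r), "n_cells": len(cells), "flag": None}
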