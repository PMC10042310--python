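"""Bayes-factor model comparison on the held-out combination task.

Evidence for each listener model is its posterior-predictive marginal
likelihood: the Part-2 (combination) data likelihood averaged over the
Part-1 posterior of the child's parameters,

    ML(model) = E_posterior[ prod_t P(y_t | params, model) ],

computed stably in log space.  Because all models share the same Part-1
fit and differ only in how parameters map to predictions, this integral is
the natural out-of-sample evidence; it is computed per child (and the
group-level value is, by design, the sum of per-child log marginal
likelihoods).  Bayes factors are ratios of marginal likelihoods, censused
against the conventional evidence thresholds 1 / 3 / 10 / 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .predict import CombinationPredictions
from .tasks import ListenerModel

__all__ = [
    "predictive_log_ml",
    "bayes_factor",
    "bf_census",
    "classify_bf",
    "per_child_log_ml",
    "comparison_table",
]

BF_THRESHOLDS = (1.0, 3.0, 10.0, 100.0)

# Conventional evidence categories by BF magnitude.
_CATEGORIES = (
    (100.0, "extreme"),
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
)


def _trial_loglik_matrix(pred: CombinationPredictions) -> np.ndarray:
    """(T, S) per-trial, per-draw Bernoulli log-likelihoods of the data."""
    p = np.clip(pred.p_novel_draws, 0.0, 1.0)
    y = pred.table["response"].to_numpy(dtype=int)[:, None]
    with np.errstate(divide="ignore"):
        return np.where(y == 1, np.log(p), np.log1p(-p))


def predictive_log_ml(pred: CombinationPredictions, trial_index=None) -> float:
    """Log posterior-predictive marginal likelihood over the given trials.

    log( mean over draws of exp( sum over trials of log P(y_t | draw) ) ),
    computed with log-sum-exp.  ``trial_index`` restricts the scope (e.g.
    to one child's rows); None uses every trial.  If the data are
    impossible under every draw the result is -inf (a flag, not an error).
    """
    ll = _trial_loglik_matrix(pred)
    if trial_index is not None:
        ll = ll[np.asarray(trial_index)]
    per_draw = ll.sum(axis=0)  # (S,)
    if np.all(np.isneginf(per_draw)):
        return -np.inf
    return float(logsumexp(per_draw) - np.log(per_draw.size))


def per_child_log_ml(pred: CombinationPredictions, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Per-child log marginal likelihood with a bootstrap Monte-Carlo SE.

    The SE resamples posterior draws; it quantifies Monte-Carlo noise in
    the log-mean-exp, useful when Bayes factors sit near a threshold.
    """
    ll = _trial_loglik_matrix(pred)
    child = pred.table["child_id"].to_numpy()
    rng = np.random.default_rng([seed, 31337])
    s = ll.shape[1]
    boot_idx = rng.integers(0, s, size=(n_boot, s))
    out = []
    for cid in pd.unique(child):
        rows = np.flatnonzero(child == cid)
        per_draw = ll[rows].sum(axis=0)
        log_ml = (
            -np.inf
            if np.all(np.isneginf(per_draw))
            else float(logsumexp(per_draw) - np.log(s))
        )
        boots = logsumexp(per_draw[boot_idx], axis=1) - np.log(s)
        out.append(
            {
                "child_id": cid,
                "log_ml": log_ml,
                "mc_se": float(np.std(boots)),
                "n_trials": rows.size,
            }
        )
    return pd.DataFrame(out)


def bayes_factor(log_ml_1: float, log_ml_2: float) -> float:
    """BF12 = exp(log ML1 - log ML2); may overflow to inf for huge evidence —
    work with the log difference where magnitudes matter."""
    if not (np.isfinite(log_ml_1) and np.isfinite(log_ml_2)):
        raise ValueError("log marginal likelihoods must be finite")
    with np.errstate(over="ignore"):
        return float(np.exp(log_ml_1 - log_ml_2))


def classify_bf(log_bf: float) -> str:
    """Evidence category of a (log) Bayes factor for model 1 over model 2."""
    mag = abs(log_bf)
    direction = "m1" if log_bf > 0 else ("m2" if log_bf < 0 else "none")
    for thr, label in _CATEGORIES:
        if mag > np.log(thr):
            return f"{label}_{direction}" if direction != "none" else "equal"
    return "equal"


def bf_census(log_bfs, thresholds=BF_THRESHOLDS) -> dict:
    """Fraction of children whose BF (for the focal model) exceeds thresholds.

    Comparisons are strict (> threshold), so a BF of exactly 1 counts for
    nothing at the 1 threshold.
    """
    log_bfs = np.asarray(log_bfs, dtype=float)
    return {
        thr: float(np.mean(log_bfs > np.log(thr))) for thr in thresholds
    }


def comparison_table(
    preds: dict[ListenerModel, CombinationPredictions],
    focal: ListenerModel = ListenerModel.RATIONAL,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-child model comparison: log-MLs, log-BFs vs the focal model, and
    evidence categories, one row per child per alternative model."""
    mls = {m: per_child_log_ml(p, n_boot=n_boot, seed=seed) for m, p in preds.items()}
    focal_ml = mls[focal].set_index("child_id")["log_ml"]
    rows = []
    for m, df in mls.items():
        if m is focal:
            continue
        for rec in df.itertuples(index=False):
            log_bf = float(focal_ml[rec.child_id] - rec.log_ml)
            rows.append(
                {
                    "child_id": rec.child_id,
                    "pair": f"{focal.value}_vs_{m.value}",
                    "log_ml_focal": float(focal_ml[rec.child_id]),
                    "log_ml_alt": rec.log_ml,
                    "log_bf": log_bf,
                    "category": classify_bf(log_bf),
                }
            )
    return pd.DataFrame(rows)
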