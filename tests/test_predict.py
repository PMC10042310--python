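"""MAP estimation, coin-flip binarization, match rates, chance comparison
and group-level correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from pragint.fitting import FitConfig, PosteriorDraws
from pragint.hierarchy import ChildRoster
from pragint.predict import (
    CombinationPredictions,
    binarize,
    chance_comparison,
    group_correlation,
    map_estimate,
    match_rate,
    predict_combination,
)
from pragint.tasks import ListenerModel


# -- map_estimate -----------------------------------------------------------


def test_map_degenerate_samples():
    assert map_estimate(np.full(100, 0.6)) == 0.6
    assert map_estimate([0.25]) == 0.25
    with pytest.raises(ValueError):
        map_estimate([])


def test_map_symmetric_samples_near_center(rng):
    x = rng.normal(0.5, 0.08, 2000)
    x = np.clip(np.concatenate([x, 1 - x]), 0, 1)  # exactly mirrored
    assert map_estimate(x) == pytest.approx(0.5, abs=0.02)


def test_map_bimodal_prefers_heavier_cluster(rng):
    """Histogram-count oracle: the mode should sit in the heavier cluster."""
    x = np.concatenate([rng.normal(0.2, 0.03, 300), rng.normal(0.8, 0.03, 700)])
    x = np.clip(x, 0, 1)
    counts, edges = np.histogram(x, bins=20, range=(0, 1))
    oracle_bin = edges[np.argmax(counts)]
    m = map_estimate(x)
    assert abs(m - (oracle_bin + 0.025)) < 0.1
    assert m > 0.6


# -- binarize ---------------------------------------------------------------


def test_binarize_endpoints_and_lln():
    assert binarize(1.0, 0) == 1
    assert binarize(0.0, 0) == 0
    rng = np.random.default_rng(7)
    flips = [binarize(0.7, rng) for _ in range(10000)]
    assert np.mean(flips) == pytest.approx(0.7, abs=0.015)
    # seeded reproducibility
    assert binarize(0.7, 99) == binarize(0.7, 99)


# -- match_rate -------------------------------------------------------------


def _preds_from(p_map, responses, child_ids=None):
    t = len(p_map)
    table = pd.DataFrame(
        {
            "child_id": child_ids if child_ids is not None else ["c0"] * t,
            "trial": range(t),
            "item_id": [0] * t,
            "condition": ["congruent"] * t,
            "model": ["rational"] * t,
            "p_map": p_map,
            "response": responses,
        }
    )
    return CombinationPredictions(
        model=ListenerModel.RATIONAL,
        table=table,
        p_novel_draws=np.asarray(p_map)[:, None],
    )


def test_match_rate_perfect_predictor():
    resp = [1, 0, 1, 1, 0]
    summ = match_rate(_preds_from([1.0, 0.0, 1.0, 1.0, 0.0], resp), runs=50, seed=3)
    assert summ.proportion_matched == 1.0
    assert np.all(summ.run_proportions == 1.0)
    assert summ.n_trials == 5


def test_match_rate_chance_predictor():
    resp = [0, 1] * 100
    summ = match_rate(_preds_from([0.5] * 200, resp), runs=400, seed=3)
    assert summ.run_proportions.mean() == pytest.approx(0.5, abs=0.02)
    assert len(summ.run_proportions) == 400


def test_match_rate_seed_reproducible():
    resp = [1, 0, 1, 0]
    a = match_rate(_preds_from([0.6, 0.4, 0.7, 0.2], resp), runs=10, seed=5)
    b = match_rate(_preds_from([0.6, 0.4, 0.7, 0.2], resp), runs=10, seed=5)
    np.testing.assert_array_equal(a.run_proportions, b.run_proportions)
    assert a.proportion_matched == b.proportion_matched


# -- chance comparison (JZS Bayes factor) -----------------------------------


def _jzs_bf10_oracle(t, n, r=0.707):
    """Numerical integration of the JZS Bayes factor (Cauchy prior on the
    standardized effect, scale r), independent of the library used."""
    nu = n - 1

    def h1(g):
        return (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** (-1.5)
            * np.exp(-1 / (2 * g))
        )

    num, _ = integrate.quad(h1, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


def test_chance_bf_matches_quadrature_oracle():
    x = np.array([0.55, 0.62, 0.58, 0.71, 0.66, 0.60, 0.52, 0.68])
    res = chance_comparison(x, chance=0.5, seed=1)
    oracle = _jzs_bf10_oracle(res["t"], res["n"])
    assert res["bf10"] == pytest.approx(oracle, rel=1e-3)


def test_chance_bf_directionality():
    null = chance_comparison(np.full(20, 0.5) + np.linspace(-0.001, 0.001, 20), seed=1)
    assert null["bf10"] < 1
    strong = chance_comparison(np.linspace(0.7, 0.75, 20), seed=1)
    assert strong["bf10"] > 100
    lo, hi = strong["ci95"]
    assert lo <= strong["mean"] <= hi


# -- group correlation ------------------------------------------------------


def test_group_correlation_perfect_and_degenerate():
    # one child per whole-year age bin, so each (trial, bin) cell is one trial
    roster = pd.DataFrame({"child_id": [f"c{i}" for i in range(4)], "age_years": [3.2, 4.4, 5.1, 6.6]})
    p_map = [1.0, 0.0, 1.0, 0.0]  # predictions equal to the aggregated data
    resp = [1, 0, 1, 0]
    preds = _preds_from(p_map, resp, child_ids=["c0", "c1", "c2", "c3"])
    out = group_correlation(preds, roster)
    assert out["flag"] is None
    assert out["r"] == pytest.approx(1.0)
    assert out["r2"] == pytest.approx(out["r"] ** 2)

    flat = _preds_from([0.5] * 4, resp, child_ids=["c0", "c1", "c2", "c3"])
    out = group_correlation(flat, roster)
    assert out["flag"] == "zero variance"
    assert np.isnan(out["r"])


# -- predict_combination contracts ------------------------------------------


def _single_draw_fit():
    """A posterior collapsed to one draw with known parameter values."""
    h = np.array([[[0.0, 0.0, 0.5, 0.25, 1.0, 0.0, 0.5, np.log(0.88 / 0.12), 0.0, 0.5, 0.8]]])
    roster = ChildRoster(["c0"], np.array([3.0]))
    return PosteriorDraws(
        hyper=h,
        items=np.full((1, 1, 16, 2), [40.0, 0.0]),  # theta -> 1 (to fp precision)
        latents={"me": np.zeros((1, 1, 1)), "rho": np.zeros((1, 1, 1))},
        roster=roster,
        config=FitConfig(),
        diagnostics={},
    )


def _comb_trials():
    return pd.DataFrame(
        {
            "child_id": ["c0", "c0"],
            "task": ["combination", "combination"],
            "item_id": [0, 1],
            "condition": ["congruent", "incongruent"],
            "response": [1, 0],
        }
    )


def test_single_draw_prediction_equals_deterministic_model():
    fit = _single_draw_fit()
    pred = predict_combination(fit, _comb_trials(), ListenerModel.RATIONAL, max_draws=None)
    assert pred.p_novel_draws.shape == (2, 1)
    # alpha=1, theta=1, rho=0.88: congruent -> 0.88/(0.88+0.12/3)
    assert pred.table["p_map"][0] == pytest.approx(0.88 / (0.88 + 0.12 / 3), abs=1e-9)
    # incongruent prior 0.12 -> 0.12/(0.12+0.88/3)
    assert pred.table["p_map"][1] == pytest.approx(0.12 / (0.12 + 0.88 / 3), abs=1e-9)

    no_si = predict_combination(fit, _comb_trials(), ListenerModel.NO_SI, max_draws=None)
    assert no_si.table["p_map"].tolist() == pytest.approx([0.88, 0.12], abs=1e-9)

    no_cg = predict_combination(fit, _comb_trials(), ListenerModel.NO_CG, max_draws=None)
    assert no_cg.table["p_map"][0] == no_cg.table["p_map"][1]  # condition-blind


def test_predict_rejects_unknown_children():
    fit = _single_draw_fit()
    trials = _comb_trials()
    trials.loc[0, "child_id"] = "ghost"
    with pytest.raises(ValueError, match="unfitted"):
        predict_combination(fit, trials, ListenerModel.RATIONAL)
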