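"""Posterior sampling for the Part-1 hierarchy.

The sampler is an adaptive Metropolis-within-Gibbs scheme tailored to the
model's conditional-independence structure: given the population-level
parameters, children are independent (so all child latents in a family are
proposed simultaneously and accepted per child) and items are independent
(so all 16 item trajectories are proposed simultaneously and accepted per
item).  The eleven population-level parameters are updated one at a time by
random-walk Metropolis, each against only the density terms it touches.
Dispersions are sampled on the log scale and gamma on the logit scale, with
the appropriate Jacobian corrections.

Proposal scales adapt per coordinate during warmup (Robbins-Monro toward a
0.44 acceptance rate) and are frozen afterwards, preserving detailed
balance in the sampling phase.  Runs are deterministic given (seed, chain).

Convergence is summarized with split-R-hat and effective sample size
(arviz) for every sampled population-level parameter; a fit whose worst
R-hat exceeds the configured threshold is flagged, not rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit, xlogy

from .hierarchy import (
    HYPER_NAMES,
    ChildLatents,
    ChildRoster,
    HyperpriorConfig,
    Hyperparams,
    ItemEffects,
    Part1Data,
    _halfnormal_logpdf,
    _masked_bernoulli_ll,
    _normal_logpdf,
    realize_arrays,
)
from .rsa import p_novel_pragmatic
from .tasks import N_ITEMS

__all__ = ["FitConfig", "PosteriorDraws", "fit_part1", "developmental_curve"]

_IDX = {name: i for i, name in enumerate(HYPER_NAMES)}
_SIGMA_IDX = (2, 3, 6, 9)
_GAMMA_IDX = 10
_TARGET_ACCEPT = 0.44


@dataclass
class FitConfig:
    """Sampler settings; the defaults suit the study-scale design (N=60)."""

    chains: int = 3
    draws: int = 1000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    latent_mode: str = "joint_me"  # "joint_me" | "separate" | "single"
    sigma_theta_latent: float = 0.5  # only used in "separate" mode
    hyperprior: HyperpriorConfig = field(default_factory=HyperpriorConfig)
    fixed_hypers: dict = field(default_factory=dict)  # name -> constrained value
    fixed_item_slopes: float | None = None


def _to_sampling(h_con: np.ndarray) -> np.ndarray:
    h = np.array(h_con, dtype=float)
    for i in _SIGMA_IDX:
        h[i] = np.log(h[i])
    h[_GAMMA_IDX] = logit(h[_GAMMA_IDX])
    return h


def _to_constrained(h_samp: np.ndarray) -> np.ndarray:
    h = np.array(h_samp, dtype=float)
    for i in _SIGMA_IDX:
        h[i] = np.exp(h[i])
    h[_GAMMA_IDX] = expit(h[_GAMMA_IDX])
    return h


def _latent_names(mode: str) -> list[str]:
    return {"joint_me": ["me", "rho"], "separate": ["theta", "alpha", "rho"], "single": ["all"]}[mode]


def _family_latent(mode: str, family: str) -> str:
    """Which latent vector drives the given parameter family."""
    if mode == "joint_me":
        return {"theta": "me", "alpha": "me", "rho": "rho"}[family]
    if mode == "separate":
        return family
    return "all"


class _Part1Sampler:
    """Metropolis-within-Gibbs on the non-centered parameterization.

    Item effects and child latents are represented as standardized
    deviates (u for items, z for latents) so that dispersion updates move
    the realized parameters through the likelihood rather than only
    through the hierarchy's prior terms — the standard remedy for the
    poor mixing of weakly identified hierarchical scales.
    """

    def __init__(self, data: Part1Data, config: FitConfig):
        self.data = data
        self.cfg = config
        self.k = data.roster.age_std
        self.n = data.roster.n_children
        self.j = data.n_items
        self.mode = config.latent_mode
        self.latent_names = _latent_names(self.mode)
        self.t_lat = _family_latent(self.mode, "theta")
        self.a_lat = _family_latent(self.mode, "alpha")
        self.r_lat = _family_latent(self.mode, "rho")
        self.free_hypers = [i for i, n in enumerate(HYPER_NAMES) if n not in config.fixed_hypers]
        if config.fixed_item_slopes is not None:
            for req in ("mu1_theta", "sigma1_theta"):
                if req not in config.fixed_hypers:
                    raise ValueError("fixed_item_slopes requires fixing mu1_theta and sigma1_theta")

    # -- likelihood pieces --------------------------------------------------

    def _me_ll(self, theta, alpha):
        return _masked_bernoulli_ll(self.data.me, p_novel_pragmatic(alpha[:, None], theta, 0.5))

    def _comp_ll(self, theta):
        return _masked_bernoulli_ll(self.data.comp, theta + (1.0 - theta) / 6.0)

    def _prod_ll(self, theta, gamma):
        return _masked_bernoulli_ll(self.data.prod, theta * gamma)

    def _disc_ll(self, rho):
        return xlogy(self.data.disc_k, rho) + xlogy(self.data.disc_n - self.data.disc_k, 1.0 - rho)

    def _latent_sigma(self, name: str, h_con: np.ndarray) -> float:
        if name == "rho":
            return h_con[_IDX["sigma_i_rho"]]
        if name == "theta":
            return self.cfg.sigma_theta_latent
        return h_con[_IDX["sigma_i_alpha"]]  # "me", "alpha", "all"

    def _hyperprior_term(self, i: int, x_samp: float) -> float:
        hp = self.cfg.hyperprior
        if i in _SIGMA_IDX:
            s = np.exp(x_samp)
            return float(_halfnormal_logpdf(s, hp.sigma_scale)) + x_samp  # + log-Jacobian
        if i == _GAMMA_IDX:
            g = expit(x_samp)
            return float(np.log(g) + np.log1p(-g))  # Uniform(0,1) x logit Jacobian
        return float(_normal_logpdf(x_samp, 0.0, hp.loc_scale))

    # -- derived quantities -------------------------------------------------

    def _derive_items(self, h_con, u):
        return np.column_stack(
            [h_con[0] + h_con[2] * u[:, 0], h_con[1] + h_con[3] * u[:, 1]]
        )

    def _derive_lat(self, h_con, z, name):
        return self.k + self._latent_sigma(name, h_con) * z

    def _theta(self, items, lat_theta):
        return expit(items[None, :, 0] + lat_theta[:, None] * items[None, :, 1])

    def _alpha(self, h_con, lat_alpha):
        return np.maximum(0.0, h_con[4] + lat_alpha * h_con[5])

    def _rho(self, h_con, lat_rho):
        return expit(h_con[7] + lat_rho * h_con[8])

    def _refresh(self, hc, cur, ch_theta=False, ch_alpha=False, ch_rho=False, ch_gamma=False):
        """Recompute the realized arrays / likelihood pieces that a candidate
        state invalidates; returns (log-likelihood delta, replacements)."""
        upd = {}
        delta = 0.0
        theta, alpha = cur["theta"], cur["alpha"]
        if ch_theta:
            theta = self._theta(upd.get("items", cur["items"]), cur["lats"][self.t_lat])
        if ch_alpha:
            alpha = self._alpha(hc, cur["lats"][self.a_lat])
            upd["alpha"] = alpha
        if ch_theta or ch_alpha:
            me = self._me_ll(theta, alpha)
            upd["me"] = me
            delta += me.sum() - cur["me"].sum()
        if ch_theta:
            upd["theta"] = theta
            comp = self._comp_ll(theta)
            upd["comp"] = comp
            delta += comp.sum() - cur["comp"].sum()
        if ch_theta or ch_gamma:
            prod = self._prod_ll(theta, hc[_GAMMA_IDX])
            upd["prod"] = prod
            delta += prod.sum() - cur["prod"].sum()
        if ch_rho:
            rho = self._rho(hc, cur["lats"][self.r_lat])
            disc = self._disc_ll(rho)
            upd["rho"], upd["disc"] = rho, disc
            delta += disc.sum() - cur["disc"].sum()
        return delta, upd

    # -- one chain ----------------------------------------------------------

    def run_chain(self, chain: int):
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, chain, 2029])
        n, j = self.n, self.j

        # init (sampling space), jittered per chain
        h = np.zeros(len(HYPER_NAMES))
        h[list(_SIGMA_IDX)] = np.log(0.5)
        for name, val in cfg.fixed_hypers.items():
            i = _IDX[name]
            h[i] = np.log(val) if i in _SIGMA_IDX else (logit(val) if i == _GAMMA_IDX else val)
        free = np.array(self.free_hypers, dtype=int)
        if free.size:
            h[free] = h[free] + 0.3 * rng.standard_normal(free.size)
        h_con = _to_constrained(h)

        u = 0.2 * rng.standard_normal((j, 2))
        if cfg.fixed_item_slopes is not None:
            u[:, 1] = (cfg.fixed_item_slopes - h_con[1]) / h_con[3]
        z = {nm: 0.2 * rng.standard_normal(n) for nm in self.latent_names}

        cur = {"items": self._derive_items(h_con, u)}
        cur["lats"] = {nm: self._derive_lat(h_con, z[nm], nm) for nm in self.latent_names}
        cur["theta"] = self._theta(cur["items"], cur["lats"][self.t_lat])
        cur["alpha"] = self._alpha(h_con, cur["lats"][self.a_lat])
        cur["rho"] = self._rho(h_con, cur["lats"][self.r_lat])
        cur["me"] = self._me_ll(cur["theta"], cur["alpha"])
        cur["comp"] = self._comp_ll(cur["theta"])
        cur["prod"] = self._prod_ll(cur["theta"], h_con[_GAMMA_IDX])
        cur["disc"] = self._disc_ll(cur["rho"])

        # which realized families each hyperparameter feeds into
        sigma_a_latents = [nm for nm in self.latent_names if nm in ("me", "alpha", "all")]
        def hyper_flags(i):
            if i in (0, 1, 2, 3):
                return dict(ch_theta=True)
            if i in (4, 5):
                return dict(ch_alpha=True)
            if i == 6:
                return dict(
                    ch_theta=self.t_lat in sigma_a_latents,
                    ch_alpha=self.a_lat in sigma_a_latents,
                    ch_rho=self.r_lat in sigma_a_latents,
                )
            if i in (7, 8):
                return dict(ch_rho=True)
            if i == 9:
                return dict(ch_rho=self.r_lat == "rho")
            return dict(ch_gamma=True)

        h_scale = np.full(len(HYPER_NAMES), 0.2)
        item_scale = np.full((j, 2), 0.3)
        lat_scale = {nm: np.full(n, 0.3) for nm in self.latent_names}

        # intercept/slope pairs are strongly anticorrelated (age is not
        # centered), so coordinate-wise walks mix slowly; joint proposals
        # with a warmup-estimated covariance fix that
        pair_flags = {(0, 1): dict(ch_theta=True), (4, 5): dict(ch_alpha=True), (7, 8): dict(ch_rho=True)}
        pairs = [p for p in pair_flags if p[0] in self.free_hypers and p[1] in self.free_hypers]
        pair_hist = {p: [] for p in pairs}
        pair_chol = {p: 0.2 * np.eye(2) for p in pairs}
        pair_scale = {p: 1.0 for p in pairs}
        asis_scale = np.full(len(HYPER_NAMES), 0.2)

        n_sweeps = cfg.warmup + cfg.draws * cfg.thin
        keep_h = np.empty((cfg.draws, len(HYPER_NAMES)))
        keep_items = np.empty((cfg.draws, j, 2))
        keep_lats = {nm: np.empty((cfg.draws, n)) for nm in self.latent_names}

        def adapt(scale_arr, acc, idx, t):
            step = 1.0 / (t + 1.0) ** 0.6
            scale_arr[idx] = scale_arr[idx] * np.exp(step * (acc - _TARGET_ACCEPT))

        kept = 0
        for t in range(n_sweeps):
            warm = t < cfg.warmup

            # --- population-level parameters, one at a time ---
            for i in self.free_hypers:
                x_new = h[i] + h_scale[i] * rng.standard_normal()
                hc_new = h_con.copy()
                hc_new[i] = (
                    np.exp(x_new)
                    if i in _SIGMA_IDX
                    else (expit(x_new) if i == _GAMMA_IDX else x_new)
                )
                flags = hyper_flags(i)
                trial = dict(cur)
                if i in (0, 1, 2, 3):
                    trial["items"] = self._derive_items(hc_new, u)
                if i == 6:
                    trial["lats"] = dict(cur["lats"])
                    for nm in sigma_a_latents:
                        trial["lats"][nm] = self._derive_lat(hc_new, z[nm], nm)
                if i == 9 and self.r_lat == "rho":
                    trial["lats"] = dict(cur["lats"])
                    trial["lats"]["rho"] = self._derive_lat(hc_new, z["rho"], "rho")
                delta, upd = self._refresh(hc_new, trial, **flags)
                delta += self._hyperprior_term(i, x_new) - self._hyperprior_term(i, h[i])

                if np.log(rng.uniform()) < delta:
                    acc = 1.0
                    h[i] = x_new
                    h_con = hc_new
                    cur.update(upd)
                    cur["items"] = trial["items"]
                    cur["lats"] = trial["lats"]
                else:
                    acc = 0.0
                if warm:
                    adapt(h_scale, acc, i, t)

            # --- joint intercept/slope proposals for the trajectory pairs ---
            for p in pairs:
                i1, i2 = p
                step = pair_scale[p] * (pair_chol[p] @ rng.standard_normal(2))
                x1, x2 = h[i1] + step[0], h[i2] + step[1]
                hc_new = h_con.copy()
                hc_new[i1], hc_new[i2] = x1, x2  # all six are location params
                trial = dict(cur)
                if p == (0, 1):
                    trial["items"] = self._derive_items(hc_new, u)
                delta, upd = self._refresh(hc_new, trial, **pair_flags[p])
                delta += (
                    self._hyperprior_term(i1, x1)
                    + self._hyperprior_term(i2, x2)
                    - self._hyperprior_term(i1, h[i1])
                    - self._hyperprior_term(i2, h[i2])
                )
                if np.log(rng.uniform()) < delta:
                    acc = 1.0
                    h[i1], h[i2] = x1, x2
                    h_con = hc_new
                    cur.update(upd)
                    cur["items"] = trial["items"]
                else:
                    acc = 0.0
                if warm:
                    pair_hist[p].append((h[i1], h[i2]))
                    pair_scale[p] *= np.exp((acc - 0.3) / (t + 1.0) ** 0.6)
                    if len(pair_hist[p]) >= 200 and t % 100 == 0:
                        cov = np.cov(np.array(pair_hist[p][-1000:]).T)
                        cov = 2.88 * cov + 1e-8 * np.eye(2)  # 2.38^2 / d
                        try:
                            pair_chol[p] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass

            # --- item trajectories (standardized deviates), per item ---
            u_prop = u + item_scale * rng.standard_normal((j, 2))
            if cfg.fixed_item_slopes is not None:
                u_prop[:, 1] = u[:, 1]
            items_prop = self._derive_items(h_con, u_prop)
            theta_new = self._theta(items_prop, cur["lats"][self.t_lat])
            me_new = self._me_ll(theta_new, cur["alpha"])
            comp_new = self._comp_ll(theta_new)
            prod_new = self._prod_ll(theta_new, h_con[_GAMMA_IDX])
            delta_j = (
                0.5 * (u**2 - u_prop**2).sum(axis=1)
                + (me_new + comp_new + prod_new - cur["me"] - cur["comp"] - cur["prod"]).sum(axis=0)
            )
            acc_j = np.log(rng.uniform(size=j)) < delta_j
            if acc_j.any():
                u[acc_j] = u_prop[acc_j]
                cur["items"][acc_j] = items_prop[acc_j]
                cur["theta"][:, acc_j] = theta_new[:, acc_j]
                cur["me"][:, acc_j] = me_new[:, acc_j]
                cur["comp"][:, acc_j] = comp_new[:, acc_j]
                cur["prod"][:, acc_j] = prod_new[:, acc_j]
            if warm:
                adapt(item_scale, acc_j[:, None].astype(float), slice(None), t)

            # --- interweaved (centered) updates of the theta moments ---
            # holding the realized item effects fixed, the conditional for
            # (mu, sigma) involves only the item-prior terms; afterwards the
            # standardized deviates are recomputed.  Interweaving both
            # parameterizations mixes well whether items are data-rich or not.
            b_cur = cur["items"]
            for i in (0, 1, 2, 3):
                if i not in self.free_hypers:
                    continue
                x_new = h[i] + asis_scale[i] * rng.standard_normal()
                hc_new = h_con.copy()
                hc_new[i] = np.exp(x_new) if i in _SIGMA_IDX else x_new
                col = 0 if i in (0, 2) else 1
                mu_o, s_o = h_con[col], h_con[col + 2]
                mu_n, s_n = hc_new[col], hc_new[col + 2]
                delta = (
                    _normal_logpdf(b_cur[:, col], mu_n, s_n).sum()
                    - _normal_logpdf(b_cur[:, col], mu_o, s_o).sum()
                    + self._hyperprior_term(i, x_new)
                    - self._hyperprior_term(i, h[i])
                )
                acc = float(np.log(rng.uniform()) < delta)
                if acc:
                    h[i] = x_new
                    h_con = hc_new
                if warm:
                    adapt(asis_scale, acc, i, t)
            u[:, 0] = (b_cur[:, 0] - h_con[0]) / h_con[2]
            u[:, 1] = (b_cur[:, 1] - h_con[1]) / h_con[3]

            # --- child latents (standardized deviates), per child ---
            for nm in self.latent_names:
                z_prop = z[nm] + lat_scale[nm] * rng.standard_normal(n)
                lat_prop = self._derive_lat(h_con, z_prop, nm)
                delta_i = 0.5 * (z[nm] ** 2 - z_prop**2)
                upd = {}
                if nm == self.t_lat:
                    theta_n = expit(
                        cur["items"][None, :, 0] + lat_prop[:, None] * cur["items"][None, :, 1]
                    )
                    comp_n = self._comp_ll(theta_n)
                    prod_n = self._prod_ll(theta_n, h_con[_GAMMA_IDX])
                    upd.update(theta=theta_n, comp=comp_n, prod=prod_n)
                    if nm == self.a_lat:
                        alpha_n = self._alpha(h_con, lat_prop)
                        me_n = self._me_ll(theta_n, alpha_n)
                        upd["alpha"] = alpha_n
                    else:
                        me_n = self._me_ll(theta_n, cur["alpha"])
                    upd["me"] = me_n
                    delta_i += (
                        me_n + comp_n + prod_n - cur["me"] - cur["comp"] - cur["prod"]
                    ).sum(axis=1)
                elif nm == self.a_lat:
                    alpha_n = self._alpha(h_con, lat_prop)
                    me_n = self._me_ll(cur["theta"], alpha_n)
                    upd.update(alpha=alpha_n, me=me_n)
                    delta_i += (me_n - cur["me"]).sum(axis=1)
                if nm == self.r_lat:
                    rho_n = self._rho(h_con, lat_prop)
                    disc_n = self._disc_ll(rho_n)
                    upd.update(rho=rho_n, disc=disc_n)
                    delta_i += disc_n - cur["disc"]

                acc_i = np.log(rng.uniform(size=n)) < delta_i
                if acc_i.any():
                    z[nm][acc_i] = z_prop[acc_i]
                    cur["lats"][nm][acc_i] = lat_prop[acc_i]
                    if "theta" in upd:
                        cur["theta"][acc_i] = upd["theta"][acc_i]
                        cur["comp"][acc_i] = upd["comp"][acc_i]
                        cur["prod"][acc_i] = upd["prod"][acc_i]
                    if "me" in upd:
                        cur["me"][acc_i] = upd["me"][acc_i]
                    if "alpha" in upd:
                        cur["alpha"][acc_i] = upd["alpha"][acc_i]
                    if "rho" in upd:
                        cur["rho"][acc_i] = upd["rho"][acc_i]
                        cur["disc"][acc_i] = upd["disc"][acc_i]
                if warm:
                    adapt(lat_scale[nm], acc_i.astype(float), slice(None), t)

            if not warm and (t - cfg.warmup) % cfg.thin == 0 and kept < cfg.draws:
                keep_h[kept] = h_con
                keep_items[kept] = cur["items"]
                for nm in self.latent_names:
                    keep_lats[nm][kept] = cur["lats"][nm]
                kept += 1

        return keep_h, keep_items, keep_lats


@dataclass
class PosteriorDraws:
    """Posterior draws of all latent quantities from a Part-1 fit.

    Arrays are indexed (chain, draw, ...); hyper draws are on the
    constrained scale (sigmas positive, gamma in [0, 1]).
    """

    hyper: np.ndarray  # (C, S, 11)
    items: np.ndarray  # (C, S, J, 2)
    latents: dict  # name -> (C, S, N)
    roster: ChildRoster
    config: FitConfig
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.hyper.shape[0] * self.hyper.shape[1]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def hyper_flat(self) -> np.ndarray:
        return self.hyper.reshape(-1, self.hyper.shape[-1])

    def hyper_df(self) -> pd.DataFrame:
        c, s, _ = self.hyper.shape
        df = pd.DataFrame(self.hyper_flat(), columns=HYPER_NAMES)
        df.insert(0, "draw", np.tile(np.arange(s), c))
        df.insert(0, "chain", np.repeat(np.arange(c), s))
        return df

    def realize(self, max_draws: int | None = None, rng: np.random.Generator | None = None):
        """Realized (theta, alpha, rho, gamma) per flattened posterior draw.

        Returns theta (S, N, J), alpha (S, N), rho (S, N), gamma (S,).
        When ``max_draws`` is set, draws are evenly strided down to it.
        """
        mode = self.config.latent_mode
        h = self.hyper_flat()
        items = self.items.reshape(-1, *self.items.shape[2:])
        lat = {nm: v.reshape(-1, v.shape[-1]) for nm, v in self.latents.items()}
        s_total = h.shape[0]
        if max_draws is not None and max_draws < s_total:
            sel = np.linspace(0, s_total - 1, max_draws).astype(int)
            h, items = h[sel], items[sel]
            lat = {nm: v[sel] for nm, v in lat.items()}
        lt = lat[_family_latent(mode, "theta")]
        la = lat[_family_latent(mode, "alpha")]
        lr = lat[_family_latent(mode, "rho")]
        theta = expit(items[:, None, :, 0] + lt[:, :, None] * items[:, None, :, 1])
        alpha = np.maximum(0.0, h[:, 4, None] + la * h[:, 5, None])
        rho = expit(h[:, 7, None] + lr * h[:, 8, None])
        return theta, alpha, rho, h[:, _GAMMA_IDX]

    def hyper_ci(self, prob: float = 0.90) -> pd.DataFrame:
        """Posterior mean and central credible interval per hyperparameter."""
        flat = self.hyper_flat()
        lo = np.percentile(flat, 100 * (1 - prob) / 2, axis=0)
        hi = np.percentile(flat, 100 * (1 + prob) / 2, axis=0)
        return pd.DataFrame(
            {"name": HYPER_NAMES, "mean": flat.mean(axis=0), "lo": lo, "hi": hi}
        )

    # -- serialization ------------------------------------------------------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.hyper_df()
        j = self.items.shape[2]
        flat_items = self.items.reshape(-1, j, 2)
        for jj in range(j):
            df[f"b0_theta_{jj}"] = flat_items[:, jj, 0]
            df[f"b1_theta_{jj}"] = flat_items[:, jj, 1]
        for nm, v in self.latents.items():
            flat = v.reshape(-1, v.shape[-1])
            for i, cid in enumerate(self.roster.child_id):
                df[f"lat_{nm}_{cid}"] = flat[:, i]
        df.to_csv(outdir / "draws.csv", index=False)
        sidecar = {
            "config": _config_dict(self.config),
            "age_ref": self.roster.age_ref,
            "child_id": [str(c) for c in self.roster.child_id],
            "age_years": self.roster.age_years.tolist(),
            "n_items": int(j),
            "latent_names": list(self.latents.keys()),
            "diagnostics": self.diagnostics,
        }
        (outdir / "fit.json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        meta = json.loads((outdir / "fit.json").read_text())
        df = pd.read_csv(outdir / "draws.csv")
        chains = int(df["chain"].max()) + 1
        draws = int(df["draw"].max()) + 1
        j = meta["n_items"]
        hyper = df[HYPER_NAMES].to_numpy().reshape(chains, draws, -1)
        items = np.stack(
            [
                np.stack([df[f"b0_theta_{jj}"], df[f"b1_theta_{jj}"]], axis=-1)
                for jj in range(j)
            ],
            axis=1,
        ).reshape(chains, draws, j, 2)
        latents = {}
        for nm in meta["latent_names"]:
            cols = [f"lat_{nm}_{cid}" for cid in meta["child_id"]]
            latents[nm] = df[cols].to_numpy().reshape(chains, draws, -1)
        roster = ChildRoster(
            child_id=meta["child_id"],
            age_years=np.array(meta["age_years"]),
            age_ref=meta["age_ref"],
        )
        cfg_d = dict(meta["config"])
        cfg_d["hyperprior"] = HyperpriorConfig(**cfg_d["hyperprior"])
        return PosteriorDraws(
            hyper=hyper,
            items=items,
            latents=latents,
            roster=roster,
            config=FitConfig(**cfg_d),
            diagnostics=meta["diagnostics"],
        )


def _config_dict(cfg: FitConfig) -> dict:
    d = asdict(cfg)
    return d


def fit_part1(
    trials: pd.DataFrame,
    roster: ChildRoster | pd.DataFrame,
    config: FitConfig | None = None,
    n_items: int = N_ITEMS,
) -> PosteriorDraws:
    """Sample the Part-1 posterior from the four sensitivity tasks.

    ``trials`` follows the trial CSV schema (child_id, task, item_id,
    condition, response); combination rows, if present, are ignored here.
    Returns posterior draws with split-R-hat / ESS diagnostics attached;
    identical (data, config) including seed reproduce identical draws.
    """
    config = config or FitConfig()
    if isinstance(roster, pd.DataFrame):
        roster = ChildRoster.from_frame(roster)
    data = Part1Data.from_frame(trials, roster, n_items=n_items)
    sampler = _Part1Sampler(data, config)

    hs, its, lts = [], [], []
    for chain in range(config.chains):
        kh, ki, kl = sampler.run_chain(chain)
        hs.append(kh)
        its.append(ki)
        lts.append(kl)
    hyper = np.stack(hs)
    items = np.stack(its)
    latents = {nm: np.stack([kl[nm] for kl in lts]) for nm in lts[0]}

    free = [HYPER_NAMES[i] for i in sampler.free_hypers]
    diagnostics = _diagnose(hyper, free, config)
    return PosteriorDraws(
        hyper=hyper,
        items=items,
        latents=latents,
        roster=roster,
        config=config,
        diagnostics=diagnostics,
    )


def _diagnose(hyper: np.ndarray, free_names: list[str], config: FitConfig) -> dict:
    posterior = {n: hyper[:, :, _IDX[n]] for n in free_names}
    rhat, ess = {}, {}
    if free_names and hyper.shape[0] >= 2 and hyper.shape[1] >= 4:
        idata = az.from_dict(posterior=posterior)
        r = az.rhat(idata)
        e = az.ess(idata)
        rhat = {n: float(r[n].values) for n in free_names}
        ess = {n: float(e[n].values) for n in free_names}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and max(finite) < config.rhat_threshold
    return {
        "rhat": rhat,
        "ess": ess,
        "converged": converged,
        "rhat_threshold": config.rhat_threshold,
    }


def developmental_curve(
    draws: PosteriorDraws, family: str, age_grid: np.ndarray, hdi_prob: float = 0.95
) -> pd.DataFrame:
    """Population developmental trajectory of one parameter family.

    For each age on the grid (standardized years, youngest child = 0) the
    population-level transform of the hyperparameter draws is summarized by
    its posterior mean and HDI: logistic(mu0 + age * mu1) for THETA,
    logistic(b0 + age * b1) for RHO, and max(0, b0 + age * b1) for ALPHA.
    """
    fam = family.lower()
    flat = draws.hyper_flat()
    coef = {
        "theta": (flat[:, 0], flat[:, 1]),
        "alpha": (flat[:, 4], flat[:, 5]),
        "rho": (flat[:, 7], flat[:, 8]),
    }
    if fam not in coef:
        raise ValueError(f"family must be theta/alpha/rho, got {family}")
    b0, b1 = coef[fam]
    age_grid = np.asarray(age_grid, dtype=float)
    lin = b0[:, None] + age_grid[None, :] * b1[:, None]
    curve = np.maximum(0.0, lin) if fam == "alpha" else expit(lin)
    hdi = az.hdi(curve[None, :, :], hdi_prob=hdi_prob)
    return pd.DataFrame(
        {
            "age_std": age_grid,
            "mean": curve.mean(axis=0),
            "hdi_lo": hdi[:, 0],
            "hdi_hi": hdi[:, 1],
        }
    )
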