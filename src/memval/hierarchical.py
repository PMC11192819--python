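"""Hierarchical Bayesian regression models of willingness-to-pay.

Each candidate model regresses the trial bid on one predictor (or two for the
"both" model) with a participant-specific random intercept:

    bid_ij ~ Normal(b0 + u_j + sum_k beta_k * x_ijk, sigma),   u_j ~ Normal(0, tau)

with weakly informative priors: Normal(1, 0.5) on each slope, Normal(0, 10) on
the population intercept, half-Student-t(3, 0, 10) on both the group spread tau
and the residual spread sigma, and Uniform(0, 1) on the temporal-difference
learning rate alpha.  The TD model's predictor is recomputed inside the
sampler as a function of alpha, so (alpha, b0, beta, tau, sigma) have a joint
posterior.

The participant intercepts are integrated out analytically (the per-participant
marginal is Gaussian with compound-symmetry covariance sigma^2 I + tau^2 J), so
the sampler only explores the 4-6 population-level parameters; posterior draws
of the u_j are recovered exactly from their conjugate conditional.  Sampling
uses an affine-invariant ensemble sampler (emcee), one independent ensemble
per chain, with convergence summarised by the maximum rank-normalised split
R-hat across parameters.  The log marginal likelihood — the quantity the
model comparison ranks — is estimated by bridge sampling in the unconstrained
parametrisation (log tau, log sigma, logit alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .bridge import bridge_log_marginal_likelihood
from .design import build_design, td_weights
from .task import N_ITEMS

RHAT_THRESHOLD = 1.05

FIT_MODELS = ("recalled", "presented", "both", "td")


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters (GC scale)."""

    slope_mean: float = 1.0
    slope_sd: float = 0.5
    intercept_mean: float = 0.0
    intercept_sd: float = 10.0
    group_sd_df: float = 3.0
    group_sd_scale: float = 10.0
    resid_sd_df: float = 3.0
    resid_sd_scale: float = 10.0

    def __post_init__(self):
        for name in ("slope_sd", "intercept_sd", "group_sd_scale", "resid_sd_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: ``samples`` retained draws per chain after ``warmup``
    ensemble steps; defaults match the reference analysis settings."""

    warmup: int = 1000
    samples: int = 4000
    chains: int = 4
    n_walkers: int = 24
    seed: int | None = None

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence checks")

    @staticmethod
    def td_default(seed: int | None = None) -> "McmcConfig":
        return McmcConfig(warmup=5000, samples=10000, chains=4, seed=seed)

    @staticmethod
    def desk(seed: int | None = None) -> "McmcConfig":
        """Reduced settings for quick desk-scale runs and simulation studies."""
        return McmcConfig(warmup=300, samples=1500, chains=2, seed=seed)


def _log_half_t(x, df, scale):
    return np.log(2.0) + stats.t.logpdf(x / scale, df) - np.log(scale)


class _MarginalisedModel:
    """Batch log posterior of one candidate model in the unconstrained space.

    Parameter vector layout: (b0, slopes..., [logit_alpha], log_tau, log_sigma).
    """

    def __init__(self, design: pd.DataFrame, model: str, priors: PriorConfig):
        self.model = model
        self.priors = priors
        self.y = design["bid"].to_numpy(dtype=float)
        ids = design["participant_id"].to_numpy()
        self.participants, groups = np.unique(ids, return_inverse=True)
        self.n_groups = len(self.participants)
        self.G = np.zeros((self.n_groups, len(self.y)))
        self.G[groups, np.arange(len(self.y))] = 1.0
        self.n_j = self.G.sum(axis=1)
        self.group_index = groups

        if model == "recalled":
            self.X = design[["predictor_recalled"]].to_numpy(dtype=float)
        elif model == "presented":
            self.X = design[["predictor_presented"]].to_numpy(dtype=float)
        elif model == "both":
            self.X = design[["predictor_recalled", "predictor_presented"]].to_numpy(dtype=float)
        elif model == "td":
            self.V = design[[f"x{k}" for k in range(1, N_ITEMS + 1)]].to_numpy(dtype=float)
            self.X = None
        else:
            raise ValueError(f"model must be one of {FIT_MODELS}")
        if self.X is not None and np.isnan(self.X).any():
            raise ValueError("design contains missing predictors; build it with dropna=True")

        self.n_slopes = 2 if model == "both" else 1
        self.has_alpha = model == "td"
        self.param_names = (
            ["b0"]
            + (["beta_recall", "beta_presented"] if model == "both" else ["beta"])
            + (["logit_alpha"] if self.has_alpha else [])
            + ["log_tau", "log_sigma"]
        )
        self.ndim = len(self.param_names)

    # -- parameter unpacking ------------------------------------------------
    def _unpack(self, theta):
        theta = np.atleast_2d(theta)
        b0 = theta[:, 0]
        betas = theta[:, 1 : 1 + self.n_slopes]
        k = 1 + self.n_slopes
        alpha = None
        if self.has_alpha:
            alpha = 1.0 / (1.0 + np.exp(-theta[:, k]))
            k += 1
        log_tau, log_sigma = theta[:, k], theta[:, k + 1]
        return b0, betas, alpha, log_tau, log_sigma

    def linear_term(self, betas, alpha):
        """(n_draws, n_trials) slope contribution to the mean bid."""
        if self.has_alpha:
            W = td_weights(alpha)  # (n_draws, 7)
            xtd = W @ self.V.T  # (n_draws, n_trials)
            return betas[:, 0][:, None] * xtd
        return betas @ self.X.T

    def log_posterior(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        b0, betas, alpha, log_tau, log_sigma = self._unpack(theta)
        tau2 = np.exp(2.0 * log_tau)
        sigma2 = np.exp(2.0 * log_sigma)

        resid = self.y[None, :] - b0[:, None] - self.linear_term(betas, alpha)
        S = resid @ self.G.T  # (n_draws, J) per-participant residual sums
        SS = (resid**2) @ self.G.T

        # marginal over u_j: y_j ~ N(mean, sigma^2 I + tau^2 11')
        shrink = tau2[:, None] / (sigma2[:, None] + self.n_j[None, :] * tau2[:, None])
        quad = SS / sigma2[:, None] - shrink * S**2 / sigma2[:, None]
        logdet = self.n_j[None, :] * np.log(2.0 * np.pi * sigma2[:, None]) + np.log1p(
            self.n_j[None, :] * tau2[:, None] / sigma2[:, None]
        )
        loglik = -0.5 * np.sum(logdet + quad, axis=1)

        p = self.priors
        logprior = stats.norm.logpdf(b0, p.intercept_mean, p.intercept_sd)
        logprior = logprior + stats.norm.logpdf(betas, p.slope_mean, p.slope_sd).sum(axis=1)
        tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)
        logprior = logprior + _log_half_t(tau, p.group_sd_df, p.group_sd_scale) + log_tau
        logprior = logprior + _log_half_t(sigma, p.resid_sd_df, p.resid_sd_scale) + log_sigma
        if self.has_alpha:
            # Uniform(0,1) on alpha; logistic Jacobian
            logprior = logprior + np.log(alpha) + np.log1p(-alpha)
        out = loglik + logprior
        return out if len(out) > 1 else out[0]

    # -- initialisation -----------------------------------------------------
    def heuristic_start(self):
        y = self.y
        if self.has_alpha:
            x = (td_weights(0.5) @ self.V.T).ravel()
            X1 = np.column_stack([np.ones_like(y), x])
        else:
            X1 = np.column_stack([np.ones_like(y), self.X])
        coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ coef
        pm = self.G @ resid / self.n_j
        tau0 = max(float(np.std(pm)), 0.5)
        sig0 = max(float(np.std(resid - pm[self.group_index])), 0.5)
        start = [coef[0], *coef[1:]]
        if self.has_alpha:
            start.append(0.0)  # alpha = 0.5
        start += [np.log(tau0), np.log(sig0)]
        return np.asarray(start, dtype=float)

    def map_estimate(self):
        x0 = self.heuristic_start()
        res = optimize.minimize(
            lambda t: -float(self.log_posterior(t[None, :])),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-6},
        )
        return res.x if np.isfinite(res.fun) else x0


def _max_rhat(chains: np.ndarray, names) -> float:
    """Maximum rank-normalised split R-hat over parameters; ``chains`` has
    shape (n_chains, n_draws, n_params)."""
    import warnings

    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({n: chains[:, :, i] for i, n in enumerate(names)})
        r = az.rhat(ds)
    return float(max(r[n].item() for n in names))


class HierarchicalEvaluationModel(BaseEstimator):
    """Bayesian multilevel regression of bids on one candidate predictor.

    Parameters
    ----------
    model : {"recalled", "presented", "both", "td"}
        Which predictor(s) enter the mean: mean of recalled values, mean of
        presented values, both, or the temporal-difference value with a free
        learning rate.
    priors : PriorConfig, optional
    mcmc : McmcConfig, optional
        Defaults to the reference settings (1000 warmup, 4000 retained draws,
        4 chains; use ``McmcConfig.td_default()`` for the TD model).
    compute_lml : bool
        Estimate the log marginal likelihood by bridge sampling after fitting.

    Attributes
    ----------
    posterior_ : DataFrame of retained draws on the natural scale, one row per
        draw, with a ``chain`` column; ``chains * samples`` rows in total.
    intercepts_ : (n_draws, n_participants) conditional draws of the u_j.
    max_rhat_ : float
    log_marginal_likelihood_, lml_se_ : float
    """

    def __init__(self, model="presented", priors=None, mcmc=None, compute_lml=True):
        self.model = model
        self.priors = priors
        self.mcmc = mcmc
        self.compute_lml = compute_lml

    # -- sklearn plumbing ---------------------------------------------------
    def _resolved(self):
        priors = self.priors or PriorConfig()
        if self.mcmc is not None:
            mcmc = self.mcmc
        elif self.model == "td":
            mcmc = McmcConfig.td_default()
        else:
            mcmc = McmcConfig()
        return priors, mcmc

    def fit(self, data, y=None):
        """Fit to a trial dataset (list of TrialRecord) or a design frame."""
        if self.model not in FIT_MODELS:
            raise ValueError(f"model must be one of {FIT_MODELS}")
        design = data if isinstance(data, pd.DataFrame) else build_design(data)
        priors, mcmc = self._resolved()
        core = _MarginalisedModel(design, self.model, priors)
        rng = np.random.default_rng(mcmc.seed)

        x_map = core.map_estimate()
        nw = max(mcmc.n_walkers, 2 * core.ndim + 2)
        steps_post = max(int(math.ceil(mcmc.samples / nw)), 2)

        per_chain = []
        for _ in range(mcmc.chains):
            chain_seed = int(rng.integers(2**31 - 1))
            crng = np.random.default_rng(chain_seed)
            p0 = x_map[None, :] + 0.05 * crng.standard_normal((nw, core.ndim))
            sampler = emcee.EnsembleSampler(
                nw, core.ndim, core.log_posterior, vectorize=True,
            )
            sampler._random = np.random.RandomState(chain_seed)  # deterministic chains
            state = sampler.run_mcmc(
                p0, mcmc.warmup, skip_initial_state_check=True,
                progress=False,
            )
            sampler.reset()
            sampler.run_mcmc(state, steps_post, progress=False)
            per_chain.append(sampler.get_chain())  # (steps, walkers, dim)

        # step-major flattening keeps time order, so split R-hat still sees drift
        chains = np.stack(
            [c.reshape(-1, core.ndim)[: mcmc.samples] for c in per_chain]
        )  # may briefly exceed `samples`; truncated to the contract below
        self.max_rhat_ = _max_rhat(chains, core.param_names)

        flat = chains.reshape(-1, core.ndim)
        self._core_ = core
        self._draws_unconstrained_ = flat
        self.param_names_ = core.param_names
        self.posterior_ = self._natural_frame(chains)
        self.participants_ = core.participants
        self.n_obs_ = len(core.y)
        self.design_ = design
        self.priors_ = priors
        self.mcmc_ = mcmc
        self.intercepts_ = self._draw_intercepts(flat, rng)

        self.log_marginal_likelihood_ = None
        self.lml_se_ = None
        if self.compute_lml:
            n_bridge = min(len(flat), 4000)
            idx = rng.choice(len(flat), size=n_bridge, replace=False)
            self.log_marginal_likelihood_, self.lml_se_ = bridge_log_marginal_likelihood(
                flat[idx], core.log_posterior, rng
            )
        return self

    def _natural_frame(self, chains) -> pd.DataFrame:
        core = self._core_
        frames = []
        for c in range(chains.shape[0]):
            b0, betas, alpha, log_tau, log_sigma = core._unpack(chains[c])
            cols = {"chain": c, "b0": b0}
            if core.model == "both":
                cols["beta_recall"], cols["beta_presented"] = betas[:, 0], betas[:, 1]
            else:
                cols["beta"] = betas[:, 0]
            if alpha is not None:
                cols["alpha"] = alpha
            cols["tau"] = np.exp(log_tau)
            cols["sigma"] = np.exp(log_sigma)
            frames.append(pd.DataFrame(cols))
        return pd.concat(frames, ignore_index=True)

    def _draw_intercepts(self, flat, rng) -> np.ndarray:
        """Exact conditional draws of u_j given each retained draw."""
        core = self._core_
        b0, betas, alpha, log_tau, log_sigma = core._unpack(flat)
        tau2, sigma2 = np.exp(2 * log_tau), np.exp(2 * log_sigma)
        resid = core.y[None, :] - b0[:, None] - core.linear_term(betas, alpha)
        S = resid @ core.G.T
        denom = sigma2[:, None] + core.n_j[None, :] * tau2[:, None]
        mean = tau2[:, None] * S / denom
        sd = np.sqrt(tau2[:, None] * sigma2[:, None] / denom)
        return mean + sd * rng.standard_normal(mean.shape)

    def predict(self, data):
        """Posterior-mean bid prediction; unseen participants get u_j = 0."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        design = data if isinstance(data, pd.DataFrame) else build_design(data)
        core = _MarginalisedModel(design, self.model, self.priors_)
        flat = self._draws_unconstrained_
        b0, betas, alpha, _, _ = self._core_._unpack(flat)
        mu = b0[:, None] + _MarginalisedModel.linear_term(core, betas, alpha)
        u_mean = self.intercepts_.mean(axis=0)
        u_map = dict(zip(self.participants_, u_mean))
        offsets = np.array([u_map.get(p, 0.0) for p in design["participant_id"]])
        return mu.mean(axis=0) + offsets

    def summary(self) -> pd.DataFrame:
        post = self.posterior_.drop(columns="chain")
        return pd.DataFrame(
            {
                "mean": post.mean(),
                "sd": post.std(),
                "q2.5": post.quantile(0.025),
                "q97.5": post.quantile(0.975),
            }
        )

    def results_dict(self) -> dict:
        """JSON-serialisable record of the fit."""
        priors, mcmc = self.priors_, self.mcmc_
        return {
            "model_id": self.model,
            "priors": asdict(priors),
            "mcmc": asdict(mcmc),
            "n_obs": int(self.n_obs_),
            "n_participants": int(len(self.participants_)),
            "posterior_summary": {
                k: {kk: float(vv) for kk, vv in row.items()}
                for k, row in self.summary().T.to_dict().items()
            },
            "max_rhat": float(self.max_rhat_),
            "log_marginal_likelihood": (
                None if self.log_marginal_likelihood_ is None else float(self.log_marginal_likelihood_)
            ),
            "lml_se": None if self.lml_se_ is None else float(self.lml_se_),
        }


def fit_hierarchical(design, model_id, priors=None, mcmc=None, compute_lml=True):
    """Fit one of the recalled/presented/both regressions; returns the fitted
    :class:`HierarchicalEvaluationModel`."""
    if model_id == "td":
        raise ValueError("use fit_td for the temporal-difference model")
    return HierarchicalEvaluationModel(model_id, priors, mcmc, compute_lml).fit(design)


def fit_td(design, priors=None, mcmc=None, compute_lml=True):
    """Fit the temporal-difference model (joint posterior over the learning
    rate and the regression parameters)."""
    return HierarchicalEvaluationModel("td", priors, mcmc, compute_lml).fit(design)
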