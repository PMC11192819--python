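"""Trial-level strategy mixture: which evaluation rule generated each trial?

Each trial's bid is modelled as coming from one of three component
regressions — recalled-items only, presented-items only, or both predictors —
with per-participant mixing weights theta_j on the 3-simplex under a flat
Dirichlet(1,1,1) prior.  The participant intercept u_j, the residual spread
sigma, and the population intercept b0 are shared across components; each
component has its own slope(s) with the Normal(1, 0.5) prior used by the
single-strategy models.

Inference is by Gibbs sampling: the per-trial component indicators and the
theta_j have exact conjugate conditionals (categorical / Dirichlet), the
location parameters are conjugate Gaussians, and the two scale parameters are
updated by univariate slice sampling under their half-Student-t(3, 0, 10)
priors.  Per-trial component posteriors are Rao-Blackwellised (the categorical
probabilities are averaged over retained sweeps rather than the sampled
indicators), and participants are classified by the argmax of their
posterior-mean theta_j, ties going to "both".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import build_design
from .hierarchical import (
    HierarchicalEvaluationModel,
    McmcConfig,
    PriorConfig,
    _log_half_t,
    _max_rhat,
)

COMPONENTS = ("recalled", "presented", "both")


def slice_sample(x0: float, log_f, rng: np.random.Generator, w: float = 1.0, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    log_y = log_f(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if log_f(lo) < log_y:
            break
        lo -= w
    for _ in range(max_steps):
        if log_f(hi) < log_y:
            break
        hi += w
    for _ in range(1000):
        x1 = rng.uniform(lo, hi)
        if log_f(x1) >= log_y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pragma: no cover - shrinkage always terminates in practice


class TrialMixtureModel(BaseEstimator):
    """Latent-strategy mixture over the recalled/presented/both regressions.

    Parameters
    ----------
    priors : PriorConfig, optional
    mcmc : McmcConfig, optional
        ``samples`` retained Gibbs sweeps per chain after ``warmup``.
    theta_fixed : length-3 simplex vector, optional
        Pin every participant's mixing weights (used for sanity checks; at a
        simplex vertex the model collapses onto one component regression and
        its marginal likelihood is additionally estimated).

    Attributes
    ----------
    posterior_ : DataFrame of shared-parameter draws (b0, component slopes,
        tau, sigma) with a ``chain`` column.
    theta_mean_ : (n_participants, 3) posterior-mean mixing weights.
    theta_draws_ : (n_draws, n_participants, 3) retained theta draws.
    trial_probs_ : (n_trials, 3) Rao-Blackwellised component posteriors.
    classification_ : DataFrame with one row per participant.
    max_rhat_ : float, over the shared continuous parameters.
    degenerate_ : bool, True when some component explains almost no trials.
    """

    def __init__(self, priors=None, mcmc=None, theta_fixed=None):
        self.priors = priors
        self.mcmc = mcmc
        self.theta_fixed = theta_fixed

    def fit(self, data, y=None):
        priors = self.priors or PriorConfig()
        mcmc = self.mcmc or McmcConfig(warmup=1000, samples=4000, chains=4)
        design = data if isinstance(data, pd.DataFrame) else build_design(data)
        rng = np.random.default_rng(mcmc.seed)

        y_ = design["bid"].to_numpy(dtype=float)
        xr = design["predictor_recalled"].to_numpy(dtype=float)
        xp = design["predictor_presented"].to_numpy(dtype=float)
        if np.isnan(xr).any():
            raise ValueError("mixture model needs both predictors on every trial")
        ids = design["participant_id"].to_numpy()
        participants, g = np.unique(ids, return_inverse=True)
        J, n = len(participants), len(y_)
        n_j = np.bincount(g, minlength=J).astype(float)

        theta_fixed = None
        if self.theta_fixed is not None:
            theta_fixed = np.asarray(self.theta_fixed, dtype=float)
            if theta_fixed.shape != (3,) or not np.isclose(theta_fixed.sum(), 1.0):
                raise ValueError("theta_fixed must be a length-3 simplex vector")

        shared_names = ["b0", "beta_recall", "beta_presented", "beta_both_recall",
                        "beta_both_presented", "tau", "sigma"]
        chains_shared, chains_theta, chains_probs = [], [], []
        for _ in range(mcmc.chains):
            crng = np.random.default_rng(int(rng.integers(2**31 - 1)))
            out = self._run_chain(
                crng, y_, xr, xp, g, J, n, n_j, priors, mcmc, theta_fixed
            )
            chains_shared.append(out["shared"])
            chains_theta.append(out["theta"])
            chains_probs.append(out["probs"])

        shared = np.stack(chains_shared)  # (chains, sweeps, 7)
        self.max_rhat_ = _max_rhat(shared, shared_names)
        flat = shared.reshape(-1, shared.shape[-1])
        post = pd.DataFrame(flat, columns=shared_names)
        post.insert(0, "chain", np.repeat(np.arange(mcmc.chains), shared.shape[1]))
        self.posterior_ = post
        self.theta_draws_ = np.concatenate(chains_theta, axis=0)
        self.theta_mean_ = self.theta_draws_.mean(axis=0)
        self.trial_probs_ = np.mean(chains_probs, axis=0)
        self.participants_ = participants
        self.design_ = design
        self.priors_ = priors
        self.mcmc_ = mcmc

        usage = self.trial_probs_.mean(axis=0)
        self.component_usage_ = dict(zip(COMPONENTS, usage))
        self.degenerate_ = bool((usage < 0.005).any()) and theta_fixed is None

        self.classification_ = self._classify()

        self.log_marginal_likelihood_ = None
        self.lml_se_ = None
        if theta_fixed is not None and np.isclose(theta_fixed.max(), 1.0):
            # at a simplex vertex the mixture is exactly one component
            # regression; estimate its marginal likelihood with the
            # marginalised-intercept machinery
            comp = COMPONENTS[int(np.argmax(theta_fixed))]
            single = HierarchicalEvaluationModel(comp, priors, mcmc).fit(design)
            self.log_marginal_likelihood_ = single.log_marginal_likelihood_
            self.lml_se_ = single.lml_se_
        return self

    # -- Gibbs sweep --------------------------------------------------------
    def _run_chain(self, rng, y, xr, xp, g, J, n, n_j, priors, mcmc, theta_fixed):
        p = priors
        slope_prec = 1.0 / p.slope_sd**2
        b0_prec0 = 1.0 / p.intercept_sd**2

        beta = np.ones(4)  # (beta_r, beta_p, beta_both_r, beta_both_p)
        b0 = 0.0
        u = np.zeros(J)
        sigma = max(float(np.std(y)), 1.0)
        tau = 1.0
        theta = np.full((J, 3), 1.0 / 3.0) if theta_fixed is None else np.tile(theta_fixed, (J, 1))

        keep = mcmc.samples
        shared_out = np.empty((keep, 7))
        theta_out = np.empty((keep, J, 3))
        probs_acc = np.zeros((n, 3))

        for sweep in range(mcmc.warmup + keep):
            # component means without intercepts, one column per component
            M = np.column_stack([beta[0] * xr, beta[1] * xp, beta[2] * xr + beta[3] * xp])
            resid = y[:, None] - b0 - u[g][:, None] - M
            loglik = -0.5 * (resid / sigma) ** 2
            logw = np.log(np.maximum(theta[g], 1e-300)) + loglik
            logw -= logw.max(axis=1, keepdims=True)
            wgt = np.exp(logw)
            wgt /= wgt.sum(axis=1, keepdims=True)
            z = (wgt.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)

            if theta_fixed is None:
                counts = np.zeros((J, 3))
                np.add.at(counts, (g, z), 1.0)
                theta = rng.gamma(1.0 + counts)
                theta /= theta.sum(axis=1, keepdims=True)

            # design row per trial given its indicator
            D = np.zeros((n, 4))
            D[z == 0, 0] = xr[z == 0]
            D[z == 1, 1] = xp[z == 1]
            D[z == 2, 2] = xr[z == 2]
            D[z == 2, 3] = xp[z == 2]

            r0 = y - b0 - u[g]
            prec = D.T @ D / sigma**2 + slope_prec * np.eye(4)
            mean = np.linalg.solve(prec, D.T @ r0 / sigma**2 + slope_prec * p.slope_mean)
            L = np.linalg.cholesky(np.linalg.inv(prec))
            beta = mean + L @ rng.standard_normal(4)

            rowlin = D @ beta
            r1 = y - u[g] - rowlin
            prec_b0 = n / sigma**2 + b0_prec0
            b0 = rng.normal((r1.sum() / sigma**2 + b0_prec0 * p.intercept_mean) / prec_b0,
                            1.0 / np.sqrt(prec_b0))

            r2 = y - b0 - rowlin
            S = np.bincount(g, weights=r2, minlength=J)
            prec_u = n_j / sigma**2 + 1.0 / tau**2
            u = S / sigma**2 / prec_u + rng.standard_normal(J) / np.sqrt(prec_u)

            ss = float(np.sum((r2 - u[g]) ** 2))
            def log_post_lsig(ls):
                s = np.exp(ls)
                return -n * ls - ss / (2 * s * s) + _log_half_t(s, p.resid_sd_df, p.resid_sd_scale) + ls
            sigma = float(np.exp(slice_sample(np.log(sigma), log_post_lsig, rng)))

            uu = float(np.sum(u**2))
            def log_post_ltau(lt):
                t = np.exp(lt)
                return -J * lt - uu / (2 * t * t) + _log_half_t(t, p.group_sd_df, p.group_sd_scale) + lt
            tau = float(np.exp(slice_sample(np.log(tau), log_post_ltau, rng)))

            if sweep >= mcmc.warmup:
                k = sweep - mcmc.warmup
                shared_out[k] = [b0, beta[0], beta[1], beta[2], beta[3], tau, sigma]
                theta_out[k] = theta
                probs_acc += wgt

        return {"shared": shared_out, "theta": theta_out, "probs": probs_acc / keep}

    # -- classification -----------------------------------------------------
    def _classify(self) -> pd.DataFrame:
        rows = []
        for j, pid in enumerate(self.participants_):
            th = self.theta_mean_[j]
            top = th.max()
            winners = np.flatnonzero(np.isclose(th, top))
            label = "both" if len(winners) > 1 else COMPONENTS[winners[0]]
            rows.append(
                {
                    "participant_id": pid,
                    "theta_recalled": th[0],
                    "theta_presented": th[1],
                    "theta_both": th[2],
                    "strategy": label,
                }
            )
        return pd.DataFrame(rows)

    def predict(self, data=None) -> pd.Series:
        """Per-participant strategy labels (argmax of posterior-mean theta)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "classification_")
        return self.classification_.set_index("participant_id")["strategy"]


def fit_mixture(dataset, priors=None, mcmc=None) -> TrialMixtureModel:
    return TrialMixtureModel(priors=priors, mcmc=mcmc).fit(dataset)


def classify_participants(fit: TrialMixtureModel) -> dict:
    """Strategy counts in the n_recalled/n_presented/n_both summary format."""
    counts = fit.classification_["strategy"].value_counts()
    return {c: int(counts.get(c, 0)) for c in COMPONENTS}
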