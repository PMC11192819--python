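"""Bayes factors: model comparison by marginal likelihood and the default
JZS t-test.

``bayes_factor`` and ``select_best`` operate on fitted
:class:`~memval.hierarchical.HierarchicalEvaluationModel` objects and compare
bridge-sampling marginal likelihoods; fits whose chains have not converged
(max R-hat above 1.05) are refused unless ``force=True``.

``jzs_ttest_bf`` is the default Bayes-factor t-test: a Cauchy prior with scale
``r`` (default sqrt(2)/2) on the standardised effect size and Jeffreys' prior
on the variance.  The Cauchy is integrated in its scale-mixture form — an
inverse-gamma(1/2, r^2/2) mixing density on the effect-size prior variance g —
by adaptive quadrature on the log-g axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .hierarchical import RHAT_THRESHOLD


@dataclass(frozen=True)
class BayesTestConfig:
    rscale: float = math.sqrt(2.0) / 2.0

    def __post_init__(self):
        if self.rscale <= 0:
            raise ValueError("rscale must be positive")


def wagenmakers_label(bf: float) -> str:
    """Verbal evidence category for a Bayes factor BF >= 0 (evidence for the
    numerator model; reciprocal categories below 1)."""
    if bf < 1:
        return wagenmakers_label(1.0 / bf).replace("for", "against") if bf > 0 else "extreme against"
    for hi, lab in [(3, "anecdotal for"), (10, "moderate for"), (30, "strong for"), (100, "very strong for")]:
        if bf < hi:
            return lab
    return "extreme for"


def _check_comparable(fit_a, fit_b, force: bool):
    ya = fit_a.design_["bid"].to_numpy()
    yb = fit_b.design_["bid"].to_numpy()
    if len(ya) != len(yb) or not np.allclose(np.sort(ya), np.sort(yb)):
        raise ValueError("fits were not estimated on identical response data")
    for f in (fit_a, fit_b):
        if f.log_marginal_likelihood_ is None:
            raise ValueError(f"fit '{f.model}' has no marginal-likelihood estimate")
        if f.max_rhat_ > RHAT_THRESHOLD and not force:
            raise ValueError(
                f"fit '{f.model}' has max R-hat {f.max_rhat_:.3f} > {RHAT_THRESHOLD}; "
                "refit with more iterations or pass force=True"
            )


def bayes_factor(fit_best, fit_other, force: bool = False) -> float:
    """``exp(lml_best - lml_other)``: evidence for ``fit_best``."""
    _check_comparable(fit_best, fit_other, force)
    with np.errstate(over="ignore"):
        return float(np.exp(fit_best.log_marginal_likelihood_ - fit_other.log_marginal_likelihood_))


def select_best(fits, force: bool = False) -> pd.DataFrame:
    """Rank fits by log marginal likelihood (best first).

    Returns a frame with one row per model: its log marginal likelihood and
    the Bayes factor of the best model over it (1 for the best itself), with
    a verbal evidence label.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    for f in fits[1:]:
        _check_comparable(fits[0], f, force)
    if any(f.max_rhat_ > RHAT_THRESHOLD for f in fits) and not force:
        raise ValueError("non-converged fit in comparison; pass force=True to override")
    order = np.argsort([-f.log_marginal_likelihood_ for f in fits])
    best = fits[order[0]]
    rows = []
    for i in order:
        f = fits[i]
        with np.errstate(over="ignore"):
            bf = float(np.exp(best.log_marginal_likelihood_ - f.log_marginal_likelihood_))
        rows.append(
            {
                "model_id": f.model,
                "log_marginal_likelihood": f.log_marginal_likelihood_,
                "lml_se": f.lml_se_,
                "bf_best_over_model": bf,
                "evidence": "best" if f is best else wagenmakers_label(bf),
                "max_rhat": f.max_rhat_,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JZS t-test Bayes factor


def _jzs_bf_from_t(t: float, n_eff: float, df: float, rscale: float) -> float:
    """BF10 from a t statistic with effective sample size ``n_eff`` and
    ``df`` degrees of freedom."""
    log_p0 = -0.5 * (df + 1.0) * np.log1p(t * t / df)

    r2 = rscale * rscale

    def log_integrand(u):
        g = np.exp(u)
        # inverse-gamma(1/2, r^2/2) density on g, times the Jacobian g
        log_ig = 0.5 * np.log(r2 / 2.0) - math.lgamma(0.5) - 1.5 * u - r2 / (2.0 * g)
        log_lik = -0.5 * np.log1p(n_eff * g) - 0.5 * (df + 1.0) * np.log1p(
            t * t / ((1.0 + n_eff * g) * df)
        )
        return log_ig + log_lik + u

    shift = log_p0  # factor out the null density for numerical headroom

    def integrand(u):
        return math.exp(log_integrand(u) - shift)

    val, _ = integrate.quad(integrand, -35.0, 35.0, limit=400, points=[-2.0, 0.0, 2.0])
    return float(val)


def jzs_ttest_bf(
    group_a,
    group_b=None,
    paired: bool = False,
    config: BayesTestConfig | None = None,
) -> float:
    """Default Bayes-factor t-test (BF10, evidence for a nonzero effect).

    One-sample on ``group_a`` alone; paired on the differences; otherwise an
    independent two-sample test with a pooled variance.
    """
    config = config or BayesTestConfig()
    a = np.asarray(group_a, dtype=float)
    if group_b is not None and paired:
        b = np.asarray(group_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        a, group_b = a - b, None
    if group_b is None:
        n = len(a)
        if n < 2:
            raise ValueError("need at least 2 observations")
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance input: t statistic undefined")
        t = a.mean() / (sd / math.sqrt(n))
        return _jzs_bf_from_t(t, n_eff=n, df=n - 1, rscale=config.rscale)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero-variance input: t statistic undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    n_eff = n1 * n2 / (n1 + n2)
    return _jzs_bf_from_t(t, n_eff=n_eff, df=n1 + n2 - 2, rscale=config.rscale)
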