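"""Parametric Weibull survival comparison by likelihood ratio.

Model: T ~ Weibull(shape k, scale lambda_g) with a common shape and a
group-specific log-scale, lambda_g = exp(mu + beta * treated) — an
accelerated-failure-time parameterization in which beta is the log of the
treatment time ratio. Right censoring enters the likelihood through the
survival function S(t) = exp(-(t/lambda)^k). The treatment effect is tested
by the likelihood ratio Lambda = 2(l_full - l_reduced) against chi^2 with
1 degree of freedom; per-group medians are lambda_g * (ln 2)^(1/k).

For the well-characterized SOD1 survival curve this parametric route has
more power than a proportional-hazards fit, which is why it is preferred
here for the survival endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .ranktests import SurvivalSample


class FitError(RuntimeError):
    """Weibull maximum-likelihood fit failed to converge."""


@dataclass
class WeibullFitResult:
    shape: float
    log_scale_intercept: float  # mu
    treatment_coef: float  # beta (log time ratio; 0 in the reduced model)
    loglik_full: float
    loglik_reduced: float
    lrt_statistic: float
    p_value: float
    medians: dict  # group label -> median survival
    scales: dict  # group label -> scale lambda_g


def _negloglik(params, log_t, events, treated, with_treatment):
    log_k, mu, *rest = params
    beta = rest[0] if with_treatment else 0.0
    k = np.exp(log_k)
    z = k * (log_t - (mu + beta * treated))  # = (t/lambda)^k on the log scale
    ez = np.exp(np.clip(z, -700, 700))
    ll = np.where(events, np.log(k) + z - log_t, 0.0) - ez
    return -ll.sum()


def _fit(log_t, events, treated, with_treatment):
    mu0 = float(np.mean(log_t))
    s0 = max(float(np.std(log_t)), 1e-2)
    x0 = [-np.log(s0), mu0] + ([0.0] if with_treatment else [])
    res = optimize.minimize(
        _negloglik,
        x0,
        args=(log_t, events, treated, with_treatment),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    if not res.success:
        raise FitError(f"Weibull ML fit did not converge: {res.message}")
    return res


def weibull_lrt(sample: SurvivalSample) -> WeibullFitResult:
    """Censored Weibull ML fit (common shape, group log-scale) + LRT."""
    sample.require_two_groups()
    if not sample.events.any():
        raise ValueError("no events; Weibull likelihood uninformative")
    labels = sample.group_labels
    treated = (sample.groups == labels[1]).astype(float)
    log_t = np.log(sample.times)
    events = sample.events

    full = _fit(log_t, events, treated, with_treatment=True)
    reduced = _fit(log_t, events, treated, with_treatment=False)
    ll1, ll0 = -full.fun, -reduced.fun
    lam = max(0.0, 2.0 * (ll1 - ll0))
    k = float(np.exp(full.x[0]))
    mu, beta = float(full.x[1]), float(full.x[2])
    scales = {labels[0]: float(np.exp(mu)), labels[1]: float(np.exp(mu + beta))}
    medians = {g: s * np.log(2) ** (1.0 / k) for g, s in scales.items()}
    return WeibullFitResult(
        shape=k,
        log_scale_intercept=mu,
        treatment_coef=beta,
        loglik_full=float(ll1),
        loglik_reduced=float(ll0),
        lrt_statistic=float(lam),
        p_value=float(chi2.sf(lam, df=1)),
        medians=medians,
        scales=scales,
    )
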