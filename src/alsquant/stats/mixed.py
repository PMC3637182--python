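"""Mixed-effects models for the balance-beam session.

Both endpoints share one design: fixed effects intercept + beam difficulty
(mm below the largest beam) + treatment, with per-animal random intercepts
and difficulty slopes — an animal-specific regression on successive beams.
Latency (s) is fit as a linear mixed model (delegated to statsmodels
MixedLM; the estimation machinery is not the contribution here, the model
structure and the treatment LRT are). Foot slips are counts and are fit as
a Poisson GLMM with log link via a Laplace approximation to the marginal
likelihood (the same approximation lme4::glmer uses by default), authored
here because the installed Python stack offers no classical-likelihood
Poisson GLMM.

The treatment effect is tested by a likelihood-ratio test (ML, not REML)
against the model without the treatment term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2


@dataclass
class MixedModelResult:
    fixed_effects: dict  # name -> estimate
    fixed_se: dict  # name -> standard error (may be NaN for the GLMM)
    var_intercept: float
    var_slope: float
    loglik: float
    lrt_statistic: float | None
    p_value: float | None
    boundary: bool = False  # variance component at/near zero or singular fit
    degenerate: bool = False  # e.g. all-zero counts


_FIXED = ["intercept", "difficulty", "treatment"]


def _design(trials: pd.DataFrame):
    df = trials.copy()
    if df.empty:
        raise ValueError("empty trial table")
    df["difficulty"] = float(df["beam_mm"].max()) - df["beam_mm"].astype(float)
    df["treatment"] = (df["arm"] == "treated").astype(float)
    if df["beam_mm"].nunique() < 2:
        raise ValueError("need at least 2 beam sizes")
    if df.groupby("treatment")["mouse_id"].nunique().min() < 2:
        raise ValueError("need at least 2 animals per arm")
    return df


def fit_beam_latency(trials: pd.DataFrame) -> MixedModelResult:
    """Linear mixed model for traversal latency with treatment LRT."""
    import statsmodels.formula.api as smf

    df = _design(trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits warn; flagged below
        full = smf.mixedlm(
            "latency_s ~ difficulty + treatment",
            df,
            groups=df["mouse_id"],
            re_formula="~difficulty",
        ).fit(reml=False)
        reduced = smf.mixedlm(
            "latency_s ~ difficulty",
            df,
            groups=df["mouse_id"],
            re_formula="~difficulty",
        ).fit(reml=False)
    lam = max(0.0, 2.0 * (full.llf - reduced.llf))
    cov_re = np.asarray(full.cov_re)
    var_int, var_slope = float(cov_re[0, 0]), float(cov_re[1, 1])
    boundary = (
        (not full.converged)
        or var_int < 1e-8
        or var_slope < 1e-8
    )
    params = full.params
    bse = full.bse
    return MixedModelResult(
        fixed_effects={
            "intercept": float(params["Intercept"]),
            "difficulty": float(params["difficulty"]),
            "treatment": float(params["treatment"]),
        },
        fixed_se={
            "intercept": float(bse["Intercept"]),
            "difficulty": float(bse["difficulty"]),
            "treatment": float(bse["treatment"]),
        },
        var_intercept=var_int,
        var_slope=var_slope,
        loglik=float(full.llf),
        lrt_statistic=float(lam),
        p_value=float(chi2.sf(lam, df=1)),
        boundary=boundary,
    )


# ---- Poisson GLMM by Laplace approximation -------------------------------

def _animal_blocks(df: pd.DataFrame):
    blocks = []
    for _, grp in df.groupby("mouse_id", sort=True):
        X = np.column_stack(
            [np.ones(len(grp)), grp["difficulty"].to_numpy(), grp["treatment"].to_numpy()]
        )
        Z = X[:, :2]  # random intercept + difficulty slope
        blocks.append((X, Z, grp["slips"].to_numpy(dtype=float)))
    return blocks


def _laplace_loglik(params, blocks, with_treatment):
    if with_treatment:
        beta = params[:3]
        log_sd = params[3:]
    else:
        beta = np.array([params[0], params[1], 0.0])
        log_sd = params[2:]
    d_inv = np.exp(-2.0 * log_sd)  # precision of the two random effects
    log_det_d = 2.0 * log_sd.sum()
    total = 0.0
    for X, Z, y in blocks:
        eta0 = X @ beta
        b = np.zeros(2)
        for _ in range(100):  # damped Newton for the conditional mode
            mu = np.exp(np.clip(eta0 + Z @ b, -30, 30))
            grad = Z.T @ (y - mu) - d_inv * b
            hess = Z.T @ (mu[:, None] * Z) + np.diag(d_inv)
            step = np.linalg.solve(hess, grad)
            while np.abs(step).max() > 5.0:
                step *= 0.5
            b = b + step
            if np.abs(step).max() < 1e-10:
                break
        mu = np.exp(np.clip(eta0 + Z @ b, -30, 30))
        h = float(y @ (eta0 + Z @ b) - mu.sum() - 0.5 * (d_inv * b * b).sum())
        hess = Z.T @ (mu[:, None] * Z) + np.diag(d_inv)
        sign, log_det_h = np.linalg.slogdet(hess)
        total += h - 0.5 * log_det_d - 0.5 * log_det_h
    return total


def _fit_poisson_glmm(blocks, with_treatment):
    # moment-style starting values
    all_y = np.concatenate([y for _, _, y in blocks])
    y_bar = max(all_y.mean(), 0.05)
    x0 = [np.log(y_bar), 0.0] + ([0.0] if with_treatment else []) + [np.log(0.3), np.log(0.1)]
    res = optimize.minimize(
        lambda p: -_laplace_loglik(p, blocks, with_treatment),
        np.asarray(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 6000, "maxfev": 8000},
    )
    return res


def fit_beam_slips(trials: pd.DataFrame) -> MixedModelResult:
    """Poisson GLMM (log link) for foot slips with treatment LRT."""
    df = _design(trials)
    y = df["slips"].to_numpy()
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("slip counts must be non-negative integers")
    if not y.any():
        return MixedModelResult(
            fixed_effects=dict.fromkeys(_FIXED, float("nan")),
            fixed_se=dict.fromkeys(_FIXED, float("nan")),
            var_intercept=0.0,
            var_slope=0.0,
            loglik=0.0,
            lrt_statistic=None,
            p_value=None,
            degenerate=True,
            boundary=True,
        )
    blocks = _animal_blocks(df)
    full = _fit_poisson_glmm(blocks, with_treatment=True)
    reduced = _fit_poisson_glmm(blocks, with_treatment=False)
    boundary = not (full.success and reduced.success)
    ll1, ll0 = -full.fun, -reduced.fun
    lam = max(0.0, 2.0 * (ll1 - ll0))
    beta = full.x[:3]
    sd_int, sd_slope = np.exp(full.x[3]), np.exp(full.x[4])
    if sd_int < 1e-4 or sd_slope < 1e-4:
        boundary = True
    return MixedModelResult(
        fixed_effects=dict(zip(_FIXED, map(float, beta))),
        fixed_se=dict.fromkeys(_FIXED, float("nan")),  # Wald SEs not reported
        var_intercept=float(sd_int**2),
        var_slope=float(sd_slope**2),
        loglik=float(ll1),
        lrt_statistic=float(lam),
        p_value=float(chi2.sf(lam, df=1)),
        boundary=boundary,
    )
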