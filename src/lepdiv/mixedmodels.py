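"""Habitat-comparison mixed models for per-site diversity responses.

Each per-site diversity value (one number per site) is modelled with a
habitat fixed effect (broadleaf woodland as the reference level, plantation
as the contrast) and two random intercept terms: pair nested in year and
pair nested in month.  Naive species richness is a count, so it is fitted
with a Poisson generalized linear mixed model on the log link; constrained
diversity responses are continuous effective numbers and use a Gaussian
linear mixed model.

Gaussian models are fitted by REML through statsmodels' MixedLM with
variance components.  The Poisson mixed model is fitted here by maximum
likelihood with a Laplace approximation to the marginal likelihood (inner
Newton iterations find the random-effect mode; the outer optimizer profiles
the fixed effects and log standard deviations).

Variance explained is summarized with marginal and conditional R^2 (the
variance-partitioning approach of Nakagawa & Schielzeth): marginal uses the
fixed-effect variance only; conditional adds the random-intercept variances.
For the Poisson model the residual variance on the latent (log) scale uses
the log-normal approximation ln(1 + 1/lambda), with lambda the exponential
of the fitted intercept.

An effect is flagged "significant" when its +/- 1 SE interval excludes zero
(|estimate| > SE) -- a deliberately liberal field convention, reported as a
flag rather than a p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelError",
    "ModelFit",
    "fit_diversity_model",
    "nakagawa_r2",
    "significance_by_se",
]

REFERENCE_HABITAT = "broadleaf"
SINGULAR_SD = 1e-4  # a random-effect SD at/below this is a boundary fit


class ModelError(ValueError):
    """Invalid model input or a degenerate fit."""


@dataclass
class ModelFit:
    """Fixed effects, variance components and R^2 for one response."""

    response: str
    family: str
    intercept: float
    intercept_se: float
    plantation: float
    plantation_se: float
    t_value: float
    variance_components: dict[str, float]
    residual_variance: float
    fixed_variance: float
    marginal_r2: float = field(default=np.nan)
    conditional_r2: float = field(default=np.nan)
    singular: bool = False
    n_obs: int = 0

    def summary_row(self) -> dict:
        flags = significance_by_se(self)
        return {
            "response": self.response,
            "family": self.family,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "plantation": self.plantation,
            "plantation_se": self.plantation_se,
            "t": self.t_value,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "significant": flags["plantation"],
            "singular": self.singular,
        }


def _design(habitat: Sequence[str]) -> np.ndarray:
    hab = pd.Series(list(habitat), dtype=str)
    levels = set(hab)
    if not levels <= {"broadleaf", "plantation"}:
        raise ModelError(f"unknown habitat levels: {sorted(levels)}")
    x = (hab == "plantation").to_numpy(dtype=float)
    return np.column_stack([np.ones(len(hab)), x])


def _indicator(labels: Sequence) -> np.ndarray:
    codes, _ = pd.factorize(pd.Series(list(labels), dtype=str))
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _grouping_labels(structure, pair_id, year, month, n):
    """Labels for the two random terms under the chosen structure."""
    if structure == "pair":
        a = [f"{y}:{p}" for y, p in zip(year, pair_id)]
        b = [f"{m}:{p}" for m, p in zip(month, pair_id)]
    elif structure == "site":
        # observation-level grouping: site (= row) nested in year and month
        a = [f"{y}:site{i}" for i, y in enumerate(year)]
        b = [f"{m}:site{i}" for i, m in enumerate(month)]
    else:
        raise ModelError(f"unknown random_structure {structure!r}")
    return a, b


def fit_diversity_model(
    site_responses: Sequence[float],
    habitat: Sequence[str],
    pair_id: Sequence,
    year: Sequence,
    month: Sequence,
    family: str = "gaussian",
    response: str = "",
    random_structure: str = "pair",
) -> ModelFit:
    """Fit the habitat-comparison mixed model to one per-site response.

    Parameters
    ----------
    site_responses
        One diversity value per site.
    habitat
        ``broadleaf`` (reference) or ``plantation`` per site.
    pair_id, year, month
        Per-site design metadata; the random intercepts group pairs within
        years and pairs within months (``random_structure="pair"``, default)
        or use site-level terms (``"site"``).  ``"none"`` drops the random
        terms and reduces to OLS / Poisson GLM.
    family
        ``gaussian`` or ``poisson`` (the latter requires integer responses).
    """
    y = np.asarray(list(site_responses), dtype=float)
    n = y.size
    if n == 0:
        raise ModelError("no responses")
    X = _design(habitat)
    if len(list(pair_id)) != n or len(list(year)) != n or len(list(month)) != n:
        raise ModelError("metadata length does not match responses")
    if family not in ("gaussian", "poisson"):
        raise ModelError(f"unknown family {family!r}")
    if family == "poisson" and np.any(y != np.floor(y)):
        raise ModelError("poisson family requires integer responses")

    if np.var(y) < 1e-12:
        # constant response: habitat effect exactly zero, nothing to model
        return ModelFit(
            response=response, family=family, intercept=float(y.mean()),
            intercept_se=0.0, plantation=0.0, plantation_se=0.0,
            t_value=np.nan, variance_components={}, residual_variance=0.0,
            fixed_variance=0.0, marginal_r2=np.nan, conditional_r2=np.nan,
            singular=True, n_obs=n,
        )
    if random_structure == "none":
        fit = _fit_fixed_only(y, X, family)
    else:
        lab_a, lab_b = _grouping_labels(random_structure, pair_id, year, month, n)
        if family == "gaussian":
            fit = _fit_gaussian_lmm(y, X, lab_a, lab_b)
        else:
            fit = _fit_poisson_laplace(y, X, lab_a, lab_b)

    intercept, plantation = fit["beta"]
    se_i, se_p = fit["se"]
    mf = ModelFit(
        response=response,
        family=family,
        intercept=float(intercept),
        intercept_se=float(se_i),
        plantation=float(plantation),
        plantation_se=float(se_p),
        t_value=float(plantation / se_p) if se_p > 0 else np.nan,
        variance_components=fit["vc"],
        residual_variance=float(fit["resid_var"]),
        fixed_variance=float(np.var(X @ fit["beta"])),
        singular=bool(fit["singular"]),
        n_obs=n,
    )
    mf.marginal_r2, mf.conditional_r2 = nakagawa_r2(mf)
    return mf


def _fit_fixed_only(y, X, family):
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        resid_var = float(res.mse_resid) if X.shape[0] > X.shape[1] else 0.0
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        resid_var = float(np.log1p(1.0 / np.exp(res.params[0])))
    return {
        "beta": np.asarray(res.params),
        "se": np.asarray(res.bse),
        "vc": {},
        "resid_var": resid_var,
        "singular": False,
    }


def _same_partition(lab_a, lab_b) -> bool:
    ca, _ = pd.factorize(pd.Series(lab_a))
    cb, _ = pd.factorize(pd.Series(lab_b))
    return bool(np.array_equal(ca, cb))


def _fit_gaussian_lmm(y, X, lab_a, lab_b):
    """REML fit with two variance-component terms via statsmodels MixedLM.

    When the two groupings induce the same partition of sites (each pair
    sampled in a single year and month) only the sum of the two variances is
    identifiable; the model is then fitted with one term, its variance
    reported under pair_year with pair_month pinned at zero, and the fit
    flagged singular.
    """
    df = pd.DataFrame(
        {
            "y": y,
            "plantation": X[:, 1],
            "pair_year": lab_a,
            "pair_month": lab_b,
            "grp": 1,
        }
    )
    duplicated = _same_partition(lab_a, lab_b)
    vcf = {"pair_year": "0 + C(pair_year)"}
    if not duplicated:
        vcf["pair_month"] = "0 + C(pair_month)"
    model = MixedLM.from_formula(
        "y ~ plantation", groups="grp", vc_formula=vcf, re_formula="0", data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
    vc = {name: float(v) for name, v in zip(model.exog_vc.names, res.vcomp)}
    if duplicated:
        vc["pair_month"] = 0.0
    singular = duplicated or any(v <= SINGULAR_SD**2 for v in vc.values())
    return {
        "beta": beta,
        "se": se,
        "vc": vc,
        "resid_var": float(res.scale),
        "singular": singular,
    }


def _fit_poisson_laplace(y, X, lab_a, lab_b, max_inner=100):
    """Poisson GLMM, ML via Laplace approximation.

    Random effects u ~ N(0, diag(sigma_a^2, sigma_b^2) per block); the inner
    Newton solve finds the conditional mode of u, the outer L-BFGS-B
    optimizes (beta, log sigma_a, log sigma_b) on the Laplace objective.
    """
    Za, Zb = _indicator(lab_a), _indicator(lab_b)
    Z = np.hstack([Za, Zb])
    qa, qb = Za.shape[1], Zb.shape[1]
    p = X.shape[1]

    def inner_mode(beta, d):
        """Maximize the joint log-density over u for fixed (beta, D)."""
        dinv = 1.0 / d
        u = np.zeros(qa + qb)
        off = X @ beta
        for _ in range(max_inner):
            eta = np.clip(off + Z @ u, -30, 30)
            mu = np.exp(eta)
            g = Z.T @ (y - mu) - dinv * u
            H = Z.T @ (Z * mu[:, None])
            H[np.diag_indices_from(H)] += dinv
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = np.clip(off + Z @ u, -30, 30)
        mu = np.exp(eta)
        H = Z.T @ (Z * mu[:, None])
        H[np.diag_indices_from(H)] += dinv
        return u, eta, mu, H

    def neg_laplace(theta):
        beta = theta[:p]
        sig2 = np.exp(2.0 * theta[p:])
        d = np.concatenate([np.full(qa, sig2[0]), np.full(qb, sig2[1])])
        u, eta, mu, H = inner_mode(beta, d)
        joint = float(y @ eta - mu.sum() - 0.5 * np.sum(u * u / d)
                      - 0.5 * np.sum(np.log(d)))
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        return -(joint - 0.5 * logdet)

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.concatenate([np.asarray(glm.params), [np.log(0.3), np.log(0.3)]])
    bounds = [(None, None)] * p + [(-7.0, 3.0)] * 2
    opt = optimize.minimize(
        neg_laplace, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = opt.x[:p]
    sig = np.exp(opt.x[p:])
    d = np.concatenate([np.full(qa, sig[0] ** 2), np.full(qb, sig[1] ** 2)])
    u, eta, mu, H = inner_mode(beta, d)
    # fixed-effect covariance: beta block of the joint observed information
    A = X.T @ (X * mu[:, None])
    B = X.T @ (Z * mu[:, None])
    cov_beta = np.linalg.inv(A - B @ np.linalg.solve(H, B.T))
    se = np.sqrt(np.diag(cov_beta))
    vc = {"pair_year": float(sig[0] ** 2), "pair_month": float(sig[1] ** 2)}
    resid_var = float(np.log1p(1.0 / np.exp(beta[0])))
    return {
        "beta": beta,
        "se": se,
        "vc": vc,
        "resid_var": resid_var,
        "singular": bool(np.any(sig <= SINGULAR_SD)) or not opt.success,
    }


def nakagawa_r2(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 from a fitted model's variance partition.

    marginal = var_fixed / (var_fixed + sum var_random + var_residual);
    conditional replaces the numerator with var_fixed + sum var_random.
    """
    var_f = fit.fixed_variance
    var_r = float(sum(fit.variance_components.values()))
    var_e = fit.residual_variance
    total = var_f + var_r + var_e
    if total <= 0:
        raise ModelError("zero total variance; R^2 undefined")
    return var_f / total, (var_f + var_r) / total


def significance_by_se(fit: ModelFit) -> dict[str, bool]:
    """Flag effects whose +/- 1 SE interval excludes zero."""

    def flag(est, se):
        if not (np.isfinite(est) and np.isfinite(se)):
            return False
        return abs(est) > se + 1e-8

    return {
        "intercept": flag(fit.intercept, fit.intercept_se),
        "plantation": flag(fit.plantation, fit.plantation_se),
    }
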