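"""Bayesian bivariate surrogacy models and surrogacy-criteria evaluation.

Three models are provided, all sharing the within-study likelihood

    (Y1i, Y2i) ~ N((delta1i, delta2i), Sigma_i),

where Sigma_i is built from the reported standard errors and the
within-study correlation rho_wi:

``fit_dh``
    The Daniels & Hughes model: independent vague-prior true surrogate
    effects delta1i, and a linear conditional model
    delta2i | delta1i ~ N(lambda0 + lambda1 delta1i, psi2^2). The triple
    (lambda0, lambda1, psi2^2) carries the surrogacy criteria.
``fit_brma_pnf``
    Bivariate random-effects meta-analysis in product normal formulation:
    exchangeable correlated true effects with pooled surrogate mean d1,
    between-studies SDs tau1, tau2 and correlation rho; lambda1, psi2^2
    and the study-level R^2 = rho^2 are derived per draw from
    lambda1 = rho tau2 / tau1 and psi2^2 = tau2^2 - lambda1^2 tau1^2.
``fit_brma_pnf_bias``
    The BRMA PNF extension for real-world evidence: the within-study
    means of comparative (cRWE) and matched single-arm (sRWE) studies
    gain additive study-level bias terms drawn from design-specific
    normal distributions with their own mean and SD hyperparameters.

A surrogate relationship is considered perfect when lambda0 = 0,
lambda1 != 0 and psi2^2 = 0 (plus rho = +-1 for the random-effects
model); in practice the criteria are read off 95% credible intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _gibbs
from .datamodel import Design, MCMCSettings, PosteriorSummary, StudyEffect, summarize_posterior

__all__ = [
    "PriorConfig",
    "PosteriorDraws",
    "CriteriaReport",
    "ConvergenceWarning",
    "fit_dh",
    "fit_brma_pnf",
    "fit_brma_pnf_bias",
    "transform_brma_params",
    "evaluate_criteria",
    "summarize_fit",
]


class ConvergenceWarning(UserWarning):
    """Emitted when split-R-hat or effective sample size look poor."""


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters shared by the three models.

    Defaults are the vague choices of the reference analysis: Normal(0, 1e4)
    on fixed effects, regression parameters and bias means; Uniform(0, 2)
    on every SD (conditional, between-studies, bias); Uniform(-1, 1) on the
    between-studies correlation; Uniform(0, 1) on unknown within-study
    correlations. ``sd_sensitivity()`` widens the SD priors to
    Uniform(0, 100) and ``with_rho_w_fixed`` pins all within-study
    correlations (e.g. at a bootstrapped 0.52).
    """

    var_fixed: float = 1e4
    psi2_upper: float = 2.0
    tau_upper: float = 2.0
    rho_w_fixed: float | None = None
    bias_mean_var: float = 1e4
    bias_sd_upper: float = 2.0

    def __post_init__(self) -> None:
        for nm in ("var_fixed", "psi2_upper", "tau_upper", "bias_mean_var", "bias_sd_upper"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.rho_w_fixed is not None and not 0.0 <= self.rho_w_fixed <= 1.0:
            raise ValueError("rho_w_fixed must lie in [0, 1]")

    def sd_sensitivity(self, upper: float = 100.0) -> "PriorConfig":
        return replace(self, psi2_upper=upper, tau_upper=upper, bias_sd_upper=upper)

    def with_rho_w_fixed(self, value: float = 0.52) -> "PriorConfig":
        return replace(self, rho_w_fixed=value)

    def as_dict(self) -> dict:
        return {
            "var_fixed": self.var_fixed,
            "psi2_upper": self.psi2_upper,
            "tau_upper": self.tau_upper,
            "rho_w_fixed": self.rho_w_fixed,
            "bias_mean_var": self.bias_mean_var,
            "bias_sd_upper": self.bias_sd_upper,
        }


#: parameters whose posterior is skewed by construction; summarised by median
_MEDIAN_PARAMS = {"psi2_sq", "psi1_sq", "r2"}
#: scalar parameters reported per model
_SCALAR_PARAMS = {
    "DH": ("lambda0", "lambda1", "psi2_sq"),
    "BRMA": ("d1", "d2", "rho", "tau1", "tau2", "lambda0", "lambda1", "psi2_sq", "r2"),
    "BRMA_bias": (
        "d1", "d2", "rho", "tau1", "tau2", "lambda0", "lambda1", "psi2_sq", "r2",
        "alpha1", "alpha2", "beta1", "beta2",
    ),
}


@dataclass
class PosteriorDraws:
    """MCMC output of one model fit.

    ``draws[name]`` has shape (chain, draw) for scalars and
    (chain, draw, study) for per-study quantities.
    """

    model: str
    draws: dict
    study_ids: tuple
    settings: MCMCSettings
    priors: PriorConfig
    diagnostics: pd.DataFrame
    converged: bool

    def parameters(self) -> tuple:
        return tuple(self.draws)

    def get(self, name: str, study_id: str | None = None) -> np.ndarray:
        """Flattened draws of one parameter (optionally one study's)."""
        if name not in self.draws:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(self.draws)}"
            )
        arr = self.draws[name]
        if study_id is not None:
            arr = arr[..., self.study_ids.index(study_id)]
        if arr.ndim > 2:
            return arr.reshape(-1, arr.shape[-1])
        return arr.reshape(-1)

    @property
    def n_retained(self) -> int:
        return self.settings.n_retained

    def summarize(self, name: str, style: str | None = None) -> PosteriorSummary:
        if style is None:
            style = "median" if name in _MEDIAN_PARAMS else "mean"
        return summarize_posterior(self.get(name), parameter=name, style=style)


def _diagnose(stacked: dict, scalar_params: Sequence[str]) -> tuple[pd.DataFrame, bool]:
    import arviz as az

    rows = []
    for name in scalar_params:
        arr = stacked[name]
        if arr.shape[0] == 1:  # split a single chain in two for R-hat
            half = arr.shape[1] // 2
            arr = arr[0, : 2 * half].reshape(2, half)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(arr.copy()))
            ess = float(az.ess(arr.copy()))
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
    diag = pd.DataFrame(rows)
    converged = bool((diag["rhat"] < 1.05).all() and (diag["ess_bulk"] > 400).all())
    return diag, converged


def _finalize(
    model: str,
    stacked: dict,
    data: _gibbs.StudyArrays,
    priors: PriorConfig,
    mcmc: MCMCSettings,
) -> PosteriorDraws:
    diag, converged = _diagnose(stacked, _SCALAR_PARAMS[model])
    if not converged:
        worst = diag.loc[diag["rhat"].idxmax()]
        warnings.warn(
            f"{model} fit may not have converged (max R-hat "
            f"{worst['rhat']:.3f} on {worst['parameter']}, min bulk ESS "
            f"{diag['ess_bulk'].min():.0f}); treat summaries with caution",
            ConvergenceWarning,
            stacklevel=3,
        )
    return PosteriorDraws(
        model=model,
        draws=stacked,
        study_ids=data.ids,
        settings=mcmc,
        priors=priors,
        diagnostics=diag,
        converged=converged,
    )


def _check_data(effects: Sequence[StudyEffect], y2_missing: Sequence[str]) -> None:
    if len(effects) < 3:
        raise ValueError("need at least 3 studies")
    ids = [e.study_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study_id values")


def fit_dh(
    data: Sequence[StudyEffect],
    priors: PriorConfig | None = None,
    mcmc: MCMCSettings | None = None,
    y2_missing: Sequence[str] = (),
) -> PosteriorDraws:
    """Fit the Daniels & Hughes fixed-effects surrogacy model.

    ``y2_missing`` lists studies whose final-outcome effect is treated as
    missing at random (the cross-validation device); their ``delta2``
    draws are the posterior predictions of the missing effect.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCSettings()
    _check_data(data, y2_missing)
    arrays = _gibbs.StudyArrays(data, y2_missing, priors.rho_w_fixed)
    pri = {"var_fixed": priors.var_fixed, "psi2_upper": priors.psi2_upper}
    stacked = _gibbs.run_chains("DH", arrays, pri, mcmc)
    return _finalize("DH", stacked, arrays, priors, mcmc)


def _pri_brma(priors: PriorConfig) -> dict:
    return {
        "var_fixed": priors.var_fixed,
        "tau_upper": priors.tau_upper,
        "bias_mean_var": priors.bias_mean_var,
        "bias_sd_upper": priors.bias_sd_upper,
    }


def fit_brma_pnf(
    data: Sequence[StudyEffect],
    priors: PriorConfig | None = None,
    mcmc: MCMCSettings | None = None,
    y2_missing: Sequence[str] = (),
) -> PosteriorDraws:
    """Fit the BRMA product-normal-formulation model."""
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCSettings()
    _check_data(data, y2_missing)
    arrays = _gibbs.StudyArrays(data, y2_missing, priors.rho_w_fixed)
    stacked = _gibbs.run_chains("BRMA", arrays, _pri_brma(priors), mcmc)
    return _finalize("BRMA", stacked, arrays, priors, mcmc)


def fit_brma_pnf_bias(
    data: Sequence[StudyEffect],
    priors: PriorConfig | None = None,
    mcmc: MCMCSettings | None = None,
    y2_missing: Sequence[str] = (),
) -> PosteriorDraws:
    """Fit the bias-adjusted BRMA PNF model (requires non-randomized studies)."""
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCSettings()
    _check_data(data, y2_missing)
    designs = {e.design for e in data}
    if designs == {Design.RCT}:
        raise ValueError(
            "all studies are RCTs; the bias-adjusted model is not identified -- "
            "use fit_brma_pnf instead"
        )
    arrays = _gibbs.StudyArrays(data, y2_missing, priors.rho_w_fixed)
    stacked = _gibbs.run_chains("BRMA_bias", arrays, _pri_brma(priors), mcmc)
    return _finalize("BRMA_bias", stacked, arrays, priors, mcmc)


def transform_brma_params(tau1, tau2, rho, lambda0=None):
    """Map the bivariate-normal parameters to product-normal form.

    Returns ``(lambda1, psi1_sq, psi2_sq)`` with lambda1 = rho tau2 / tau1,
    psi1^2 = tau1^2 and psi2^2 = tau2^2 (1 - rho^2), the latter being the
    numerically safe form of tau2^2 - lambda1^2 tau1^2 (exactly zero at
    rho = +-1). ``lambda0`` passes through the map unchanged and is
    accepted only for signature symmetry with the model parameters.
    """
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(tau1 <= 0):
        raise ValueError("tau1 must be positive")
    if np.any(tau2 < 0):
        raise ValueError("tau2 must be non-negative")
    if np.any(np.abs(rho) > 1):
        raise ValueError("rho must lie in [-1, 1]")
    lambda1 = rho * tau2 / tau1
    psi1_sq = tau1**2
    psi2_sq = tau2**2 * (1.0 - rho**2)
    if lambda1.ndim == 0:
        return float(lambda1), float(psi1_sq), float(psi2_sq)
    return lambda1, psi1_sq, psi2_sq


@dataclass(frozen=True)
class CriteriaReport:
    """Surrogacy-criteria evidence from one fit.

    ``intercept_zero`` -- 95% CrI of lambda0 contains 0;
    ``slope_nonzero`` -- 95% CrI of lambda1 excludes 0;
    the conditional variance psi2^2 is reported (point + CrI), not
    thresholded; for the random-effects models the between-studies
    correlation summary is included as well.
    """

    model: str
    intercept_zero: bool
    slope_nonzero: bool
    lambda0: PosteriorSummary
    lambda1: PosteriorSummary
    psi2_sq: PosteriorSummary
    rho: PosteriorSummary | None = None

    @property
    def satisfied(self) -> bool:
        """Both interval-based criteria hold."""
        return self.intercept_zero and self.slope_nonzero

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "intercept_zero": self.intercept_zero,
            "slope_nonzero": self.slope_nonzero,
            "psi2_sq_point": self.psi2_sq.point,
            "psi2_sq_cri": [self.psi2_sq.cri_low, self.psi2_sq.cri_high],
        }
        if self.rho is not None:
            out["rho_point"] = self.rho.point
            out["rho_cri"] = [self.rho.cri_low, self.rho.cri_high]
        return out


def evaluate_criteria(
    summaries: Mapping[str, PosteriorSummary] | PosteriorDraws,
    model: str | None = None,
) -> CriteriaReport:
    """Evaluate the surrogacy criteria from posterior summaries.

    Accepts either a fitted :class:`PosteriorDraws` or a mapping of
    parameter name to :class:`PosteriorSummary` containing at least
    lambda0, lambda1 and psi2_sq (plus rho for the BRMA models).
    """
    if isinstance(summaries, PosteriorDraws):
        fit = summaries
        model = fit.model
        summaries = {p: fit.summarize(p) for p in _SCALAR_PARAMS[model]}
    if model is None:
        raise ValueError("model kind required when passing plain summaries")
    try:
        lam0 = summaries["lambda0"]
        lam1 = summaries["lambda1"]
        psi2 = summaries["psi2_sq"]
    except KeyError as exc:
        raise KeyError(f"missing posterior summary for parameter {exc}") from None
    rho = summaries.get("rho")
    if model != "DH" and rho is None:
        raise KeyError("missing posterior summary for parameter 'rho'")
    return CriteriaReport(
        model=model,
        intercept_zero=lam0.contains(0.0),
        slope_nonzero=not lam1.contains(0.0),
        lambda0=lam0,
        lambda1=lam1,
        psi2_sq=psi2,
        rho=rho if model != "DH" else None,
    )


def summarize_fit(fit: PosteriorDraws, parameters: Sequence[str] | None = None) -> pd.DataFrame:
    """Posterior-summary table (one row per parameter).

    Means are reported for location-like parameters and medians for the
    skewed variance-type parameters (psi2^2, R^2), with the equal-tailed
    95% credible interval.
    """
    params = parameters or _SCALAR_PARAMS[fit.model]
    rows = []
    for p in params:
        s = fit.summarize(p)
        rows.append(
            {
                "parameter": p,
                "point": s.point,
                "cri_low": s.cri_low,
                "cri_high": s.cri_high,
                "point_style": s.point_style,
            }
        )
    return pd.DataFrame(rows)
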