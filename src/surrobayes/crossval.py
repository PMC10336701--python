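"""Take-one-out cross-validation of surrogate-based predictions.

Each study's treatment effect on the final outcome is in turn treated as
missing at random, the surrogacy model is refitted on the remaining
information (the left-out study still contributes its surrogate effect),
and the missing effect is predicted from the posterior of the study's
true final-outcome effect. The predictive variance adds the study's own
sampling variance to the posterior variance of the true effect,

    Var(Y2_pred) = sigma_2i^2 + Var(delta2_i | Y1i, sigma_1i, Y_(-i)),

so the 95% predicted interval is never narrower than the study's observed
95% confidence interval: the width ratio is a >= 1 measure of how much
precision the surrogate-based prediction gives up relative to direct
observation. Absolute discrepancy |predicted - observed| measures
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import MCMCSettings, StudyEffect
from .models import PosteriorDraws, PriorConfig, fit_brma_pnf, fit_brma_pnf_bias, fit_dh

__all__ = ["PredictionRecord", "CrossValReport", "loo_predict", "crossvalidate"]

_Z95 = 1.959963984540054

_FITTERS: dict[str, Callable] = {
    "DH": fit_dh,
    "BRMA": fit_brma_pnf,
    "BRMA_bias": fit_brma_pnf_bias,
}


@dataclass(frozen=True)
class PredictionRecord:
    """Prediction of one left-out study's final-outcome effect."""

    study_id: str
    pred_mean: float
    pred_var: float  # sigma2^2 + var(delta2 | rest)
    interval: tuple[float, float]  # equal-tailed quantiles of predictive draws
    interval_normal: tuple[float, float]  # mean +- 1.96 sqrt(pred_var)
    observed: float
    observed_se: float
    observed_ci: tuple[float, float]
    abs_discrepancy: float
    width_ratio: float
    converged: bool

    @property
    def observed_width(self) -> float:
        return self.observed_ci[1] - self.observed_ci[0]


@dataclass
class CrossValReport:
    """All per-study predictions plus median/range summaries."""

    model: str
    records: tuple[PredictionRecord, ...]
    failed: tuple[str, ...] = ()

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records], dtype=float)

    @property
    def median_abs_discrepancy(self) -> float:
        return float(np.median(self._values("abs_discrepancy")))

    @property
    def abs_discrepancy_range(self) -> tuple[float, float]:
        v = self._values("abs_discrepancy")
        return float(v.min()), float(v.max())

    @property
    def median_width_ratio(self) -> float:
        return float(np.median(self._values("width_ratio")))

    @property
    def width_ratio_range(self) -> tuple[float, float]:
        v = self._values("width_ratio")
        return float(v.min()), float(v.max())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "pred_mean": r.pred_mean,
                "pred_var": r.pred_var,
                "pred_low": r.interval[0],
                "pred_high": r.interval[1],
                "pred_low_normal": r.interval_normal[0],
                "pred_high_normal": r.interval_normal[1],
                "observed": r.observed,
                "obs_low": r.observed_ci[0],
                "obs_high": r.observed_ci[1],
                "abs_discrepancy": r.abs_discrepancy,
                "width_ratio": r.width_ratio,
                "converged": r.converged,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "abs_discrepancy_median": self.median_abs_discrepancy,
            "abs_discrepancy_min": self.abs_discrepancy_range[0],
            "abs_discrepancy_max": self.abs_discrepancy_range[1],
            "width_ratio_median": self.median_width_ratio,
            "width_ratio_min": self.width_ratio_range[0],
            "width_ratio_max": self.width_ratio_range[1],
            "n_failed": len(self.failed),
        }


def loo_predict(
    data: Sequence[StudyEffect],
    model: str,
    leave_out: str,
    priors: PriorConfig | None = None,
    mcmc: MCMCSettings | None = None,
) -> PredictionRecord:
    """Predict one study's final-outcome effect with that effect held out.

    The model is refitted with the study's Y2 flagged missing; the
    predicted mean is the posterior mean of its true effect delta2, and
    predictive draws add Normal(0, sigma2^2) observation noise on top of
    the delta2 draws.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_FITTERS)}")
    ids = [e.study_id for e in data]
    if leave_out not in ids:
        raise KeyError(f"study {leave_out!r} not in the dataset")
    if len(data) < 4:
        raise ValueError("need at least 3 studies besides the left-out one")
    mcmc = mcmc or MCMCSettings()
    study = data[ids.index(leave_out)]

    fit: PosteriorDraws = _FITTERS[model](data, priors, mcmc, y2_missing=(leave_out,))
    delta2 = fit.get("delta2", study_id=leave_out)
    pred_mean = float(delta2.mean())
    pred_var = float(study.se2**2 + delta2.var(ddof=1))

    noise_rng = np.random.default_rng(
        np.random.SeedSequence(mcmc.seed).spawn(1)[0]
    )
    pred_draws = delta2 + noise_rng.normal(0.0, study.se2, size=delta2.size)
    lo, hi = (float(q) for q in np.quantile(pred_draws, [0.025, 0.975]))
    half = _Z95 * float(np.sqrt(pred_var))
    obs_half = _Z95 * study.se2
    return PredictionRecord(
        study_id=leave_out,
        pred_mean=pred_mean,
        pred_var=pred_var,
        interval=(lo, hi),
        interval_normal=(pred_mean - half, pred_mean + half),
        observed=study.y2,
        observed_se=study.se2,
        observed_ci=(study.y2 - obs_half, study.y2 + obs_half),
        abs_discrepancy=abs(pred_mean - study.y2),
        width_ratio=float(np.sqrt(pred_var) / study.se2),
        converged=fit.converged,
    )


def crossvalidate(
    data: Sequence[StudyEffect],
    model: str,
    priors: PriorConfig | None = None,
    mcmc: MCMCSettings | None = None,
) -> CrossValReport:
    """Take-one-out cross-validation over every study in the dataset.

    Each refit uses an offset seed (base seed + study index) so per-study
    predictions are independently reproducible. Studies whose refit fails
    are recorded and excluded from the summaries with a warning.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 studies to cross-validate")
    mcmc = mcmc or MCMCSettings()
    records: list[PredictionRecord] = []
    failed: list[str] = []
    for i, study in enumerate(data):
        seeded = MCMCSettings(
            n_iter=mcmc.n_iter,
            n_burnin=mcmc.n_burnin,
            n_chains=mcmc.n_chains,
            seed=(mcmc.seed + i) % (2**31 - 1),
        )
        try:
            records.append(loo_predict(data, model, study.study_id, priors, seeded))
        except Exception as exc:
            failed.append(study.study_id)
            warnings.warn(
                f"take-one-out refit failed for study {study.study_id!r}: {exc}",
                stacklevel=2,
            )
    if not records:
        raise RuntimeError("every take-one-out refit failed")
    return CrossValReport(model=model, records=tuple(records), failed=tuple(failed))
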