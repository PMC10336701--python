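"""Synthetic meta-analytic and survival-arm data with the exact structure
the surrogacy models assume.

The between-studies model draws each study's true effects from a
bivariate normal written as a product of conditionals,

    delta_1i ~ N(eta1, tau1^2),
    delta_2i | delta_1i ~ N(lambda0 + lambda1 * delta_1i, psi2^2),

with the two parameterisations linked by lambda1 = rho * tau2 / tau1 and
psi2^2 = tau2^2 - lambda1^2 * tau1^2. Observed effects add design-specific
bias (zero for RCTs, study-level normal bias terms for comparative and
matched single-arm real-world studies) and bivariate-normal within-study
sampling error.

Defaults emulate the metastatic colorectal cancer evidence base that
motivates the package: a moderately protective mean surrogate effect,
between-studies SDs around 0.2, a between-studies correlation of 0.74,
within-study standard errors between 0.1 and 0.35, and a within-study
correlation of 0.52.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import Design, StudyEffect
from .km import KMDataset, km_estimate
from .matching import CovariateProfile, CovariateSpec, default_covariate_spec

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "SurvivalArmConfig",
    "simulate_meta_dataset",
    "simulate_survival_arm",
    "simulate_covariate_profiles",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study counts, surrogacy-model truth, bias structure, and error scales.

    Exactly one of the two between-studies parameterisations must be
    supplied free: either ``(tau2, rho)`` or ``(lambda1, psi2)``; the other
    is derived and both always agree.
    """

    n_rct: int = 7
    n_crwe: int = 4
    n_srwe: int = 2
    eta1: float = -0.36
    tau1: float = 0.20
    tau2: float | None = 0.16
    rho: float | None = 0.74
    lambda0: float = 0.05
    lambda1: float | None = None
    psi2: float | None = None
    se_range: tuple[float, float] = (0.10, 0.35)
    rho_w: float = 0.52
    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    sigma_alpha1: float = 0.0
    sigma_alpha2: float = 0.0
    sigma_beta1: float = 0.0
    sigma_beta2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError("tau1 must be positive")
        given_tr = self.tau2 is not None and self.rho is not None
        given_lp = self.lambda1 is not None and self.psi2 is not None
        if given_tr == given_lp:
            raise ValueError(
                "exactly one of (tau2, rho) or (lambda1, psi2) must be supplied"
            )
        if given_tr:
            if self.tau2 < 0:
                raise ValueError("tau2 must be non-negative")
            if not -1.0 <= self.rho <= 1.0:
                raise ValueError("rho must lie in [-1, 1]")
            lam1 = self.rho * self.tau2 / self.tau1
            psi2_sq = self.tau2**2 * (1.0 - self.rho**2)
            object.__setattr__(self, "lambda1", lam1)
            object.__setattr__(self, "psi2", math.sqrt(psi2_sq))
        else:
            if self.psi2 < 0:
                raise ValueError("psi2 must be non-negative")
            tau2_sq = self.lambda1**2 * self.tau1**2 + self.psi2**2
            tau2 = math.sqrt(tau2_sq)
            rho = self.lambda1 * self.tau1 / tau2 if tau2 > 0 else 0.0
            object.__setattr__(self, "tau2", tau2)
            object.__setattr__(self, "rho", rho)
        if self.psi2**2 < -1e-12:
            raise ValueError("derived psi2^2 is negative; tau/rho/lambda inputs clash")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("se_range must be positive with lo <= hi")
        if not 0.0 <= self.rho_w <= 1.0:
            raise ValueError("rho_w must lie in [0, 1]")
        for nm in ("sigma_alpha1", "sigma_alpha2", "sigma_beta1", "sigma_beta2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")

    @property
    def psi2_sq(self) -> float:
        return self.psi2**2


@dataclass(frozen=True)
class SimulatedStudy:
    """Observed study effects plus the latent truth behind them."""

    effect: StudyEffect
    delta1: float
    delta2: float
    bias1: float
    bias2: float


def _draw_study(
    rng: np.random.Generator, cfg: SimulationConfig, design: Design, study_id: str
) -> SimulatedStudy:
    d1 = rng.normal(cfg.eta1, cfg.tau1)
    d2 = rng.normal(cfg.lambda0 + cfg.lambda1 * d1, cfg.psi2)
    if design is Design.RCT:
        b1 = b2 = 0.0
    elif design is Design.cRWE:
        b1 = rng.normal(cfg.alpha1, cfg.sigma_alpha1)
        b2 = rng.normal(cfg.alpha2, cfg.sigma_alpha2)
    else:
        b1 = rng.normal(cfg.beta1, cfg.sigma_beta1)
        b2 = rng.normal(cfg.beta2, cfg.sigma_beta2)
    se1, se2 = rng.uniform(*cfg.se_range, size=2)
    cov = cfg.rho_w * se1 * se2
    y1, y2 = rng.multivariate_normal(
        [d1 + b1, d2 + b2], [[se1**2, cov], [cov, se2**2]]
    )
    return SimulatedStudy(
        effect=StudyEffect(
            study_id=study_id,
            design=design,
            y1=float(y1),
            se1=float(se1),
            y2=float(y2),
            se2=float(se2),
            rho_w=cfg.rho_w,
        ),
        delta1=float(d1),
        delta2=float(d2),
        bias1=float(b1),
        bias2=float(b2),
    )


def simulate_meta_dataset(config: SimulationConfig) -> list[SimulatedStudy]:
    """Draw a full meta-analytic dataset.

    Each study consumes an independent substream spawned from the global
    seed, so enlarging one design group never perturbs the studies of
    another.
    """
    n_total = config.n_rct + config.n_crwe + config.n_srwe
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    labels = (
        [(Design.RCT, f"RCT{i + 1}") for i in range(config.n_rct)]
        + [(Design.cRWE, f"cRWE{i + 1}") for i in range(config.n_crwe)]
        + [(Design.sRWE, f"sRWE{i + 1}") for i in range(config.n_srwe)]
    )
    return [
        _draw_study(np.random.default_rng(ss), config, design, sid)
        for ss, (design, sid) in zip(streams, labels)
    ]


def truth_frame(studies: Sequence[SimulatedStudy]):
    """Companion table of latent truths for recovery tests."""
    import pandas as pd

    return pd.DataFrame(
        {
            "study_id": [s.effect.study_id for s in studies],
            "delta1": [s.delta1 for s in studies],
            "delta2": [s.delta2 for s in studies],
            "bias1": [s.bias1 for s in studies],
            "bias2": [s.bias2 for s in studies],
        }
    )


@dataclass(frozen=True)
class SurvivalArmConfig:
    """Exponential survival arm with exponential plus administrative censoring."""

    n_patients: int
    hazard: float
    censor_rate: float = 0.0
    admin_cutoff: float | None = None
    risk_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.hazard <= 0:
            raise ValueError("hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.admin_cutoff is not None and self.admin_cutoff <= 0:
            raise ValueError("admin_cutoff must be positive")


def simulate_survival_arm(config: SurvivalArmConfig):
    """Simulate one arm; returns (records DataFrame, exact KM dataset).

    Event times are exponential with the configured hazard; censoring is
    the minimum of an exponential censoring time (if any) and an
    administrative cut-off (if any).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    event_t = rng.exponential(1.0 / config.hazard, size=config.n_patients)
    cens_t = np.full(config.n_patients, np.inf)
    if config.censor_rate > 0:
        cens_t = rng.exponential(1.0 / config.censor_rate, size=config.n_patients)
    if config.admin_cutoff is not None:
        cens_t = np.minimum(cens_t, config.admin_cutoff)
    time = np.minimum(event_t, cens_t)
    event = (event_t <= cens_t).astype(int)
    records = pd.DataFrame({"time": time, "event": event})
    km = km_estimate(
        (time, event), arm_id=f"sim-seed{config.seed}", risk_interval=config.risk_interval
    )
    return records, km


_PROFILE_RANGES = {
    "treatment_line": (1.0, 2.0),
    "age": (55.0, 72.0),
    "performance_score": (0.3, 1.2),
    "colon_proportion": (0.45, 0.85),
    "female_proportion": (0.30, 0.50),
}


def simulate_covariate_profiles(
    n_treat: int,
    n_ctrl: int,
    seed: int = 0,
    spec: CovariateSpec | None = None,
) -> tuple[list[CovariateProfile], list[CovariateProfile]]:
    """Aggregate covariate profiles for matching fixtures.

    Values are drawn uniformly within realistic sub-ranges of each
    covariate's scaling range (e.g. median age 55-72 for mCRC cohorts).
    """
    if n_treat < 1 or n_ctrl < 1:
        raise ValueError("need at least one profile per role")
    spec = spec or default_covariate_spec()
    rng = np.random.default_rng(seed)

    def draw(study_id: str, role: str) -> CovariateProfile:
        values = {}
        for cov in spec:
            lo, hi = _PROFILE_RANGES.get(cov.name, (cov.min, cov.max))
            values[cov.name] = float(rng.uniform(lo, hi))
        return CovariateProfile(study_id=study_id, role=role, values=values)

    treat = [draw(f"T{i + 1}", "treatment") for i in range(n_treat)]
    ctrl = [draw(f"C{i + 1}", "control") for i in range(n_ctrl)]
    return treat, ctrl
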