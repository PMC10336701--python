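"""Core domain types, delimited-text I/O, and posterior summarisation.

The unit of analysis throughout the package is the *study*: each study
contributes a pair of log hazard ratios -- one on the surrogate outcome
(e.g. PFS) and one on the final outcome (e.g. OS) -- with their standard
errors and, optionally, the correlation between the two sampling errors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Design",
    "StudyEffect",
    "MCMCSettings",
    "PosteriorSummary",
    "read_study_effects",
    "write_study_effects",
    "study_effects_to_frame",
    "summarize_posterior",
]


class Design(str, enum.Enum):
    """Study design label.

    RCT
        randomized controlled trial.
    cRWE
        comparative (two-arm) real-world evidence.
    sRWE
        single-arm real-world evidence, made comparative by aggregate
        matching.
    """

    RCT = "RCT"
    cRWE = "cRWE"
    sRWE = "sRWE"


@dataclass(frozen=True)
class StudyEffect:
    """Observed treatment effects of one study on both outcomes.

    Parameters
    ----------
    study_id
        Unique study label.
    design
        One of :class:`Design` (or its string value).
    y1, y2
        Observed log hazard ratios on the surrogate and final outcome.
    se1, se2
        Standard errors of ``y1`` and ``y2``; must be positive.
    rho_w
        Within-study correlation between the sampling errors of ``y1``
        and ``y2``, in [0, 1]. ``None`` marks it as unknown, in which
        case the models place a Uniform(0, 1) prior on it.
    """

    study_id: str
    design: Design
    y1: float
    se1: float
    y2: float
    se2: float
    rho_w: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", Design(self.design))
        if not (self.se1 > 0 and self.se2 > 0):
            raise ValueError(
                f"study {self.study_id!r}: standard errors must be positive "
                f"(got se1={self.se1}, se2={self.se2})"
            )
        if self.rho_w is not None and not (0.0 <= self.rho_w <= 1.0):
            raise ValueError(
                f"study {self.study_id!r}: rho_w must lie in [0, 1], got {self.rho_w}"
            )


@dataclass(frozen=True)
class MCMCSettings:
    """Markov chain Monte Carlo run configuration.

    Defaults match a long single-machine run (150,000 iterations of which
    50,000 are burn-in); two chains are run so that split-R-hat and
    effective-sample-size diagnostics are meaningful.
    """

    n_iter: int = 150_000
    n_burnin: int = 50_000
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("n_burnin must satisfy 0 <= n_burnin < n_iter")
        if self.n_chains <= 0:
            raise ValueError("n_chains must be positive")
        if self.n_retained <= 0:
            raise ValueError("no retained draws")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iter - self.n_burnin)


@dataclass(frozen=True)
class PosteriorSummary:
    """Point estimate and equal-tailed 95% credible interval."""

    parameter: str
    point: float
    cri_low: float
    cri_high: float
    point_style: str  # "mean" or "median"

    @property
    def width(self) -> float:
        return self.cri_high - self.cri_low

    def contains(self, value: float) -> bool:
        return self.cri_low <= value <= self.cri_high


_REQUIRED_COLUMNS = ("study_id", "design", "y1", "se1", "y2", "se2")


def read_study_effects(path) -> list[StudyEffect]:
    """Read a study-effects table from a comma-separated text file.

    The file must have a header naming at least ``study_id``, ``design``,
    ``y1``, ``se1``, ``y2``, ``se2``; an optional ``rho_w`` column may be
    present, with empty fields meaning "unknown". Row order is preserved.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study-effects file {path} lacks required column(s): {missing}")
    out: list[StudyEffect] = []
    has_rho = "rho_w" in df.columns
    for _, row in df.iterrows():
        rho_w = None
        if has_rho and not pd.isna(row["rho_w"]):
            rho_w = float(row["rho_w"])
        out.append(
            StudyEffect(
                study_id=str(row["study_id"]),
                design=Design(str(row["design"])),
                y1=float(row["y1"]),
                se1=float(row["se1"]),
                y2=float(row["y2"]),
                se2=float(row["se2"]),
                rho_w=rho_w,
            )
        )
    return out


def study_effects_to_frame(effects: Iterable[StudyEffect]) -> pd.DataFrame:
    rows = [
        {
            "study_id": e.study_id,
            "design": e.design.value,
            "y1": e.y1,
            "se1": e.se1,
            "y2": e.y2,
            "se2": e.se2,
            "rho_w": e.rho_w,
        }
        for e in effects
    ]
    return pd.DataFrame(
        rows, columns=["study_id", "design", "y1", "se1", "y2", "se2", "rho_w"]
    )


def write_study_effects(effects: Iterable[StudyEffect], path) -> None:
    """Write studies as CSV (UTF-8, '.' decimal; unknown rho_w as empty field).

    Floats are written with :func:`repr`, so a write/read round trip
    reproduces every field bit-identically.
    """
    df = study_effects_to_frame(effects)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            vals = []
            for col in df.columns:
                v = row[col]
                if col in ("study_id", "design"):
                    vals.append(str(v))
                elif v is None or (isinstance(v, float) and math.isnan(v)):
                    vals.append("")
                else:
                    vals.append(repr(float(v)))
            fh.write(",".join(vals) + "\n")


def summarize_posterior(
    draws: "np.ndarray | Sequence[float] | object",
    parameter: str = "",
    style: str = "auto",
) -> PosteriorSummary:
    """Summarise posterior draws of one scalar parameter.

    Parameters
    ----------
    draws
        Either a 1-d array of draws, or an object with a ``get`` method
        (such as :class:`surrobayes.models.PosteriorDraws`), in which case
        ``parameter`` selects the variable.
    parameter
        Name recorded on the summary (and the lookup key when ``draws``
        is a draws container).
    style
        ``"mean"``, ``"median"``, or ``"auto"``. Auto uses the median when
        |mean - median| > 0.1 x IQR (a skewness heuristic standing in for
        visual inspection), the mean otherwise.

    The credible interval is the equal-tailed empirical 2.5%/97.5%
    quantile pair.
    """
    if hasattr(draws, "get") and not isinstance(draws, (np.ndarray, list, tuple)):
        arr = np.asarray(draws.get(parameter), dtype=float).ravel()
    else:
        arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 100:
        raise ValueError(
            f"need at least 100 retained draws to summarise {parameter!r}, got {arr.size}"
        )
    mean = float(np.mean(arr))
    median = float(np.median(arr))
    if style == "auto":
        iqr = float(np.quantile(arr, 0.75) - np.quantile(arr, 0.25))
        style = "median" if abs(mean - median) > 0.1 * iqr else "mean"
    if style == "mean":
        point = mean
    elif style == "median":
        point = median
    else:
        raise ValueError(f"unknown style {style!r}")
    lo, hi = (float(q) for q in np.quantile(arr, [0.025, 0.975]))
    return PosteriorSummary(
        parameter=parameter, point=point, cri_low=lo, cri_high=hi, point_style=style
    )
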