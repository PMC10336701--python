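"""Aggregate-level matching of single-arm studies.

Single-arm studies carry no internal comparison, so relative treatment
effects can only be formed by pairing a treatment-arm study with a
control-arm study that enrolled a similar population. With only
aggregate (study-level) covariates available, similarity is measured by
a weighted average of scaled covariate differences

    D_tot[j, k] = sum_c w_c * D_c[j, k] / sum_c w_c,

where each D_c = |value_j - value_k| / (max_c - min_c) is scaled to
[0, 1] so that all covariates contribute on a common footing before
weighting. D_tot therefore also lies in [0, 1], with small values
indicating similar studies.

A matching threshold is derived from reference two-arm designs: the
largest distance observed *between the arms of the same study* (RCTs
for the primary analysis, comparative real-world studies for a
sensitivity analysis) bounds how dissimilar two arms of a "fair"
comparison can be. Candidate pairs at or below the threshold are then
matched greedily, smallest distance first, each study used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "CovariateSpec",
    "CovariateProfile",
    "DistanceMatrix",
    "MatchedPairs",
    "scaled_difference",
    "total_distance",
    "distance_matrix",
    "derive_threshold",
    "select_matches",
]


@dataclass(frozen=True)
class Covariate:
    """One matching covariate: a name, a positive weight, and the value
    range used to scale absolute differences to [0, 1]."""

    name: str
    weight: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"covariate {self.name!r}: weight must be positive")
        if not self.min < self.max:
            raise ValueError(f"covariate {self.name!r}: require min < max")


@dataclass(frozen=True)
class CovariateSpec:
    """An ordered collection of matching covariates."""

    covariates: tuple[Covariate, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in spec")
        if not self.covariates:
            raise ValueError("spec must contain at least one covariate")

    def __iter__(self):
        return iter(self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_weight(self) -> float:
        return float(sum(c.weight for c in self.covariates))

    @classmethod
    def from_dicts(cls, items: Iterable[Mapping]) -> "CovariateSpec":
        return cls(
            tuple(
                Covariate(
                    name=str(d["name"]),
                    weight=float(d["weight"]),
                    min=float(d["min"]),
                    max=float(d["max"]),
                )
                for d in items
            )
        )


def default_covariate_spec() -> CovariateSpec:
    """The five-covariate set reported by all candidate mCRC single-arm
    studies: treatment line, median age, mean ECOG/WHO performance score,
    proportion with colon (vs rectum) primary, and proportion female.
    Sex carries weight 1, all others weight 2, following consensus
    rankings of baseline characteristics."""
    return CovariateSpec(
        (
            Covariate("treatment_line", 2.0, 1.0, 3.0),
            Covariate("age", 2.0, 18.0, 100.0),
            Covariate("performance_score", 2.0, 0.0, 3.0),
            Covariate("colon_proportion", 2.0, 0.0, 1.0),
            Covariate("female_proportion", 1.0, 0.0, 1.0),
        )
    )


@dataclass(frozen=True)
class CovariateProfile:
    """Aggregate covariate values of one study arm.

    ``role`` distinguishes treatment-like arms (rows of the distance
    matrix) from control-like arms (columns).
    """

    study_id: str
    role: str  # "treatment" or "control"
    values: Mapping[str, float]

    def value(self, name: str) -> float:
        try:
            return float(self.values[name])
        except KeyError:
            raise KeyError(
                f"study {self.study_id!r} has no value for covariate {name!r}"
            ) from None


@dataclass(frozen=True)
class DistanceMatrix:
    """All pairwise distances between treatment-arm and control-arm studies."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray  # shape (len(row_ids), len(col_ids)), full precision

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("distance matrix shape does not match ids")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def to_frame(self, decimals: int | None = 3) -> pd.DataFrame:
        v = self.values if decimals is None else np.round(self.values, decimals)
        return pd.DataFrame(v, index=list(self.row_ids), columns=list(self.col_ids))

    def count_at_or_below(self, threshold: float) -> int:
        return int(np.sum(self.values <= threshold))


@dataclass(frozen=True)
class MatchedPairs:
    """Greedy matching result: (treatment id, control id, distance) triples,
    emitted in non-decreasing distance order, plus the threshold used."""

    pairs: tuple[tuple[str, str, float], ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.pairs), columns=["treat_id", "ctrl_id", "distance"]
        )


def scaled_difference(
    a: CovariateProfile, b: CovariateProfile, name: str, spec: CovariateSpec
) -> float:
    """|value_a - value_b| scaled by the covariate's range, clipped to [0, 1]."""
    cov = spec[name]
    d = abs(a.value(name) - b.value(name)) / (cov.max - cov.min)
    return float(min(max(d, 0.0), 1.0))


def total_distance(a: CovariateProfile, b: CovariateProfile, spec: CovariateSpec) -> float:
    """Weighted average of scaled covariate differences; lies in [0, 1]."""
    num = sum(c.weight * scaled_difference(a, b, c.name, spec) for c in spec)
    return float(num / spec.total_weight)


def distance_matrix(
    treat: Sequence[CovariateProfile],
    ctrl: Sequence[CovariateProfile],
    spec: CovariateSpec,
) -> DistanceMatrix:
    """Distance between every treatment-arm and control-arm study."""
    if not treat or not ctrl:
        raise ValueError("profile sets must be non-empty")
    values = np.array(
        [[total_distance(t, c, spec) for c in ctrl] for t in treat], dtype=float
    )
    return DistanceMatrix(
        row_ids=tuple(p.study_id for p in treat),
        col_ids=tuple(p.study_id for p in ctrl),
        values=values,
    )


def derive_threshold(
    reference_pairs: Sequence[tuple[CovariateProfile, CovariateProfile]],
    spec: CovariateSpec,
) -> float:
    """Maximum between-arm distance over reference two-arm studies.

    Within an RCT (or a comparative observational study) both arms are, by
    design, drawn from one population; the largest distance seen between
    such arms bounds the covariate imbalance compatible with a fair
    comparison and is used as the maximum allowable matching distance.
    """
    if not reference_pairs:
        raise ValueError("need at least one reference pair to derive a threshold")
    return max(total_distance(a, b, spec) for a, b in reference_pairs)


def select_matches(m: DistanceMatrix, threshold: float) -> MatchedPairs:
    """Greedy unique matching among entries at or below the threshold.

    Repeatedly takes the globally smallest remaining entry (ties broken by
    lexicographic (row id, column id) order), emits it as a matched pair,
    and removes its row and column so each study is used at most once.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    work = m.values.copy()
    alive_rows = list(range(len(m.row_ids)))
    alive_cols = list(range(len(m.col_ids)))
    pairs: list[tuple[str, str, float]] = []
    while alive_rows and alive_cols:
        best: tuple[float, str, str, int, int] | None = None
        for i in alive_rows:
            for j in alive_cols:
                d = work[i, j]
                if d > threshold:
                    continue
                key = (d, m.row_ids[i], m.col_ids[j])
                if best is None or key < (best[0], best[1], best[2]):
                    best = (d, m.row_ids[i], m.col_ids[j], i, j)
        if best is None:
            break
        d, rid, cid, i, j = best
        pairs.append((rid, cid, float(d)))
        alive_rows.remove(i)
        alive_cols.remove(j)
    return MatchedPairs(pairs=tuple(pairs), threshold=float(threshold))
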