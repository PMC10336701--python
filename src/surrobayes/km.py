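"""Pseudo-IPD reconstruction from digitized Kaplan-Meier curves, and
log hazard ratio estimation by Cox partial likelihood.

Published single-arm studies report Kaplan-Meier curves rather than
patient-level data. Given digitized (time, survival) coordinates and the
numbers-at-risk table printed beneath the curve, an approximate
individual-patient dataset can be solved for: within each inter-risk-table
interval the numbers of events and censorings are chosen so that (i) the
recomputed product-limit steps match the digitized drops and (ii) the
number at risk at the next interval boundary matches the printed count,
with censoring times spread uniformly within the interval. When no risk
table is printed, the per-arm sample size and total event count constrain
the solution instead, censoring being assumed to accrue at a constant
rate over follow-up.

The reconstructed arms are then compared with a Cox proportional-hazards
model with a single binary covariate for treatment arm (Efron tie
handling -- reconstruction places many events at shared coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "KMDataset",
    "ReconstructedIPD",
    "EffectEstimate",
    "ReconstructionError",
    "EstimationError",
    "reconstruct_ipd",
    "km_estimate",
    "cox_loghr",
]


class ReconstructionError(RuntimeError):
    """Raised when no feasible event/censoring pattern exists."""


class EstimationError(RuntimeError):
    """Raised when a Cox fit is impossible (e.g. no events)."""


@dataclass
class KMDataset:
    """One arm's digitized survival curve plus risk-table information.

    Parameters
    ----------
    arm_id
        Arm label.
    times, survival
        Digitized step coordinates; times strictly increasing, survival in
        [0, 1] and non-increasing. A (0, 1) origin is prepended when absent.
    risk_times, risk_counts
        Numbers-at-risk table (optional). The first count is the number of
        patients at the start of follow-up.
    n_start, total_events
        Per-arm totals, used as the reconstruction constraint when no risk
        table is available.
    """

    arm_id: str
    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray | None = None
    risk_counts: np.ndarray | None = None
    n_start: int | None = None
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and survival must be equal-length 1-d arrays")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"arm {self.arm_id!r}: times must be strictly increasing")
        repaired = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        repair = float(np.max(np.abs(repaired - s)))
        if repair > 0.02:
            warnings.warn(
                f"arm {self.arm_id!r}: monotonicity repair of digitized survival "
                f"reached {repair:.3f} (> 0.02); check the digitization",
                stacklevel=2,
            )
        self.times = t
        self.survival = repaired
        if (self.risk_times is None) != (self.risk_counts is None):
            raise ValueError("risk_times and risk_counts must be given together")
        if self.risk_times is not None:
            rt = np.asarray(self.risk_times, dtype=float)
            rn = np.asarray(self.risk_counts, dtype=float)
            if rt.shape != rn.shape or rt.ndim != 1 or rt.size == 0:
                raise ValueError("risk table must be two equal-length 1-d arrays")
            if np.any(np.diff(rt) <= 0):
                raise ValueError("risk-table times must be strictly increasing")
            if np.any(np.diff(rn) > 0):
                raise ValueError("risk-table counts must be non-increasing")
            self.risk_times = rt
            self.risk_counts = rn.astype(int)
            if self.n_start is None:
                self.n_start = int(rn[0])
        if self.risk_times is None and self.n_start is None:
            raise ValueError("either a risk table or n_start must be supplied")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame | None]:
        coords = pd.DataFrame({"time": self.times, "survival": self.survival})
        risk = None
        if self.risk_times is not None:
            risk = pd.DataFrame({"time": self.risk_times, "n_at_risk": self.risk_counts})
        return coords, risk


@dataclass
class ReconstructedIPD:
    """Pseudo individual-patient data for one arm."""

    arm_id: str
    times: np.ndarray
    events: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")

    @property
    def n_patients(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "event": self.events, "arm": self.arm_id},
            columns=["time", "event", "arm"],
        )


@dataclass(frozen=True)
class EffectEstimate:
    """Cox log hazard ratio (treatment vs control) with its standard error."""

    loghr: float
    se: float
    n_treat: int
    n_ctrl: int
    events_treat: int
    events_ctrl: int


def _interval_pass(
    t: np.ndarray,
    s: np.ndarray,
    lo: int,
    up: int,
    n_at_lo: float,
    km_before: float,
    cen_times: np.ndarray,
    t_end: float,
):
    """Forward pass over coordinates lo..up of one risk-table interval.

    Given the number at risk entering the interval and censoring times
    already laid out, solve the integer event counts that reproduce the
    digitized drops. Returns (events per coordinate, censored count per
    gap, n at risk after the interval, KM value after the interval).
    """
    k_idx = np.arange(lo, up + 1)
    d = np.zeros(up - lo + 1, dtype=int)
    c = np.zeros(up - lo + 1, dtype=int)
    n_hat = float(n_at_lo)
    km = float(km_before)
    for pos, k in enumerate(k_idx):
        if k == 0:
            dk = 0
        else:
            if n_hat <= 0:
                if s[k] < km - 1e-9:
                    raise ReconstructionError(
                        f"no patients left at risk before time {t[k]:g} "
                        "but the curve still drops"
                    )
                dk = 0
            else:
                ratio = s[k] / km if km > 0 else 1.0
                dk = int(round(n_hat * (1.0 - ratio)))
                dk = max(0, min(dk, int(n_hat)))
        if dk > 0:
            km = km * (1.0 - dk / n_hat)
        d[pos] = dk
        gap_end = t[k + 1] if k + 1 <= up else t_end
        ck = int(np.sum((cen_times >= t[k]) & (cen_times < gap_end)))
        ck = min(ck, int(n_hat) - dk)
        c[pos] = ck
        n_hat = n_hat - dk - ck
        if n_hat < 0:
            raise ReconstructionError(
                f"implied events exceed patients at risk near time {t[k]:g}"
            )
    return d, c, n_hat, km


def _spread(n: int, start: float, end: float) -> np.ndarray:
    """n censoring times spread uniformly over [start, end)."""
    if n <= 0:
        return np.empty(0)
    q = np.arange(1, n + 1)
    return start + (q - 0.5) * (end - start) / n


def reconstruct_ipd(km: KMDataset) -> ReconstructedIPD:
    """Solve for pseudo individual-patient data reproducing a digitized curve.

    With a risk table, the number censored in each interval is iterated
    until the implied number at risk at the next boundary matches the
    printed count. With totals only, a single interval is used and the
    censoring count is iterated until the implied total number of events
    matches the reported total.
    """
    t, s = km.times, km.survival
    n_coords = t.size
    t_max = float(t[-1])

    if km.risk_times is not None:
        trisk = km.risk_times
        nrisk = km.risk_counts.astype(float)
        # drop risk-table entries beyond the digitized follow-up
        keep = trisk <= t_max + 1e-12
        trisk, nrisk = trisk[keep], nrisk[keep]
        bounds = [int(np.searchsorted(t, bt, side="left")) for bt in trisk]
        n_int = len(bounds)
    else:
        bounds = [0]
        trisk = np.array([0.0])
        nrisk = np.array([float(km.n_start)])
        n_int = 1

    event_times: list[float] = []
    censor_times: list[float] = []
    n_carry = float(nrisk[0])
    km_carry = 1.0

    for j in range(n_int):
        lo = bounds[j]
        if j < n_int - 1:
            up = bounds[j + 1] - 1
            t_end = float(trisk[j + 1])
            target = float(nrisk[j + 1])
        else:
            up = n_coords - 1
            t_end = t_max
            target = None
        if up < lo:
            continue

        s_lo = s[lo] if s[lo] > 0 else 1.0
        if target is not None:
            s_next = s[bounds[j + 1]] if bounds[j + 1] < n_coords else s[-1]
            guess = int(round(n_carry * s_next / s_lo - target))
        elif km.total_events is not None:
            guess = 0
        else:
            guess = 0
        guess = max(0, guess)

        best = None  # (abs deviation, d, c, cen_times, n_after, km_after)
        seen: set[int] = set()
        last_err: ReconstructionError | None = None
        for _ in range(60):
            seen.add(guess)
            cen_times = _spread(guess, float(t[lo]), t_end)
            try:
                d, c, n_after, km_after = _interval_pass(
                    t, s, lo, up, n_carry, km_carry, cen_times, t_end
                )
            except ReconstructionError as err:
                # too much censoring laid down for the observed drops;
                # back off and retry with fewer censored patients
                last_err = err
                if guess == 0:
                    break
                nxt = max(0, guess - max(1, guess // 4))
                if nxt in seen:
                    break
                guess = nxt
                continue
            if target is not None:
                dev = n_after - target
            elif km.total_events is not None:
                # too many implied events -> censor more patients
                dev = int(d.sum()) - int(km.total_events)
            else:
                dev = 0
            if best is None or abs(dev) < abs(best[0]):
                best = (dev, d, c, cen_times, n_after, km_after)
            if dev == 0:
                break
            nxt = max(0, guess + int(round(dev)))
            if nxt in seen:
                # nudge by one toward reducing the deviation
                nxt = max(0, guess + (1 if dev > 0 else -1))
                if nxt in seen:
                    break
            guess = nxt
        if best is None:
            raise ReconstructionError(
                f"arm {km.arm_id!r}: no feasible event/censoring pattern in "
                f"risk-table interval {j} (starting at t={trisk[j]:g}): {last_err}"
            )
        dev, d, c, cen_times, n_after, km_after = best

        # lay down events and censorings for this interval
        used = 0
        for pos, k in enumerate(range(lo, up + 1)):
            event_times.extend([float(t[k])] * int(d[pos]))
            censor_times.extend(cen_times[used : used + int(c[pos])].tolist())
            used += int(c[pos])
        n_carry, km_carry = n_after, km_after

    # patients still at risk at the end of follow-up are censored there
    n_left = int(round(n_carry))
    censor_times.extend([t_max] * n_left)

    times = np.array(event_times + censor_times, dtype=float)
    events = np.array([1] * len(event_times) + [0] * len(censor_times), dtype=int)
    order = np.argsort(times, kind="stable")
    ipd = ReconstructedIPD(arm_id=km.arm_id, times=times[order], events=events[order])
    expected_n = int(nrisk[0])
    if ipd.n_patients != expected_n:
        raise ReconstructionError(
            f"arm {km.arm_id!r}: reconstructed {ipd.n_patients} patients, "
            f"expected {expected_n}"
        )
    return ipd


def _as_time_event(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, ReconstructedIPD):
        return records.times, records.events
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(float), records["event"].to_numpy(int)
    times, events = records
    return np.asarray(times, dtype=float), np.asarray(events, dtype=int)


def km_estimate(records, arm_id: str = "arm", risk_interval: float | None = None) -> KMDataset:
    """Product-limit estimate (with steps at event times) and risk table."""
    times, events = _as_time_event(records)
    if times.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    ev_times = np.unique(times[events == 1])
    coords_t = ev_times
    coords_s = np.array([float(sf.loc[tt]) for tt in ev_times])
    if ev_times.size == 0 or ev_times[0] > 0:
        coords_t = np.concatenate([[0.0], coords_t])
        coords_s = np.concatenate([[1.0], coords_s])
    risk_t = risk_n = None
    if risk_interval is not None:
        risk_t = np.arange(0.0, times.max() + risk_interval, risk_interval)
        risk_n = np.array([(times >= rt - 1e-12).sum() for rt in risk_t], dtype=int)
    return KMDataset(
        arm_id=arm_id,
        times=coords_t,
        survival=coords_s,
        risk_times=risk_t,
        risk_counts=risk_n,
        n_start=int(times.size),
        total_events=int(events.sum()),
    )


def cox_loghr(treat, ctrl) -> EffectEstimate:
    """Cox partial-likelihood log hazard ratio, treatment vs control.

    A single binary covariate distinguishes the arms; ties are handled by
    Efron's approximation. The standard error comes from the inverse
    observed information at the maximum.
    """
    t1, e1 = _as_time_event(treat)
    t0, e0 = _as_time_event(ctrl)
    if e1.sum() + e0.sum() == 0:
        raise EstimationError("no events in either arm; log hazard ratio undefined")
    df = pd.DataFrame(
        {
            "time": np.concatenate([t1, t0]),
            "event": np.concatenate([e1, e0]),
            "treat": np.concatenate([np.ones_like(t1), np.zeros_like(t0)]),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure surfaces with context
        raise EstimationError(f"Cox fit failed: {exc}") from exc
    return EffectEstimate(
        loghr=float(cph.params_["treat"]),
        se=float(cph.standard_errors_["treat"]),
        n_treat=int(t1.size),
        n_ctrl=int(t0.size),
        events_treat=int(e1.sum()),
        events_ctrl=int(e0.sum()),
    )
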