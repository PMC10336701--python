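"""Gibbs-within-slice MCMC engine for the bivariate surrogacy models.

All three models share a bivariate-normal within-study likelihood and a
(product-normal) between-studies layer, which makes them conditionally
conjugate almost everywhere: the per-study true effects, the regression
parameters, the pooled mean, and the bias terms all have closed-form
bivariate/univariate normal full conditionals, and the conditional SD of
the regression layer has a truncated inverse-gamma full conditional under
its uniform-on-SD prior. The remaining bounded scalars (between-studies
SDs and correlation) are updated by univariate slice sampling, and the
per-study within-study correlations by independence Metropolis with a
uniform proposal on their [0, 1] prior support.

All randomness flows through one :class:`numpy.random.Generator` per
chain, seeded from the run seed, so every fit is exactly reproducible.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammainc as _gammainc, gammaincinv as _gammaincinv

_PSI2_SQ_FLOOR = 1e-12
_SD_FLOOR = 1e-5


# ---------------------------------------------------------------------------
# primitive updates


def _mvn2_draw(rng, P11, P12, P22, h1, h2):
    """Draw from N(P^-1 h, P^-1) for a (batched) 2x2 precision matrix."""
    det = P11 * P22 - P12 * P12
    S11 = P22 / det
    S22 = P11 / det
    S12 = -P12 / det
    mu1 = S11 * h1 + S12 * h2
    mu2 = S12 * h1 + S22 * h2
    L11 = np.sqrt(S11)
    L21 = S12 / L11
    L22 = np.sqrt(np.maximum(S22 - L21 * L21, 1e-300))
    z = rng.standard_normal((2,) + np.shape(mu1))
    return mu1 + L11 * z[0], mu2 + L21 * z[0] + L22 * z[1]


def _slice_update(
    rng, x0: float, logf: Callable[[float], float], lower: float, upper: float, w: float
) -> float:
    """One stepping-out/shrinkage slice-sampling update on (lower, upper)."""
    f0 = logf(x0)
    if not math.isfinite(f0):
        x0 = 0.5 * (lower + upper)
        f0 = logf(x0)
    y = f0 - rng.exponential()
    L = max(lower, x0 - w * rng.random())
    R = min(upper, L + w)
    for _ in range(30):
        if L <= lower or logf(L) <= y:
            break
        L = max(lower, L - w)
    for _ in range(30):
        if R >= upper or logf(R) <= y:
            break
        R = min(upper, R + w)
    for _ in range(100):
        x = rng.uniform(L, R)
        if logf(x) >= y:
            return float(x)
        if x < x0:
            L = x
        else:
            R = x
    return float(x0)


def _draw_sd(rng, ss: float, n: int, upper: float, current: float) -> float:
    """Draw an SD with density proportional to sd^-n * exp(-ss / (2 sd^2))
    on (0, upper] -- the full conditional under a Uniform(0, upper) prior.

    For n >= 2 this is an exact inverse-CDF draw from a truncated gamma on
    the precision; for n < 2 (possible for tiny bias groups) a slice update
    is used instead.
    """
    ss = max(float(ss), 1e-12)
    shape = 0.5 * (n - 1)
    if shape > 0:
        qmin = 1.0 / (upper * upper)
        scale = 2.0 / ss
        u0 = float(_gammainc(shape, qmin / scale))
        if u0 >= 1.0 - 1e-12:
            return float(upper)
        u = rng.uniform(u0, 1.0 - 1e-16)
        q = float(_gammaincinv(shape, u)) * scale
        q = max(q, qmin)
        return float(max(1.0 / math.sqrt(q), _SD_FLOOR))

    def logf(s: float) -> float:
        return -n * math.log(s) - ss / (2.0 * s * s)

    lo = max(1e-6 * upper, _SD_FLOOR)
    x0 = min(max(current, lo), upper)
    return float(max(_slice_update(rng, x0, logf, lo, upper, w=0.25 * upper), _SD_FLOOR))


def _update_rho_w(rng, rho_w, mask, e1, e2, se1, se2) -> None:
    """Independence-Metropolis sweep for sampled within-study correlations."""
    idx = np.where(mask)[0]
    if idx.size == 0:
        return
    a = e1[idx] / se1[idx]
    b = e2[idx] / se2[idx]

    def ll(r):
        c = 1.0 - r * r
        return -0.5 * (np.log(c) + (a * a - 2.0 * r * a * b + b * b) / c)

    cur = rho_w[idx]
    llc = ll(cur)
    for _ in range(2):
        prop = rng.uniform(0.0, 1.0 - 1e-9, size=idx.size)
        llp = ll(prop)
        acc = np.log(rng.uniform(size=idx.size)) < (llp - llc)
        cur = np.where(acc, prop, cur)
        llc = np.where(acc, llp, llc)
    rho_w[idx] = cur


def _draw_delta(rng, Q11, Q12, Q22, y1c, y2c, m1, v1, lam0, lam1, psi2sq):
    """Conjugate draw of the per-study true effects (delta1, delta2).

    The between-studies factorisation delta1 ~ N(m1, v1),
    delta2 | delta1 ~ N(lam0 + lam1 delta1, psi2sq) contributes a joint
    normal prior in natural (precision/linear) form; the within-study
    likelihood contributes the precision blocks Q.
    """
    P011 = 1.0 / v1 + lam1 * lam1 / psi2sq
    P012 = -lam1 / psi2sq
    P022 = 1.0 / psi2sq
    h01 = m1 / v1 - lam0 * lam1 / psi2sq
    h02 = lam0 / psi2sq
    h1 = h01 + Q11 * y1c + Q12 * y2c
    h2 = h02 + Q12 * y1c + Q22 * y2c
    return _mvn2_draw(rng, P011 + Q11, P012 + Q12, P022 + Q22, h1, h2)


# ---------------------------------------------------------------------------
# data container


class StudyArrays:
    """Vectorised study data plus missing-y2 and correlation bookkeeping."""

    def __init__(
        self,
        effects: Sequence,
        y2_missing: Sequence[str] = (),
        rho_w_fixed: float | None = None,
    ) -> None:
        missing = set(y2_missing)
        unknown_missing = missing - {e.study_id for e in effects}
        if unknown_missing:
            raise KeyError(f"y2_missing names unknown studies: {sorted(unknown_missing)}")
        self.ids = tuple(e.study_id for e in effects)
        self.n = len(self.ids)
        self.design = np.array([e.design.value for e in effects])
        self.y1 = np.array([e.y1 for e in effects], dtype=float)
        self.y2 = np.array([e.y2 for e in effects], dtype=float)
        self.se1 = np.array([e.se1 for e in effects], dtype=float)
        self.se2 = np.array([e.se2 for e in effects], dtype=float)
        self.y2_obs = np.array([e.study_id not in missing for e in effects])
        self.y2z = np.where(self.y2_obs, self.y2, 0.0)
        if rho_w_fixed is not None:
            fixed = np.full(self.n, float(rho_w_fixed))
        else:
            fixed = np.array(
                [np.nan if e.rho_w is None else float(e.rho_w) for e in effects]
            )
        self.rho_w_fixed = fixed
        # a correlation only enters the likelihood when both outcomes are seen
        self.rho_w_sampled = np.isnan(fixed) & self.y2_obs

    def init_rho_w(self) -> np.ndarray:
        out = np.where(np.isnan(self.rho_w_fixed), 0.5, self.rho_w_fixed)
        return out.astype(float)

    def lik_prec(self, rho_w: np.ndarray):
        c = 1.0 - rho_w**2
        Q11 = 1.0 / (self.se1**2 * c)
        Q22 = 1.0 / (self.se2**2 * c)
        Q12 = -rho_w / (self.se1 * self.se2 * c)
        miss = ~self.y2_obs
        if miss.any():
            Q11 = Q11.copy()
            Q12 = Q12.copy()
            Q22 = Q22.copy()
            Q11[miss] = 1.0 / self.se1[miss] ** 2
            Q12[miss] = 0.0
            Q22[miss] = 0.0
        return Q11, Q12, Q22


# ---------------------------------------------------------------------------
# chains


def run_dh_chain(rng, data: StudyArrays, pri: dict, n_iter: int, n_burnin: int) -> dict:
    """One chain of the fixed-effects (Daniels & Hughes) surrogacy model."""
    n = data.n
    Vf = pri["var_fixed"]
    psi_up = pri["psi2_upper"]

    rho_w = data.init_rho_w()
    lam0 = 0.1 * rng.standard_normal()
    lam1 = 0.5 + 0.3 * rng.standard_normal()
    psi2 = rng.uniform(0.05, min(0.5, psi_up))
    Q11, Q12, Q22 = data.lik_prec(rho_w)

    n_rec = n_iter - n_burnin
    rec = {
        "lambda0": np.empty(n_rec),
        "lambda1": np.empty(n_rec),
        "psi2_sq": np.empty(n_rec),
        "delta1": np.empty((n_rec, n)),
        "delta2": np.empty((n_rec, n)),
        "rho_w": np.empty((n_rec, n)),
    }

    for it in range(n_iter):
        psi2sq = max(psi2 * psi2, _PSI2_SQ_FLOOR)
        d1, d2 = _draw_delta(
            rng, Q11, Q12, Q22, data.y1, data.y2z, 0.0, Vf, lam0, lam1, psi2sq
        )
        S1 = float(d1.sum())
        S11 = float(d1 @ d1)
        S2 = float(d2.sum())
        S12 = float(d1 @ d2)
        # joint conjugate draw of (lambda0, lambda1)
        A11 = n / psi2sq + 1.0 / Vf
        A12 = S1 / psi2sq
        A22 = S11 / psi2sq + 1.0 / Vf
        lam0, lam1 = (
            float(v) for v in _mvn2_draw(rng, A11, A12, A22, S2 / psi2sq, S12 / psi2sq)
        )
        resid = d2 - lam0 - lam1 * d1
        psi2 = _draw_sd(rng, float(resid @ resid), n, psi_up, psi2)
        if data.rho_w_sampled.any():
            _update_rho_w(
                rng, rho_w, data.rho_w_sampled, data.y1 - d1, data.y2z - d2,
                data.se1, data.se2,
            )
            Q11, Q12, Q22 = data.lik_prec(rho_w)
        if it >= n_burnin:
            r = it - n_burnin
            rec["lambda0"][r] = lam0
            rec["lambda1"][r] = lam1
            rec["psi2_sq"][r] = psi2 * psi2
            rec["delta1"][r] = d1
            rec["delta2"][r] = d2
            rec["rho_w"][r] = rho_w
    return rec


def _bias_group_update(rng, idx, data, d1v, d2v, Q11, Q12, Q22, mu1, mu2, s1, s2, pri):
    """Per-study bias draws plus their normal-mean / uniform-SD hyperupdates."""
    ng = idx.size
    s1 = max(s1, _SD_FLOOR)
    s2 = max(s2, _SD_FLOOR)
    r1 = data.y1[idx] - d1v[idx]
    r2 = data.y2z[idx] - d2v[idx]
    P11 = Q11[idx] + 1.0 / s1**2
    P12 = Q12[idx].astype(float)
    P22 = Q22[idx] + 1.0 / s2**2
    h1 = mu1 / s1**2 + Q11[idx] * r1 + Q12[idx] * r2
    h2 = mu2 / s2**2 + Q12[idx] * r1 + Q22[idx] * r2
    b1, b2 = _mvn2_draw(rng, P11, P12, P22, h1, h2)
    Vb = pri["bias_mean_var"]
    prec1 = ng / s1**2 + 1.0 / Vb
    mu1 = rng.normal((b1.sum() / s1**2) / prec1, math.sqrt(1.0 / prec1))
    prec2 = ng / s2**2 + 1.0 / Vb
    mu2 = rng.normal((b2.sum() / s2**2) / prec2, math.sqrt(1.0 / prec2))
    up = pri["bias_sd_upper"]
    s1 = _draw_sd(rng, float(((b1 - mu1) ** 2).sum()), ng, up, s1)
    s2 = _draw_sd(rng, float(((b2 - mu2) ** 2).sum()), ng, up, s2)
    return b1, b2, float(mu1), float(mu2), s1, s2


def run_brma_chain(
    rng, data: StudyArrays, pri: dict, n_iter: int, n_burnin: int, bias: bool
) -> dict:
    """One chain of the BRMA product-normal model (optionally bias-adjusted)."""
    n = data.n
    Vf = pri["var_fixed"]
    tau_up = pri["tau_upper"]

    rho_w = data.init_rho_w()
    eta1 = float(np.mean(data.y1)) + 0.1 * rng.standard_normal()
    lam0 = 0.1 * rng.standard_normal()
    tau1 = rng.uniform(0.1, min(0.5, tau_up))
    tau2 = rng.uniform(0.1, min(0.5, tau_up))
    rho = rng.uniform(-0.5, 0.9)
    Q11, Q12, Q22 = data.lik_prec(rho_w)

    bias1 = np.zeros(n)
    bias2 = np.zeros(n)
    idx_c = np.where(data.design == "cRWE")[0]
    idx_s = np.where(data.design == "sRWE")[0]
    a1 = a2 = b1m = b2m = 0.0
    sa1 = sa2 = sb1 = sb2 = 0.2

    n_rec = n_iter - n_burnin
    rec = {
        "d1": np.empty(n_rec),
        "lambda0": np.empty(n_rec),
        "tau1": np.empty(n_rec),
        "tau2": np.empty(n_rec),
        "rho": np.empty(n_rec),
        "lambda1": np.empty(n_rec),
        "psi2_sq": np.empty(n_rec),
        "psi1_sq": np.empty(n_rec),
        "r2": np.empty(n_rec),
        "d2": np.empty(n_rec),
        "delta1": np.empty((n_rec, n)),
        "delta2": np.empty((n_rec, n)),
        "rho_w": np.empty((n_rec, n)),
    }
    if bias:
        for k in ("alpha1", "alpha2", "beta1", "beta2",
                  "sigma_alpha1", "sigma_alpha2", "sigma_beta1", "sigma_beta2"):
            rec[k] = np.empty(n_rec)
        rec["bias1"] = np.empty((n_rec, n))
        rec["bias2"] = np.empty((n_rec, n))

    for it in range(n_iter):
        lam1 = rho * tau2 / tau1
        psi2sq = max(tau2 * tau2 * (1.0 - rho * rho), _PSI2_SQ_FLOOR)
        y1c = data.y1 - bias1
        y2c = np.where(data.y2_obs, data.y2 - bias2, 0.0)
        d1v, d2v = _draw_delta(
            rng, Q11, Q12, Q22, y1c, y2c, eta1, tau1 * tau1, lam0, lam1, psi2sq
        )
        S1 = float(d1v.sum())
        S11 = float(d1v @ d1v)
        S2 = float(d2v.sum())
        S22 = float(d2v @ d2v)
        S12 = float(d1v @ d2v)
        # pooled surrogate mean
        prec = n / (tau1 * tau1) + 1.0 / Vf
        eta1 = float(rng.normal((S1 / (tau1 * tau1)) / prec, math.sqrt(1.0 / prec)))
        # regression intercept
        prec0 = n / psi2sq + 1.0 / Vf
        lam0 = float(
            rng.normal(((S2 - lam1 * S1) / psi2sq) / prec0, math.sqrt(1.0 / prec0))
        )

        def logf_between(t1_: float, t2_: float, r_: float) -> float:
            l1 = r_ * t2_ / t1_
            p2 = max(t2_ * t2_ * (1.0 - r_ * r_), _PSI2_SQ_FLOOR)
            q1 = S11 - 2.0 * eta1 * S1 + n * eta1 * eta1
            q2 = (
                S22 + n * lam0 * lam0 + l1 * l1 * S11
                - 2.0 * lam0 * S2 - 2.0 * l1 * S12 + 2.0 * lam0 * l1 * S1
            )
            return (
                -n * math.log(t1_) - q1 / (2.0 * t1_ * t1_)
                - 0.5 * n * math.log(p2) - q2 / (2.0 * p2)
            )

        tau1 = _slice_update(
            rng, tau1, lambda x: logf_between(x, tau2, rho), 1e-4, tau_up, w=0.15
        )
        tau2 = _slice_update(
            rng, tau2, lambda x: logf_between(tau1, x, rho), 1e-4, tau_up, w=0.15
        )
        rho = _slice_update(
            rng, rho, lambda x: logf_between(tau1, tau2, x), -1.0 + 1e-9, 1.0 - 1e-9, w=0.3
        )
        lam1 = rho * tau2 / tau1
        psi2sq = max(tau2 * tau2 * (1.0 - rho * rho), _PSI2_SQ_FLOOR)

        if bias:
            if idx_c.size:
                bc1, bc2, a1, a2, sa1, sa2 = _bias_group_update(
                    rng, idx_c, data, d1v, d2v, Q11, Q12, Q22, a1, a2, sa1, sa2, pri
                )
                bias1[idx_c] = bc1
                bias2[idx_c] = bc2
            if idx_s.size:
                bs1, bs2, b1m, b2m, sb1, sb2 = _bias_group_update(
                    rng, idx_s, data, d1v, d2v, Q11, Q12, Q22, b1m, b2m, sb1, sb2, pri
                )
                bias1[idx_s] = bs1
                bias2[idx_s] = bs2

        if data.rho_w_sampled.any():
            _update_rho_w(
                rng, rho_w, data.rho_w_sampled,
                data.y1 - d1v - bias1, data.y2z - d2v - bias2,
                data.se1, data.se2,
            )
            Q11, Q12, Q22 = data.lik_prec(rho_w)

        if it >= n_burnin:
            r = it - n_burnin
            rec["d1"][r] = eta1
            rec["lambda0"][r] = lam0
            rec["tau1"][r] = tau1
            rec["tau2"][r] = tau2
            rec["rho"][r] = rho
            rec["lambda1"][r] = lam1
            rec["psi2_sq"][r] = psi2sq
            rec["psi1_sq"][r] = tau1 * tau1
            rec["r2"][r] = rho * rho
            rec["d2"][r] = lam0 + lam1 * eta1
            rec["delta1"][r] = d1v
            rec["delta2"][r] = d2v
            rec["rho_w"][r] = rho_w
            if bias:
                rec["alpha1"][r] = a1
                rec["alpha2"][r] = a2
                rec["beta1"][r] = b1m
                rec["beta2"][r] = b2m
                rec["sigma_alpha1"][r] = sa1
                rec["sigma_alpha2"][r] = sa2
                rec["sigma_beta1"][r] = sb1
                rec["sigma_beta2"][r] = sb2
                rec["bias1"][r] = bias1
                rec["bias2"][r] = bias2
    return rec


def run_chains(model: str, data: StudyArrays, pri: dict, settings) -> dict:
    """Run ``settings.n_chains`` independent chains and stack the draws to
    shape (chain, draw[, study])."""
    seqs = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = []
    for ss in seqs:
        rng = np.random.default_rng(ss)
        if model == "DH":
            chains.append(run_dh_chain(rng, data, pri, settings.n_iter, settings.n_burnin))
        elif model == "BRMA":
            chains.append(
                run_brma_chain(rng, data, pri, settings.n_iter, settings.n_burnin, False)
            )
        elif model == "BRMA_bias":
            chains.append(
                run_brma_chain(rng, data, pri, settings.n_iter, settings.n_burnin, True)
            )
        else:
            raise ValueError(f"unknown model {model!r}")
    return {k: np.stack([c[k] for c in chains]) for k in chains[0]}
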