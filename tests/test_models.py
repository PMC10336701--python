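import warnings

import numpy as np
import pytest

from surrobayes import (
    MCMCSettings,
    PriorConfig,
    SimulationConfig,
    StudyEffect,
    evaluate_criteria,
    fit_brma_pnf,
    fit_brma_pnf_bias,
    fit_dh,
    simulate_meta_dataset,
    summarize_fit,
    transform_brma_params,
)
from surrobayes.datamodel import PosteriorSummary
from surrobayes.models import ConvergenceWarning


def line_dataset(n=20, lam0=0.1, lam1=0.7, se=1e-6, seed=0):
    """Studies lying exactly on y2 = lam0 + lam1 * y1 with tiny SEs."""
    rng = np.random.default_rng(seed)
    y1 = rng.uniform(-1.0, 0.2, size=n)
    return [
        StudyEffect(f"S{i}", "RCT", float(v), se, float(lam0 + lam1 * v), se, rho_w=0.0)
        for i, v in enumerate(y1)
    ]


class TestTransform:
    def test_half_correlation_example(self):
        lam1, psi1_sq, psi2_sq = transform_brma_params(1.0, 1.0, 0.5)
        assert lam1 == pytest.approx(0.5)
        assert psi1_sq == pytest.approx(1.0)
        assert psi2_sq == pytest.approx(0.75)

    @pytest.mark.parametrize("rho", [1.0, -1.0])
    def test_perfect_correlation_gives_exactly_zero(self, rho):
        _, _, psi2_sq = transform_brma_params(0.37, 0.91, rho)
        assert psi2_sq == 0.0

    def test_inverse_map_round_trip(self):
        rng = np.random.default_rng(1)
        tau1 = rng.uniform(0.05, 2.0, 1000)
        tau2 = rng.uniform(0.05, 2.0, 1000)
        rho = rng.uniform(-1.0, 1.0, 1000)
        lam1, psi1_sq, psi2_sq = transform_brma_params(tau1, tau2, rho)
        tau2_back = np.sqrt(lam1**2 * psi1_sq + psi2_sq)
        rho_back = lam1 * np.sqrt(psi1_sq) / tau2_back
        assert np.allclose(tau2_back, tau2, atol=1e-12)
        assert np.allclose(rho_back, rho, atol=1e-12)

    def test_zero_tau1_rejected(self):
        with pytest.raises(ValueError, match="tau1"):
            transform_brma_params(0.0, 0.5, 0.2)


class TestDH:
    def test_noise_free_limit_recovers_the_line(self, fast_mcmc):
        fit = fit_dh(line_dataset(), PriorConfig(), fast_mcmc)
        assert fit.get("lambda0").mean() == pytest.approx(0.1, abs=0.01)
        assert fit.get("lambda1").mean() == pytest.approx(0.7, abs=0.01)
        assert fit.summarize("psi2_sq").point < 1e-3

    def test_tiny_se_limit_matches_ols(self, fast_mcmc):
        rng = np.random.default_rng(3)
        y1 = rng.uniform(-1, 0.3, 15)
        y2 = 0.05 + 0.6 * y1 + rng.normal(0, 0.08, 15)
        data = [
            StudyEffect(f"S{i}", "RCT", float(a), 1e-6, float(b), 1e-6, rho_w=0.0)
            for i, (a, b) in enumerate(zip(y1, y2))
        ]
        X = np.column_stack([np.ones(15), y1])
        ols = np.linalg.lstsq(X, y2, rcond=None)[0]
        fit = fit_dh(data, PriorConfig(), fast_mcmc)
        assert fit.get("lambda0").mean() == pytest.approx(ols[0], abs=0.01)
        assert fit.get("lambda1").mean() == pytest.approx(ols[1], abs=0.01)

    def test_reproducible_given_seed(self, mixed_dataset, fast_mcmc):
        a = fit_dh(mixed_dataset, PriorConfig(), fast_mcmc)
        b = fit_dh(mixed_dataset, PriorConfig(), fast_mcmc)
        assert np.array_equal(a.get("lambda1"), b.get("lambda1"))

    def test_prior_supports_respected(self, mixed_dataset, fast_mcmc):
        fit = fit_dh(mixed_dataset, PriorConfig(), fast_mcmc)
        assert np.all(fit.get("psi2_sq") <= 4.0)  # psi2 <= 2
        rho_w = fit.get("rho_w")
        assert np.all((rho_w >= 0) & (rho_w <= 1))

    def test_sensitivity_prior_widens_support(self, fast_mcmc):
        # a dataset with large conditional spread needs psi2 > 2
        rng = np.random.default_rng(4)
        y1 = rng.uniform(-1, 1, 12)
        y2 = 5.0 * rng.standard_normal(12)
        data = [
            StudyEffect(f"S{i}", "RCT", float(a), 0.01, float(b), 0.01, rho_w=0.0)
            for i, (a, b) in enumerate(zip(y1, y2))
        ]
        wide = fit_dh(data, PriorConfig().sd_sensitivity(100.0), fast_mcmc)
        assert wide.get("psi2_sq").mean() > 4.0

    def test_too_few_studies_rejected(self, fast_mcmc):
        with pytest.raises(ValueError, match="3 studies"):
            fit_dh(line_dataset(n=2), PriorConfig(), fast_mcmc)

    def test_unknown_parameter_lookup(self, mixed_dataset, fast_mcmc):
        fit = fit_dh(mixed_dataset, PriorConfig(), fast_mcmc)
        with pytest.raises(KeyError, match="unknown parameter"):
            fit.get("nonexistent")


class TestBRMA:
    def test_eq5_identities_hold_per_draw(self, mixed_dataset, fast_mcmc, fixed_rho_priors):
        fit = fit_brma_pnf(mixed_dataset, fixed_rho_priors, fast_mcmc)
        tau1 = fit.get("tau1")
        tau2 = fit.get("tau2")
        rho = fit.get("rho")
        lam1 = fit.get("lambda1")
        psi2 = fit.get("psi2_sq")
        assert np.allclose(lam1, rho * tau2 / tau1, atol=1e-10)
        assert np.allclose(psi2 + lam1**2 * tau1**2, tau2**2, atol=1e-10)
        assert np.allclose(fit.get("r2"), rho**2, atol=1e-12)
        assert np.allclose(fit.get("d2"), fit.get("lambda0") + lam1 * fit.get("d1"), atol=1e-10)

    def test_null_association_concentrates_rho_near_zero(self, fixed_rho_priors):
        cfg = SimulationConfig(
            n_rct=40, n_crwe=0, n_srwe=0, tau1=0.3, tau2=0.3, rho=0.0,
            se_range=(0.02, 0.05), rho_w=0.52, seed=9,
        )
        data = [s.effect for s in simulate_meta_dataset(cfg)]
        fit = fit_brma_pnf(data, fixed_rho_priors, MCMCSettings(3000, 1000, 1, 2))
        s = fit.summarize("rho")
        assert s.contains(0.0)
        assert abs(s.point) < 0.3
        assert fit.summarize("r2").point < 0.3

    def test_prior_supports_respected(self, mixed_dataset, fast_mcmc):
        fit = fit_brma_pnf(mixed_dataset, PriorConfig(), fast_mcmc)
        assert np.all(np.abs(fit.get("rho")) <= 1.0)
        assert np.all(fit.get("tau1") <= 2.0)
        assert np.all(fit.get("tau2") <= 2.0)
        rho_w = fit.get("rho_w")
        assert np.all((rho_w >= 0) & (rho_w <= 1))


class TestBRMABias:
    def test_all_rct_input_redirected(self, fast_mcmc):
        with pytest.raises(ValueError, match="fit_brma_pnf"):
            fit_brma_pnf_bias(line_dataset(n=5), PriorConfig(), fast_mcmc)

    def test_pinned_bias_reduces_to_base_model(self, fixed_rho_priors):
        cfg = SimulationConfig(n_rct=10, n_crwe=6, n_srwe=0, se_range=(0.05, 0.15), seed=10)
        data = [s.effect for s in simulate_meta_dataset(cfg)]
        mc = MCMCSettings(4000, 1500, 1, 3)
        import dataclasses

        pinned = dataclasses.replace(
            fixed_rho_priors, bias_mean_var=1e-10, bias_sd_upper=1e-4
        )
        base = fit_brma_pnf(data, fixed_rho_priors, mc)
        red = fit_brma_pnf_bias(data, pinned, mc)
        for p in ("lambda1", "lambda0", "rho"):
            sb_, sr = base.summarize(p), red.summarize(p)
            # posterior means agree within Monte-Carlo error
            tol = 0.2 * (sb_.width + sr.width) / 2 + 0.02
            assert abs(sb_.point - sr.point) < tol
        assert np.all(np.abs(red.get("bias1")) < 0.01)

    def test_recovers_injected_crwe_bias(self, fixed_rho_priors):
        cfg = SimulationConfig(
            n_rct=10, n_crwe=20, n_srwe=0, tau1=0.25, tau2=None, rho=None,
            lambda1=0.7, psi2=0.1, lambda0=0.0, se_range=(0.02, 0.05), rho_w=0.52,
            alpha1=0.3, alpha2=0.3, sigma_alpha1=0.05, sigma_alpha2=0.05, seed=7,
        )
        data = [s.effect for s in simulate_meta_dataset(cfg)]
        fit = fit_brma_pnf_bias(data, fixed_rho_priors, MCMCSettings(5000, 1500, 1, 3))
        assert fit.summarize("alpha1").contains(0.3)
        assert fit.summarize("alpha2").contains(0.3)


class TestDiagnosticsAndSummaries:
    def test_nonconvergence_is_flagged_not_silent(self, mixed_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            with pytest.raises(ConvergenceWarning):
                # far too short to reach ESS > 400
                fit_dh(mixed_dataset, PriorConfig(), MCMCSettings(260, 50, 1, 0))

    def test_summary_table_layout(self, mixed_dataset, fast_mcmc):
        fit = fit_dh(mixed_dataset, PriorConfig(), fast_mcmc)
        df = summarize_fit(fit)
        assert list(df.columns) == ["parameter", "point", "cri_low", "cri_high", "point_style"]
        assert set(df["parameter"]) == {"lambda0", "lambda1", "psi2_sq"}
        row = df.set_index("parameter").loc["psi2_sq"]
        assert row["point_style"] == "median"


class TestCriteria:
    @staticmethod
    def _summary(name, lo, hi, point=None):
        point = point if point is not None else 0.5 * (lo + hi)
        return PosteriorSummary(name, point, lo, hi, "mean")

    def test_intercept_criterion_satisfied(self):
        rep = evaluate_criteria(
            {
                "lambda0": self._summary("lambda0", -0.13, 0.34, 0.11),
                "lambda1": self._summary("lambda1", 0.12, 1.30, 0.71),
                "psi2_sq": self._summary("psi2_sq", 0.0, 0.11, 0.0089),
            },
            model="DH",
        )
        assert rep.intercept_zero
        assert rep.slope_nonzero
        assert rep.satisfied

    def test_slope_criterion_fails_when_cri_straddles_zero(self):
        rep = evaluate_criteria(
            {
                "lambda0": self._summary("lambda0", -0.22, 0.33),
                "lambda1": self._summary("lambda1", -0.16, 1.31, 0.54),
                "psi2_sq": self._summary("psi2_sq", 0.0008, 0.099),
                "rho": self._summary("rho", -0.25, 0.99, 0.75),
            },
            model="BRMA",
        )
        assert not rep.slope_nonzero
        assert not rep.satisfied

    def test_slope_criterion_satisfied(self):
        rep = evaluate_criteria(
            {
                "lambda0": self._summary("lambda0", -0.10, 0.20),
                "lambda1": self._summary("lambda1", 0.31, 1.04, 0.68),
                "psi2_sq": self._summary("psi2_sq", 0.0003, 0.037),
            },
            model="DH",
        )
        assert rep.slope_nonzero

    def test_missing_parameter_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            evaluate_criteria({"lambda0": self._summary("lambda0", -1, 1)}, model="DH")

    def test_brma_requires_rho(self):
        with pytest.raises(KeyError, match="rho"):
            evaluate_criteria(
                {
                    "lambda0": self._summary("lambda0", -1, 1),
                    "lambda1": self._summary("lambda1", 0.1, 1),
                    "psi2_sq": self._summary("psi2_sq", 0, 0.1),
                },
                model="BRMA",
            )
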