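"""End-to-end scenario orchestration with manifests for reproducibility.

An *evidence scenario* is a design filter plus a model choice: the same
surrogacy dataset can be analysed with RCTs only, RCTs plus comparative
real-world evidence, all evidence, or all evidence with the bias-adjusted
model. ``run_scenario`` chains filtering, fitting, criteria evaluation and
take-one-out cross-validation, writing tidy CSV/JSON outputs plus a
manifest (configuration, seeds, input hash, convergence diagnostics) from
which every number in the tables can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .crossval import CrossValReport, crossvalidate
from .datamodel import Design, MCMCSettings, StudyEffect, study_effects_to_frame
from .km import KMDataset, cox_loghr, reconstruct_ipd
from .matching import (
    CovariateProfile,
    CovariateSpec,
    DistanceMatrix,
    MatchedPairs,
    default_covariate_spec,
    derive_threshold,
    distance_matrix,
    select_matches,
)
from .models import (
    PriorConfig,
    evaluate_criteria,
    fit_brma_pnf,
    fit_brma_pnf_bias,
    fit_dh,
    summarize_fit,
)

__all__ = [
    "ScenarioConfig",
    "run_scenario",
    "run_matching_stage",
    "load_run_config",
]

SCENARIO_DESIGNS: dict[str, set[Design]] = {
    "RCT": {Design.RCT},
    "RCT+cRWE": {Design.RCT, Design.cRWE},
    "RCT+cRWE+sRWE": {Design.RCT, Design.cRWE, Design.sRWE},
    "RCT+cRWE+sRWE-bias": {Design.RCT, Design.cRWE, Design.sRWE},
}

_FIT = {"DH": fit_dh, "BRMA": fit_brma_pnf, "BRMA_bias": fit_brma_pnf_bias}


@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis scenario: evidence filter, model, priors, MCMC settings."""

    scenario: str
    model: str
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    threshold_source: str = "manual"  # "RCT-derived", "cRWE-derived", "manual"
    crossval: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_DESIGNS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(SCENARIO_DESIGNS)}"
            )
        if self.model not in _FIT:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_FIT)}")
        if self.model == "BRMA_bias" and self.scenario == "RCT":
            raise ValueError("the bias-adjusted model needs non-RCT evidence")

    @property
    def designs(self) -> set[Design]:
        return SCENARIO_DESIGNS[self.scenario]

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "model": self.model,
            "priors": self.priors.as_dict(),
            "mcmc": {
                "n_iter": self.mcmc.n_iter,
                "n_burnin": self.mcmc.n_burnin,
                "n_chains": self.mcmc.n_chains,
                "seed": self.mcmc.seed,
            },
            "threshold_source": self.threshold_source,
            "crossval": self.crossval,
        }


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_scenario(
    config: ScenarioConfig,
    effects: Sequence[StudyEffect],
    outdir: str | Path | None = None,
):
    """Run one evidence scenario end to end.

    Returns a dict with the fit, its summary table, the criteria report,
    the cross-validation report (when requested), and the manifest; when
    ``outdir`` is given, writes ``summary.csv``, ``criteria.json``,
    ``crossval.csv``, ``crossval_summary.csv`` and ``manifest.json``.
    """
    subset = [e for e in effects if e.design in config.designs]
    if not subset:
        raise ValueError(f"scenario {config.scenario!r}: no studies after filtering")
    if config.model == "BRMA_bias" and all(e.design is Design.RCT for e in subset):
        raise ValueError("bias-adjusted scenario received RCT-only data")

    fit = _FIT[config.model](subset, config.priors, config.mcmc)
    summary = summarize_fit(fit)
    criteria = evaluate_criteria(fit)
    report: CrossValReport | None = None
    if config.crossval:
        report = crossvalidate(subset, config.model, config.priors, config.mcmc)
        extra = pd.DataFrame(
            [
                {
                    "parameter": "abs_discrepancy_median",
                    "point": report.median_abs_discrepancy,
                    "cri_low": report.abs_discrepancy_range[0],
                    "cri_high": report.abs_discrepancy_range[1],
                    "point_style": "median",
                },
                {
                    "parameter": "width_ratio_median",
                    "point": report.median_width_ratio,
                    "cri_low": report.width_ratio_range[0],
                    "cri_high": report.width_ratio_range[1],
                    "point_style": "median",
                },
            ]
        )
        summary = pd.concat([summary, extra], ignore_index=True)

    manifest = {
        "config": config.to_dict(),
        "n_studies": len(subset),
        "study_ids": [e.study_id for e in subset],
        "input_sha256": _hash_frame(study_effects_to_frame(subset)),
        "converged": fit.converged,
        "diagnostics": fit.diagnostics.to_dict(orient="records"),
    }
    bundle = {
        "fit": fit,
        "summary": summary,
        "criteria": criteria,
        "crossval": report,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "criteria.json", "w") as fh:
            json.dump(criteria.to_dict(), fh, indent=2)
        if report is not None:
            report.to_frame().to_csv(outdir / "crossval.csv", index=False)
            pd.DataFrame([report.summary_row()]).to_csv(
                outdir / "crossval_summary.csv", index=False
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle


def run_matching_stage(
    treat_profiles: Sequence[CovariateProfile],
    ctrl_profiles: Sequence[CovariateProfile],
    spec: CovariateSpec | None = None,
    threshold: float | None = None,
    reference_pairs: Sequence[tuple[CovariateProfile, CovariateProfile]] | None = None,
    km_data: Mapping[str, Mapping[str, KMDataset]] | None = None,
):
    """Match single-arm studies and, when KM data are supplied, estimate
    their treatment effects.

    ``km_data`` maps study_id -> outcome ("surrogate"/"final") -> KMDataset.
    For each matched pair with KM data for both studies and both outcomes,
    pseudo-IPD is reconstructed and a Cox log hazard ratio estimated,
    yielding study-effect rows with design ``sRWE``.

    Returns ``(matches, distance_matrix_or_None, effects)``; a manual
    ``threshold`` takes precedence over one derived from reference pairs.
    """
    spec = spec or default_covariate_spec()
    if not treat_profiles or not ctrl_profiles:
        return MatchedPairs(pairs=(), threshold=float(threshold or 1.0)), None, []
    if threshold is None:
        if reference_pairs is None:
            raise ValueError("supply either a manual threshold or reference pairs")
        threshold = derive_threshold(reference_pairs, spec)
    dm: DistanceMatrix = distance_matrix(treat_profiles, ctrl_profiles, spec)
    matches = select_matches(dm, threshold)

    effects: list[StudyEffect] = []
    if km_data is not None:
        for treat_id, ctrl_id, dist in matches.pairs:
            missing = [
                sid for sid in (treat_id, ctrl_id)
                if sid not in km_data
                or not {"surrogate", "final"} <= set(km_data[sid])
            ]
            if missing:
                raise KeyError(
                    f"matched pair ({treat_id!r}, {ctrl_id!r}) lacks KM data "
                    f"for: {missing}"
                )
            est = {}
            for outcome in ("surrogate", "final"):
                ipd_t = reconstruct_ipd(km_data[treat_id][outcome])
                ipd_c = reconstruct_ipd(km_data[ctrl_id][outcome])
                est[outcome] = cox_loghr(ipd_t, ipd_c)
            effects.append(
                StudyEffect(
                    study_id=f"{treat_id} vs {ctrl_id}",
                    design=Design.sRWE,
                    y1=est["surrogate"].loghr,
                    se1=est["surrogate"].se,
                    y2=est["final"].loghr,
                    se2=est["final"].se,
                    rho_w=None,
                )
            )
    return matches, dm, effects


def load_run_config(path) -> tuple[PriorConfig, MCMCSettings, dict]:
    """Read priors + MCMC settings (plus any extra keys) from YAML/JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    priors = PriorConfig(**raw.get("priors", {}))
    mcmc = MCMCSettings(**raw.get("mcmc", {}))
    extra = {k: v for k, v in raw.items() if k not in ("priors", "mcmc")}
    return priors, mcmc, extra
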