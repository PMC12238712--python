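"""End-to-end orchestration: simulate -> qc -> index -> impute -> famd -> regress.

:func:`analyze_cohort` runs the whole analysis in memory on a cohort
(synthetic or loaded) and returns every stage's result object;
:func:`run_all` is the file-based runner behind the command line,
writing each stage's artifact plus a manifest that suffices to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import LogisticFit, regression_table, sex_stratified_run
from .datamodel import (
    CovariateSchema,
    missingness_report,
    read_covariates,
    read_measurements,
    to_trait_table,
)
from .fa import FAIndexResult, compute_fa_index
from .famd import FAMD, FAMDResults
from .impute import ImputationResult, impute_famd
from .qc import ScreenConfig, ScreenResult, run_screen
from .simulate import SimulationConfig, SyntheticCohort, align_dimensions, generate


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run (defaults per stage)."""

    out_dir: str = "odontofa_run"
    measurements_path: str | None = None
    covariates_path: str | None = None
    schema_path: str | None = None
    simulate: bool = False
    seed: int = 0
    qc_alpha: float = 0.05
    min_presence_fraction: float = 0.25
    min_traits: int | None = None  # default: ceil(battery / 2)
    fa_cutoff: float = 1.0
    famd_ndim: int = 4
    impute_ncp: int = 5
    impute_tol: float = 1e-6
    impute_max_iter: int = 1000
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class CohortAnalysis:
    """All stage results for one cohort."""

    screen: ScreenResult
    fa: FAIndexResult
    imputation: ImputationResult | None
    famd: FAMDResults
    dims: pd.DataFrame
    fits: dict[str, LogisticFit]
    aligned_fits: dict[str, LogisticFit] | None = None


def analyze_cohort(
    cohort: SyntheticCohort,
    ndim: int = 4,
    ncp: int = 5,
    qc_config: ScreenConfig | None = None,
    min_traits: int | None = None,
    cutoff: float = 1.0,
    impute_tol: float = 1e-6,
    impute_max_iter: int = 1000,
    align: bool = False,
) -> CohortAnalysis:
    """Run the full analysis on an in-memory cohort.

    With ``align=True`` (synthetic cohorts only) a second set of
    regressions is fitted on dimensions matched and sign-aligned to the
    generator's latent factors, so recovered coefficient signs can be
    compared with the injected ones.
    """
    traits = to_trait_table(cohort.measurements)
    screen = run_screen(traits, cohort.measurements, qc_config)
    fa = compute_fa_index(screen.cleaned, min_traits=min_traits, cutoff=cutoff)

    if cohort.covariates.isna().any().any():
        imputation = impute_famd(
            cohort.covariates, ncp=ncp, tol=impute_tol, max_iter=impute_max_iter,
            schema=cohort.schema,
        )
        model = FAMD.from_completed(imputation)
    else:
        imputation = None
        model = FAMD(cohort.covariates, cohort.schema)
    famd_res = model.fit(ndim)
    dims = famd_res.row_coordinates

    fits = sex_stratified_run(fa, dims)
    aligned_fits = None
    if align and cohort.truth is not None:
        aligned = align_dimensions(dims, cohort.truth)
        aligned_fits = sex_stratified_run(fa, aligned)
    return CohortAnalysis(
        screen=screen,
        fa=fa,
        imputation=imputation,
        famd=famd_res,
        dims=dims,
        fits=fits,
        aligned_fits=aligned_fits,
    )


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """File-based pipeline run; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "odontofa_version": __version__,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    if cfg.simulate:
        sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.sim_overrides)
        cohort = generate(sim_cfg)
        cohort.measurements.to_csv(out / "measurements.csv", index=False)
        cohort.covariates.to_csv(out / "covariates.csv", na_rep="NA")
        truth = cohort.truth.latent.copy()
        truth["instability"] = cohort.truth.instability
        truth["sex"] = cohort.truth.sex
        truth.to_csv(out / "truth.csv")
        with open(out / "schema.yaml", "w") as fh:
            yaml.safe_dump({"variables": cohort.schema.to_dict()}, fh)
        measurements, covariates, schema = cohort.measurements, cohort.covariates, cohort.schema
        manifest["stages"]["simulate"] = {
            "n_individuals": sim_cfg.n_individuals,
            "n_measurement_rows": len(measurements),
        }
    else:
        if not (cfg.measurements_path and cfg.covariates_path and cfg.schema_path):
            raise ValueError("need measurements, covariates and schema paths (or simulate: true)")
        measurements = read_measurements(cfg.measurements_path)
        schema = CovariateSchema.from_yaml(cfg.schema_path)
        covariates = read_covariates(cfg.covariates_path, schema)
        cohort = SyntheticCohort(measurements, covariates, schema, truth=None)  # type: ignore[arg-type]

    traits = to_trait_table(measurements)
    screen = run_screen(
        traits,
        measurements,
        ScreenConfig(alpha=cfg.qc_alpha, min_presence_fraction=cfg.min_presence_fraction),
    )
    screen.to_frame().to_csv(out / "screen_report.csv", index=False)
    manifest["stages"]["qc"] = {
        "summary": screen.summary(),
        "retained": screen.retained_traits,
        "n_outlier_cells": len(screen.removed_cells),
    }

    fa = compute_fa_index(screen.cleaned, min_traits=cfg.min_traits, cutoff=cfg.fa_cutoff)
    fa.table.to_csv(out / "fa.csv", index_label="individual_id")
    manifest["stages"]["index"] = {
        "min_traits": fa.min_traits,
        "cutoff": fa.cutoff,
        "n_included": fa.n_included,
        "n_excluded": fa.n_excluded,
        "n_high_fa": int((fa.included["high_fa"] == 1).sum()),
    }

    miss = missingness_report(covariates)
    miss.to_csv(out / "missingness.csv", index_label="variable")
    if covariates.isna().any().any():
        imp = impute_famd(
            covariates, ncp=cfg.impute_ncp, tol=cfg.impute_tol,
            max_iter=cfg.impute_max_iter, schema=schema,
        )
        imp.completed.to_csv(out / "covariates_complete.csv", index_label="individual_id")
        imp.fuzzy.to_csv(out / "covariates_fuzzy.csv", index_label="individual_id")
        model = FAMD.from_completed(imp)
        manifest["stages"]["impute"] = {
            "ncp": imp.ncp,
            "iterations": imp.iterations,
            "converged": imp.converged,
        }
    else:
        model = FAMD(covariates, schema)
        manifest["stages"]["impute"] = {"skipped": "no missing cells"}

    res = model.fit(cfg.famd_ndim)
    res.screeplot_data().to_csv(out / "scree.csv", index=False)
    res.row_coordinates.to_csv(out / "ind_coords.csv", index_label="individual_id")
    res.variable_contributions_pct.to_csv(out / "contributions.csv", index_label="variable")
    pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(out / "eigenvalues.csv", index_label="dimension")
    manifest["stages"]["famd"] = {
        "ndim": cfg.famd_ndim,
        "explained_pct_first": [round(float(p), 4) for p in res.explained_variance_pct[: cfg.famd_ndim]],
    }

    fits = sex_stratified_run(fa, res.row_coordinates)
    regression_table(fits).to_csv(out / "regression.csv", index=False)
    manifest["stages"]["regress"] = {
        sex: {"n": fit.n, "lack_of_fit_p": round(fit.lack_of_fit_p, 4)} for sex, fit in fits.items()
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
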