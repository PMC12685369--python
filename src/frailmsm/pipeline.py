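"""Config-driven end-to-end analysis pipeline.

Runs the full analytic sequence on synthetic or user data: FI scoring (when
item-level data is given), panel assembly with an exclusion report,
descriptive table, optional multiple imputation, model fits (covariate-free,
multivariable, interaction), hazard-ratio tables, interval transition
probabilities, sojourn and length-of-stay summaries, and stratified refits.
Every output is a labelled CSV; a JSON manifest records the seed, stage
timings and subject counts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptives import descriptive_table
from .fit import (
    AGE_BANDS,
    FittedMSM,
    fit_interaction_model,
    fit_mle,
    fit_stratified,
    hazard_ratio_table,
)
from .impute import fit_pooled
from .index import assemble_panel, build_assessments, read_long_csv
from .panel import DESIGN_COLUMNS, PanelDataset
from .simulate import SyntheticCohortConfig, generate_cohort
from .summaries import (
    interval_transition_table,
    length_of_stay_table,
    reference_profile,
    sojourn_table,
)

DEFAULT_COVARIATES = DESIGN_COLUMNS


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause),
                "error_type": type(self.cause).__name__}


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    output_dir: str = "frailmsm_output"
    seed: int = 0
    # input: either a long-format CSV path or a synthetic cohort
    input_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    use_items: bool = False
    models: tuple[str, ...] = ("no_covariate", "multivariable")
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    prediction_times: tuple[float, ...] = (1.0, 3.0, 5.0)
    horizon: float = 10.0
    stratify: tuple[str, ...] = ()      # subset of {"age", "gender"}
    impute: bool = False
    m_imputations: int = 5
    death_convention: str = "exact"
    age_timevarying: bool = True

    def __post_init__(self):
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input file not found: {self.input_csv}")
        for t in self.prediction_times:
            if t <= 0:
                raise ValueError("prediction times must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        bad = set(self.models) - {"no_covariate", "multivariable", "interaction"}
        if bad:
            raise ValueError(f"unknown model variants: {sorted(bad)}")
        bad = set(self.stratify) - {"age", "gender"}
        if bad:
            raise ValueError(f"unknown strata: {sorted(bad)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        with open(path) as fh:
            payload = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) \
                else json.load(fh)
        for key in ("models", "covariates", "prediction_times", "stratify"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _load_data(config: RunConfig) -> tuple[PanelDataset, pd.DataFrame | None]:
    if config.input_csv is not None:
        return read_long_csv(config.input_csv,
                             death_convention=config.death_convention), None
    syn = dict(config.synthetic)
    syn.setdefault("seed", config.seed)
    syn.setdefault("death_convention", config.death_convention)
    cfg = SyntheticCohortConfig(**syn)
    if config.use_items:
        panel, items = generate_cohort(cfg, items=True)
        assessments = build_assessments(items)
        deaths = panel.observations.query("state == 4").rename(
            columns={"time": "death_time"})[["subject_id", "death_time"]]
        panel2 = assemble_panel(assessments, deaths, panel.covariates,
                                config.death_convention)
        return panel2, items
    return generate_cohort(cfg), None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "config": _jsonable(asdict(config)), "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:   # noqa: BLE001 - recorded and re-raised
                err = PipelineError(name, exc)
                manifest["stages"][name] = err.record()
                _write_manifest(manifest, out)
                raise err from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)}
            return result
        return deco

    data = stage("load_data")(lambda: _load_data(config))[0]
    manifest["n_subjects"] = int(data.n_subjects)
    if data.exclusions is not None:
        data.exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["n_excluded"] = int(len(data.exclusions))

    desc = stage("descriptive_table")(lambda: descriptive_table(data))
    desc.to_csv(out / "descriptive_table.csv", index=False)
    manifest["descriptive_overall_n"] = float(desc.loc[
        desc["characteristic"] == "n", "overall"].iloc[0])

    fits: dict[str, FittedMSM] = {}
    if "no_covariate" in config.models:
        fits["no_covariate"] = stage("fit_no_covariate")(
            lambda: fit_mle(data, (), age_timevarying=config.age_timevarying))
    if "multivariable" in config.models:
        if config.impute and data.covariates is not None \
                and data.covariates.isna().any().any():
            def _pooled():
                pooled, hr, imp = fit_pooled(
                    data, config.covariates, m=config.m_imputations,
                    rng=config.seed, age_timevarying=config.age_timevarying)
                hr.to_csv(out / "hr_table_pooled.csv", index=False)
                return imp.fits[0]
            fits["multivariable"] = stage("impute_fit_multivariable")(_pooled)
        else:
            fits["multivariable"] = stage("fit_multivariable")(
                lambda: fit_mle(data, config.covariates,
                                age_timevarying=config.age_timevarying))
    if "interaction" in config.models:
        fits["interaction"] = stage("fit_interaction")(
            lambda: fit_interaction_model(
                data, config.covariates,
                age_timevarying=config.age_timevarying))

    manifest["fits"] = {}
    for name, fit in fits.items():
        fit.model.to_json(out / f"model_{name}.json")
        manifest["fits"][name] = {
            "log_likelihood": float(fit.log_likelihood),
            "converged": bool(fit.converged),
            "n_iter": int(fit.n_iter),
            "n_subjects": int(fit.n_subjects),
            "n_intervals": int(fit.n_intervals),
        }
        if fit.model.n_covariates:
            hazard_ratio_table(fit).to_csv(out / f"hr_table_{name}.csv",
                                           index=False)

    # prediction surfaces from the covariate-free fit when available,
    # otherwise from the multivariable fit at the cohort reference profile
    base = fits.get("no_covariate") or next(iter(fits.values()))
    profile = None
    if base.model.n_covariates:
        profile = reference_profile(data.covariates)

    def _predict():
        tables = interval_transition_table(base, config.prediction_times,
                                           profile)
        for t, tab in tables.items():
            tab.to_csv(out / f"p_matrix_{t:g}y.csv")
        sojourn_table(base, profile).to_csv(out / "sojourn.csv", index=False)
        los = []
        for start in (1, 2, 3):
            tab = length_of_stay_table(base, config.horizon, start=start,
                                       profile=profile)
            tab.insert(0, "start_state",
                       {1: "robust", 2: "pre_frail", 3: "frail"}[start])
            los.append(tab)
        pd.concat(los, ignore_index=True).to_csv(
            out / "length_of_stay.csv", index=False)
        return tables

    stage("predictions")(_predict)

    if config.stratify and data.covariates is not None:
        def _strata():
            strata_fits = fit_stratified(
                data, (),
                age_bands=AGE_BANDS if "age" in config.stratify else None,
                by_gender="gender" in config.stratify,
                age_timevarying=config.age_timevarying)
            rows = []
            for label, f in strata_fits.items():
                st = sojourn_table(f)
                st.insert(0, "stratum", label)
                rows.append(st)
                for t, tab in interval_transition_table(
                        f, config.prediction_times).items():
                    tab.to_csv(out / f"p_matrix_{t:g}y_{label}.csv")
            pd.concat(rows, ignore_index=True).to_csv(
                out / "sojourn_by_stratum.csv", index=False)
            return strata_fits
        stage("stratified_fits")(_strata)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
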