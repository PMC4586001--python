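"""Stage orchestration: reproducible runs from config to artifacts.

Ties the stages (simulate → impute → cost → QALY → CEA → scenarios) into
one run with a recorded master seed. Every artifact directory gets a JSON
provenance record (inputs, seed, config hash, package version) so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalogue import (CostCatalogue, CourseSpec, SalaryTable, data_path,
                        load_catalogue, load_course_spec, load_salary_table)
from .costing import course_cost, cost_components, total_costs
from .cea import DEFAULT_B, default_lambda_grid
from .missingness import DEFAULT_M, nonresponse_analysis, response_indicator, DEFAULT_PREDICTORS
from .qaly import panel_qaly
from .scenarios import MAIN_SCENARIO, Scenario, ScenarioResult, run_scenario, scenario_suite
from .synth import TrialParams, apply_missingness, generate_trial

__all__ = ["RunConfig", "load_default_costing", "compute_costs", "simulate_stage",
           "cost_stage", "qaly_stage", "cea_stage", "report", "write_provenance"]

NONRESPONSE_VARIABLES = ("age", "gender", "cost_general_practice", "cost_outpatient",
                         "cost_admissions", "cost_medicine", "weeks_disability",
                         "weeks_sick", "training_attended", "education_attended")


@dataclass
class RunConfig:
    """Paths, sizes and the master seed of one reproducible run."""

    out_dir: Path
    patients_csv: Path | None = None          # existing patient table, or None to simulate
    params_yaml: Path | None = None           # TrialParams (defaults if None)
    catalogue_yaml: Path | None = None
    salaries_yaml: Path | None = None
    course_yamls: Mapping[str, Path] = field(default_factory=dict)
    scenario_yamls: Sequence[Path] = ()
    B: int = DEFAULT_B
    m: int = DEFAULT_M
    seed: int = 0
    perspective: str = "societal"

    def __post_init__(self):
        if self.B < 1 or self.m < 1:
            raise ValueError("B and m must be >= 1")
        self.out_dir = Path(self.out_dir)

    def config_hash(self) -> str:
        doc = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def load_default_costing() -> tuple[CostCatalogue, SalaryTable, dict[str, CourseSpec]]:
    """The shipped unit-cost catalogue, salary table and course specs."""
    catalogue = load_catalogue(data_path("item_costs_2013.yaml"))
    salaries = load_salary_table(data_path("salaries_synthetic.yaml"))
    specs = {"lc": load_course_spec(data_path("course_lc.yaml")),
             "standard": load_course_spec(data_path("course_standard.yaml"))}
    return catalogue, salaries, specs


def compute_costs(records: pd.DataFrame, catalogue: CostCatalogue, salaries: SalaryTable,
                  specs: Mapping[str, CourseSpec], perspective: str = "societal",
                  exclusions: Sequence[str] = ()) -> pd.Series:
    """Per-patient perspective totals straight from a trial table."""
    courses = {arm: course_cost(spec, catalogue) for arm, spec in specs.items()}
    comp = cost_components(records, catalogue, salaries, courses)
    return total_costs(comp, perspective, exclusions)


def write_provenance(out_dir: Path, config: RunConfig, stage: str, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"stage": stage, "seed": config.seed, "config_hash": config.config_hash(),
           "rehabcea_version": __version__,
           "inputs": {k: str(v) for k, v in asdict(config).items()}}
    if extra:
        doc.update(extra)
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path


def _load_params(config: RunConfig) -> TrialParams:
    return (TrialParams.from_yaml(config.params_yaml) if config.params_yaml
            else TrialParams.default())


def _load_costing(config: RunConfig):
    catalogue = (load_catalogue(config.catalogue_yaml) if config.catalogue_yaml
                 else load_catalogue(data_path("item_costs_2013.yaml")))
    salaries = (load_salary_table(config.salaries_yaml) if config.salaries_yaml
                else load_salary_table(data_path("salaries_synthetic.yaml")))
    if config.course_yamls:
        specs = {arm: load_course_spec(p) for arm, p in config.course_yamls.items()}
    else:
        specs = {"lc": load_course_spec(data_path("course_lc.yaml")),
                 "standard": load_course_spec(data_path("course_standard.yaml"))}
    return catalogue, salaries, specs


def _load_records(config: RunConfig) -> pd.DataFrame:
    if config.patients_csv:
        return pd.read_csv(config.patients_csv)
    params = _load_params(config)
    trial = generate_trial(params, seed=config.seed)
    return apply_missingness(trial, mechanism="MAR", params=params, seed=config.seed + 1)


def _missingness_log(records: pd.DataFrame) -> dict:
    resp = response_indicator(records)
    return {"n_patients": int(len(records)),
            "n_complete_response": int(resp.sum()),
            "nonresponse_rate": float(1 - resp.mean()),
            "per_column_missing": {c: float(records[c].isna().mean()) for c in ("u0", "u2", "u5")}}


def simulate_stage(config: RunConfig) -> Path:
    """Generate a synthetic trial (with MAR nonresponse) and write it as CSV."""
    params = _load_params(config)
    trial = generate_trial(params, seed=config.seed)
    masked = apply_missingness(trial, mechanism="MAR", params=params, seed=config.seed + 1)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = config.out_dir / "patients.csv"
    masked.to_csv(out, index=False)
    write_provenance(config.out_dir, config, "simulate", _missingness_log(masked))
    return out


def cost_stage(config: RunConfig) -> Path:
    """Per-patient cost profiles plus a per-category summary shaped like a cost table."""
    records = _load_records(config)
    catalogue, salaries, specs = _load_costing(config)
    courses = {arm: course_cost(spec, catalogue) for arm, spec in specs.items()}
    comp = cost_components(records, catalogue, salaries, courses)
    comp = comp.assign(arm=records["arm"].values,
                       total_societal=total_costs(comp, "societal"),
                       total_healthcare=total_costs(comp, "healthcare"))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = config.out_dir / "patient_costs.csv"
    comp.to_csv(out, index=False)

    rng = np.random.default_rng(config.seed)
    summary = {"course_breakdown": {arm: c.to_dict() for arm, c in courses.items()},
               "category_means": {}}
    for arm, group in comp.groupby("arm"):
        means = {}
        for col in comp.columns.drop("arm"):
            x = group[col].to_numpy(float)
            boot = np.array([x[rng.integers(0, x.size, x.size)].mean() for _ in range(500)])
            means[col] = {"mean": float(x.mean()), "bootstrap_se": float(boot.std(ddof=1))}
        summary["category_means"][arm] = means
    (config.out_dir / "cost_summary.json").write_text(json.dumps(summary, indent=2))
    write_provenance(config.out_dir, config, "cost")
    return out


def qaly_stage(config: RunConfig) -> Path:
    """Per-patient QALY column (errors if utilities are still missing)."""
    records = _load_records(config)
    records["qaly"] = panel_qaly(records)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = config.out_dir / "patient_qalys.csv"
    records.to_csv(out, index=False)
    write_provenance(config.out_dir, config, "qaly")
    return out


def impute_stage(config: RunConfig) -> Path:
    """Chained-equation imputation; m stacked completed datasets + sidecar."""
    from .missingness import mice_impute
    records = _load_records(config)
    imp = mice_impute(records, m=config.m, seed=config.seed)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = config.out_dir / "imputations.csv"
    imp.save(out)
    sidecar = {"m": imp.m, "seed": imp.seed, "predictors": list(imp.predictors)}
    (config.out_dir / "imputations.json").write_text(json.dumps(sidecar, indent=2))
    write_provenance(config.out_dir, config, "impute", _missingness_log(records))
    return out


def cea_stage(config: RunConfig, scenario: Scenario | None = None) -> ScenarioResult:
    """Main cost-utility analysis: bootstrap, summary, CEAC (CSV + plot).

    An explicit patient CSV must be complete or stacked output of the
    impute stage (an ``imputation`` index column): pipeline order matters.
    Without a CSV the run simulates, imputes and analyses in one go.
    """
    records = _load_records(config)
    imputed = None
    if config.patients_csv is not None:
        if "imputation" in records.columns:
            imputed = [g.drop(columns="imputation").reset_index(drop=True)
                       for _, g in records.groupby("imputation")]
            records = imputed[0]
        elif records[["u0", "u2", "u5"]].isna().any().any():
            raise ValueError("patient table has missing utilities: run the 'impute' "
                             "stage first, or 'report' for the full pipeline")
    catalogue, salaries, specs = _load_costing(config)
    scenario = scenario or Scenario(name="main", perspective=config.perspective)
    result = run_scenario(records, scenario, catalogue, salaries, specs,
                          B=config.B, m=config.m, seed=config.seed,
                          imputed_datasets=imputed)
    out = config.out_dir / scenario.name
    out.mkdir(parents=True, exist_ok=True)
    result.curve.to_frame().to_csv(out / "ceac.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary.to_dict(), indent=2))
    from .plotting import plot_ceac
    plot_ceac({scenario.name: result.curve}, out / "ceac.png")
    write_provenance(out, config, "cea", _missingness_log(records))
    return result


def report(config: RunConfig) -> dict:
    """End-to-end run: course-cost table, nonresponse analysis, utility/QALY
    summary, main CEAC and all shipped sensitivity scenarios."""
    records = _load_records(config)
    catalogue, salaries, specs = _load_costing(config)
    courses = {arm: course_cost(spec, catalogue) for arm, spec in specs.items()}

    scen_paths = list(config.scenario_yamls) or sorted(
        Path(data_path("scenarios")).glob("*.yaml"))
    from .scenarios import load_scenario
    scens = [MAIN_SCENARIO] + [load_scenario(p) for p in scen_paths]
    results = scenario_suite(records, scens, catalogue, salaries, specs,
                             B=config.B, m=config.m, seed=config.seed)

    nonresp = nonresponse_analysis(records, NONRESPONSE_VARIABLES)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "course_costs.json").write_text(
        json.dumps({arm: c.to_dict() for arm, c in courses.items()}, indent=2))
    if not nonresp.table.empty:
        nonresp.table.to_csv(out / "nonresponse_analysis.csv", index=False)
    curves = pd.concat([r.curve.to_frame().assign(scenario=name)
                        for name, r in results.items()])
    curves.to_csv(out / "ceac_all_scenarios.csv", index=False)
    summaries = {name: r.summary.to_dict() for name, r in results.items()}
    (out / "cea_summaries.json").write_text(json.dumps(summaries, indent=2))
    from .plotting import plot_ceac
    plot_ceac({name: r.curve for name, r in results.items()}, out / "ceac_scenarios.png")
    write_provenance(out, config, "report", _missingness_log(records))
    return {"courses": courses, "results": results, "nonresponse": nonresp}
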