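"""Declarative sensitivity scenarios, one CEAC each.

A scenario bundles the knobs the sensitivity analyses turn: the costing
perspective (societal vs healthcare), unit-cost overrides (lower staff
wages, no load factor, more patients per course), cost-category exclusions
(patient time; admissions discharged after follow-up), and the imputation
mode (chained equations, LOCF, complete case). ``run_scenario`` re-runs
costing → QALY → imputation → bootstrap under the modified configuration;
``scenario_suite`` produces one labelled curve per scenario on a shared
willingness-to-pay grid. The shipped fixtures under ``data/scenarios/``
cover the published sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalogue import (CatalogueError, CostCatalogue, CourseSpec, SalaryTable)
from .costing import KNOWN_EXCLUSIONS, PERSPECTIVES, course_cost, cost_components, total_costs
from .cea import (CEACCurve, CEASummary, IncrementalDraws, bootstrap_incrementals,
                  bootstrap_incrementals_mi, ceac, default_lambda_grid, summarize, DEFAULT_B)
from .missingness import (DEFAULT_M, complete_cases, locf_impute, mice_impute,
                          response_indicator)
from .qaly import panel_qaly

__all__ = ["Scenario", "ScenarioResult", "load_scenario", "run_scenario",
           "scenario_suite", "MAIN_SCENARIO"]

IMPUTATION_MODES = ("mice", "locf", "complete_case")
_COURSE_OVERRIDES = ("patients_per_course",)


@dataclass(frozen=True)
class Scenario:
    """One sensitivity configuration of the cost-utility analysis."""

    name: str
    perspective: str = "societal"
    overrides: Mapping[str, float] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()
    imputation: str = "mice"

    def __post_init__(self):
        if self.perspective not in PERSPECTIVES:
            raise CatalogueError("perspective", f"must be one of {PERSPECTIVES}")
        if self.imputation not in IMPUTATION_MODES:
            raise CatalogueError("imputation", f"must be one of {IMPUTATION_MODES}")
        for exc in self.exclusions:
            if exc not in KNOWN_EXCLUSIONS:
                raise CatalogueError("exclusions", f"unknown exclusion {exc!r}")

    def apply(self, catalogue: CostCatalogue,
              specs: Mapping[str, CourseSpec]) -> tuple[CostCatalogue, dict[str, CourseSpec]]:
        """Validated catalogue/spec copies with the overrides applied.

        Unknown override keys raise before any computation.
        """
        cat_over = {k: v for k, v in self.overrides.items() if k not in _COURSE_OVERRIDES}
        new_cat = catalogue.replace(**cat_over)
        spec_over = {k: v for k, v in self.overrides.items() if k in _COURSE_OVERRIDES}
        new_specs = {arm: spec.replace(**spec_over) if spec_over else spec
                     for arm, spec in specs.items()}
        return new_cat, new_specs

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["overrides"] = dict(self.overrides)
        doc["exclusions"] = list(self.exclusions)
        return doc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


MAIN_SCENARIO = Scenario(name="main")


def load_scenario(path: str | Path) -> Scenario:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "name" not in doc:
        raise CatalogueError(str(path), "scenario file must be a mapping with a 'name'")
    return Scenario(
        name=str(doc["name"]),
        perspective=doc.get("perspective", "societal"),
        overrides=dict(doc.get("overrides") or {}),
        exclusions=tuple(doc.get("exclusions") or ()),
        imputation=doc.get("imputation", "mice"),
    )


@dataclass
class ScenarioResult:
    """Labelled CEAC plus incremental summary for one scenario."""

    scenario: Scenario
    curve: CEACCurve
    summary: CEASummary
    draws: IncrementalDraws
    courses: dict
    n_dropped: int = 0   # patients excluded (LOCF missing baseline / complete case)

    @property
    def name(self) -> str:
        return self.scenario.name


def run_scenario(records: pd.DataFrame, scenario: Scenario, catalogue: CostCatalogue,
                 salaries: SalaryTable, specs: Mapping[str, CourseSpec],
                 B: int = DEFAULT_B, m: int = DEFAULT_M, seed: int = 0,
                 lambda_grid: Sequence[float] | None = None,
                 imputed_datasets: Sequence[pd.DataFrame] | None = None) -> ScenarioResult:
    """Full cost-utility analysis of one scenario on a patient-level table.

    Costs are complete by construction (registry-style categories), so only
    the utility columns pass through imputation. With chained equations the
    bootstrap runs within each completed dataset and pools draws; LOCF and
    complete-case run a single bootstrap on their completed/restricted table.
    """
    new_cat, new_specs = scenario.apply(catalogue, specs)
    courses = {arm: course_cost(spec, new_cat) for arm, spec in new_specs.items()}
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    root = np.random.default_rng(seed)
    s_imp, s_boot = [int(x) for x in root.integers(0, 2**31 - 1, 2)]

    def arm_arrays(table: pd.DataFrame) -> tuple:
        comp = cost_components(table, new_cat, salaries, courses)
        costs = total_costs(comp, scenario.perspective, scenario.exclusions).to_numpy()
        q = panel_qaly(table).to_numpy()
        is_lc = (table["arm"] == "lc").to_numpy()
        if is_lc.all() or (~is_lc).all():
            raise ValueError("both arms must be non-empty")
        return costs[is_lc], q[is_lc], costs[~is_lc], q[~is_lc]

    n_dropped = 0
    has_missing = records[["u0", "u2", "u5"]].isna().any().any()
    if scenario.imputation == "mice" and imputed_datasets is not None:
        draws = bootstrap_incrementals_mi([arm_arrays(d) for d in imputed_datasets],
                                          B=B, seed=s_boot)
    elif scenario.imputation == "mice" and has_missing:
        imputations = mice_impute(records, m=m, seed=s_imp)
        draws = bootstrap_incrementals_mi([arm_arrays(d) for d in imputations.datasets],
                                          B=B, seed=s_boot)
    elif scenario.imputation == "locf" and has_missing:
        completed, n_dropped = locf_impute(records)
        draws = bootstrap_incrementals(*arm_arrays(completed), B=B, seed=s_boot)
    elif scenario.imputation == "complete_case":
        subset = complete_cases(records)
        n_dropped = len(records) - len(subset)
        draws = bootstrap_incrementals(*arm_arrays(subset), B=B, seed=s_boot)
    else:  # complete data
        draws = bootstrap_incrementals(*arm_arrays(records), B=B, seed=s_boot)

    return ScenarioResult(
        scenario=scenario,
        curve=ceac(draws, grid, label=scenario.name),
        summary=summarize(draws),
        draws=draws,
        courses={arm: c.to_dict() for arm, c in courses.items()},
        n_dropped=n_dropped,
    )


def scenario_suite(records: pd.DataFrame, scenarios: Sequence[Scenario],
                   catalogue: CostCatalogue, salaries: SalaryTable,
                   specs: Mapping[str, CourseSpec], B: int = DEFAULT_B,
                   m: int = DEFAULT_M, seed: int = 0,
                   lambda_grid: Sequence[float] | None = None) -> dict[str, ScenarioResult]:
    """Run several scenarios on a shared willingness-to-pay grid."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate scenario names: {dupes}")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    return {s.name: run_scenario(records, s, catalogue, salaries, specs,
                                 B=B, m=m, seed=seed, lambda_grid=grid)
            for s in scenarios}
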