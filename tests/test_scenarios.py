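"""Sensitivity scenarios: overrides, exclusions, imputation modes."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rehabcea.catalogue import CatalogueError, data_path
from rehabcea.costing import course_cost
from rehabcea.scenarios import (MAIN_SCENARIO, Scenario, load_scenario, run_scenario,
                                scenario_suite)

B, M = 400, 3  # small bootstrap sizes: these tests check wiring, not precision


@pytest.fixture(scope="module")
def shipped_scenarios():
    return [load_scenario(p) for p in sorted(Path(data_path("scenarios")).glob("*.yaml"))]


class TestScenarioValidation:
    def test_unknown_override_rejected_before_computation(self, catalogue, course_specs):
        s = Scenario(name="bad", overrides={"surgeon_hourly": 999})
        with pytest.raises(CatalogueError, match="surgeon_hourly"):
            s.apply(catalogue, course_specs)

    def test_bad_perspective_and_imputation_rejected(self):
        with pytest.raises(CatalogueError, match="perspective"):
            Scenario(name="x", perspective="payer")
        with pytest.raises(CatalogueError, match="imputation"):
            Scenario(name="x", imputation="hot-deck")
        with pytest.raises(CatalogueError, match="exclusions"):
            Scenario(name="x", exclusions=("weekends",))

    def test_round_trip(self, tmp_path):
        s = Scenario(name="t", perspective="healthcare",
                     overrides={"nurse_hourly": 150}, exclusions=("patient_time",),
                     imputation="locf")
        path = tmp_path / "s.yaml"
        s.save(path)
        assert load_scenario(path) == s


class TestOverrides:
    def test_lower_salaries_reduce_intervention_cost(self, catalogue, course_specs):
        s = Scenario(name="lower", overrides={"nurse_hourly": 150,
                                              "physiotherapist_hourly": 120})
        new_cat, new_specs = s.apply(catalogue, course_specs)
        c = course_cost(new_specs["lc"], new_cat)
        # re-derived by hand from the worked example with the new wages:
        # 93*150 + 87*120 + 7488 = 31,878; +21% overhead = 38,572; /10 patients
        assert c.total_per_course == 38_572
        assert c.cost_per_patient == 3_857 < 4_807

    def test_no_load_factor_gives_formal_hours(self, catalogue, course_specs):
        s = Scenario(name="noload", overrides={"load_factor": 1.0})
        new_cat, new_specs = s.apply(catalogue, course_specs)
        c = course_cost(new_specs["lc"], new_cat)
        assert c.nurse_loaded_h == c.nurse_formal_h == 62

    def test_twelve_patients_changes_only_divisor(self, catalogue, course_specs):
        s = Scenario(name="p12", overrides={"patients_per_course": 12})
        new_cat, new_specs = s.apply(catalogue, course_specs)
        c12 = course_cost(new_specs["lc"], new_cat)
        c10 = course_cost(course_specs["lc"], catalogue)
        assert c12.total_per_course == c10.total_per_course
        assert c12.cost_per_patient == round(48_072 / 12) == 4_006


class TestRunScenario:
    def test_identity_scenario_matches_main(self, small_masked_trial, catalogue,
                                            salaries, course_specs):
        a = run_scenario(small_masked_trial, MAIN_SCENARIO, catalogue, salaries,
                         course_specs, B=B, m=M, seed=3)
        b = run_scenario(small_masked_trial, Scenario(name="noop"), catalogue, salaries,
                         course_specs, B=B, m=M, seed=3)
        assert np.array_equal(a.curve.probabilities, b.curve.probabilities)
        assert a.summary.delta_cost == b.summary.delta_cost

    def test_healthcare_never_exceeds_societal_cost(self, small_masked_trial, catalogue,
                                                    salaries, course_specs,
                                                    shipped_scenarios):
        from rehabcea.costing import cost_components, total_costs
        for s in shipped_scenarios:
            new_cat, new_specs = s.apply(catalogue, course_specs)
            courses = {arm: course_cost(spec, new_cat) for arm, spec in new_specs.items()}
            comp = cost_components(small_masked_trial, new_cat, salaries, courses)
            soc = total_costs(comp, "societal", s.exclusions)
            hc = total_costs(comp, "healthcare", s.exclusions)
            assert (soc >= hc).all(), s.name

    def test_excluding_a_costlier_category_helps_at_zero_wtp(self, catalogue, salaries,
                                                             course_specs):
        """If the intervention arm's informal-time cost exceeds the control
        arm's for every patient, dropping that category cannot lower the
        probability of cost-effectiveness at zero willingness to pay."""
        n = 40
        rng = np.random.default_rng(23)
        df = pd.DataFrame({
            "arm": ["lc"] * n + ["standard"] * n,
            "age": 55, "gender": "male", "diagnosis": "ihd",
            "training_attended": [24] * n + [2] * n,   # LC informal time strictly higher
            "education_attended": [9] * n + [0] * n,
            "interviews_attended": [2] * n + [0] * n,
            "cost_general_practice": rng.gamma(2, 600, 2 * n),
            "cost_specialist": 0.0, "cost_physiotherapist": 0.0, "cost_dentist": 0.0,
            "cost_primary_other": 0.0,
            "cost_medicine": rng.gamma(2, 1000, 2 * n),
            "cost_outpatient": rng.gamma(4, 10_000, 2 * n),
            "cost_admissions": 0.0, "cost_admissions_post_followup": 0.0,
            "weeks_reschooling": 0.0, "weeks_disability": 0.0, "weeks_sick": 0.0,
            "u0": 0.7, "u2": 0.75, "u5": 0.75,
        })
        base = run_scenario(df, Scenario(name="base"), catalogue, salaries, course_specs,
                            B=B, m=M, seed=5)
        excl = run_scenario(df, Scenario(name="excl", exclusions=("patient_time",)),
                            catalogue, salaries, course_specs, B=B, m=M, seed=5)
        assert excl.curve.probabilities[0] >= base.curve.probabilities[0]

    def test_imputation_modes_run_and_report_drops(self, small_masked_trial, catalogue,
                                                   salaries, course_specs):
        locf = run_scenario(small_masked_trial, Scenario(name="l", imputation="locf"),
                            catalogue, salaries, course_specs, B=B, m=M, seed=6)
        assert locf.n_dropped == int(small_masked_trial.u0.isna().sum())
        cc = run_scenario(small_masked_trial, Scenario(name="c", imputation="complete_case"),
                          catalogue, salaries, course_specs, B=B, m=M, seed=6)
        complete = small_masked_trial[["u0", "u2", "u5"]].notna().all(axis=1)
        assert cc.n_dropped == int((~complete).sum())


class TestSuite:
    def test_duplicate_names_rejected(self, small_masked_trial, catalogue, salaries,
                                      course_specs):
        twice = [Scenario(name="same"), Scenario(name="same", perspective="healthcare")]
        with pytest.raises(ValueError, match="duplicate"):
            scenario_suite(small_masked_trial, twice, catalogue, salaries, course_specs,
                           B=B, m=M, seed=1)

    def test_empty_suite_rejected(self, small_masked_trial, catalogue, salaries,
                                  course_specs):
        with pytest.raises(ValueError, match="at least one"):
            scenario_suite(small_masked_trial, [], catalogue, salaries, course_specs)

    def test_shipped_scenarios_end_to_end(self, small_masked_trial, catalogue, salaries,
                                          course_specs, shipped_scenarios):
        """The published sensitivity analyses all run on synthetic data and
        share one willingness-to-pay grid."""
        results = scenario_suite(small_masked_trial, shipped_scenarios, catalogue,
                                 salaries, course_specs, B=B, m=M, seed=2)
        assert len(results) == len(shipped_scenarios) >= 5
        names = {s.name for s in shipped_scenarios}
        assert {"healthcare_perspective", "lower_salaries", "no_load_factor",
                "twelve_patients_per_course", "exclude_patient_time"} <= names
        grids = [r.curve.lambdas for r in results.values()]
        for g in grids[1:]:
            assert np.array_equal(g, grids[0])
        for r in results.values():
            assert ((r.curve.probabilities >= 0) & (r.curve.probabilities <= 1)).all()
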