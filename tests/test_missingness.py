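"""Imputation of missing utilities and the nonresponse analysis."""

import numpy as np
import pandas as pd
import pytest

from rehabcea.missingness import (impute_attendance_mean, locf_impute, mice_impute,
                                  nonresponse_analysis, response_indicator)
from rehabcea.qaly import panel_qaly
from rehabcea.synth import apply_missingness, generate_trial
from tests.conftest import scaled_params


class TestLocf:
    @pytest.mark.parametrize("row, expected", [
        ((0.7, np.nan, np.nan), (0.7, 0.7, 0.7)),
        ((0.7, 0.8, np.nan), (0.7, 0.8, 0.8)),
        ((0.7, 0.8, 0.9), (0.7, 0.8, 0.9)),
        ((0.7, np.nan, 0.9), (0.7, 0.7, 0.9)),
    ])
    def test_carry_forward(self, row, expected):
        df = pd.DataFrame([dict(zip(("u0", "u2", "u5"), row))])
        out, n_excluded = locf_impute(df)
        assert n_excluded == 0
        assert tuple(out.iloc[0]) == pytest.approx(expected)

    def test_missing_baseline_excluded_with_count(self):
        df = pd.DataFrame({"u0": [np.nan, 0.6], "u2": [0.7, np.nan], "u5": [0.8, 0.9]})
        out, n_excluded = locf_impute(df)
        assert n_excluded == 1 and len(out) == 1
        assert tuple(out.iloc[0]) == (0.6, 0.6, 0.9)

    def test_idempotent(self, small_masked_trial):
        once, n1 = locf_impute(small_masked_trial)
        twice, n2 = locf_impute(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once, twice)


class TestAttendanceMean:
    def test_two_point_mean(self):
        df = pd.DataFrame({"arm": ["a"] * 3, "training_attended": [18.0, 20.0, np.nan],
                           "education_attended": [5.0, 5.0, 5.0]})
        out = impute_attendance_mean(df)
        assert out.training_attended.iloc[2] == 19

    def test_mean_preserved_and_observed_untouched(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"arm": np.repeat(["a", "b"], 50),
                           "training_attended": rng.integers(1, 24, 100).astype(float),
                           "education_attended": rng.integers(0, 9, 100).astype(float)})
        df.loc[df.sample(20, random_state=1).index, "training_attended"] = np.nan
        out = impute_attendance_mean(df)
        assert not out.training_attended.isna().any()
        for arm in "ab":
            obs = df[df.arm == arm].training_attended.dropna()
            assert out[out.arm == arm].training_attended.mean() == pytest.approx(obs.mean())
        untouched = df.training_attended.notna()
        assert (out.training_attended[untouched] == df.training_attended[untouched]).all()

    def test_empty_arm_errors(self):
        df = pd.DataFrame({"arm": ["a", "a"], "training_attended": [np.nan, np.nan],
                           "education_attended": [1.0, 2.0]})
        with pytest.raises(ValueError, match="zero observed"):
            impute_attendance_mean(df)


class TestMice:
    def test_no_missing_gives_identical_copies(self, small_trial):
        imp = mice_impute(small_trial, m=3, seed=0)
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, small_trial)

    def test_deterministic_under_seed(self, small_masked_trial):
        a = mice_impute(small_masked_trial, m=3, seed=11)
        b = mice_impute(small_masked_trial, m=3, seed=11)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        c = mice_impute(small_masked_trial, m=3, seed=12)
        assert not all(da.equals(dc) for da, dc in zip(a.datasets, c.datasets))

    def test_observed_cells_never_altered(self, small_masked_trial):
        imp = mice_impute(small_masked_trial, m=4, seed=5)
        for col in ("u0", "u2", "u5"):
            obs = small_masked_trial[col].notna()
            for d in imp.datasets:
                assert np.array_equal(d.loc[obs, col], small_masked_trial.loc[obs, col])
                assert not d[col].isna().any()

    def test_imputed_values_within_observed_range(self, small_masked_trial):
        imp = mice_impute(small_masked_trial, m=4, seed=5)
        for col in ("u0", "u2", "u5"):
            lo, hi = small_masked_trial[col].min(), small_masked_trial[col].max()
            for d in imp.datasets:
                assert d[col].between(lo, hi).all()

    def test_m_below_two_rejected(self, small_masked_trial):
        with pytest.raises(ValueError, match="m >= 2"):
            mice_impute(small_masked_trial, m=1)

    def test_all_missing_column_rejected(self, small_trial):
        broken = small_trial.copy()
        broken["u5"] = np.nan
        with pytest.raises(ValueError, match="zero observed"):
            mice_impute(broken, m=2)

    def test_mcar_mean_recovery(self, default_params):
        """30 % MCAR deletion: the pooled imputed mean lands within 2
        Monte-Carlo SEs of the full-data mean."""
        trial = generate_trial(scaled_params(default_params, 400), seed=21)
        masked = apply_missingness(trial, mechanism="MCAR", rate=0.30,
                                   params=default_params, seed=22)
        imp = mice_impute(masked, m=10, seed=23)
        for col in ("u0", "u2", "u5"):
            full = trial[col].mean()
            mc_se = trial[col].std(ddof=1) / np.sqrt(len(trial))
            assert abs(imp.pooled_mean(col) - full) < 2 * mc_se

    def test_agrees_with_statsmodels_chained_equations(self, default_params):
        """Independent cross-check: statsmodels' MICE on the same masked panel
        pools to the same utility means (within Monte-Carlo slack)."""
        statsmodels = pytest.importorskip("statsmodels.imputation.mice")
        trial = generate_trial(scaled_params(default_params, 300), seed=31)
        masked = apply_missingness(trial, mechanism="MAR", params=default_params, seed=32)
        ours = mice_impute(masked, m=10, seed=33)

        cols = ["u0", "u2", "u5", "age", "cost_outpatient", "cost_admissions"]
        data = masked[cols].copy()
        np.random.seed(34)  # statsmodels draws from the global RNG
        md = statsmodels.MICEData(data)
        pooled = {c: [] for c in ("u0", "u2", "u5")}
        for _ in range(10):
            md.update_all(2)
            for c in pooled:
                pooled[c].append(md.data[c].mean())
        for c in ("u0", "u2", "u5"):
            se = masked[c].std(ddof=1) / np.sqrt(masked[c].notna().sum())
            assert abs(ours.pooled_mean(c) - np.mean(pooled[c])) < 3 * se


class TestNonresponse:
    def test_mcar_null_rarely_flags(self, default_params):
        trial = generate_trial(scaled_params(default_params, 400), seed=41)
        masked = apply_missingness(trial, mechanism="MCAR", rate=0.4,
                                   params=default_params, seed=42)
        table = nonresponse_analysis(masked, ["age", "gender", "cost_medicine",
                                              "cost_general_practice", "weeks_sick"])
        assert table.status == "ok"
        assert len(table.significant_variables) <= 2  # nominal type-I rate

    def test_cost_driven_nonresponse_detected(self):
        """Nonresponse shifted by 1 SD of secondary-care cost at n=800 is
        flagged essentially always."""
        rng = np.random.default_rng(43)
        for rep in range(5):
            n = 800
            cost = rng.normal(40_000, 16_000, n)
            p = 0.25 + 0.35 * (cost > np.quantile(cost, 0.6))  # mean shift ~1 SD
            df = pd.DataFrame({"cost_outpatient": cost,
                               "u0": 0.7, "u2": 0.7, "u5": 0.7})
            miss = rng.random(n) < p
            df.loc[miss, "u5"] = np.nan
            table = nonresponse_analysis(df, ["cost_outpatient"])
            assert "cost_outpatient" in table.significant_variables

    def test_zero_nonresponders_flagged(self, small_trial):
        table = nonresponse_analysis(small_trial, ["age"])
        assert table.status == "no_nonresponders"
        assert table.table.empty

    def test_response_indicator(self, small_masked_trial):
        resp = response_indicator(small_masked_trial)
        complete = small_masked_trial[["u0", "u2", "u5"]].notna().all(axis=1)
        assert (resp == complete).all()


def test_mi_pipeline_preserves_qaly_scale(small_masked_trial):
    """Pooled QALYs from imputed panels stay on the plausible scale
    (bounded by support x horizon)."""
    imp = mice_impute(small_masked_trial, m=3, seed=9)
    for d in imp.datasets:
        q = panel_qaly(d)
        assert q.between(0.30 * 5 / 12, 5 / 12).all()
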