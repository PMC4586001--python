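"""Synthetic two-arm rehabilitation trials.

Generates patient-level records with the statistical structure the
cost-utility pipeline assumes, so every stage is testable without access
to the administrative registries the real study drew on. The generator
emulates:

* covariates — age discretised around a mean of 63 (range bounded),
  76 % male, 79 %/21 % ischemic-heart-disease / heart-failure split;
* attendance — bounded counts of training and education sessions per arm,
  plus two clarifying interviews in the intervention arm;
* utilities — correlated measurements at months 0/2/5 (Gaussian copula
  over beta marginals on the preference-weighted support), so values never
  leave [0.30, 1];
* costs — right-skewed per-category amounts (gamma, matched to target
  mean and SD) for the registry-priced categories, and weeks of work
  inability for patients below pension age;
* nonresponse — a patient-level propensity to leave utility measurements
  missing, either completely at random (MCAR) or depending on observed
  secondary-care cost and attendance (MAR), calibrated to a marginal rate.

Defaults (``TrialParams.default()``) are calibrated to the published trial's
arm means and SEs; see ``data/trial_defaults.yaml``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .catalogue import data_path

__all__ = ["ArmParams", "TrialParams", "generate_trial", "apply_missingness",
           "end_to_end_recovery", "COST_CATEGORIES", "WEEK_TYPES"]

COST_CATEGORIES = ("general_practice", "specialist", "physiotherapist", "dentist",
                   "primary_other", "medicine", "outpatient", "admissions")
WEEK_TYPES = ("reschooling", "disability", "sick")
_UTILITY_TIMES = 3


@dataclass
class ArmParams:
    """Marginal targets for one randomisation arm."""

    label: str
    n: int
    utility_means: tuple[float, float, float]
    utility_sds: tuple[float, float, float]
    interviews: int
    training_mean: float
    training_range: tuple[float, float]
    education_mean: float
    education_range: tuple[float, float]
    cost_means: dict[str, float]
    cost_sds: dict[str, float]
    week_means: dict[str, float]
    week_sds: dict[str, float]
    attendance_kappa: float = 1.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")
        for u in self.utility_means:
            if not 0 <= u <= 1:
                raise ValueError(f"{self.label}: utility mean {u} outside [0, 1]")
        for s in self.utility_sds:
            if s < 0:
                raise ValueError(f"{self.label}: negative utility SD")
        for cat in COST_CATEGORIES:
            if cat not in self.cost_means or cat not in self.cost_sds:
                raise ValueError(f"{self.label}: missing cost category {cat!r}")


@dataclass
class TrialParams:
    """Full generator configuration for a two-arm trial."""

    lc: ArmParams
    standard: ArmParams
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_range: tuple[int, int] = (27, 92)
    male_frac: float = 0.76
    ihd_frac: float = 0.79
    utility_corr: float = 0.6
    utility_cost_corr: float = -0.3   # latent corr: health utility vs secondary-care cost
    utility_support: tuple[float, float] = (0.30, 1.0)
    post_followup_admission_frac: float = 0.10
    nonresponse_rate: float = 0.43
    mar_beta_cost: float = 0.7
    mar_beta_attendance: float = -0.7
    pension_age: float = 67.0

    def __post_init__(self):
        if not -1 < self.utility_corr < 1:
            raise ValueError(f"utility correlation must be in (-1, 1), got {self.utility_corr}")
        if not -1 < self.utility_cost_corr < 1:
            raise ValueError(f"utility-cost correlation must be in (-1, 1)")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValueError(f"nonresponse rate must be in [0, 1), got {self.nonresponse_rate}")
        for frac in (self.male_frac, self.ihd_frac, self.post_followup_admission_frac):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")

    @property
    def arms(self) -> tuple[ArmParams, ArmParams]:
        return (self.lc, self.standard)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        doc = asdict(self)
        return doc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TrialParams":
        doc = dict(doc)
        arms = {}
        for key in ("lc", "standard"):
            raw = dict(doc.pop(key))
            for tup in ("utility_means", "utility_sds", "training_range", "education_range"):
                raw[tup] = tuple(raw[tup])
            arms[key] = ArmParams(**raw)
        for tup in ("age_range", "utility_support"):
            if tup in doc:
                doc[tup] = tuple(doc[tup])
        return cls(lc=arms["lc"], standard=arms["standard"], **doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "TrialParams":
        """The study-calibrated defaults shipped with the package."""
        return cls.from_yaml(data_path("trial_defaults.yaml"))


# ---------------------------------------------------------------------------
# sampling primitives


def _gamma(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed non-negative draws with the requested mean and SD."""
    if mean < 0 or sd < 0:
        raise ValueError("gamma targets must be non-negative")
    if mean == 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, scale=sd**2 / mean, size=size)


def _beta_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    m = (mean - lo) / (hi - lo)
    if not 0 < m < 1:
        raise ValueError(f"mean {mean} outside the open support ({lo}, {hi})")
    v = (sd / (hi - lo)) ** 2
    if v >= m * (1 - m):
        raise ValueError(f"infeasible moments: SD {sd} too large for mean {mean} on [{lo}, {hi}]")
    kappa = m * (1 - m) / v - 1
    return m * kappa, (1 - m) * kappa


def _bounded_counts(mean: float, bounds: tuple[float, float], kappa: float, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Integer counts on [lo, hi] from a scaled beta with dispersion kappa."""
    lo, hi = bounds
    if kappa == 0:  # degenerate: everyone at the (rounded) mean
        return np.full(size, round(mean))
    m = (mean - lo) / (hi - lo)
    if not 0 < m < 1:
        raise ValueError(f"attendance mean {mean} outside the open range ({lo}, {hi})")
    x = lo + (hi - lo) * rng.beta(m * kappa, (1 - m) * kappa, size=size)
    return np.clip(np.rint(x), lo, hi).astype(int)


def _ages(params: TrialParams, size: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.age_range
    if params.age_sd == 0:
        return np.full(size, round(params.age_mean))
    grid = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((grid - params.age_mean) / params.age_sd) ** 2)
    return rng.choice(grid, size=size, p=w / w.sum())


def _under_pension_prob(params: TrialParams) -> float:
    """P(age < pension age) under the discretised age distribution."""
    lo, hi = params.age_range
    if params.age_sd == 0:
        return float(round(params.age_mean) < params.pension_age)
    grid = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((grid - params.age_mean) / params.age_sd) ** 2)
    return float(w[grid < params.pension_age].sum() / w.sum())


def _correlated_utilities(arm: ArmParams, params: TrialParams, size: int,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian copula over beta marginals on the utility support.

    Returns the utilities and the standardised latent health factor (mean
    of the latent normals), used to correlate secondary-care costs with
    health status.
    """
    rho = params.utility_corr
    cov = np.full((_UTILITY_TIMES, _UTILITY_TIMES), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(_UTILITY_TIMES), cov, size=size, method="cholesky")
    latent = z.mean(axis=1) / np.sqrt((1 + (_UTILITY_TIMES - 1) * rho) / _UTILITY_TIMES)
    lo, hi = params.utility_support
    out = np.empty((size, _UTILITY_TIMES))
    for j in range(_UTILITY_TIMES):
        mean, sd = arm.utility_means[j], arm.utility_sds[j]
        if sd == 0:
            out[:, j] = mean
            continue
        a, b = _beta_params(mean, sd, lo, hi)
        out[:, j] = lo + (hi - lo) * stats.beta.ppf(stats.norm.cdf(z[:, j]), a, b)
    return out, latent


def _gamma_from_latent(mean: float, sd: float, latent: np.ndarray, corr: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Gamma draws copula-coupled to a standard-normal latent factor."""
    if mean == 0:
        return np.zeros(latent.size)
    if sd == 0:
        return np.full(latent.size, mean)
    z = corr * latent + np.sqrt(1 - corr**2) * rng.standard_normal(latent.size)
    shape = (mean / sd) ** 2
    return stats.gamma.ppf(stats.norm.cdf(z), shape, scale=sd**2 / mean)


# ---------------------------------------------------------------------------
# public operations


def generate_trial(params: TrialParams, seed: int = 0) -> pd.DataFrame:
    """Draw a complete two-arm trial table (no missingness applied).

    Deterministic given ``seed``. Utilities lie on the preference-weighted
    support, costs are non-negative, attendance respects its stated ranges.
    """
    rng = np.random.default_rng(seed)
    p_under = _under_pension_prob(params)
    frames = []
    for arm in params.arms:
        n = arm.n
        age = _ages(params, n, rng)
        gender = np.where(rng.random(n) < params.male_frac, "male", "female")
        diagnosis = np.where(rng.random(n) < params.ihd_frac, "ihd", "hf")
        training = _bounded_counts(arm.training_mean, arm.training_range,
                                   arm.attendance_kappa, n, rng)
        education = _bounded_counts(arm.education_mean, arm.education_range,
                                    arm.attendance_kappa, n, rng)
        u, latent = _correlated_utilities(arm, params, n, rng)

        rec = {
            "arm": arm.label, "age": age, "gender": gender, "diagnosis": diagnosis,
            "training_attended": training, "education_attended": education,
            "interviews_attended": np.full(n, arm.interviews),
        }
        # secondary care tracks health status: worse latent health (lower
        # utilities) draws higher outpatient/admission costs
        for cat in COST_CATEGORIES:
            if cat in ("outpatient", "admissions"):
                rec[f"cost_{cat}"] = _gamma_from_latent(
                    arm.cost_means[cat], arm.cost_sds[cat], latent,
                    params.utility_cost_corr, rng)
            else:
                rec[f"cost_{cat}"] = _gamma(arm.cost_means[cat], arm.cost_sds[cat], n, rng)
        post = (rng.random(n) < params.post_followup_admission_frac).astype(float)
        rec["cost_admissions_post_followup"] = rec["cost_admissions"] * post

        # weeks of work inability exist only below pension age; the
        # conditional mean is rescaled so the marginal mean stays on target
        under = age < params.pension_age
        for wt in WEEK_TYPES:
            weeks = np.zeros(n)
            if p_under > 0 and arm.week_means[wt] > 0:
                cond_mean = arm.week_means[wt] / p_under
                weeks[under] = _gamma(cond_mean, arm.week_sds[wt], int(under.sum()), rng)
            rec[f"weeks_{wt}"] = weeks
        rec["u0"], rec["u2"], rec["u5"] = u[:, 0], u[:, 1], u[:, 2]
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", np.arange(len(out)))
    return out


def _calibrated_propensity(x: np.ndarray, rate: float) -> np.ndarray:
    """Logistic propensities sigmoid(b0 + x) with mean calibrated to ``rate``."""
    if rate == 0:
        return np.zeros_like(x)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1 / (1 + np.exp(-(mid + x)))) < rate:
            lo = mid
        else:
            hi = mid
    return 1 / (1 + np.exp(-(0.5 * (lo + hi) + x)))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def apply_missingness(records: pd.DataFrame, mechanism: str = "MAR",
                      rate: float | None = None, params: TrialParams | None = None,
                      seed: int = 0,
                      columns: Sequence[str] = ("u0", "u2", "u5")) -> pd.DataFrame:
    """Delete utility cells under an MCAR or MAR nonresponse mechanism.

    A patient-level propensity p_i of being a non-responder (any missing
    utility) is constant under MCAR, and under MAR increases with
    secondary-care cost and decreases with attendance through a logistic
    model whose intercept is calibrated to the marginal rate. Each utility
    cell is then deleted independently with q_i = 1 - (1 - p_i)^(1/3), so
    that P(any cell missing) = p_i exactly and the pattern is non-monotone.
    """
    params = params or TrialParams.default()
    rate = params.nonresponse_rate if rate is None else rate
    if not 0 <= rate < 1:
        raise ValueError(f"nonresponse rate must be in [0, 1), got {rate}")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"mechanism must be 'MCAR' or 'MAR', got {mechanism!r}")
    rng = np.random.default_rng(seed)
    n = len(records)
    if mechanism == "MCAR" or rate == 0:
        p = np.full(n, rate)
    else:
        secondary = (records["cost_outpatient"] + records["cost_admissions"]).to_numpy(float)
        attendance = (records["training_attended"] + records["education_attended"]).to_numpy(float)
        x = params.mar_beta_cost * _zscore(secondary) + params.mar_beta_attendance * _zscore(attendance)
        p = _calibrated_propensity(x, rate)
    q = 1 - (1 - p) ** (1 / len(columns))
    out = records.copy()
    for col in columns:
        out.loc[rng.random(n) < q, col] = np.nan
    return out


def end_to_end_recovery(params: TrialParams | None = None, B: int = 2_000, m: int = 5,
                        seed: int = 0, mechanism: str = "MAR",
                        n_truth_per_arm: int = 40_000, perspective: str = "societal") -> dict:
    """Generate → mask → impute → cost → CEA, and report recovery vs truth.

    Truth for ΔQALY is analytic (the QALY is linear in the utilities, so the
    expected QALY is the AUC of the arm's mean trajectory); truth for ΔCost
    is estimated from one large complete-data run of the same generator
    (``n_truth_per_arm`` per arm). The report carries point estimates,
    bootstrap SEs and z-scores of (estimate − truth) / SE.
    """
    from .pipeline import load_default_costing, compute_costs
    from .missingness import mice_impute
    from .cea import bootstrap_incrementals_mi, summarize, ceac
    from .qaly import qaly_auc, panel_qaly, DEFAULT_TIMES

    params = params or TrialParams.default()
    root = np.random.default_rng(seed)
    s_truth, s_trial, s_miss, s_mice, s_boot = [int(x) for x in root.integers(0, 2**31 - 1, 5)]
    catalogue, salaries, courses = load_default_costing()

    # --- truth ------------------------------------------------------------
    true_dq = (qaly_auc(params.lc.utility_means, DEFAULT_TIMES)
               - qaly_auc(params.standard.utility_means, DEFAULT_TIMES))
    big = dataclasses.replace(
        params,
        lc=dataclasses.replace(params.lc, n=n_truth_per_arm),
        standard=dataclasses.replace(params.standard, n=n_truth_per_arm),
    )
    big_trial = generate_trial(big, seed=s_truth)
    big_costs = compute_costs(big_trial, catalogue, salaries, courses, perspective)
    is_lc = big_trial["arm"] == "lc"
    true_dc = float(big_costs[is_lc].mean() - big_costs[~is_lc].mean())

    # --- study-scale run --------------------------------------------------
    trial = generate_trial(params, seed=s_trial)
    masked = apply_missingness(trial, mechanism=mechanism, params=params, seed=s_miss)
    imputations = mice_impute(masked, m=m, seed=s_mice)
    costs = compute_costs(trial, catalogue, salaries, courses, perspective)
    lc_mask = (trial["arm"] == "lc").to_numpy()
    per_imp = []
    for completed in imputations.datasets:
        q = panel_qaly(completed).to_numpy()
        per_imp.append((costs.to_numpy()[lc_mask], q[lc_mask],
                        costs.to_numpy()[~lc_mask], q[~lc_mask]))
    draws = bootstrap_incrementals_mi(per_imp, B=B, seed=s_boot)
    summary = summarize(draws)
    curve = ceac(draws)

    return {
        "true_delta_cost": true_dc,
        "true_delta_qaly": true_dq,
        "est_delta_cost": summary.delta_cost,
        "est_delta_qaly": summary.delta_qaly,
        "se_delta_cost": summary.se_delta_cost,
        "se_delta_qaly": summary.se_delta_qaly,
        "z_delta_cost": (summary.delta_cost - true_dc) / summary.se_delta_cost,
        "z_delta_qaly": (summary.delta_qaly - true_dq) / summary.se_delta_qaly,
        "ceac_at_0": curve.probabilities[0],
        "ceac_at_max": curve.probabilities[-1],
        "n_per_arm": {"lc": params.lc.n, "standard": params.standard.n},
        "B": draws.B, "m": m, "seed": seed,
    }
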