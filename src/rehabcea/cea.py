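"""Incremental cost-effectiveness with bootstrapped uncertainty.

Costs and QALYs are skewed, so uncertainty around the incremental cost
(ΔC) and incremental QALY (ΔE) of the intervention arm versus control is
quantified by the non-parametric bootstrap: each replicate resamples
patients with replacement independently within each arm (the arms are
independent randomised groups), preserving arm sizes, and records the pair
of arm-mean differences. 10,000 replications are the convention.

Decision uncertainty is summarised by the net monetary benefit
NB(λ) = λ·ΔE − ΔC over a grid of willingness-to-pay thresholds λ
(DKK 0-500,000 per QALY) and by the cost-effectiveness acceptability curve
(CEAC): the fraction of bootstrap draws with NB(λ) > 0 at each λ.

With multiply-imputed data the bootstrap runs within each completed
dataset and the draws are pooled across imputations, so the CEAC carries
both sampling and imputation uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncrementalDraws",
    "CEACCurve",
    "CEASummary",
    "bootstrap_incrementals",
    "bootstrap_incrementals_mi",
    "net_benefit",
    "ceac",
    "default_lambda_grid",
    "summarize",
    "DEFAULT_B",
]

DEFAULT_B = 10_000
LAMBDA_MAX = 500_000
LAMBDA_STEP = 1_000


def default_lambda_grid() -> np.ndarray:
    """Willingness-to-pay grid: DKK 0 to 500,000 per QALY in steps of 1,000."""
    return np.arange(0, LAMBDA_MAX + LAMBDA_STEP, LAMBDA_STEP, dtype=float)


@dataclass
class IncrementalDraws:
    """Bootstrap sample of (ΔCost, ΔQALY) pairs plus point estimates.

    Point estimates are computed on the original (un-resampled) data; with
    multiple imputation they are means over the completed datasets.
    """

    delta_cost: np.ndarray     # B draws, DKK
    delta_qaly: np.ndarray     # B draws, years
    point_delta_cost: float
    point_delta_qaly: float
    arm_means: dict = field(default_factory=dict)   # {"cost": {arm: mean}, "qaly": {...}}
    n_per_arm: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def B(self) -> int:
        return self.delta_cost.size

    def __post_init__(self):
        self.delta_cost = np.asarray(self.delta_cost, dtype=float)
        self.delta_qaly = np.asarray(self.delta_qaly, dtype=float)
        if self.delta_cost.shape != self.delta_qaly.shape or self.delta_cost.ndim != 1:
            raise ValueError("delta_cost and delta_qaly must be 1-D arrays of equal length")
        if self.B < 1:
            raise ValueError("need at least one bootstrap replication")
        if not (np.isfinite(self.delta_cost).all() and np.isfinite(self.delta_qaly).all()):
            raise ValueError("bootstrap draws must be finite")


def _resample_means(values: np.ndarray, B: int, rng: np.random.Generator,
                    chunk: int = 2_000) -> np.ndarray:
    """B means of with-replacement resamples of ``values`` (chunked for memory)."""
    n = values.size
    out = np.empty(B)
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        idx = rng.integers(0, n, size=(stop - start, n))
        out[start:stop] = values[idx].mean(axis=1)
    return out


def bootstrap_incrementals(cost_a: Sequence[float], qaly_a: Sequence[float],
                           cost_b: Sequence[float], qaly_b: Sequence[float],
                           B: int = DEFAULT_B, seed: int = 0,
                           labels: tuple[str, str] = ("lc", "standard")) -> IncrementalDraws:
    """Bootstrap (ΔCost, ΔQALY) = arm-a means minus arm-b means.

    Within each replicate, patients are resampled with replacement
    independently within each arm (joint cost/QALY indices per patient, so
    their correlation is preserved), keeping the original arm sizes.
    """
    cost_a, qaly_a = np.asarray(cost_a, float), np.asarray(qaly_a, float)
    cost_b, qaly_b = np.asarray(cost_b, float), np.asarray(qaly_b, float)
    if cost_a.size == 0 or cost_b.size == 0:
        raise ValueError("both arms must be non-empty")
    if cost_a.size != qaly_a.size or cost_b.size != qaly_b.size:
        raise ValueError("cost and QALY vectors must align per patient")
    if B < 1:
        raise ValueError("B must be >= 1")

    rng = np.random.default_rng(seed)
    dc = np.empty(B)
    de = np.empty(B)
    chunk = max(1, min(B, 4_000_000 // max(cost_a.size, cost_b.size)))
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        ia = rng.integers(0, cost_a.size, size=(stop - start, cost_a.size))
        ib = rng.integers(0, cost_b.size, size=(stop - start, cost_b.size))
        dc[start:stop] = cost_a[ia].mean(axis=1) - cost_b[ib].mean(axis=1)
        de[start:stop] = qaly_a[ia].mean(axis=1) - qaly_b[ib].mean(axis=1)

    return IncrementalDraws(
        delta_cost=dc, delta_qaly=de,
        point_delta_cost=float(cost_a.mean() - cost_b.mean()),
        point_delta_qaly=float(qaly_a.mean() - qaly_b.mean()),
        arm_means={"cost": {labels[0]: float(cost_a.mean()), labels[1]: float(cost_b.mean())},
                   "qaly": {labels[0]: float(qaly_a.mean()), labels[1]: float(qaly_b.mean())}},
        n_per_arm={labels[0]: int(cost_a.size), labels[1]: int(cost_b.size)},
        seed=seed,
    )


def bootstrap_incrementals_mi(per_imputation: Sequence[tuple], B: int = DEFAULT_B,
                              seed: int = 0,
                              labels: tuple[str, str] = ("lc", "standard")) -> IncrementalDraws:
    """Bootstrap pooled over m completed datasets.

    ``per_imputation`` holds one ``(cost_a, qaly_a, cost_b, qaly_b)`` tuple
    per imputation. B // m replicates are drawn within each completed
    dataset and the draws pooled, so between-imputation variability enters
    the CEAC; point estimates are the means of the per-imputation point
    estimates (Rubin's rule for means).
    """
    m = len(per_imputation)
    if m == 0:
        raise ValueError("need at least one completed dataset")
    b_each = B // m
    if b_each < 1:
        raise ValueError(f"B={B} too small for m={m} imputations")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=m)
    parts = [bootstrap_incrementals(*args, B=b_each, seed=int(s), labels=labels)
             for args, s in zip(per_imputation, seeds)]
    return IncrementalDraws(
        delta_cost=np.concatenate([p.delta_cost for p in parts]),
        delta_qaly=np.concatenate([p.delta_qaly for p in parts]),
        point_delta_cost=float(np.mean([p.point_delta_cost for p in parts])),
        point_delta_qaly=float(np.mean([p.point_delta_qaly for p in parts])),
        arm_means={stat: {lab: float(np.mean([p.arm_means[stat][lab] for p in parts]))
                          for lab in labels} for stat in ("cost", "qaly")},
        n_per_arm=parts[0].n_per_arm,
        seed=seed,
    )


def net_benefit(delta_cost, delta_qaly, lam: float):
    """Net monetary benefit λ·ΔQALY − ΔCost (DKK); vectorised over draws."""
    if lam < 0:
        raise ValueError(f"willingness to pay must be >= 0, got {lam}")
    return lam * np.asarray(delta_qaly, float) - np.asarray(delta_cost, float)


@dataclass
class CEACCurve:
    """Probability of positive net benefit across the willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: np.ndarray
    label: str = "main"

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.lambdas.size == 0:
            raise ValueError("empty willingness-to-pay grid")
        if np.any(np.diff(self.lambdas) <= 0) or self.lambdas[0] < 0:
            raise ValueError("lambda grid must be non-negative and strictly ascending")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def at(self, lam: float) -> float:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.probabilities[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda_dkk_per_qaly": self.lambdas,
                             "probability_cost_effective": self.probabilities})


def ceac(draws: IncrementalDraws, lambda_grid: Sequence[float] | None = None,
         label: str = "main") -> CEACCurve:
    """Cost-effectiveness acceptability curve from bootstrap draws.

    probability(λ) = #{draws with λ·ΔE − ΔC > 0} / B. Net benefit exactly 0
    counts as not cost-effective (strict inequality; conservative, and ties
    have measure zero for continuous data). At λ = 0 the probability is the
    fraction of cost-saving draws; as λ → ∞ it tends to P(ΔE > 0).
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    # chunk over the grid: grid x B can be large at B = 10,000
    probs = np.empty(grid.size)
    for start in range(0, grid.size, 64):
        stop = min(start + 64, grid.size)
        nb = grid[start:stop, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
        probs[start:stop] = (nb > 0).mean(axis=1)
    return CEACCurve(lambdas=grid, probabilities=probs, label=label)


@dataclass
class CEASummary:
    """Arm means, incremental point estimates, bootstrap SEs and percentile CIs."""

    arm_means: dict
    n_per_arm: dict
    delta_cost: float
    delta_qaly: float
    se_delta_cost: float
    se_delta_qaly: float
    ci_delta_cost: tuple[float, float]
    ci_delta_qaly: tuple[float, float]
    B: int

    def to_dict(self) -> dict:
        return {
            "arm_means": self.arm_means, "n_per_arm": self.n_per_arm, "B": self.B,
            "delta_cost": self.delta_cost, "se_delta_cost": self.se_delta_cost,
            "ci_delta_cost": list(self.ci_delta_cost),
            "delta_qaly": self.delta_qaly, "se_delta_qaly": self.se_delta_qaly,
            "ci_delta_qaly": list(self.ci_delta_qaly),
        }


def summarize(draws: IncrementalDraws, alpha: float = 0.05) -> CEASummary:
    """Point estimates with bootstrap SEs (SD of draws) and percentile CIs."""
    if draws.B < 100:
        warnings.warn(f"B={draws.B} < 100: percentile confidence intervals are unstable",
                      stacklevel=2)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ddof = 1 if draws.B > 1 else 0
    return CEASummary(
        arm_means=draws.arm_means,
        n_per_arm=draws.n_per_arm,
        delta_cost=draws.point_delta_cost,
        delta_qaly=draws.point_delta_qaly,
        se_delta_cost=float(np.std(draws.delta_cost, ddof=ddof)),
        se_delta_qaly=float(np.std(draws.delta_qaly, ddof=ddof)),
        ci_delta_cost=tuple(np.percentile(draws.delta_cost, [lo, hi])),
        ci_delta_qaly=tuple(np.percentile(draws.delta_qaly, [lo, hi])),
        B=draws.B,
    )
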