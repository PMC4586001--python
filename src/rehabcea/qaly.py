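"""QALYs from repeated utility measurements.

A patient's health-related quality of life is measured as a preference-
weighted utility in [0, 1] at fixed timepoints (here months 0, 2 and 5:
baseline, after the intervention, after follow-up). The quality-adjusted
life years accrued over the horizon are the area under the piecewise-linear
utility curve, with time converted from months to years, i.e. the
trapezoidal rule

    QALY = sum_k (u_k + u_{k+1}) / 2 * (t_{k+1} - t_k) / 12 .

Utilities must be complete: imputation of nonresponse happens upstream.
Values outside [0, 1] are rejected rather than clamped — the preference
weighting never leaves that interval, so an out-of-range value signals
data corruption.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MONTHS_PER_YEAR", "DEFAULT_TIMES", "UTILITY_COLUMNS", "qaly_auc", "panel_qaly"]

MONTHS_PER_YEAR = 12.0
DEFAULT_TIMES = (0.0, 2.0, 5.0)       # months: baseline, post-intervention, follow-up
UTILITY_COLUMNS = ("u0", "u2", "u5")


def qaly_auc(utilities: Sequence[float], times: Sequence[float] = DEFAULT_TIMES) -> float:
    """Area under the utility curve (linear interpolation), in years.

    ``times`` are months with the first equal to 0 and strictly increasing.
    Raises if any utility is missing (impute first) or outside [0, 1], or if
    fewer than two timepoints are given.
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times, dtype=float)
    if u.shape != t.shape:
        raise ValueError(f"got {u.size} utilities for {t.size} timepoints")
    if u.size < 2:
        raise ValueError("QALY needs at least two timepoints; a single measurement has no area")
    if np.isnan(u).any():
        raise ValueError("missing utility values: impute (chained equations or LOCF) before QALY")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError(f"times must start at 0 and be strictly increasing, got {times}")
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError(f"utilities must lie in [0, 1], got {utilities}")
    return float(np.trapezoid(u, t) / MONTHS_PER_YEAR)


def panel_qaly(panel: pd.DataFrame, columns: Sequence[str] = UTILITY_COLUMNS,
               times: Sequence[float] = DEFAULT_TIMES) -> pd.Series:
    """Per-patient QALYs for a utility panel (one row per patient).

    Vectorised trapezoid over the utility columns; same validation as
    :func:`qaly_auc`.
    """
    u = panel[list(columns)].to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    if u.shape[1] != t.size or t.size < 2:
        raise ValueError(f"{len(columns)} utility columns for {t.size} timepoints")
    if np.isnan(u).any():
        n_bad = int(np.isnan(u).any(axis=1).sum())
        raise ValueError(f"{n_bad} patients have missing utilities: impute before QALY")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError(f"times must start at 0 and be strictly increasing, got {times}")
    if (u < 0).any() or (u > 1).any():
        raise ValueError("utilities must lie in [0, 1]")
    auc = np.trapezoid(u, t, axis=1) / MONTHS_PER_YEAR
    return pd.Series(auc, index=panel.index, name="qaly")
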