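"""Per-temperature decay kinetics: rate-constant fits and order selection.

At constant temperature a zero-order quality loss is a straight line,
SH(t) = SH0 − k·t, and k is estimated by ordinary least squares of SH on
time. The reaction order is chosen by comparing the linearity of SH (order
0), ln SH (order 1) and 1/SH (order 2) against time and keeping the order
with the highest R²; ties go to the lower order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GROUP_COLUMNS, UNIT_PERCENT, StudyDataset, celsius_to_kelvin
from .errors import (
    DegenerateDesignError,
    GroupingError,
    GroupNotFoundError,
    TransformDomainError,
)

_R2_TIE_TOL = 1e-12


@dataclass(frozen=True)
class IsothermalFit:
    """One-temperature linear decay fit.

    ``k`` is the positive decay rate in %/day (k = −slope of SH on t);
    ``intercept`` the fitted day-0 level in percent.
    """

    temperature_k: float
    k: float
    intercept: float
    order: int
    r2: float
    rmse: float
    n_points: int


def _extract_series(series) -> tuple[np.ndarray, np.ndarray, float]:
    """Pull (t, SH, T_K) out of a one-group series; verify the grouping."""
    if isinstance(series, StudyDataset):
        frame = series.data
    else:
        frame = series
    if isinstance(frame, pd.DataFrame):
        for col in GROUP_COLUMNS:
            if col in frame.columns and frame[col].nunique() > 1:
                raise GroupingError(
                    f"observations span multiple values of {col!r}; "
                    "fit one (treatment, heat_state, temperature) group at a time"
                )
        t = frame["time_days"].to_numpy(dtype=float)
        y = frame["sh_value"].to_numpy(dtype=float)
        if "temperature_c" in frame.columns and len(frame):
            temperature_k = float(celsius_to_kelvin(frame["temperature_c"].iloc[0]))
        else:
            temperature_k = float("nan")
        return t, y, temperature_k
    raise TypeError("series must be a StudyDataset or DataFrame")


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on t."""
    tbar, ybar = t.mean(), y.mean()
    stt = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / stt)
    return slope, float(ybar - slope * tbar)


def _fit_metrics(t, y, slope, intercept):
    fitted = intercept + slope * t
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    rmse = float(np.sqrt(sse / len(y)))
    return r2, rmse


def fit_zero_order(series, fix_intercept: bool = False) -> IsothermalFit:
    """Fit SH = intercept − k·t by OLS at a single temperature.

    With ``fix_intercept`` the intercept is pinned to 100% (the normalized
    day-0 level) and only the slope is estimated.
    """
    t, y, temperature_k = _extract_series(series)
    if len(t) < 2 or np.unique(t).size < 2:
        raise DegenerateDesignError("need at least two distinct time points")
    if fix_intercept:
        intercept = 100.0
        slope = float(np.sum(t * (y - intercept)) / np.sum(t * t))
    else:
        slope, intercept = _ols_line(t, y)
    r2, rmse = _fit_metrics(t, y, slope, intercept)
    return IsothermalFit(
        temperature_k=temperature_k, k=-slope, intercept=intercept, order=0,
        r2=r2, rmse=rmse, n_points=len(t),
    )


def select_order(series) -> int:
    """Choose the reaction order (0, 1 or 2) by straight-line R².

    Order 0 regresses SH on t, order 1 regresses ln SH, order 2 regresses
    1/SH. Requires strictly positive SH values; ties break to the lower
    order.
    """
    t, y, _ = _extract_series(series)
    if np.any(y <= 0):
        rows = np.flatnonzero(y <= 0).tolist()
        raise TransformDomainError(
            f"non-positive SH values at rows {rows} forbid order selection"
        )
    if len(t) < 2 or np.unique(t).size < 2:
        raise DegenerateDesignError("need at least two distinct time points")
    best_order, best_r2 = 0, -np.inf
    for order, transformed in ((0, y), (1, np.log(y)), (2, 1.0 / y)):
        slope, intercept = _ols_line(t, transformed)
        r2, _ = _fit_metrics(t, transformed, slope, intercept)
        if r2 > best_r2 + _R2_TIE_TOL:
            best_order, best_r2 = order, r2
    return best_order


def fit_all_temperatures(
    dataset: StudyDataset,
    treatment: str,
    heat_state: str,
    holdout_temp_c: float | None = 12.0,
    fix_intercept: bool = False,
    average_replicates: bool = False,
) -> list[IsothermalFit]:
    """Zero-order fits at every available temperature of one group.

    The external-validation temperature (default 12 °C) is excluded; pass
    ``holdout_temp_c=None`` to fit all temperatures.
    ``average_replicates`` collapses replicates to their per-day mean before
    fitting; by default replicates enter as individual points.
    """
    if dataset.unit != UNIT_PERCENT:
        raise GroupingError("kinetic fits require percent units; normalize first")
    group = dataset.group(treatment, heat_state)
    fits = []
    for tc, sub in group.groupby("temperature_c"):
        if holdout_temp_c is not None and np.isclose(tc, holdout_temp_c):
            continue
        if average_replicates:
            sub = (
                sub.groupby("time_days", as_index=False)["sh_value"].mean()
                .assign(temperature_c=tc)
            )
        fits.append(fit_zero_order(sub, fix_intercept=fix_intercept))
    if len(fits) < 2:
        raise GroupNotFoundError(
            f"group ({treatment!r}, {heat_state!r}) present at fewer than two "
            "fitting temperatures"
        )
    return sorted(fits, key=lambda f: f.temperature_k)


def fits_to_frame(fits, treatment=None, heat_state=None) -> pd.DataFrame:
    """Tabular fit report (k stored as positive decay rate, %/day)."""
    frame = pd.DataFrame(
        {
            "temperature_k": [f.temperature_k for f in fits],
            "k": [f.k for f in fits],
            "intercept": [f.intercept for f in fits],
            "r2": [f.r2 for f in fits],
            "rmse": [f.rmse for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )
    if treatment is not None:
        frame.insert(0, "treatment", treatment)
        frame.insert(1, "heat_state", heat_state)
    return frame
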