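"""Arrhenius temperature dependence of the decay rate, and SH prediction.

Two estimators of (k0, Ea) are provided:

* **two-stage** — the classical linearization: per-temperature rate
  constants k(T) from the isothermal fits, then OLS of ln k on 1/T, whose
  slope is −Ea/R and intercept ln k0;
* **global** — Levenberg–Marquardt nonlinear least squares of
  SH = SH0 − k0·exp(−Ea/(R·T))·t over all observations at once,
  parameterized in (ln k0, Ea) because k0 spans many orders of magnitude.

Both coincide exactly on noiseless zero-order data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataset import UNIT_PERCENT, StudyDataset, celsius_to_kelvin
from .errors import (
    DegenerateDesignError,
    FitFailureError,
    IdentifiabilityError,
    LogDomainError,
)
from .isothermal import IsothermalFit, _ols_line
from .synthetic import GAS_CONSTANT_KJ

#: Fallback activation energy (kJ/mol) when no two-stage initial value exists;
#: mid-range of the published estimates (25–116 kJ/mol).
_FALLBACK_EA = 60.0


@dataclass(frozen=True)
class ArrheniusParams:
    """Estimated pre-exponential factor k0 (day⁻¹, percent scale) and
    activation energy Ea (kJ/mol), with the R² of the producing fit."""

    k0: float
    ea: float
    r2: float
    method: str  # "two_stage" | "global_lm"


@dataclass(frozen=True)
class KineticModel:
    """A fitted predictive model SH(t, T) = sh0 − k0·exp(−Ea/(R·T))·t."""

    treatment: str
    heat_state: str
    params: ArrheniusParams
    sh0: float = 100.0
    fitted_temperatures_c: tuple = ()


def rate_at(params: ArrheniusParams, temperature_k) -> float | np.ndarray:
    """k(T) = k0·exp(−Ea/(R·T)) in %/day."""
    temperature_k = np.asarray(temperature_k, dtype=float)
    if np.any(temperature_k <= 0):
        raise ValueError("absolute temperature must be positive")
    value = params.k0 * np.exp(-params.ea / (GAS_CONSTANT_KJ * temperature_k))
    return float(value) if value.ndim == 0 else value


def predict_sh(model: KineticModel, time_days, temperature_c=None, temperature_k=None):
    """SH(%) on a time grid at one temperature (give °C or K, not both)."""
    if (temperature_c is None) == (temperature_k is None):
        raise ValueError("give exactly one of temperature_c, temperature_k")
    if temperature_k is None:
        temperature_k = celsius_to_kelvin(temperature_c)
    time_days = np.asarray(time_days, dtype=float)
    if np.any(time_days < 0):
        raise ValueError("time_days must be non-negative")
    value = model.sh0 - rate_at(model.params, temperature_k) * time_days
    return float(value) if value.ndim == 0 else value


def fit_arrhenius_two_stage(fits: list[IsothermalFit]) -> ArrheniusParams:
    """OLS of ln k on 1/T over per-temperature rate constants.

    Ea = −slope·R and k0 = exp(intercept); R² is that of the ln k vs 1/T
    regression.
    """
    ks = np.array([f.k for f in fits], dtype=float)
    temps = np.array([f.temperature_k for f in fits], dtype=float)
    if np.any(ks <= 0):
        bad = temps[ks <= 0].tolist()
        raise LogDomainError(f"non-positive rate constants at T(K)={bad}")
    if np.unique(temps).size < 2:
        raise DegenerateDesignError("need rate constants at >= 2 temperatures")
    x = 1.0 / temps
    y = np.log(ks)
    slope, intercept = _ols_line(x, y)
    fitted = intercept + slope * x
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((y - fitted) ** 2)) / sst
    return ArrheniusParams(
        k0=math.exp(intercept), ea=-slope * GAS_CONSTANT_KJ, r2=r2,
        method="two_stage",
    )


def _observed_arrays(series):
    if isinstance(series, StudyDataset):
        if series.unit != UNIT_PERCENT:
            raise ValueError("global fit requires percent units; normalize first")
        frame = series.data
    else:
        frame = series
    t = frame["time_days"].to_numpy(dtype=float)
    temps_k = celsius_to_kelvin(frame["temperature_c"].to_numpy(dtype=float))
    y = frame["sh_value"].to_numpy(dtype=float)
    return t, temps_k, y


def fit_arrhenius_global(
    series,
    init: ArrheniusParams | None = None,
    sh0: float = 100.0,
    max_nfev: int = 500,
) -> ArrheniusParams:
    """Levenberg–Marquardt fit of SH = sh0 − exp(ln k0 − Ea/(R·T))·t.

    ``init`` seeds (ln k0, Ea); without it Ea starts at 60 kJ/mol and ln k0
    is set so the model matches the mean observed decay rate. R² is computed
    on observed vs fitted SH.
    """
    t, temps_k, y = _observed_arrays(series)
    if np.unique(np.round(temps_k, 6)).size < 2:
        raise IdentifiabilityError(
            "k0 and Ea are not separately identifiable from a single temperature"
        )
    if init is None:
        moving = t > 0
        mean_rate = float(np.mean((sh0 - y[moving]) / t[moving]))
        mean_rate = max(mean_rate, 1e-6)
        ln_k0 = math.log(mean_rate) + _FALLBACK_EA / (
            GAS_CONSTANT_KJ * float(np.mean(temps_k))
        )
        x0 = np.array([ln_k0, _FALLBACK_EA])
    else:
        x0 = np.array([math.log(init.k0), init.ea])

    inv_rt = 1.0 / (GAS_CONSTANT_KJ * temps_k)

    def residuals(theta):
        ln_k0, ea = theta
        return y - (sh0 - np.exp(ln_k0 - ea * inv_rt) * t)

    def jacobian(theta):
        ln_k0, ea = theta
        k = np.exp(ln_k0 - ea * inv_rt)
        return np.column_stack((k * t, -k * t * inv_rt))

    result = least_squares(
        residuals, x0, jac=jacobian, method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
    )
    if not result.success or not np.all(np.isfinite(result.x)):
        raise FitFailureError(
            f"Levenberg-Marquardt did not converge: {result.message}",
            last_params=tuple(result.x),
            residual_norm=float(np.linalg.norm(result.fun)),
        )
    ln_k0, ea = result.x
    fitted = y - result.fun
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(result.fun**2)) / sst
    return ArrheniusParams(k0=math.exp(ln_k0), ea=float(ea), r2=r2, method="global_lm")


def models_to_frame(models: list[KineticModel]) -> pd.DataFrame:
    """Registry table: treatment, heat_state, k0, ea, method, r2."""
    return pd.DataFrame(
        {
            "treatment": [m.treatment for m in models],
            "heat_state": [m.heat_state for m in models],
            "k0": [m.params.k0 for m in models],
            "ea": [m.params.ea for m in models],
            "method": [m.params.method for m in models],
            "r2": [m.params.r2 for m in models],
        }
    )
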