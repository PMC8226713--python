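"""Dummy-coded multiple linear regression of SH on storage conditions.

SH% is regressed on 13 treatment indicator variables (the control is the
uncoded reference), storage temperature (°C) and storage time (days),
pooling all temperatures and times within one heat state:

    SH = β0 + Σ βj·1[treatment j] + β_temp·T + β_time·t + ε

A positive treatment coefficient means the extract preserved thiols relative
to the control (antioxidant effect); a negative one means a prooxidant
effect. Per-coefficient two-sided t-tests at p ≤ 0.05 flag extracts that
differ significantly from the control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import TREATMENTS, UNIT_PERCENT, StudyDataset
from .errors import ConfigurationError, DesignMatrixError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLRFit:
    """OLS estimates with classical standard errors and t-tests."""

    coefficients: pd.Series
    standard_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    r2: float
    see: float  # standard error of estimate (residual std error)
    f_pvalue: float
    n: int
    treatment_terms: tuple


def build_design_matrix(
    dataset: StudyDataset,
    heat_state: str,
    reference: str = "control",
) -> tuple[pd.DataFrame, pd.Series]:
    """Intercept + treatment dummies (reference omitted) + temperature + time.

    Temperature stays in °C and time in days so the slopes read directly as
    %/°C and %/day. Fits are per heat state.
    """
    if dataset.unit != UNIT_PERCENT:
        raise ConfigurationError("MLR requires percent units; normalize first")
    frame = dataset.data.loc[dataset.data["heat_state"] == heat_state]
    if frame.empty:
        raise ConfigurationError(f"no observations with heat_state={heat_state!r}")
    present = set(frame["treatment"].unique())
    if reference not in present:
        raise ConfigurationError(f"reference level {reference!r} absent")
    levels = [t for t in TREATMENTS if t in present and t != reference]
    extra = sorted(present - set(TREATMENTS))
    levels += extra  # accept non-study labels, appended after canon order
    missing = [t for t in TREATMENTS if t not in present]
    if missing:
        logger.warning("treatments absent from data: %s", missing)
    design = pd.DataFrame(index=frame.index)
    design["intercept"] = 1.0
    for level in levels:
        design[level] = (frame["treatment"] == level).astype(float)
    design["temperature"] = frame["temperature_c"].astype(float)
    design["time"] = frame["time_days"].astype(float)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DesignMatrixError("design matrix is rank deficient")
    return design, frame["sh_value"].astype(float)


def fit_mlr(design: pd.DataFrame, response: pd.Series) -> MLRFit:
    """Ordinary least squares with classical (homoscedastic) inference."""
    if len(design) <= design.shape[1]:
        raise DesignMatrixError("need more observations than design columns")
    model = sm.OLS(np.asarray(response, dtype=float), design)
    result = model.fit()
    treatment_terms = tuple(
        c for c in design.columns if c not in ("intercept", "temperature", "time")
    )
    return MLRFit(
        coefficients=result.params,
        standard_errors=result.bse,
        t_statistics=result.tvalues,
        p_values=result.pvalues,
        r2=float(result.rsquared),
        see=float(np.sqrt(result.scale)),
        f_pvalue=float(result.f_pvalue),
        n=int(result.nobs),
        treatment_terms=treatment_terms,
    )


def compare_to_control(fit: MLRFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-treatment slopes vs the control with significance flags.

    ``significant`` is True when p ≤ alpha (boundary inclusive);
    ``direction`` is "antioxidant" for positive slopes (thiols preserved
    relative to control) and "prooxidant" for negative ones.
    """
    rows = []
    for term in fit.treatment_terms:
        slope = float(fit.coefficients[term])
        p = float(fit.p_values[term])
        rows.append(
            {
                "treatment": term,
                "slope": slope,
                "se": float(fit.standard_errors[term]),
                "t": float(fit.t_statistics[term]),
                "p_value": p,
                "significant": p <= alpha,
                "direction": "antioxidant" if slope > 0 else "prooxidant",
            }
        )
    return pd.DataFrame(rows)
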