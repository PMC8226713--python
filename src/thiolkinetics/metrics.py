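"""Goodness of fit and external (hold-out temperature) validation.

R² is 1 − SSE/SST with SST about the observed mean; RMSE uses denominator n
(not n − p) — recorded in the report so downstream readers know the
convention. External validation scores a predictor on a storage temperature
it never saw, which is the honest test of a shelf-life model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arrhenius import KineticModel, rate_at
from .dataset import StudyDataset, celsius_to_kelvin
from .errors import DegenerateDesignError, LeakageError, ZeroVarianceError


@dataclass(frozen=True)
class FitReport:
    """Observed-vs-predicted summary retained with its point pairs."""

    r2: float
    adjusted_r2: float | None
    rmse: float
    n: int
    p: int
    observed: np.ndarray
    predicted: np.ndarray
    rmse_denominator: str = "n"


def goodness_of_fit(observed, predicted, p: int = 2) -> FitReport:
    """R², adjusted R² (penalizing p parameters) and RMSE of predictions."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = observed.size
    if n < 2:
        raise DegenerateDesignError("need at least two observation pairs")
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise ZeroVarianceError("observed values are constant; R^2 undefined")
    r2 = 1.0 - sse / sst
    adjusted = None
    if n - p - 1 > 0:
        adjusted = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    rmse = float(np.sqrt(sse / n))
    return FitReport(
        r2=r2, adjusted_r2=adjusted, rmse=rmse, n=n, p=p,
        observed=observed, predicted=predicted,
    )


def _predict_for(predictor, holdout: StudyDataset) -> np.ndarray:
    if isinstance(predictor, KineticModel):
        frame = holdout.data
        times = frame["time_days"].to_numpy(dtype=float)
        temps_k = celsius_to_kelvin(frame["temperature_c"].to_numpy(dtype=float))
        return predictor.sh0 - rate_at(predictor.params, temps_k) * times
    # MLP ensembles (and anything else) expose predict(StudyDataset).
    return np.asarray(predictor.predict(holdout), dtype=float)


def external_validate(predictor, holdout: StudyDataset) -> FitReport:
    """Score a predictor on observations at a reserved temperature.

    Refuses to run if any hold-out temperature appears among the
    temperatures the predictor was built from (data leakage).
    """
    holdout_temps = set(np.round(holdout.temperatures_c, 6))
    trained = getattr(predictor, "fitted_temperatures_c", ()) or ()
    overlap = holdout_temps & set(np.round(np.asarray(list(trained), float), 6))
    if overlap:
        raise LeakageError(
            f"hold-out temperatures {sorted(overlap)} °C were used in fitting"
        )
    predicted = _predict_for(predictor, holdout)
    p = getattr(predictor, "n_parameters", 2)
    observed = holdout.data["sh_value"].to_numpy(dtype=float)
    return goodness_of_fit(observed, predicted, p=p)


def scatter_report(report: FitReport, path) -> None:
    """Predicted-vs-observed scatter with the identity (perfect-match) line."""
    if report.n == 0 or report.observed.size == 0:
        raise ValueError("report holds no observation pairs")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.observed, report.predicted, s=14, alpha=0.7,
               edgecolor="none")
    lo = min(report.observed.min(), report.predicted.min())
    hi = max(report.observed.max(), report.predicted.max())
    ax.plot([lo, hi], [lo, hi], "k-", lw=1, label="perfect match")
    ax.set_xlabel("observed SH (%)")
    ax.set_ylabel("predicted SH (%)")
    ax.set_title(f"R² = {report.r2:.3f}, RMSE = {report.rmse:.2f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
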