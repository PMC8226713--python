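"""Seeded generator of SH(%) storage time series.

Emulates the statistical structure the downstream estimators assume:
zero-order decay SH(t) = SH0 − k·t at each fixed temperature, Arrhenius
temperature dependence k(T) = k0·exp(−Ea/(R·T)), and additive Gaussian
measurement noise on the percent scale. The default full-factorial design
mirrors the storage study it stands in for: 14 treatments × 2 heat states,
triplicates, 4/8/12 °C sampled daily for 13 days and 16/20 °C for 5 days.

Simulated values below zero are kept by default so that estimators are
exercised on the model's actual support; pass ``clamp_negative=True`` for
realism studies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import COLUMNS, HEAT_STATES, UNIT_PERCENT, StudyDataset, celsius_to_kelvin
from .errors import ConfigurationError

#: Gas constant in kJ·mol⁻¹·K⁻¹, so activation energies are in kJ/mol.
GAS_CONSTANT_KJ = 8.314e-3


@dataclass(frozen=True)
class GeneratingModel:
    """Zero-order Arrhenius decay model for one (treatment, heat_state) cell.

    ``k0`` is the pre-exponential factor in day⁻¹ on the percent scale,
    ``ea`` the activation energy in kJ/mol, ``sh0`` the initial level in
    percent (100 by construction of the normalization).
    """

    treatment: str
    heat_state: str
    k0: float
    ea: float
    sh0: float = 100.0

    def __post_init__(self):
        if self.k0 <= 0:
            raise ConfigurationError("k0 must be positive")
        if self.ea < 0:
            raise ConfigurationError("ea must be non-negative")
        if self.sh0 <= 0:
            raise ConfigurationError("sh0 must be positive")
        if self.heat_state not in HEAT_STATES:
            raise ConfigurationError(f"unknown heat_state {self.heat_state!r}")


def rate_constant(model: GeneratingModel, temperature_k) -> np.ndarray | float:
    """Decay rate k(T) = k0·exp(−Ea/(R·T)) in %/day."""
    temperature_k = np.asarray(temperature_k, dtype=float)
    if np.any(temperature_k <= 0):
        raise ValueError("absolute temperature must be positive")
    return model.k0 * np.exp(-model.ea / (GAS_CONSTANT_KJ * temperature_k))


def sh_true(model: GeneratingModel, time_days, temperature_k):
    """Noise-free SH(%) at time t (days) and absolute temperature T (K).

    May go negative — the zero-order line is not clamped.
    """
    time_days = np.asarray(time_days, dtype=float)
    if np.any(time_days < 0):
        raise ValueError("time_days must be non-negative")
    value = model.sh0 - rate_constant(model, temperature_k) * time_days
    return float(value) if value.ndim == 0 else value


#: Storage spans of the emulated design: chilled temperatures are followed
#: for 13 days, abuse temperatures only for 5.
PAPER_TIMES = {
    4.0: tuple(range(0, 14)),
    8.0: tuple(range(0, 14)),
    12.0: tuple(range(0, 14)),
    16.0: tuple(range(0, 6)),
    20.0: tuple(range(0, 6)),
}


@dataclass(frozen=True)
class SimulationDesign:
    """Sampling plan: temperatures, per-temperature day grids, replicates,
    percent-scale noise standard deviation, and the RNG seed."""

    temperatures_c: tuple = tuple(sorted(PAPER_TIMES))
    times_by_temperature: dict = field(default_factory=lambda: dict(PAPER_TIMES))
    replicates: int = 3
    noise_sd: float = 2.0
    seed: int = 0
    clamp_negative: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for tc in self.temperatures_c:
            times = self.times_by_temperature.get(float(tc))
            if times is None:
                raise ConfigurationError(f"no time grid for {tc} °C")
            times = np.asarray(times, dtype=float)
            if np.any(times < 0) or 0.0 not in times:
                raise ConfigurationError(
                    f"time grid at {tc} °C must be non-negative and include day 0"
                )

    @property
    def n_points(self) -> int:
        """Observations per (treatment, heat_state) cell."""
        return sum(
            len(self.times_by_temperature[float(tc)]) for tc in self.temperatures_c
        ) * self.replicates


def paper_design(noise_sd: float = 2.0, seed: int = 0, replicates: int = 3,
                 clamp_negative: bool = False) -> SimulationDesign:
    """The emulated study design (5 temperatures, daily sampling, triplicates)."""
    return SimulationDesign(
        noise_sd=noise_sd, seed=seed, replicates=replicates,
        clamp_negative=clamp_negative,
    )


def _simulate_cell(model, design, rng, rows):
    for tc in design.temperatures_c:
        tc = float(tc)
        times = np.asarray(design.times_by_temperature[tc], dtype=float)
        temperature_k = celsius_to_kelvin(tc)
        truth = sh_true(model, times, temperature_k)
        for rep in range(1, design.replicates + 1):
            noise = rng.normal(0.0, design.noise_sd, size=times.size)
            values = truth + noise
            if design.clamp_negative:
                values = np.maximum(values, 0.0)
            for t, v in zip(times, values):
                rows.append(
                    (model.treatment, model.heat_state, tc, t, rep, v)
                )


def _to_dataset(rows, design) -> StudyDataset:
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return StudyDataset(
        frame,
        unit=UNIT_PERCENT,
        metadata={"generator": "zero-order-arrhenius", "seed": design.seed,
                  "noise_sd": design.noise_sd},
    )


def simulate_series(model: GeneratingModel, design: SimulationDesign) -> StudyDataset:
    """Simulate one (treatment, heat_state) cell over the design."""
    rng = np.random.default_rng(design.seed)
    rows: list = []
    _simulate_cell(model, design, rng, rows)
    return _to_dataset(rows, design)


def simulate_study(models, design: SimulationDesign) -> StudyDataset:
    """Simulate the union of cells, one shared seeded noise stream.

    Observation count = len(models) × Σ|time grid| × replicates. A single
    model reduces exactly to :func:`simulate_series`.
    """
    seen = set()
    for model in models:
        key = (model.treatment, model.heat_state)
        if key in seen:
            raise ConfigurationError(f"duplicate generating model for {key}")
        seen.add(key)
    rng = np.random.default_rng(design.seed)
    rows: list = []
    for model in models:
        _simulate_cell(model, design, rng, rows)
    return _to_dataset(rows, design)


def table2_registry() -> pd.DataFrame:
    """Packaged table of the 28 published (k0, Ea) generating parameters."""
    resource = importlib.resources.files("thiolkinetics.data").joinpath(
        "table2_kinetic_parameters.csv"
    )
    with resource.open("r") as handle:
        return pd.read_csv(handle)


def table2_models() -> list[GeneratingModel]:
    """The 28 published generating models (14 treatments × 2 heat states)."""
    frame = table2_registry()
    return [
        GeneratingModel(
            treatment=row.treatment, heat_state=row.heat_state,
            k0=float(row.k0), ea=float(row.ea),
        )
        for row in frame.itertuples(index=False)
    ]


def table2_model(treatment: str, heat_state: str) -> GeneratingModel:
    """Look up one published generating model."""
    for model in table2_models():
        if model.treatment == treatment and model.heat_state == heat_state:
            return model
    raise KeyError(f"no published model for ({treatment!r}, {heat_state!r})")
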