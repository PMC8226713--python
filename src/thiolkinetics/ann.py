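"""Single-hidden-layer MLP regression ensemble for SH% prediction.

The network maps encoded storage conditions — a 14-wide treatment one-hot
block, a 2-wide heat-state block, and min-max-scaled time and temperature
(18 inputs) — to the thiol level. Training minimizes the sum-of-squares
error with the BFGS quasi-Newton method (full batch, analytic gradients).
An architecture search trains a grid of candidates, ranks them by
validation error and retains the best five; the ensemble prediction is the
arithmetic mean of the five members.

Hidden activations: tanh, logistic, exponential. Output activations: linear,
logistic, tanh — the two bounded outputs are mapped affinely onto the [0, 1]
scaled-target range (tanh z → (tanh z + 1)/2) so each family can cover it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .dataset import HEAT_STATES, TREATMENTS, UNIT_PERCENT, StudyDataset
from .errors import ConfigurationError, EncodingError, FitFailureError

HIDDEN_ACTIVATIONS = ("tanh", "logistic", "exponential")
OUTPUT_ACTIVATIONS = ("linear", "logistic", "tanh")


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training configuration of one candidate network."""

    n_hidden: int
    hidden_activation: str = "tanh"
    output_activation: str = "linear"
    max_iterations: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ConfigurationError("n_hidden must be >= 1")
        if self.max_iterations < 0:
            raise ConfigurationError("max_iterations must be >= 0")
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ConfigurationError(
                f"hidden_activation must be one of {HIDDEN_ACTIVATIONS}"
            )
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ConfigurationError(
                f"output_activation must be one of {OUTPUT_ACTIVATIONS}"
            )


class FeatureEncoder:
    """One-hot treatment/heat blocks plus min-max-scaled time, temperature.

    Scaling (for the continuous features and the percent target) is fitted
    once on the data supplied to :meth:`fit` and reused verbatim at
    prediction time; inputs outside the fitted range map outside [0, 1]
    rather than being clipped.
    """

    def __init__(self):
        self.fitted = False

    @property
    def width(self) -> int:
        return len(TREATMENTS) + len(HEAT_STATES) + 2

    def fit(self, dataset: StudyDataset) -> "FeatureEncoder":
        if dataset.unit != UNIT_PERCENT:
            raise EncodingError("encoder requires percent units")
        frame = dataset.data
        unknown = set(frame["treatment"].unique()) - set(TREATMENTS)
        if unknown:
            raise EncodingError(f"unknown treatment labels: {sorted(unknown)}")
        self.time_min = float(frame["time_days"].min())
        self.time_max = float(frame["time_days"].max())
        self.temp_min = float(frame["temperature_c"].min())
        self.temp_max = float(frame["temperature_c"].max())
        self.target_min = float(frame["sh_value"].min())
        self.target_max = float(frame["sh_value"].max())
        for lo, hi, what in (
            (self.time_min, self.time_max, "time_days"),
            (self.temp_min, self.temp_max, "temperature_c"),
            (self.target_min, self.target_max, "sh_value"),
        ):
            if hi <= lo:
                raise EncodingError(f"cannot min-max scale constant {what}")
        self.fitted = True
        return self

    def _scale(self, values, lo, hi):
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def transform(self, dataset: StudyDataset) -> np.ndarray:
        if not self.fitted:
            raise EncodingError("encoder not fitted")
        frame = dataset.data
        n = len(frame)
        X = np.zeros((n, self.width))
        for j, label in enumerate(TREATMENTS):
            X[:, j] = (frame["treatment"] == label).to_numpy(dtype=float)
        if not np.allclose(X[:, : len(TREATMENTS)].sum(axis=1), 1.0):
            unknown = sorted(
                set(frame["treatment"].unique()) - set(TREATMENTS)
            )
            raise EncodingError(f"unknown treatment labels: {unknown}")
        base = len(TREATMENTS)
        for j, label in enumerate(HEAT_STATES):
            X[:, base + j] = (frame["heat_state"] == label).to_numpy(dtype=float)
        if not np.allclose(X[:, base : base + 2].sum(axis=1), 1.0):
            raise EncodingError("unknown heat_state labels present")
        X[:, -2] = self._scale(frame["time_days"], self.time_min, self.time_max)
        X[:, -1] = self._scale(frame["temperature_c"], self.temp_min, self.temp_max)
        return X

    def encode(self, dataset: StudyDataset) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and [0, 1]-scaled target vector."""
        X = self.transform(dataset)
        y = self._scale(
            dataset.data["sh_value"], self.target_min, self.target_max
        )
        return X, y

    def descale_target(self, scaled) -> np.ndarray:
        return self.target_min + np.asarray(scaled, dtype=float) * (
            self.target_max - self.target_min
        )

    def to_dict(self) -> dict:
        return {
            "time_min": self.time_min, "time_max": self.time_max,
            "temp_min": self.temp_min, "temp_max": self.temp_max,
            "target_min": self.target_min, "target_max": self.target_max,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureEncoder":
        enc = cls()
        for key, value in payload.items():
            setattr(enc, key, float(value))
        enc.fitted = True
        return enc


def encode_features(dataset: StudyDataset) -> tuple[np.ndarray, np.ndarray, FeatureEncoder]:
    """Fit an encoder on a dataset and return (X, y_scaled, encoder)."""
    encoder = FeatureEncoder().fit(dataset)
    X, y = encoder.encode(dataset)
    return X, y, encoder


# --- data partitioning -----------------------------------------------------

def split_indices(n: int, ratios=(70, 15, 15), seed: int = 0):
    """Disjoint random train/validation/test index split.

    Subset sizes follow largest-remainder rounding of ``ratios`` (which must
    sum to 100), so e.g. 101 rows at 70:15:15 give 71/15/15.
    """
    ratios = tuple(ratios)
    if sum(ratios) != 100:
        raise ConfigurationError(f"split ratios must sum to 100, got {ratios}")
    exact = [n * r / 100.0 for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        j = int(np.argmax(remainders))
        sizes[j] += 1
        remainders[j] = -1.0
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(sizes)
    return perm[: bounds[0]], perm[bounds[0] : bounds[1]], perm[bounds[1] :]


def split_dataset(dataset: StudyDataset, ratios=(70, 15, 15), seed: int = 0):
    """Random 70:15:15 (by default) partition of a dataset's rows."""
    if len(dataset) < 10:
        raise ConfigurationError("dataset too small to split (need >= 10 rows)")
    parts = split_indices(len(dataset), ratios, seed)
    out = []
    for idx in parts:
        frame = dataset.data.iloc[np.sort(idx)].reset_index(drop=True)
        out.append(StudyDataset(frame, unit=dataset.unit,
                                metadata=dict(dataset.metadata)))
    return tuple(out)


# --- the network -----------------------------------------------------------

_HIDDEN = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "logistic": (expit, lambda a: a * (1.0 - a)),
    "exponential": (np.exp, lambda a: a),
}

# Output maps onto the [0,1] scaled-target range; derivative in terms of z.
_OUTPUT = {
    "linear": (lambda z: z, lambda z, out: np.ones_like(z)),
    "logistic": (expit, lambda z, out: out * (1.0 - out)),
    "tanh": (
        lambda z: 0.5 * (np.tanh(z) + 1.0),
        lambda z, out: 0.5 * (1.0 - np.tanh(z) ** 2),
    ),
}


def _unpack(theta, d, h):
    w1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    w2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _forward(theta, X, spec):
    w1, b1, w2, b2 = _unpack(theta, X.shape[1], spec.n_hidden)
    act, _ = _HIDDEN[spec.hidden_activation]
    out_act, _ = _OUTPUT[spec.output_activation]
    hidden = act(X @ w1 + b1)
    z = hidden @ w2 + b2
    return out_act(z)


@dataclass
class TrainedMLP:
    """A fitted network plus its per-subset scores.

    ``*_error`` are sum-of-squares losses on the scaled target;
    ``*_r2`` are observed-vs-predicted R² on the percent scale.
    """

    spec: MLPSpec
    theta: np.ndarray
    n_inputs: int
    n_iterations: int = 0
    training_error: float = float("nan")
    validation_error: float = float("nan")
    test_error: float = float("nan")
    training_r2: float = float("nan")
    validation_r2: float = float("nan")
    test_r2: float = float("nan")

    @property
    def n_parameters(self) -> int:
        return self.theta.size

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        return _forward(self.theta, np.asarray(X, dtype=float), self.spec)

    def sos_error(self, X, y_scaled) -> float:
        resid = self.predict_scaled(X) - y_scaled
        return float(resid @ resid)


def initial_weights(spec: MLPSpec, n_inputs: int) -> np.ndarray:
    """Uniform(−0.5, 0.5) initialization from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    size = n_inputs * spec.n_hidden + 2 * spec.n_hidden + 1
    return rng.uniform(-0.5, 0.5, size=size)


def _loss_and_grad(theta, X, y, spec):
    d, h = X.shape[1], spec.n_hidden
    w1, b1, w2, b2 = _unpack(theta, d, h)
    act, dact = _HIDDEN[spec.hidden_activation]
    out_act, dout = _OUTPUT[spec.output_activation]
    with np.errstate(over="ignore", invalid="ignore"):
        hidden = act(X @ w1 + b1)
        z = hidden @ w2 + b2
        out = out_act(z)
        resid = out - y
        loss = float(resid @ resid)
        if not np.isfinite(loss):
            return np.inf, np.zeros_like(theta)
        dz = 2.0 * resid * dout(z, out)
        gw2 = hidden.T @ dz
        gb2 = float(dz.sum())
        dhidden = np.outer(dz, w2) * dact(hidden)
        gw1 = X.T @ dhidden
        gb1 = dhidden.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]])
    if not np.all(np.isfinite(grad)):
        return np.inf, np.zeros_like(theta)
    return loss, grad


def train_mlp(spec: MLPSpec, train, validation=None) -> TrainedMLP:
    """Fit one network by full-batch BFGS on the sum-of-squares loss.

    ``train`` and ``validation`` are (X, y_scaled) pairs. With
    ``max_iterations=0`` the initial (seeded) weights are returned and the
    reported training error is the initial loss.
    """
    X, y = (np.asarray(a, dtype=float) for a in train)
    theta0 = initial_weights(spec, X.shape[1])
    loss0, _ = _loss_and_grad(theta0, X, y, spec)
    if not np.isfinite(loss0):
        raise FitFailureError("non-finite loss at initial weights (iteration 0)")
    if spec.max_iterations == 0:
        theta, n_iter, final_loss = theta0, 0, loss0
    else:
        result = minimize(
            _loss_and_grad, theta0, args=(X, y, spec), jac=True,
            method="BFGS",
            options={"maxiter": spec.max_iterations, "gtol": 1e-8},
        )
        theta, n_iter = result.x, int(result.nit)
        final_loss = float(result.fun)
        if not np.isfinite(final_loss):
            raise FitFailureError(
                f"training diverged (non-finite loss at iteration {n_iter})"
            )
    net = TrainedMLP(spec=spec, theta=theta, n_inputs=X.shape[1],
                     n_iterations=n_iter, training_error=final_loss)
    net.training_r2 = _subset_r2(net, X, y)
    if validation is not None:
        Xv, yv = (np.asarray(a, dtype=float) for a in validation)
        net.validation_error = net.sos_error(Xv, yv)
        net.validation_r2 = _subset_r2(net, Xv, yv)
    return net


def _subset_r2(net: TrainedMLP, X, y_scaled) -> float:
    pred = net.predict_scaled(X)
    sst = float(np.sum((y_scaled - y_scaled.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - net.sos_error(X, y_scaled) / sst


# --- architecture search & ensembling --------------------------------------

def default_grid(hidden_sizes=(8, 12, 16, 20, 24, 28), activations=("tanh",),
                 output_activations=("linear",), max_iterations: int = 300,
                 seeds=(0,)) -> list[MLPSpec]:
    """Candidate grid: hidden sizes × hidden/output activations × seeds."""
    return [
        MLPSpec(n_hidden=h, hidden_activation=a, output_activation=o,
                max_iterations=max_iterations, seed=s)
        for h in hidden_sizes for a in activations for o in output_activations
        for s in seeds
    ]


@dataclass
class MLPEnsemble:
    """Exactly five retained networks; prediction = mean of the members."""

    members: list
    encoder: FeatureEncoder
    fitted_temperatures_c: tuple = ()
    summary: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.members) != 5:
            raise ConfigurationError(
                f"an ensemble retains exactly 5 networks, got {len(self.members)}"
            )

    @property
    def n_parameters(self) -> int:
        return int(sum(m.n_parameters for m in self.members))

    def predict(self, observations: StudyDataset) -> np.ndarray:
        """Mean member prediction, de-scaled to percent."""
        X = self.encoder.transform(observations)
        scaled = np.mean([m.predict_scaled(X) for m in self.members], axis=0)
        return self.encoder.descale_target(scaled)

    def to_json(self, path=None) -> str:
        payload = {
            "encoder": self.encoder.to_dict(),
            "fitted_temperatures_c": list(self.fitted_temperatures_c),
            "members": [
                {
                    "spec": {
                        "n_hidden": m.spec.n_hidden,
                        "hidden_activation": m.spec.hidden_activation,
                        "output_activation": m.spec.output_activation,
                        "max_iterations": m.spec.max_iterations,
                        "seed": m.spec.seed,
                    },
                    "n_inputs": m.n_inputs,
                    "n_iterations": m.n_iterations,
                    "theta": m.theta.tolist(),
                    "scores": {
                        "training_error": m.training_error,
                        "validation_error": m.validation_error,
                        "test_error": m.test_error,
                        "training_r2": m.training_r2,
                        "validation_r2": m.validation_r2,
                        "test_r2": m.test_r2,
                    },
                }
                for m in self.members
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MLPEnsemble":
        text = Path(source).read_text() if Path(str(source)).exists() else source
        payload = json.loads(text)
        members = []
        for m in payload["members"]:
            net = TrainedMLP(
                spec=MLPSpec(**m["spec"]),
                theta=np.asarray(m["theta"], dtype=float),
                n_inputs=int(m["n_inputs"]),
                n_iterations=int(m["n_iterations"]),
                **m["scores"],
            )
            members.append(net)
        return cls(
            members=members,
            encoder=FeatureEncoder.from_dict(payload["encoder"]),
            fitted_temperatures_c=tuple(payload["fitted_temperatures_c"]),
        )


def ensemble_predict(ensemble: MLPEnsemble, observations: StudyDataset) -> np.ndarray:
    """Arithmetic mean of the five member predictions, in percent."""
    return ensemble.predict(observations)


def search_architectures(
    dataset: StudyDataset,
    grid: list[MLPSpec] | None = None,
    n_keep: int = 5,
    split_seed: int = 0,
    ratios=(70, 15, 15),
) -> MLPEnsemble:
    """Train a candidate grid, rank by validation error, keep the best five.

    The dataset is split 70:15:15 into training, validation and test rows;
    candidates are ranked by ascending validation sum-of-squares error with
    ties broken by grid order. The returned ensemble carries a Table-style
    summary (per-member subset R² and errors, RMSE on percent scale).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ConfigurationError("empty candidate grid")
    if n_keep > len(grid):
        raise ConfigurationError(
            f"n_keep={n_keep} exceeds the {len(grid)} grid candidates"
        )
    encoder = FeatureEncoder().fit(dataset)
    X, y = encoder.encode(dataset)
    idx_train, idx_val, idx_test = split_indices(len(dataset), ratios, split_seed)
    train = (X[idx_train], y[idx_train])
    val = (X[idx_val], y[idx_val])
    test = (X[idx_test], y[idx_test])

    trained: list[tuple[int, TrainedMLP]] = []
    failures = []
    for i, spec in enumerate(grid):
        try:
            net = train_mlp(spec, train, val)
        except FitFailureError as exc:
            failures.append((spec, exc))
            continue
        net.test_error = net.sos_error(*test)
        net.test_r2 = _subset_r2(net, *test)
        trained.append((i, net))
    if not trained:
        raise FitFailureError(
            f"all {len(grid)} candidate networks failed to train"
        )
    if len(trained) < n_keep:
        raise FitFailureError(
            f"only {len(trained)} candidates trained; cannot keep {n_keep}"
        )
    trained.sort(key=lambda item: (item[1].validation_error, item[0]))
    members = [net for _, net in trained[:n_keep]]
    scale = encoder.target_max - encoder.target_min
    summary = pd.DataFrame(
        {
            "structure": [
                f"MLP {m.n_inputs}-{m.spec.n_hidden}-1" for m in members
            ],
            "hidden_activation": [m.spec.hidden_activation for m in members],
            "output_activation": [m.spec.output_activation for m in members],
            "bfgs_iterations": [m.n_iterations for m in members],
            "training_r2": [m.training_r2 for m in members],
            "validation_r2": [m.validation_r2 for m in members],
            "test_r2": [m.test_r2 for m in members],
            "training_error": [m.training_error for m in members],
            "validation_error": [m.validation_error for m in members],
            "test_error": [m.test_error for m in members],
            "rmse_percent": [
                float(np.sqrt(m.test_error / len(idx_test))) * scale
                for m in members
            ],
        }
    )
    return MLPEnsemble(
        members=members,
        encoder=encoder,
        fitted_temperatures_c=tuple(np.sort(dataset.temperatures_c)),
        summary=summary,
    )
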