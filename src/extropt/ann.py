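"""4-H-1 feedforward metamodel: min-max scaling, forward pass, LM training.

The network mirrors the MATLAB ``fitnet``-style single-hidden-layer
architecture used to surrogate the extraction yield: inputs and the
response are min-max normalized to [-1, 1] from the data extremes, the
hidden layer applies the hyperbolic-tangent sigmoid

    tansig(x) = 2 / (1 + exp(-2x)) - 1,

and the output layer is linear (purelin); predictions are mapped back to
actual yield units.  Training is Levenberg-Marquardt (damped Gauss-Newton
on the training-set MSE, analytic Jacobian) with validation-based early
stopping, the standard ``trainlm`` recipe.

A set of published reference weights for the 10-hidden-neuron network ships
with the package (:func:`load_fixture_weights`).  Note: those input-layer
values carry an exact Nguyen-Widrow initialization signature — identical
row norms and an arithmetic ladder of bias magnitudes — so they appear to
be the network's initial rather than final parameters; see docs/methods.md
before treating their predictions as a trained surrogate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignTable

__all__ = [
    "ScalerSet",
    "MLPWeights",
    "TrainConfig",
    "TrainingTrace",
    "tansig",
    "fit_scaler",
    "forward",
    "load_fixture_weights",
    "train",
    "sweep_hidden",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; the partial trace is attached."""

    def __init__(self, message: str, trace: "TrainingTrace | None" = None):
        super().__init__(message)
        self.trace = trace


def tansig(x: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2x)) - 1 == tanh(x)."""
    return np.tanh(x)


@dataclass(frozen=True)
class ScalerSet:
    """Per-variable min-max normalizers onto the target range [-1, 1]."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    target: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_min", np.asarray(self.x_min, dtype=float))
        object.__setattr__(self, "x_max", np.asarray(self.x_max, dtype=float))
        if np.any(self.x_min >= self.x_max) or self.y_min >= self.y_max:
            raise ValueError("degenerate scaler: min must be < max per variable")

    def _affine(self, v, lo, hi):
        a, b = self.target
        return (b - a) * (v - lo) / (hi - lo) + a

    def _inverse(self, s, lo, hi):
        a, b = self.target
        return (np.asarray(s) - a) / (b - a) * (hi - lo) + lo

    def scale_x(self, actual: np.ndarray) -> np.ndarray:
        return self._affine(np.asarray(actual, dtype=float), self.x_min, self.x_max)

    def unscale_x(self, scaled: np.ndarray) -> np.ndarray:
        return self._inverse(scaled, self.x_min, self.x_max)

    def scale_y(self, actual):
        return self._affine(np.asarray(actual, dtype=float), self.y_min, self.y_max)

    def unscale_y(self, scaled):
        return self._inverse(scaled, self.y_min, self.y_max)


def fit_scaler(design: DesignTable) -> ScalerSet:
    """Build scalers from the per-column data minima/maxima of a design."""
    if design.n_runs == 0:
        raise ValueError("empty design")
    if not design.has_responses:
        raise ValueError("design has missing responses")
    X = design.actual
    y = design.response
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    if np.any(x_min == x_max) or y.min() == y.max():
        raise ValueError("degenerate scaler: a column is constant")
    return ScalerSet(x_min, x_max, float(y.min()), float(y.max()))


@dataclass
class MLPWeights:
    """Parameters of the k-input, H-hidden, 1-output network."""

    W1: np.ndarray  # (H, k): rows are hidden neurons
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (H,): output weights
    b2: float

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        H = self.W1.shape[0]
        if self.W1.ndim != 2 or self.b1.shape != (H,) or self.W2.shape != (H,):
            raise ValueError("inconsistent weight dimensions")
        self.b2 = float(self.b2)

    @property
    def H(self) -> int:
        return self.W1.shape[0]

    @property
    def k(self) -> int:
        return self.W1.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.H * self.k + self.H + self.H + 1

    def net(self, scaled_x: np.ndarray) -> np.ndarray:
        """Normalized-scale output at normalized inputs (n x k or k)."""
        scaled_x = np.atleast_2d(np.asarray(scaled_x, dtype=float))
        if scaled_x.shape[1] != self.k:
            raise ValueError(f"expected {self.k} inputs, got {scaled_x.shape[1]}")
        hidden = tansig(scaled_x @ self.W1.T + self.b1)
        return hidden @ self.W2 + self.b2

    def to_json(self, path) -> None:
        obj = {
            "hidden_size": self.H,
            "n_inputs": self.k,
            "W1": {"shape": list(self.W1.shape), "order": "row-major",
                   "values": self.W1.tolist()},
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MLPWeights":
        with open(path) as fh:
            obj = json.load(fh)
        W1 = np.asarray(obj["W1"]["values"], dtype=float).reshape(obj["W1"]["shape"])
        return cls(W1, np.asarray(obj["b1"]), np.asarray(obj["W2"]), obj["b2"])


def forward(
    weights: MLPWeights, scalers: ScalerSet, actual_points: np.ndarray
) -> np.ndarray:
    """Predict responses in original units at actual-unit input points.

    y = unscale(purelin(W2 . tansig(W1 . scale(x) + b1) + b2)).  The linear
    output is unbounded, so predictions may exceed the observed response
    range.
    """
    pts = np.atleast_2d(np.asarray(actual_points, dtype=float))
    if pts.shape[1] != weights.k:
        raise ValueError(f"expected {weights.k}-dimensional points")
    out = weights.net(scalers.scale_x(pts))
    return np.asarray(scalers.unscale_y(out), dtype=float)


def load_fixture_weights() -> tuple[MLPWeights, ScalerSet]:
    """The packaged published reference network and its data-range scalers.

    The 40-entry hidden-input block is read row-major as 10 x 4 (rows =
    hidden neurons), the orientation matching the published statement that
    the input-to-hidden weight matrix is 10 x 4.
    """
    with resources.files("extropt.data").joinpath("ann_weights.json").open() as fh:
        obj = json.load(fh)
    W1 = np.asarray(obj["W1"]["values"], dtype=float).reshape(obj["W1"]["shape"])
    weights = MLPWeights(W1, np.asarray(obj["b1"]), np.asarray(obj["W2"]), obj["b2"])
    sc = obj["scaling"]
    scalers = ScalerSet(
        np.asarray(sc["input_min"]), np.asarray(sc["input_max"]),
        sc["response_min"], sc["response_max"],
        tuple(sc["target_range"]),
    )
    return weights, scalers


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt training configuration.

    The 80/10/10 split follows the study protocol; ``max_fail`` = 10
    consecutive validation-MSE increases stop training (the published run
    used the same patience).  Damping defaults are the conventional
    LM schedule.
    """

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    max_fail: int = 10
    max_epochs: int = 300
    seed: int = 0
    mu0: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    mu_max: float = 1e10
    hidden_sizes: tuple[int, ...] = (10,)
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be >= 0 and sum to 1")
        if self.max_fail < 1:
            raise ValueError("max_fail must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch record of an LM run (epoch 0 is the initial state)."""

    epoch: list[int] = field(default_factory=list)
    mse_train: list[float] = field(default_factory=list)
    mse_val: list[float] = field(default_factory=list)
    mse_test: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""

    def __len__(self) -> int:
        return len(self.epoch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "mse_train": self.mse_train,
                "mse_val": self.mse_val,
                "mse_test": self.mse_test,
                "grad_norm": self.grad_norm,
                "mu": self.mu,
            }
        )


def _split_indices(n: int, config: TrainConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded random permutation cut into train/val/test contiguous blocks."""
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(n * config.val_frac))
    n_test = int(round(n * config.test_frac))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("not enough runs for the requested split")
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _pack(w: MLPWeights) -> np.ndarray:
    return np.concatenate([w.W1.ravel(), w.b1, w.W2, [w.b2]])


def _unpack(theta: np.ndarray, H: int, k: int) -> MLPWeights:
    i = H * k
    return MLPWeights(
        theta[:i].reshape(H, k),
        theta[i : i + H],
        theta[i + H : i + 2 * H],
        theta[i + 2 * H],
    )


def _jacobian(w: MLPWeights, xs: np.ndarray) -> np.ndarray:
    """d(net output)/d(theta) at each training point; (n, P)."""
    z = tansig(xs @ w.W1.T + w.b1)  # (n, H)
    dz = (1.0 - z**2) * w.W2  # (n, H): dout/d(pre-activation_h)
    n, k = xs.shape
    J_W1 = dz[:, :, None] * xs[:, None, :]  # (n, H, k)
    return np.concatenate(
        [J_W1.reshape(n, -1), dz, z, np.ones((n, 1))], axis=1
    )


def _mse(w: MLPWeights, xs: np.ndarray, ts: np.ndarray) -> float:
    if len(ts) == 0:
        return float("nan")
    r = w.net(xs) - ts
    return float(r @ r / len(ts))


def init_weights(H: int, k: int, rng: np.random.Generator, scale: float = 0.5) -> MLPWeights:
    """Uniform [-scale, scale] initialization from a seeded generator."""
    return MLPWeights(
        rng.uniform(-scale, scale, (H, k)),
        rng.uniform(-scale, scale, H),
        rng.uniform(-scale, scale, H),
        float(rng.uniform(-scale, scale)),
    )


def train(
    design: DesignTable, config: TrainConfig, H: int
) -> tuple[MLPWeights, TrainingTrace]:
    """Levenberg-Marquardt training of a k-H-1 network on a design table.

    Minimizes MSE on the normalized training subset by damped Gauss-Newton:
    a proposed step solves (J'J + mu I) d = -J'r; rejected steps raise the
    damping ``mu`` by ``mu_up`` and retry, accepted steps lower it by
    ``mu_down`` — so the recorded training MSE is non-increasing across
    epochs.  Stops at ``max_epochs``, damping overflow, or after
    ``max_fail`` consecutive epochs of rising validation MSE; the returned
    weights are those of the epoch with minimum validation MSE (minimum
    training MSE when the validation split is empty).
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    scalers = fit_scaler(design)
    xs_all = scalers.scale_x(design.actual)
    ts_all = np.asarray(scalers.scale_y(design.response), dtype=float)
    itr, iva, ite = _split_indices(design.n_runs, config)
    xs, ts = xs_all[itr], ts_all[itr]
    rng = np.random.default_rng(config.seed)
    w = init_weights(H, design.k, rng, config.init_scale)
    theta = _pack(w)
    mu = config.mu0
    use_val = len(iva) > 0

    trace = TrainingTrace()

    def record(epoch: int, grad: float) -> None:
        trace.epoch.append(epoch)
        trace.mse_train.append(_mse(w, xs, ts))
        trace.mse_val.append(_mse(w, xs_all[iva], ts_all[iva]))
        trace.mse_test.append(_mse(w, xs_all[ite], ts_all[ite]))
        trace.grad_norm.append(grad)
        trace.mu.append(mu)

    r = w.net(xs) - ts
    sse = float(r @ r)
    record(0, float(np.linalg.norm(2 * _jacobian(w, xs).T @ r)))
    best_val = trace.mse_val[0] if use_val else trace.mse_train[0]
    best_theta = theta.copy()
    fails = 0
    trace.stop_reason = "max_epochs"

    for epoch in range(1, config.max_epochs + 1):
        J = _jacobian(w, xs)
        g = J.T @ r
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(len(theta)), -g)
            except np.linalg.LinAlgError:
                mu *= config.mu_up
                continue
            w_new = _unpack(theta + delta, H, design.k)
            r_new = w_new.net(xs) - ts
            sse_new = float(r_new @ r_new)
            if not np.isfinite(sse_new):
                raise TrainingDivergedError("non-finite training loss", trace)
            if sse_new < sse:
                theta = theta + delta
                w, r, sse = w_new, r_new, sse_new
                mu = max(mu * config.mu_down, 1e-20)
                accepted = True
                break
            mu *= config.mu_up
        if not accepted:
            # no descent possible: converged if the gradient is at floor,
            # otherwise genuine damping overflow
            trace.stop_reason = (
                "converged" if np.linalg.norm(g) < 1e-10 else "mu_overflow"
            )
            break
        record(epoch, float(np.linalg.norm(2 * J.T @ r)))
        current = trace.mse_val[-1] if use_val else trace.mse_train[-1]
        if current < best_val:
            best_val = current
            best_theta = theta.copy()
            trace.best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if use_val and fails >= config.max_fail:
                trace.stop_reason = "early_stopping"
                break

    best = _unpack(best_theta, H, design.k)
    return best, trace


def sweep_hidden(
    design: DesignTable, config: TrainConfig
) -> tuple[pd.DataFrame, int]:
    """Train one network per candidate hidden size under a shared seed.

    Returns a table of (H, mse_train, mse_val, best_epoch) and the hidden
    size minimizing validation MSE (training MSE if no validation split).
    """
    if not config.hidden_sizes:
        raise ValueError("no candidate hidden sizes")
    rows = []
    for H in config.hidden_sizes:
        w, trace = train(design, config, H)
        be = trace.best_epoch
        rows.append(
            {
                "H": H,
                "mse_train": trace.mse_train[trace.epoch.index(be)],
                "mse_val": trace.mse_val[trace.epoch.index(be)],
                "best_epoch": be,
            }
        )
    table = pd.DataFrame(rows)
    crit = "mse_val" if table["mse_val"].notna().all() else "mse_train"
    best_H = int(table.loc[table[crit].idxmin(), "H"])
    return table, best_H
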