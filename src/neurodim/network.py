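"""From-scratch 3-layer sigmoid feedforward network with online backprop.

Architecture and training protocol follow the small "classic connectionist"
recipe: one hidden layer, logistic activations on hidden and output units,
bias units in both layers, squared-error loss E = 0.5 * sum (t - o)^2, and
per-pattern (online) stochastic gradient descent with no momentum or decay.

Targets are min-max scaled to [0, 1] (sigmoid outputs cannot leave (0, 1));
inputs are *not* range-restricted — standardised (z-scored) inputs are the
recommended practice, since squashing inputs into [0, 1] shrinks
first-layer gradients enough to stall learning at small learning rates.
Correlation-based downstream comparisons are invariant to either affine
choice.

The training protocol draws a fresh with-replacement multiset (default:
100 of the n cases) every epoch, visits it in random order, and records
the summed squared error on the *evaluation* set (by default all n cases)
once per epoch.  Setting ``resample_each_epoch=False`` freezes the first
multiset for the whole run instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ScalingError, TrainingDivergedError


@dataclass
class NetworkConfig:
    n_inputs: int = 10
    n_hidden: int = 10
    n_outputs: int = 9
    learning_rate: float = 0.03
    epochs: int = 1000
    weight_init_halfwidth: float = 0.5
    train_sample_size: int = 100
    sample_with_replacement: bool = True
    resample_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_inputs", "n_hidden", "n_outputs", "epochs", "train_sample_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.learning_rate <= 0 and self.learning_rate != 0.0:
            raise ConfigError("learning_rate must be >= 0")
        if self.weight_init_halfwidth <= 0:
            raise ConfigError("weight_init_halfwidth must be positive")


@dataclass
class NetworkState:
    """Weights including bias rows: w_hidden is (n_inputs+1, n_hidden),
    w_output is (n_hidden+1, n_outputs); the last row of each is the bias."""

    w_hidden: np.ndarray
    w_output: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(self.w_hidden.copy(), self.w_output.copy())


@dataclass
class TrainingTrace:
    sse: List[float]               # evaluation-set SSE after each epoch
    final_rmse: float
    n_eval_cases: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.sse) + 1), "sse": self.sse})


@dataclass
class ScalingSpec:
    """Per-column min-max map to [0, 1] with exact affine inverse."""

    minima: np.ndarray
    maxima: np.ndarray
    columns: List[str] | None = None

    @classmethod
    def fit(cls, table) -> "ScalingSpec":
        arr, cols = _as_array(table)
        mins = arr.min(axis=0)
        maxs = arr.max(axis=0)
        if np.any(maxs <= mins):
            bad = (
                [cols[i] for i in np.where(maxs <= mins)[0]]
                if cols
                else list(np.where(maxs <= mins)[0])
            )
            raise ScalingError(f"constant column(s), min-max scaling undefined: {bad}")
        return cls(minima=mins, maxima=maxs, columns=cols)

    def transform(self, table) -> np.ndarray:
        arr, _ = _as_array(table)
        if arr.shape[1] != self.minima.size:
            raise ScalingError("column count does not match the fitted scaling")
        return (arr - self.minima) / (self.maxima - self.minima)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        if scaled.shape[-1] != self.minima.size:
            raise ScalingError("column count does not match the fitted scaling")
        return scaled * (self.maxima - self.minima) + self.minima


def _as_array(table) -> Tuple[np.ndarray, List[str] | None]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    return np.asarray(table, dtype=float), None


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_network(config: NetworkConfig) -> NetworkState:
    """i.i.d. uniform weights on [-halfwidth, +halfwidth], seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    hw = config.weight_init_halfwidth
    w_hidden = rng.uniform(-hw, hw, size=(config.n_inputs + 1, config.n_hidden))
    w_output = rng.uniform(-hw, hw, size=(config.n_hidden + 1, config.n_outputs))
    return NetworkState(w_hidden=w_hidden, w_output=w_output)


def forward(state: NetworkState, input_row: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One forward pass; returns (hidden activations, output activations)."""
    x = np.asarray(input_row, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    xb = np.append(x, 1.0)
    hidden = sigmoid(xb @ state.w_hidden)
    hb = np.append(hidden, 1.0)
    output = sigmoid(hb @ state.w_output)
    return hidden, output


def forward_batch(state: NetworkState, X: np.ndarray) -> np.ndarray:
    Xb = np.column_stack([X, np.ones(len(X))])
    H = sigmoid(Xb @ state.w_hidden)
    Hb = np.column_stack([H, np.ones(len(H))])
    return sigmoid(Hb @ state.w_output)


def loss_and_gradients(
    state: NetworkState, X: np.ndarray, Y: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Batch loss E = 0.5 * sum (t - o)^2 and its exact weight gradients.

    Used by the gradient-correctness tests; training itself updates
    per-pattern with the same per-pattern gradients.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xb = np.column_stack([X, np.ones(len(X))])
    H = sigmoid(Xb @ state.w_hidden)
    Hb = np.column_stack([H, np.ones(len(H))])
    O = sigmoid(Hb @ state.w_output)
    err = O - Y
    loss = 0.5 * float(np.sum(err * err))
    delta_o = err * O * (1.0 - O)
    g_out = Hb.T @ delta_o
    delta_h = (delta_o @ state.w_output[:-1].T) * H * (1.0 - H)
    g_hid = Xb.T @ delta_h
    return loss, g_hid, g_out


def _check_scaled(arr: np.ndarray, name: str) -> None:
    if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
        raise ScalingError(f"{name} must be scaled to [0, 1] before training")


def train(
    state: NetworkState,
    features: np.ndarray,
    targets: np.ndarray,
    config: NetworkConfig,
    *,
    train_indices: np.ndarray | None = None,
    eval_features: np.ndarray | None = None,
    eval_targets: np.ndarray | None = None,
) -> Tuple[NetworkState, TrainingTrace]:
    """Online backprop on a drawn training multiset; per-epoch eval-set SSE.

    ``features`` may be on any scale (z-scores recommended); ``targets``
    must be scaled to [0, 1].  The training multiset (``train_sample_size``
    cases, with replacement by default) is redrawn every epoch unless
    ``resample_each_epoch`` is off or explicit ``train_indices`` are
    supplied (which freezes the multiset).  The trace records SSE on
    ``eval_features`` (default: all passed cases) after every epoch.
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    _check_scaled(Y, "targets")
    if X.shape[1] != config.n_inputs or Y.shape[1] != config.n_outputs:
        raise ConfigError("feature/target widths do not match the network config")
    Xe = X if eval_features is None else np.asarray(eval_features, dtype=float)
    Ye = Y if eval_targets is None else np.asarray(eval_targets, dtype=float)

    rng = np.random.default_rng(config.seed + 1)  # decoupled from weight init
    n = len(X)
    m = config.train_sample_size

    def draw() -> np.ndarray:
        if config.sample_with_replacement:
            return rng.integers(0, n, size=m)
        return rng.choice(n, size=min(m, n), replace=False)

    idx = np.asarray(train_indices) if train_indices is not None else draw()

    st = state.copy()
    W, V = st.w_hidden, st.w_output
    lr = config.learning_rate
    sse_trace: List[float] = []
    Xeb = np.column_stack([Xe, np.ones(len(Xe))])

    for epoch in range(1, config.epochs + 1):
        if config.resample_each_epoch and train_indices is None and epoch > 1:
            idx = draw()
        order = rng.permutation(len(idx))
        for i in idx[order]:
            xb = np.append(X[i], 1.0)
            h = sigmoid(xb @ W)
            hb = np.append(h, 1.0)
            o = sigmoid(hb @ V)
            delta_o = (Y[i] - o) * o * (1.0 - o)
            delta_h = (V[:-1] @ delta_o) * h * (1.0 - h)
            V += lr * np.outer(hb, delta_o)
            W += lr * np.outer(xb, delta_h)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(V))):
            raise TrainingDivergedError(epoch)
        H = sigmoid(Xeb @ W)
        O = sigmoid(np.column_stack([H, np.ones(len(H))]) @ V)
        sse_trace.append(float(np.sum((Ye - O) ** 2)))

    trace = TrainingTrace(
        sse=sse_trace,
        final_rmse=rmse_from_sse(sse_trace[-1], len(Xe)),
        n_eval_cases=len(Xe),
    )
    return st, trace


def rmse_from_sse(sse: float, n_cases: int) -> float:
    """RMSE convention used throughout: sqrt(SSE / number of cases)."""
    return math.sqrt(sse / n_cases)


@dataclass
class EvaluationResult:
    predictions_scaled: np.ndarray
    predictions: np.ndarray
    sse: float
    rmse: float


def evaluate(
    state: NetworkState,
    features: np.ndarray,
    targets: np.ndarray,
    scaling: ScalingSpec | None = None,
) -> EvaluationResult:
    """Predictions plus SSE/RMSE on the scaled response.

    ``scaling`` (fitted on the targets) supplies the inverse transform for
    raw-scale predictions; if omitted, raw predictions equal scaled ones.
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    O = forward_batch(state, X)
    if O.shape != Y.shape:
        raise ScalingError("prediction/target shape mismatch")
    sse = float(np.sum((Y - O) ** 2))
    preds_raw = scaling.inverse(O) if scaling is not None else O.copy()
    return EvaluationResult(
        predictions_scaled=O,
        predictions=preds_raw,
        sse=sse,
        rmse=rmse_from_sse(sse, len(X)),
    )


@dataclass
class SweepCell:
    learning_rate: float
    n_hidden: int
    trace: TrainingTrace | None
    error: str | None = None


def sensitivity_sweep(
    features: np.ndarray,
    targets: np.ndarray,
    learning_rates: Iterable[float],
    hidden_sizes: Iterable[int],
    config: NetworkConfig,
) -> Dict[Tuple[float, int], SweepCell]:
    """Full train/evaluate per (learning rate, hidden size) grid cell.

    All cells share one training split (drawn from the base config seed);
    each cell's weight initialisation uses a seed derived from the base
    seed and its grid position.  Per-cell failures are captured, not raised.
    """
    learning_rates = list(learning_rates)
    hidden_sizes = list(hidden_sizes)
    if not learning_rates or not hidden_sizes:
        raise ConfigError("sweep grids must be nonempty")
    config.validate()
    X = np.asarray(features, dtype=float)

    # The data stream (per-epoch multisets and visit orders) is a pure
    # function of config.seed and train_sample_size, so giving every cell
    # the base seed for training shares the split sequence exactly; only
    # the weight initialisation varies per cell.
    results: Dict[Tuple[float, int], SweepCell] = {}
    for li, lr in enumerate(learning_rates):
        for hi, nh in enumerate(hidden_sizes):
            cell_cfg = NetworkConfig(
                **{**asdict(config), "learning_rate": lr, "n_hidden": nh}
            )
            is_base = (lr, nh) == (config.learning_rate, config.n_hidden)
            init_cfg = cell_cfg
            if not is_base:
                init_seed = int(
                    np.random.SeedSequence([config.seed, li, hi]).generate_state(1)[0]
                    % (2**31)
                )
                init_cfg = NetworkConfig(**{**asdict(cell_cfg), "seed": init_seed})
            try:
                st = init_network(init_cfg)
                _, trace = train(st, X, targets, cell_cfg)
                results[(lr, nh)] = SweepCell(lr, nh, trace)
            except Exception as exc:  # per-cell isolation
                results[(lr, nh)] = SweepCell(lr, nh, None, error=repr(exc))
    return results


def sweep_table(results: Dict[Tuple[float, int], SweepCell]) -> pd.DataFrame:
    """Tidy long-format table: learning_rate, n_hidden, epoch, sse."""
    rows = []
    for (lr, nh), cell in results.items():
        if cell.trace is None:
            continue
        for epoch, sse in enumerate(cell.trace.sse, start=1):
            rows.append({"learning_rate": lr, "n_hidden": nh, "epoch": epoch, "sse": sse})
    return pd.DataFrame(rows)


def plot_trace(trace: TrainingTrace, path) -> None:
    """SSE-vs-epoch curve (optional artefact; mirrors the usual learning plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    epochs = np.arange(1, len(trace.sse) + 1)
    ax.fill_between(epochs, trace.sse, color="#9ecae1", alpha=0.6)
    ax.plot(epochs, trace.sse, color="#3182bd", lw=1.5)
    ax.set_xlabel("epoch")
    ax.set_ylabel("summed squared error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
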