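"""Supervised windowing and recursive multi-step forecasting.

A one-step predictor maps the previous ``n`` daily values of a comprehensive
index to the next day's value (default n = 7, matching the weekly reporting
cycle).  Multi-step (τ-step) forecasts iterate the one-step model: each
prediction is appended to the window and the oldest value dropped, so after
n steps the input contains no observed values at all.  Forecasting operates
on the normalised index scale — the same min–max bounds the clustering uses
— so forecasts can be classified into risk levels directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._recurrent import (
    GRURegressor,
    LSTMRegressor,
    PersistencePredictor,
    RecurrentRegressor,
    SimpleRNNRegressor,
)

#: Architecture name → regressor class.  Short and long names both accepted.
ARCHITECTURES = {
    "rnn": SimpleRNNRegressor,
    "simple-recurrent": SimpleRNNRegressor,
    "gru": GRURegressor,
    "gated-recurrent": GRURegressor,
    "lstm": LSTMRegressor,
    "long-short-term-memory": LSTMRegressor,
}

#: Canonical sub-model lineup for the voting ensemble.
SUBMODEL_NAMES: tuple[str, ...] = ("rnn", "gru", "lstm")


@dataclass(frozen=True)
class ForecastConfig:
    """Training configuration for one recurrent sub-model."""

    window_n: int = 7
    horizon_tau: int = 7
    architecture: str = "lstm"
    hidden_units: int = 32
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0
    clip_norm: float = 5.0
    input_noise: float = 0.03

    def __post_init__(self) -> None:
        if self.window_n < 1 or self.horizon_tau < 0:
            raise ValueError("window_n >= 1 and horizon_tau >= 0 required")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass(frozen=True)
class WindowedDataset:
    """Chronological (window, next-value) pairs for one index series."""

    X: np.ndarray  # (m, n) input windows
    y: np.ndarray  # (m,) next-day targets
    window_n: int
    start_indices: np.ndarray  # index of each window's first day in the series

    def __len__(self) -> int:
        return len(self.X)


def make_windows(series: Sequence[float] | np.ndarray, n: int) -> WindowedDataset:
    """Slide a length-n window over a series: exactly len(series) − n pairs.

    Pair t has inputs days t..t+n−1 and target day t+n; windows are strictly
    chronological, so excising a suffix of the series only removes pairs, it
    never alters the remaining ones.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) <= n:
        raise ValueError(f"series of length {len(x)} too short for window {n}")
    m = len(x) - n
    X = np.lib.stride_tricks.sliding_window_view(x, n)[:m].copy()
    y = x[n:].copy()
    return WindowedDataset(X=X, y=y, window_n=n, start_indices=np.arange(m))


def train_submodel(data: WindowedDataset, config: ForecastConfig) -> RecurrentRegressor:
    """Fit one recurrent one-step predictor; deterministic given the seed."""
    cls = ARCHITECTURES[config.architecture]
    model = cls(
        hidden_units=config.hidden_units,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
        clip_norm=config.clip_norm,
        input_noise=config.input_noise,
    )
    model.fit(data.X, data.y)
    model.window_n = data.window_n
    return model


def recursive_forecast(model, history: Sequence[float] | np.ndarray, tau: int) -> np.ndarray:
    """τ-step forecast by iterating a one-step predictor.

    Step 1 uses the observed history; each later step appends the previous
    prediction and drops the oldest value, so beyond the window length the
    input is fully synthetic.  ``tau = 0`` returns an empty array.
    """
    window = np.asarray(history, dtype=float).ravel().copy()
    if tau < 0:
        raise ValueError("tau must be >= 0")
    expected = getattr(model, "window_n", None)
    if expected is not None and len(window) != expected:
        raise ValueError(f"history length {len(window)} != model window {expected}")
    preds = np.empty(tau)
    for s in range(tau):
        yhat = float(np.asarray(model.predict(window[None, :])).ravel()[0])
        preds[s] = yhat
        window = np.concatenate([window[1:], [yhat]])
    return preds


def persistence_model() -> PersistencePredictor:
    """The naive last-value baseline used for comparison."""
    return PersistencePredictor()
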