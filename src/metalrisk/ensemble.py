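"""Voting ensemble: convex combination of sub-model forecasts.

The combined forecast on day t is ``h_t = Σ_i w_i ζ_i(X)`` with weights on
the simplex (non-negative, summing to one).  Weights are selected by
exhaustively searching a rational simplex grid for the vector maximising the
risk-level prediction accuracy

    PA = (1/T) Σ_t I(K(h_t) = K(y_t)),

where K classifies a (NIPI, TCR, THQ) triple to its nearest cluster center.
PA is piecewise constant in the weights, so a grid search at a modest step is
both exact up to grid resolution and exactly reproducible.  Ties on PA break
to the candidate with the lower mean squared error, then lexicographically.
Point forecasts are additionally scored with RMSE and MAE.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd

from .risklevels import ClusterModel


@dataclass(frozen=True)
class VotingWeights:
    """Simplex weights over the sub-models, on a rational grid."""

    weights: tuple[float, ...]
    grid_step: float = 0.05
    pa: float = float("nan")  # accuracy attained on the optimization window

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")


def simplex_grid(n_models: int, step: float) -> np.ndarray:
    """All weight vectors with entries i/m, i integer, summing to one.

    For m = 1/step the count is C(m + n_models − 1, n_models − 1)
    (stars and bars): 66 vectors for 3 models at step 0.1, 231 at 0.05.
    """
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"grid step {step} does not divide 1")
    out = []
    for cuts in combinations_with_replacement(range(m + 1), n_models - 1):
        parts = np.diff((0, *cuts, m))
        out.append(parts / m)
    return np.asarray(out)


def vote_combine(
    sub_forecasts: Sequence[np.ndarray], weights: VotingWeights | Sequence[float]
) -> np.ndarray:
    """Pointwise convex combination of aligned sub-model forecasts.

    Each element of ``sub_forecasts`` may be a 1-D series or a 2-D
    (days × indexes) array; all must share one shape.
    """
    w = np.asarray(
        weights.weights if isinstance(weights, VotingWeights) else weights, dtype=float
    )
    if len(w) != len(sub_forecasts):
        raise ValueError("one weight per sub-model required")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must lie on the simplex")
    arrs = [np.asarray(f, dtype=float) for f in sub_forecasts]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("sub-forecast shapes do not align")
    return np.tensordot(w, np.stack(arrs), axes=1)


def level_indicator(
    forecast_triple: np.ndarray, actual_triple: np.ndarray, model: ClusterModel
) -> int:
    """1 iff the forecast day classifies to the same risk level as the actual day."""
    return int(model.classify(forecast_triple)[0] == model.classify(actual_triple)[0])


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean square error; always ≥ MAE on the same input."""
    a, p = np.asarray(actual, dtype=float), np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("rmse needs equally-shaped non-empty inputs")
    return float(np.sqrt(((a - p) ** 2).mean()))


def mae(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute error."""
    a, p = np.asarray(actual, dtype=float), np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("mae needs equally-shaped non-empty inputs")
    return float(np.abs(a - p).mean())


def prediction_accuracy(indicators: Sequence[int]) -> float:
    """Fraction of forecast days whose predicted level matches the actual one."""
    ind = np.asarray(indicators, dtype=float)
    if ind.size == 0:
        raise ValueError("no prediction days")
    return float(ind.mean())


def _levels_of(points: np.ndarray, model: ClusterModel) -> np.ndarray:
    return np.array([model.classify(p)[0] for p in np.atleast_2d(points)])


def optimize_weights(
    sub_forecasts: Sequence[np.ndarray],
    actuals: np.ndarray,
    cluster_model: ClusterModel,
    grid_step: float = 0.05,
) -> VotingWeights:
    """Exhaustive simplex-grid search for the accuracy-maximising weights.

    ``sub_forecasts`` holds one (days × 3) normalized forecast array per
    sub-model; ``actuals`` the matching observed triples.  Selection: highest
    level-prediction accuracy, then lowest mean squared error, then
    lexicographic weight order (so the result is unique and reproducible).
    """
    actuals = np.asarray(actuals, dtype=float)
    if actuals.ndim != 2 or len(actuals) == 0:
        raise ValueError("empty evaluation window")
    stack = np.stack([np.asarray(f, dtype=float) for f in sub_forecasts])
    if stack.shape[1:] != actuals.shape:
        raise ValueError("forecast/actual shapes do not align")
    actual_levels = _levels_of(actuals, cluster_model)
    grid = simplex_grid(len(sub_forecasts), grid_step)
    best: tuple[float, float, tuple[float, ...]] | None = None
    best_w = None
    for w in grid:
        combined = np.tensordot(w, stack, axes=1)
        pa = float((_levels_of(combined, cluster_model) == actual_levels).mean())
        mse = float(((combined - actuals) ** 2).mean())
        key = (-pa, mse, tuple(w))
        if best is None or key < best:
            best = key
            best_w = w
    return VotingWeights(weights=tuple(best_w), grid_step=grid_step, pa=-best[0])


@dataclass
class EvaluationReport:
    """Scores per model × dataset × index × horizon, in long format."""

    errors: pd.DataFrame  # rows (model, metric, horizon) cols (dataset, index)
    accuracy: pd.DataFrame  # rows (model, horizon) cols dataset, plus mean
    weights: dict[str, VotingWeights]  # per dataset

    def __post_init__(self) -> None:
        rm = self.errors.xs("rmse", level="metric")
        ma = self.errors.xs("mae", level="metric")
        if (rm.to_numpy() + 1e-12 < ma.to_numpy()).any():
            raise ValueError("rmse < mae: scoring inconsistency")
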