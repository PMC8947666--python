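"""End-to-end early-warning pipeline.

Chains the stages: detection records → preprocessing → daily summaries →
per-metal indexes → entropy-weight fusion → risk-level clustering → recurrent
sub-model training → voting-ensemble evaluation.  Entropy weights,
normalization bounds and the cluster model are fitted on the training portion
of the series only and frozen afterwards, so no test-period information leaks
into them or into the forecast training windows.

Evaluation follows a 21-day protocol on three dataset splits: two share the
80/20 training ratio with different 21-day test windows, the third shares the
second's test window with a shorter (70%-length) training span.  Forecast
quality is reported per index as RMSE/MAE at 7/14/21 days, and as the
risk-level prediction accuracy (PA) per horizon, for each sub-model, the
accuracy-optimised voting ensemble and a naive persistence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .config import ConsumptionTable, ToxicologyParams
from .ensemble import (
    EvaluationReport,
    VotingWeights,
    mae,
    optimize_weights,
    prediction_accuracy,
    rmse,
    vote_combine,
)
from .exposure import assess_series
from .forecast import (
    SUBMODEL_NAMES,
    ForecastConfig,
    make_windows,
    persistence_model,
    recursive_forecast,
    train_submodel,
)
from .fusion import EntropyWeights, entropy_weights, fuse_series
from .ingest import preprocess, summarize_daily
from .records import INDEX_TYPES
from .risklevels import ClusterModel, apply_bounds, fit_cluster_model, level_distribution
from .synthetic import GeneratorConfig, generate

EVAL_STEP = 21  # evaluation step length (days); horizons reported at 7/14/21
HORIZONS: tuple[int, ...] = (7, 14, 21)


@dataclass
class DatasetSplit:
    """One train/test split: train [train_start, test_start), 21-day test."""

    name: str
    train_start: int
    test_start: int

    def test_end(self) -> int:
        return self.test_start + EVAL_STEP


def default_splits(n_days: int, train_frac: float = 0.8) -> list[DatasetSplit]:
    """The three evaluation splits over a series of ``n_days`` fused days."""
    if n_days < EVAL_STEP * 3:
        raise ValueError(f"series too short for the 21-day protocol: {n_days}")
    t2 = int(round(train_frac * n_days))
    t2 = min(t2, n_days - EVAL_STEP)
    t1 = int(round(train_frac * (n_days - EVAL_STEP)))
    t1 = min(t1, t2 - 1)
    d3_start = max(0, t2 - int(round(0.7 * n_days)))
    return [
        DatasetSplit("Dataset1", 0, t1),
        DatasetSplit("Dataset2", 0, t2),
        DatasetSplit("Dataset3", d3_start, t2),
    ]


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    index_matrix: pd.DataFrame  # days × 9 per-metal indexes
    weights: EntropyWeights
    comprehensive: pd.DataFrame  # days × (nipi, tcr, thq)
    normalized: pd.DataFrame  # same, min–max normalised with training bounds
    cluster_model: ClusterModel
    levels: pd.DataFrame  # per-day level + distance
    level_proportions: dict[str, float]
    regime_agreement: float  # adjusted Rand index vs true regimes (synthetic)
    report: EvaluationReport
    true_regimes: pd.Series | None = None

    @property
    def selected_k(self) -> int:
        return self.cluster_model.k

    def pa(self, model: str, horizon: int = 7) -> float:
        """Mean risk-level prediction accuracy over the three datasets."""
        return float(self.report.accuracy.loc[(model, horizon), "mean"])


def _forecast_matrix(models: Mapping[str, object], history: np.ndarray, tau: int) -> np.ndarray:
    """Stack per-index recursive forecasts into a (tau, 3) array."""
    cols = [recursive_forecast(models[t], history[:, j], tau) for j, t in enumerate(INDEX_TYPES)]
    return np.column_stack(cols)


def evaluate_splits(
    normalized: pd.DataFrame,
    cluster_model: ClusterModel,
    splits: Sequence[DatasetSplit],
    forecast_config: ForecastConfig,
    grid_step: float = 0.05,
) -> EvaluationReport:
    """Train sub-models per split and score them, the ensemble and persistence.

    Voting weights are chosen per split on the final 21 days of its training
    segment (never on test data), by maximising level-prediction accuracy.
    """
    n = forecast_config.window_n
    values = normalized.to_numpy(dtype=float)
    err_rows: dict = {}
    acc_rows: dict = {}
    chosen: dict[str, VotingWeights] = {}

    for split in splits:
        train = values[split.train_start : split.test_start]
        test = values[split.test_start : split.test_end()]
        if len(test) < EVAL_STEP:
            raise ValueError(f"{split.name}: test window shorter than {EVAL_STEP} days")

        # per-architecture, per-index one-step models
        models: dict[str, dict[str, object]] = {}
        for arch_i, arch in enumerate(SUBMODEL_NAMES):
            per_index: dict[str, object] = {}
            for j, t in enumerate(INDEX_TYPES):
                cfg = ForecastConfig(
                    window_n=n,
                    horizon_tau=EVAL_STEP,
                    architecture=arch,
                    hidden_units=forecast_config.hidden_units,
                    epochs=forecast_config.epochs,
                    learning_rate=forecast_config.learning_rate,
                    seed=forecast_config.seed + 97 * arch_i + 11 * j,
                    clip_norm=forecast_config.clip_norm,
                    input_noise=forecast_config.input_noise,
                )
                per_index[t] = train_submodel(make_windows(train[:, j], n), cfg)
            models[arch] = per_index

        # weight selection on the last 21 training days
        opt_start = split.test_start - EVAL_STEP
        opt_hist = values[opt_start - n : opt_start]
        opt_actual = values[opt_start : split.test_start]
        opt_fc = [
            _forecast_matrix(models[arch], opt_hist, EVAL_STEP) for arch in SUBMODEL_NAMES
        ]
        w = optimize_weights(opt_fc, opt_actual, cluster_model, grid_step)
        chosen[split.name] = w

        # test-window forecasts
        hist = values[split.test_start - n : split.test_start]
        fc: dict[str, np.ndarray] = {
            arch: _forecast_matrix(models[arch], hist, EVAL_STEP) for arch in SUBMODEL_NAMES
        }
        fc["voting-ensemble"] = vote_combine([fc[a] for a in SUBMODEL_NAMES], w)
        pers = persistence_model()
        fc["persistence"] = np.column_stack(
            [recursive_forecast(pers, hist[:, j], EVAL_STEP) for j in range(hist.shape[1])]
        )

        actual_levels = [cluster_model.classify(p)[0] for p in test]
        for name, pred in fc.items():
            pred_levels = [cluster_model.classify(p)[0] for p in pred]
            hits = [int(a == b) for a, b in zip(pred_levels, actual_levels)]
            for h in HORIZONS:
                acc_rows.setdefault((name, h), {})[split.name] = prediction_accuracy(
                    hits[:h]
                )
                for j, t in enumerate(INDEX_TYPES):
                    err_rows.setdefault((name, "rmse", h), {})[(split.name, t)] = rmse(
                        test[:h, j], pred[:h, j]
                    )
                    err_rows.setdefault((name, "mae", h), {})[(split.name, t)] = mae(
                        test[:h, j], pred[:h, j]
                    )

    errors = pd.DataFrame.from_dict(err_rows, orient="index")
    errors.index = pd.MultiIndex.from_tuples(errors.index, names=["model", "metric", "horizon"])
    errors.columns = pd.MultiIndex.from_tuples(errors.columns, names=["dataset", "index"])
    errors = errors.sort_index()
    accuracy = pd.DataFrame.from_dict(acc_rows, orient="index")
    accuracy.index = pd.MultiIndex.from_tuples(accuracy.index, names=["model", "horizon"])
    accuracy = accuracy.sort_index()
    accuracy["mean"] = accuracy.mean(axis=1)
    return EvaluationReport(errors=errors, accuracy=accuracy, weights=chosen)


def run_pipeline(
    seed: int = 0,
    n_days: int = 300,
    generator_config: GeneratorConfig | None = None,
    forecast_config: ForecastConfig | None = None,
    tox: ToxicologyParams | None = None,
    consumption: ConsumptionTable | None = None,
    train_frac: float = 0.8,
    k_candidates: Sequence[int] = (3, 4, 5, 6, 7),
    grid_step: float = 0.05,
) -> PipelineResult:
    """Run the whole early-warning pipeline on a synthetic dataset.

    All randomness (generator, clustering restarts, network initialisation)
    flows from ``seed``; two runs with the same arguments are bit-identical.
    """
    tox = tox or ToxicologyParams()
    consumption = consumption or ConsumptionTable()
    gen = generator_config or GeneratorConfig(seed=seed, n_days=n_days)
    fcfg = forecast_config or ForecastConfig(seed=seed)

    records, truth = generate(gen)
    pre = preprocess(records, tox.inorganic_as_ratio)
    summaries = summarize_daily(pre, tox.limit_s)
    index_matrix = assess_series(summaries, tox, consumption)

    n_obs = len(index_matrix)
    ntrain = int(round(train_frac * n_obs))
    weights = entropy_weights(index_matrix.iloc[:ntrain])
    comprehensive = fuse_series(index_matrix, weights)

    cluster_model = fit_cluster_model(
        comprehensive.iloc[:ntrain], k_candidates=k_candidates, seed=seed
    )
    normalized = apply_bounds(comprehensive, cluster_model.norm_bounds)
    levels = cluster_model.classify_frame(normalized)
    props = level_distribution(levels["level"], all_levels=cluster_model.level_names)

    truth_aligned = truth.reindex(comprehensive.index)
    ari = float(adjusted_rand_score(truth_aligned.to_numpy(), levels["level"].to_numpy()))

    splits = default_splits(n_obs, train_frac)
    report = evaluate_splits(normalized, cluster_model, splits, fcfg, grid_step)

    return PipelineResult(
        index_matrix=index_matrix,
        weights=weights,
        comprehensive=comprehensive,
        normalized=normalized,
        cluster_model=cluster_model,
        levels=levels,
        level_proportions=props,
        regime_agreement=ari,
        report=report,
        true_regimes=truth_aligned,
    )
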