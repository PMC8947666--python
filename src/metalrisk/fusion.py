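"""Entropy-weight fusion of the nine per-metal indexes.

The nine daily indexes (three metals × NIPI/TCR/THQ) are reduced to three
comprehensive indexes with data-driven entropy weights: indicators that vary
more across days carry more information and receive larger weights.

For a days × indicators matrix X with non-negative entries:

    p_tj = x_tj / Σ_t x_tj                (column proportions, 0·ln 0 ≡ 0)
    e_j  = -(1/ln n) · Σ_t p_tj ln p_tj   (normalised Shannon entropy)
    w_j  = (1 - e_j) / Σ_k (1 - e_k)      (entropy weights, sum to 1)

Fusion (default mode) renormalises, within each index type, the three
per-metal weights to sum to one, so each comprehensive index is a convex
combination of that index's three per-metal values.  A ``global`` mode using
the raw nine weights without renormalisation is available for sensitivity
checks, and user-supplied subjective weights can be multiplied in (the
analytic-hierarchy half of a combined subjective/objective weighting).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .records import INDEX_TYPES, IndexTriple


@dataclass(frozen=True)
class EntropyWeights:
    """Nine entropy weights keyed by (metal, index type), plus sub-weights.

    ``weights`` sums to one over all nine entries; for every index type the
    renormalised three-metal sub-vector in ``sub_weights`` also sums to one.
    """

    weights: pd.Series  # MultiIndex (metal, index) -> weight

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < -1e-12).any():
            raise ValueError("entropy weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"entropy weights must sum to 1, got {w.sum()}")

    def sub_weights(self, index_type: str) -> pd.Series:
        """Per-metal weights of one index type, renormalised to sum to one."""
        block = self.weights.xs(index_type, level="index")
        total = float(block.sum())
        if total <= 0:
            # no information in this index type: fall back to equal weights
            return pd.Series(1.0 / len(block), index=block.index)
        return block / total

    def apply_subjective(self, subjective: Mapping[tuple[str, str], float]) -> "EntropyWeights":
        """Multiply user-supplied subjective weights in and renormalise."""
        w = self.weights.copy()
        for key, v in subjective.items():
            if not v >= 0:
                raise ValueError("subjective weights must be non-negative")
            w.loc[key] = w.loc[key] * v
        total = float(w.sum())
        if total <= 0:
            raise ValueError("subjective weights annihilate all entropy weight")
        return EntropyWeights(weights=w / total)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f"{m}.{t}": float(self.weights.loc[(m, t)])
            for m, t in self.weights.index
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EntropyWeights":
        data = yaml.safe_load(Path(path).read_text())
        idx = pd.MultiIndex.from_tuples(
            [tuple(k.split(".", 1)) for k in data], names=["metal", "index"]
        )
        return cls(weights=pd.Series(list(data.values()), index=idx, dtype=float))


def entropy_weights(index_matrix: pd.DataFrame) -> EntropyWeights:
    """Entropy weights of a days × indicators matrix of non-negative values.

    Requires at least two days and at least one column with variation;
    constant columns (including all-zero columns) get zero weight.  Raises if
    every column is constant, since then no indicator carries information.
    """
    X = index_matrix.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 days to compute entropy weights")
    if (X < 0).any():
        raise ValueError("index matrix must be non-negative")

    colsum = X.sum(axis=0)
    e = np.ones(m)  # constant/all-zero columns -> entropy 1 -> weight 0
    for j in range(m):
        if colsum[j] <= 0:
            continue
        p = X[:, j] / colsum[j]
        nz = p > 0
        e[j] = -(p[nz] * np.log(p[nz])).sum() / np.log(n)
    d = 1.0 - e
    d[np.abs(d) < 1e-15] = 0.0
    if d.sum() <= 0:
        raise ValueError("all indicator columns are constant: zero total information")
    w = d / d.sum()
    return EntropyWeights(weights=pd.Series(w, index=index_matrix.columns))


def fuse(
    day_indexes: pd.Series,
    weights: EntropyWeights,
    mode: str = "per-index-renormalized",
) -> IndexTriple:
    """Fuse one day's nine indexes into a comprehensive (NIPI, TCR, THQ) triple.

    Default mode takes, per index type, the convex combination of the three
    per-metal values under the renormalised sub-weights; ``global`` mode uses
    the raw nine weights without renormalisation (so the three comprehensive
    values then sum to the full weighted combination of all nine indexes).
    """
    if not day_indexes.index.equals(weights.weights.index):
        day_indexes = day_indexes.reindex(weights.weights.index)
        if day_indexes.isna().any():
            raise ValueError("day indexes do not align with the weight vector")
    vals = {}
    for t in INDEX_TYPES:
        block = day_indexes.xs(t, level="index")
        if mode == "per-index-renormalized":
            w = weights.sub_weights(t)
        elif mode == "global":
            w = weights.weights.xs(t, level="index")
        else:
            raise ValueError(f"unknown fusion mode {mode!r}")
        vals[t] = float((block * w).sum())
    return IndexTriple(**vals)


def fuse_series(
    index_matrix: pd.DataFrame,
    weights: EntropyWeights,
    mode: str = "per-index-renormalized",
) -> pd.DataFrame:
    """Comprehensive (nipi, tcr, thq) per day for a whole index matrix."""
    mats = []
    for t in INDEX_TYPES:
        block = index_matrix.xs(t, axis=1, level="index")
        if mode == "per-index-renormalized":
            w = weights.sub_weights(t)
        elif mode == "global":
            w = weights.weights.xs(t, level="index")
        else:
            raise ValueError(f"unknown fusion mode {mode!r}")
        mats.append(block.to_numpy() @ w.reindex(block.columns).to_numpy())
    out = pd.DataFrame(
        np.column_stack(mats), index=index_matrix.index, columns=list(INDEX_TYPES)
    )
    if (out.to_numpy() < 0).any():
        raise ValueError("negative comprehensive index produced")
    return out
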