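"""Data-driven risk levels via K-means++ over the comprehensive indexes.

The daily comprehensive (NIPI, TCR, THQ) triples are min–max normalised to
[0, 1]³ and clustered with K-means++ (distance-squared-proportional seeding,
Lloyd iterations, best of several restarts).  The cluster count is chosen by
the average silhouette coefficient; fitted centers are ordered by Euclidean
distance to the origin and mapped to risk-level names — a longer distance
means a higher integrated risk.  Any day (observed or forecast) is then
classified to the level of its nearest center, a dynamic threshold rather
than fixed cut-offs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: Level names for the operating point k = 4, lowest risk first.
RISK_LEVEL_NAMES_K4: tuple[str, ...] = (
    "Low-Risk",
    "Medium-Risk",
    "Second-Highest Risk",
    "High-Risk",
)


def minmax_normalize(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each index column to [0, 1] via (x − min)/(max − min).

    Returns the normalised frame and a bounds frame (rows ``min``/``max``)
    used to normalise forecasts onto the same scale and to invert the
    transform.  Raises on constant columns.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 days to normalize")
    lo = series.min(axis=0)
    hi = series.max(axis=0)
    flat = hi - lo
    if (flat <= 0).any():
        bad = list(series.columns[(flat <= 0).to_numpy()])
        raise ValueError(f"constant index column(s): {bad}")
    norm = (series - lo) / flat
    bounds = pd.DataFrame({"min": lo, "max": hi}).T
    return norm, bounds


def apply_bounds(series: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Normalise new data with previously fitted min–max bounds."""
    lo, hi = bounds.loc["min"], bounds.loc["max"]
    return (series - lo) / (hi - lo)


def invert_bounds(series: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`apply_bounds` (back to the raw index scale)."""
    lo, hi = bounds.loc["min"], bounds.loc["max"]
    return series * (hi - lo) + lo


def kmeanspp_seed(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means++ seeding: k initial centers drawn from the sample points.

    The first center is uniform over the samples; each subsequent center is a
    sample drawn with probability proportional to its squared distance to the
    nearest already-chosen center.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k > len(np.unique(points, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct points")
    centers = np.empty((k, points.shape[1]))
    idx = rng.integers(n)
    centers[0] = points[idx]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining mass on already-chosen centers
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[i] = points[idx]
        d2 = np.minimum(d2, ((points - centers[i]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    points: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations until the assignment reaches a fixpoint.

    Empty clusters are repaired by re-seeding the center to the point
    farthest from its currently assigned center, keeping k fixed.
    """
    centers = centers.copy()
    labels = np.full(len(points), -1)
    for _ in range(max_iter):
        dist = cdist(points, centers)
        new_labels = dist.argmin(axis=1)
        for j in range(len(centers)):
            if not (new_labels == j).any():
                worst = dist[np.arange(len(points)), new_labels].argmax()
                centers[j] = points[worst]
                new_labels[worst] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(len(centers)):
            members = points[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    dist = cdist(points, centers)
    labels = dist.argmin(axis=1)
    inertia = float((dist[np.arange(len(points)), labels] ** 2).sum())
    return centers, labels, inertia


def kmeans_fit(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 10,
    tol: float = 1e-12,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts K-means++: returns (centers, labels, inertia).

    Each restart runs Lloyd iterations from fresh K-means++ seeds; the run
    with the smallest within-cluster sum of squares wins.
    """
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(points) < k:
        raise ValueError("fewer points than clusters")
    rng = np.random.default_rng(rng)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        seeds = kmeanspp_seed(points, k, rng)
        centers, labels, inertia = _lloyd(points, seeds, max_iter, tol)
        if best is None or inertia < best[2] - 0.0:
            best = (centers, labels, inertia)
    assert best is not None
    return best


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette values s_j and their average SC.

    s_j = (b_j − a_j)/max(a_j, b_j) with a_j the mean distance to the other
    members of j's cluster and b_j the smallest mean distance to any other
    cluster.  Members of singleton clusters get s_j = 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(points, points)
    n = len(points)
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s, float(s.mean())


def select_k(silhouette_by_k: Mapping[int, float]) -> int:
    """The k with the largest average silhouette; ties go to the smaller k."""
    if not silhouette_by_k:
        raise ValueError("no candidate cluster counts")
    best_k, best_sc = None, -np.inf
    for k in sorted(silhouette_by_k):
        sc = silhouette_by_k[k]
        if sc > best_sc:
            best_k, best_sc = k, sc
    return int(best_k)


def scan_k(
    points: np.ndarray,
    k_candidates: Sequence[int] = (3, 4, 5, 6, 7),
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 10,
) -> dict[int, float]:
    """Average silhouette of a K-means++ fit for each candidate k."""
    rng = np.random.default_rng(rng)
    scores: dict[int, float] = {}
    for k in k_candidates:
        _, labels, _ = kmeans_fit(points, k, rng, n_restarts=n_restarts)
        scores[k] = silhouette(points, labels)[1]
    return scores


def order_levels(centers: np.ndarray) -> list[tuple[int, str, float]]:
    """Map cluster centers to risk levels by distance to the origin.

    Returns (center_index, level_name, distance) sorted by ascending norm —
    a longer distance to the origin means a higher integrated risk.  With
    k = 4 the canonical names Low / Medium / Second-Highest / High are used;
    otherwise generic "Level i".  Exact norm ties break lexicographically on
    the center coordinates.
    """
    centers = np.asarray(centers, dtype=float)
    norms = np.sqrt((centers**2).sum(axis=1))
    order = sorted(range(len(centers)), key=lambda i: (norms[i], tuple(centers[i])))
    if len(centers) == 4:
        names = RISK_LEVEL_NAMES_K4
    else:
        names = tuple(f"Level {i + 1}" for i in range(len(centers)))
    return [(int(i), names[rank], float(norms[i])) for rank, i in enumerate(order)]


@dataclass
class ClusterModel:
    """A fitted risk-level model: centers, bounds, ordering and provenance."""

    k: int
    centers: np.ndarray  # (k, 3) in normalized space
    norm_bounds: pd.DataFrame  # rows min/max, columns nipi/tcr/thq
    silhouette_by_k: dict[int, float]
    level_order: list[tuple[int, str, float]]  # (center index, name, norm)
    rng_seed: int
    inertia: float = float("nan")

    @property
    def level_names(self) -> list[str]:
        """Level names from lowest to highest risk."""
        return [name for _, name, _ in self.level_order]

    def level_of_center(self, center_index: int) -> str:
        for i, name, _ in self.level_order:
            if i == center_index:
                return name
        raise KeyError(center_index)

    def classify(self, point: np.ndarray) -> tuple[str, float]:
        """Risk level of one normalized (nipi, tcr, thq) point.

        Nearest-center assignment; exact distance ties are broken toward the
        lower-risk level.
        """
        point = np.asarray(point, dtype=float)
        best_name, best_d = None, np.inf
        for idx, name, _ in self.level_order:  # ascending risk
            d = float(np.linalg.norm(point - self.centers[idx]))
            if d < best_d:  # strict: earlier (lower) level wins ties
                best_name, best_d = name, d
        return best_name, best_d

    def classify_frame(self, normalized: pd.DataFrame) -> pd.DataFrame:
        """Classify every row; returns columns ``level`` and ``distance``."""
        pts = normalized.to_numpy(dtype=float)
        dist = cdist(pts, self.centers)
        # reorder columns so argmin ties resolve toward lower risk
        order_idx = [i for i, _, _ in self.level_order]
        d_ord = dist[:, order_idx]
        pick = d_ord.argmin(axis=1)
        names = np.array(self.level_names)[pick]
        return pd.DataFrame(
            {"level": names, "distance": d_ord[np.arange(len(pts)), pick]},
            index=normalized.index,
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "k": self.k,
            "centers": self.centers.tolist(),
            "norm_bounds": {
                "columns": list(self.norm_bounds.columns),
                "min": self.norm_bounds.loc["min"].tolist(),
                "max": self.norm_bounds.loc["max"].tolist(),
            },
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "level_order": [[i, name, d] for i, name, d in self.level_order],
            "rng_seed": self.rng_seed,
            "inertia": self.inertia,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        data = json.loads(Path(path).read_text())
        nb = data["norm_bounds"]
        bounds = pd.DataFrame(
            [nb["min"], nb["max"]], index=["min", "max"], columns=nb["columns"]
        )
        return cls(
            k=data["k"],
            centers=np.asarray(data["centers"], dtype=float),
            norm_bounds=bounds,
            silhouette_by_k={int(k): v for k, v in data["silhouette_by_k"].items()},
            level_order=[(int(i), name, float(d)) for i, name, d in data["level_order"]],
            rng_seed=int(data["rng_seed"]),
            inertia=float(data["inertia"]),
        )


def fit_cluster_model(
    comprehensive: pd.DataFrame,
    k_candidates: Sequence[int] = (3, 4, 5, 6, 7),
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterModel:
    """Normalise a comprehensive series, pick k by silhouette and fit.

    All randomness flows from ``seed``; the silhouette scan and the final fit
    use independent streams derived from it so the chosen k does not perturb
    the final centers.
    """
    norm, bounds = minmax_normalize(comprehensive)
    pts = norm.to_numpy(dtype=float)
    scores = scan_k(pts, k_candidates, np.random.default_rng(seed), n_restarts)
    k = select_k(scores)
    centers, _, inertia = kmeans_fit(
        pts, k, np.random.default_rng(seed + 1), n_restarts=n_restarts
    )
    return ClusterModel(
        k=k,
        centers=centers,
        norm_bounds=bounds,
        silhouette_by_k=scores,
        level_order=order_levels(centers),
        rng_seed=seed,
        inertia=inertia,
    )


def level_distribution(levels: Sequence[str], all_levels: Sequence[str] | None = None) -> dict[str, float]:
    """Proportion of days at each risk level (sums to one).

    ``all_levels`` forces zero entries for levels that never occur.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("empty risk-level series")
    keys = list(all_levels) if all_levels is not None else sorted(set(levels))
    counts = {k: 0 for k in keys}
    for lv in levels:
        if lv not in counts:
            counts[lv] = 0
        counts[lv] += 1
    n = len(levels)
    return {k: v / n for k, v in counts.items()}
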