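"""Independent exhaustive-enumeration oracle for tiny k-means instances.

Enumerates every labeling of n points into k clusters (k^n of them, so keep
n ≤ 8, k ≤ 3), places each cluster's center at its mean, and returns the
minimum within-cluster sum of squares.  Fully independent of the Lloyd
implementation it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_wcss(points: np.ndarray, k: int) -> float:
    points = np.asarray(points, dtype=float)
    n = len(points)
    labelings = np.array(list(itertools.product(range(k), repeat=n)))  # (L, n)
    onehot = np.eye(k)[labelings]  # (L, n, k)
    counts = onehot.sum(axis=1)  # (L, k)
    sums = np.einsum("lnk,nd->lkd", onehot, points)  # (L, k, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        centers = sums / counts[:, :, None]
    centers = np.nan_to_num(centers)  # empty clusters contribute nothing
    assigned = np.take_along_axis(
        centers, labelings[:, :, None].repeat(points.shape[1], axis=2), axis=1
    )  # (L, n, d)
    wcss = ((points[None, :, :] - assigned) ** 2).sum(axis=(1, 2))
    return float(wcss.min())
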