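"""K-centers clustering of projected conformations.

Greedy farthest-point traversal: the first center is a caller-chosen
frame, each subsequent center the frame farthest from its nearest
existing center. The covering radius of the greedy solution is at most
twice the optimal k-centers radius, a guarantee the tests check against
exhaustive search. Assignment of new data (e.g. a second dataset
projected onto shared clusters) labels each frame by its nearest center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["MicrostateModel", "kcenters", "assign"]


@dataclass
class MicrostateModel:
    centers: np.ndarray  # (k, m) coordinates, rows are input frames
    center_frame_indices: np.ndarray  # frame index of each center
    k: int
    seed_index: int
    max_radius: float


def kcenters(points: np.ndarray, k: int, seed_index: int = 0) -> MicrostateModel:
    """Greedy K-centers with deterministic ties (lowest frame index wins)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if not 0 <= seed_index < n:
        raise ValueError("seed_index out of range")
    center_idx = np.empty(k, dtype=int)
    center_idx[0] = seed_index
    dist = np.linalg.norm(points - points[seed_index], axis=1)
    for j in range(1, k):
        nxt = int(np.argmax(dist))  # argmax returns the lowest tied index
        center_idx[j] = nxt
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return MicrostateModel(
        centers=points[center_idx].copy(),
        center_frame_indices=center_idx,
        k=k,
        seed_index=seed_index,
        max_radius=float(dist.max()),
    )


def assign(
    model: MicrostateModel, points: np.ndarray, chunk: int = 100_000
) -> np.ndarray:
    """Label each frame by its nearest center (ties: lowest center index)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {points.shape[1]} coordinates, "
            f"centers {model.centers.shape[1]}"
        )
    labels = np.empty(len(points), dtype=np.int64)
    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        labels[start : start + len(block)] = cdist(block, model.centers).argmin(axis=1)
    return labels
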