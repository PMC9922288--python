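"""Point correspondences driving the registration cost.

Forward: every source vertex is paired with its nearest target vertex
(weight 0 for landmark vertices).  Reverse: a Poisson-disk subsample of
target vertices is paired with the nearest deformed-source vertex, pulling
the source toward target regions it would otherwise ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import SurfaceMesh

__all__ = [
    "CorrespondenceSet",
    "nearest_correspondences",
    "poisson_subsample",
    "reverse_correspondences",
]


@dataclass
class CorrespondenceSet:
    """Forward and reverse nearest-neighbor pairs for one solve.

    forward_targets : (n, 3) nearest target point per source vertex
    forward_weights : (n,) 0/1, zero exactly at landmark vertices
    reverse_source_idx : (k,) source vertex index per reverse pair
    reverse_targets : (k, 3) subsampled target positions
    """

    forward_targets: np.ndarray
    forward_weights: np.ndarray
    reverse_source_idx: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    reverse_targets: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


def _positions(obj) -> np.ndarray:
    return obj.vertices if isinstance(obj, SurfaceMesh) else np.asarray(obj, float)


def nearest_correspondences(deformed_source, target,
                            landmark_vertices=()) -> CorrespondenceSet:
    """Forward correspondences: nearest target vertex per source vertex."""
    src = _positions(deformed_source)
    tgt = _positions(target)
    if len(tgt) == 0:
        raise ValueError("empty target")
    if len(src) == 0:
        raise ValueError("empty source")
    tree = cKDTree(tgt)
    _, idx = tree.query(src, k=1)
    weights = np.ones(len(src))
    lm = np.asarray(list(landmark_vertices), dtype=np.int64)
    if lm.size:
        weights[lm] = 0.0
    return CorrespondenceSet(forward_targets=tgt[idx], forward_weights=weights)


def poisson_subsample(target, radius_fraction: float) -> np.ndarray:
    """Greedy maximal subset of target vertices with pairwise distance
    >= radius_fraction * (bounding-box diagonal).

    The greedy order is canonical (lexicographic by coordinates), so the
    result is independent of vertex storage order.
    """
    if not 0 < radius_fraction:
        raise ValueError("radius_fraction must be positive")
    pts = _positions(target)
    if len(pts) == 0:
        return np.empty(0, dtype=np.int64)
    diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    r = radius_fraction * diag
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    if r <= 0:
        return order  # degenerate geometry or zero radius: keep everything
    tree = cKDTree(pts)
    blocked = np.zeros(len(pts), dtype=bool)
    selected = []
    for i in order:
        if blocked[i]:
            continue
        selected.append(i)
        # tiny relative slack so points at exactly distance r are blocked
        blocked[tree.query_ball_point(pts[i], r * (1 + 1e-9))] = True
    return np.asarray(selected, dtype=np.int64)


def reverse_correspondences(subsample: np.ndarray, target,
                            deformed_source) -> tuple[np.ndarray, np.ndarray]:
    """For each subsampled target vertex, the nearest deformed-source vertex.

    Returns ``(source_indices, target_positions)``; a source vertex may
    appear multiple times.
    """
    subsample = np.asarray(subsample, dtype=np.int64)
    if subsample.size == 0:
        raise ValueError("empty subsample")
    tgt = _positions(target)[subsample]
    src = _positions(deformed_source)
    tree = cKDTree(src)
    _, idx = tree.query(tgt, k=1)
    return idx.astype(np.int64), tgt
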