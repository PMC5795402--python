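"""Distance-based evaluation of predicted breast shapes.

Two complementary metrics compare a predicted cloud with the true
post-surgery cloud, both restricted to surface points (the clinically
visible skin):

* pair-wise (point-wise) distance — Euclidean distance between
  index-corresponding points, exploiting the deterministic correspondence;
* global distance — directed mean nearest-neighbour distance, reported in
  both directions (source→target and target→source).

Each metric reports the mean (mu), the standard deviation (sigma, population
convention) and the maximum distance.  The baseline evaluation uses the
pre-surgery cloud itself as the "prediction" — the no-method reference any
model must beat.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree


class CorrespondenceError(ValueError):
    """Clouds of unequal length cannot be compared point-wise."""


@dataclass(frozen=True)
class DistanceStats:
    mu: float
    sigma: float
    max: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.sigma, self.max)


def _stats(distances: np.ndarray) -> DistanceStats:
    return DistanceStats(
        mu=float(np.mean(distances)),
        sigma=float(np.std(distances)),  # population convention
        max=float(np.max(distances)),
    )


def pairwise_distance(pred: np.ndarray, target: np.ndarray) -> DistanceStats:
    """Per-index Euclidean distance statistics between corresponding clouds."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise CorrespondenceError(
            f"cloud shapes differ: {pred.shape} vs {target.shape}"
        )
    if len(pred) == 0:
        raise ValueError("empty clouds")
    return _stats(np.linalg.norm(pred - target, axis=1))


def pairwise_distances(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Raw per-index Euclidean distances (used e.g. for adaptive weights)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise CorrespondenceError(
            f"cloud shapes differ: {pred.shape} vs {target.shape}"
        )
    return np.linalg.norm(pred - target, axis=1)


def global_distance(source: np.ndarray, target: np.ndarray) -> DistanceStats:
    """Directed nearest-neighbour distance statistics from source to target."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(source) == 0 or len(target) == 0:
        raise ValueError("empty clouds")
    d, _ = cKDTree(target).query(source, k=1)
    return _stats(d)


@dataclass(frozen=True)
class EvalReport:
    """Full evaluation of one predicted cloud against its target."""

    p2p: DistanceStats
    global_src_to_tgt: DistanceStats
    global_tgt_to_src: DistanceStats
    n_points: int
    scope: str = "surface_only"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def evaluate_clouds(pred: np.ndarray, target: np.ndarray) -> EvalReport:
    """Pair-wise plus bidirectional global distances for surface clouds."""
    return EvalReport(
        p2p=pairwise_distance(pred, target),
        global_src_to_tgt=global_distance(pred, target),
        global_tgt_to_src=global_distance(target, pred),
        n_points=len(np.asarray(pred)),
    )


def baseline_eval(pre: np.ndarray, post: np.ndarray) -> EvalReport:
    """No-method reference: evaluate with the prediction equal to pre-surgery."""
    return evaluate_clouds(pre, post)
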