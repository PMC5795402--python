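"""Per-quadrant heuristic baseline for post-surgery shape prediction.

A deliberately simple comparator for the learned regressors: estimate the
mean displacement vector of each breast quadrant from the training pairs,
then predict every point's displacement as its quadrant's mean — scaled, in
the quadrant containing the tumor, by a breast-density multiplier
({A: 4, B: 3, C: 2, D: 1}) and a tumor-size multiplier ({L: 3, M: 2, S: 1}).
The model is intentionally discontinuous across quadrant boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import case_table
from .geometry import QUADRANTS, BreastPCL, QuadrantPlanes, assign_quadrant, build_quadrant_planes
from .models import sample_points
from .synthetic import CaseData, CaseSpec

DENSITY_MULTIPLIER: dict[str, float] = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}
SIZE_MULTIPLIER: dict[str, float] = {"L": 3.0, "M": 2.0, "S": 1.0}


@dataclass
class HeuristicModel:
    """Per-quadrant, per-axis mean displacements plus the printed multipliers."""

    mean_disp: dict[str, np.ndarray]
    b_map: dict[str, float] = field(default_factory=lambda: dict(DENSITY_MULTIPLIER))
    s_map: dict[str, float] = field(default_factory=lambda: dict(SIZE_MULTIPLIER))


def fit_heuristic(
    train_cases: Sequence[CaseData],
    sampling_rate: int = 65,
    seed: int = 0,
) -> HeuristicModel:
    """Mean (post - pre) displacement per quadrant, pooled over training cases.

    The mean of each quadrant is estimated from its *healthy* occurrences —
    cases whose tumor lies in another quadrant — since the density and
    tumor-size multipliers exist precisely to rescale that healthy mean for
    the operated quadrant.  Training rows are subsampled per case at
    ``sampling_rate`` %; quadrant labels come from each case's own quadrant
    planes applied to the pre-surgery points.
    """
    sums = {q: np.zeros(3) for q in QUADRANTS}
    counts = {q: 0 for q in QUADRANTS}
    for case in train_cases:
        table = sample_points(case_table(case), sampling_rate, seed=seed)
        idx = table.index.to_numpy()
        quadrants = assign_quadrant(
            case.pre.points[idx], case.planes, case.pre.laterality
        )
        disp = table[["dx", "dy", "dz"]].to_numpy()
        for q in QUADRANTS:
            if q == case.spec.quadrant:
                continue
            mask = quadrants == q
            sums[q] += disp[mask].sum(axis=0)
            counts[q] += int(mask.sum())
    means = {}
    for q in QUADRANTS:
        if counts[q] == 0:
            raise ValueError(f"no training points fell in quadrant {q}")
        means[q] = sums[q] / counts[q]
    return HeuristicModel(mean_disp=means)


def predict_heuristic(
    model: HeuristicModel,
    pcl: BreastPCL,
    spec: CaseSpec,
    planes: QuadrantPlanes | None = None,
) -> BreastPCL:
    """Displace each point by its quadrant mean (scaled in the tumor quadrant).

    Points in healthy quadrants move by the quadrant's mean displacement;
    points in the quadrant containing the tumor move by ``b * s`` times that
    mean, with ``b`` the density multiplier and ``s`` the size multiplier.
    """
    if planes is None:
        planes = build_quadrant_planes(pcl)
    quadrants = assign_quadrant(pcl.points, planes, pcl.laterality)
    factor = model.b_map[spec.density] * model.s_map[spec.tumor_size]
    disp = np.empty_like(pcl.points)
    for q in QUADRANTS:
        mask = quadrants == q
        base = model.mean_disp[q]
        disp[mask] = base * factor if q == spec.quadrant else base
    unknown = ~np.isin(quadrants, QUADRANTS)
    if unknown.any():
        raise ValueError(f"unknown quadrant label(s): {set(quadrants[unknown])}")
    return pcl.with_points(pcl.points + disp)
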