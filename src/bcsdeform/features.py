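"""Per-point feature engineering for displacement regression.

Every pre-surgery point becomes one training row with 23 features: its
centred coordinates, its signed per-axis difference and Euclidean distance
to the excised cylinder, its cylindrical coordinates in the cylinder frame,
and one-hot encodings of tumor size, breast laterality, breast density and
tumor quadrant.  Distance-family features of damaged points (inside the
excised cylinder) are all zero.  Regression targets are the per-axis
displacements taking each pre-surgery point to its post-surgery
correspondent, so the predicted cloud is simply ``pre + predicted
displacement``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import QUADRANTS, BreastPCL, ExcisionCylinder, label_damaged
from .synthetic import DENSITIES, TUMOR_SIZES, CaseData, CaseSpec

#: The 23 model-input columns, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "px", "py", "pz",
    "dispx", "dispy", "dispz",
    "d_cyl",
    "rho", "phi", "zc",
    "s1", "s2", "s3",
    "lat_R", "lat_L",
    "dens_A", "dens_B", "dens_C", "dens_D",
    "q1", "q2", "q3", "q4",
)

#: Feature groups used for grouped importance reporting.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "coordinates": ("px", "py", "pz"),
    "difference_to_cylinder": ("dispx", "dispy", "dispz"),
    "distance_to_cylinder": ("d_cyl",),
    "polar_distance_to_cylinder": ("rho", "phi", "zc"),
    "tumor_size": ("s1", "s2", "s3"),
    "laterality": ("lat_R", "lat_L"),
    "density": ("dens_A", "dens_B", "dens_C", "dens_D"),
    "tumor_region": ("q1", "q2", "q3", "q4"),
}

TARGET_COLUMNS: tuple[str, ...] = ("dx", "dy", "dz")
META_COLUMNS: tuple[str, ...] = ("case_id", "patient_id", "is_surface", "damaged")


class CorrespondenceError(ValueError):
    """Pre/post clouds do not share length/indexing."""


def compute_features(
    pcl: BreastPCL,
    cyl: ExcisionCylinder,
    spec: CaseSpec,
    damaged: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the 23-column feature table for one pre-surgery cloud.

    Coordinates are centred on the cloud's centroid.  ``dispx/y/z`` are the
    signed per-axis differences between each point and the nearest point of
    the cylinder axis segment; ``d_cyl`` is the Euclidean distance to the
    cylinder solid (zero inside); ``(rho, phi, zc)`` are cylindrical
    coordinates in the frame whose z-axis is the cylinder axis anchored at
    its base point, with ``phi`` measured from the breast's lateral
    direction projected into the axis-normal plane.  All distance-family
    features are zeroed for damaged points.
    """
    if damaged is None:
        damaged = label_damaged(pcl, cyl)
    damaged = np.asarray(damaged, dtype=bool)
    if len(damaged) != len(pcl.points):
        raise ValueError("damaged labels must match the cloud length")

    pts = pcl.points
    centred = pts - pts.mean(axis=0)

    nearest_axis = cyl.nearest_axis_point(pts)
    disp = pts - nearest_axis
    d_cyl = cyl.distance_to_solid(pts)

    axial, rho = cyl.cylindrical_coords(pts)
    lateral = np.array([1.0, 0.0, 0.0]) if spec.laterality == "R" else np.array([-1.0, 0.0, 0.0])
    e1 = lateral - (lateral @ cyl.axis) * cyl.axis
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:  # lateral direction parallel to the axis; fall back to z
        e1 = np.array([0.0, 0.0, 1.0]) - (cyl.axis[2]) * cyl.axis
        n1 = np.linalg.norm(e1)
    e1 /= n1
    e2 = np.cross(cyl.axis, e1)
    rel = pts - cyl.base_point
    phi = np.arctan2(rel @ e2, rel @ e1)

    healthy = ~damaged
    table = pd.DataFrame(
        {
            "px": centred[:, 0],
            "py": centred[:, 1],
            "pz": centred[:, 2],
            "dispx": np.where(healthy, disp[:, 0], 0.0),
            "dispy": np.where(healthy, disp[:, 1], 0.0),
            "dispz": np.where(healthy, disp[:, 2], 0.0),
            "d_cyl": np.where(healthy, d_cyl, 0.0),
            "rho": np.where(healthy, rho, 0.0),
            "phi": np.where(healthy, phi, 0.0),
            "zc": np.where(healthy, axial, 0.0),
        }
    )
    for col, size in zip(("s1", "s2", "s3"), TUMOR_SIZES):
        table[col] = float(spec.tumor_size == size)
    table["lat_R"] = float(spec.laterality == "R")
    table["lat_L"] = float(spec.laterality == "L")
    for col, dens in zip(("dens_A", "dens_B", "dens_C", "dens_D"), DENSITIES):
        table[col] = float(spec.density == dens)
    for col, quad in zip(("q1", "q2", "q3", "q4"), QUADRANTS):
        table[col] = float(spec.quadrant == quad)
    return table


def case_table(case: CaseData) -> pd.DataFrame:
    """Feature table of a case with targets and bookkeeping columns attached.

    Targets are the per-axis displacements ``post - pre``; metadata columns
    identify the case/patient and flag surface and damaged points.  The
    result is cached on the case.
    """
    if case.features is not None:
        return case.features
    if len(case.post.points) != len(case.pre.points):
        raise CorrespondenceError(
            f"case {case.spec.case_id}: pre ({len(case.pre.points)}) and post "
            f"({len(case.post.points)}) clouds differ in length"
        )
    table = compute_features(case.pre, case.cylinder, case.spec, case.damaged)
    targets = case.post.points - case.pre.points
    table["dx"], table["dy"], table["dz"] = targets[:, 0], targets[:, 1], targets[:, 2]
    table["case_id"] = case.spec.case_id
    table["patient_id"] = case.spec.patient_id
    table["is_surface"] = np.arange(len(table)) < case.pre.n_surface
    table["damaged"] = case.damaged
    case.features = table
    return table


def assemble_training_matrix(
    cases: Sequence[CaseData],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack per-case tables into one design matrix plus per-axis targets.

    Surface and interior points are both included.  Returns the stacked
    table (features + metadata) and an ``(n, 3)`` target array.
    """
    tables = [case_table(c) for c in cases]
    stacked = pd.concat(tables, ignore_index=True)
    targets = stacked[list(TARGET_COLUMNS)].to_numpy()
    return stacked, targets
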