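"""Reading and writing clouds, case metadata and feature tables.

Point clouds travel either as PLY (via :mod:`trimesh`) or as XYZ CSV with
columns ``x,y,z,is_surface``; everything a cloud carries beyond coordinates
(laterality, nipple, pectoral corners, volume, patient id) lives in a JSON
sidecar so a case round-trips losslessly.  Feature tables round-trip as
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import BreastPCL
from .synthetic import CaseData, CaseSpec


def write_ply(points: np.ndarray, path: str | Path) -> None:
    """Write bare point coordinates as an ASCII PLY file."""
    cloud = trimesh.PointCloud(np.asarray(points, dtype=float))
    Path(path).write_bytes(cloud.export(file_type="ply", encoding="ascii"))


def read_ply(path: str | Path) -> np.ndarray:
    """Read point coordinates from a PLY file."""
    loaded = trimesh.load(str(path), process=False)
    return np.asarray(loaded.vertices, dtype=float)


def write_xyz_csv(pcl: BreastPCL, path: str | Path) -> None:
    """Write a cloud as CSV with header ``x,y,z,is_surface``."""
    is_surface = np.arange(len(pcl.points)) < pcl.n_surface
    pd.DataFrame(
        {
            "x": pcl.points[:, 0],
            "y": pcl.points[:, 1],
            "z": pcl.points[:, 2],
            "is_surface": is_surface.astype(int),
        }
    ).to_csv(path, index=False)


def read_xyz_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ CSV; returns (points, is_surface mask)."""
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return pts, df["is_surface"].to_numpy(dtype=bool)


def _pcl_metadata(pcl: BreastPCL, spec: CaseSpec | None = None) -> dict:
    meta = {
        "patient_id": pcl.patient_id,
        "laterality": pcl.laterality,
        "n_surface": pcl.n_surface,
        "n_interior": pcl.n_interior,
        "nipple": pcl.nipple.tolist(),
        "pectoral_corners": pcl.pectoral_corners.tolist(),
        "breast_volume": pcl.breast_volume,
    }
    if spec is not None:
        meta.update(
            {
                "size_class": spec.size_class,
                "density": spec.density,
                "quadrant": spec.quadrant,
                "tumor_size": spec.tumor_size,
                "seed": spec.seed,
            }
        )
    return meta


def save_case(case: CaseData, out_dir: str | Path) -> Path:
    """Write one case (pre.ply, post.ply, case.json) under ``out_dir``."""
    out = Path(out_dir) / case.spec.case_id
    out.mkdir(parents=True, exist_ok=True)
    write_ply(case.pre.points, out / "pre.ply")
    write_ply(case.post.points, out / "post.ply")
    meta = _pcl_metadata(case.pre, case.spec)
    meta["tumor_center"] = case.cylinder.tumor_center.tolist()
    meta["cylinder"] = {
        "base_point": case.cylinder.base_point.tolist(),
        "axis": case.cylinder.axis.tolist(),
        "height": case.cylinder.height,
        "radius": case.cylinder.radius,
        "volume_fraction": case.cylinder.volume_fraction,
    }
    (out / "case.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def load_pcl(case_dir: str | Path, which: str = "pre") -> BreastPCL:
    """Load a saved cloud (``pre`` or ``post``) with its JSON metadata."""
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    points = read_ply(case_dir / f"{which}.ply")
    return BreastPCL(
        points=points,
        n_surface=meta["n_surface"],
        n_interior=meta["n_interior"],
        laterality=meta["laterality"],
        nipple=np.array(meta["nipple"]),
        pectoral_corners=np.array(meta["pectoral_corners"]),
        breast_volume=meta["breast_volume"],
        patient_id=meta["patient_id"],
    )


def save_manifest(cases: list[CaseData], out_dir: str | Path) -> Path:
    """Write a dataset manifest CSV linking case ids to their directories."""
    rows = [
        {
            "case_id": c.spec.case_id,
            "patient_id": c.spec.patient_id,
            "size_class": c.spec.size_class,
            "laterality": c.spec.laterality,
            "density": c.spec.density,
            "quadrant": c.spec.quadrant,
            "tumor_size": c.spec.tumor_size,
            "seed": c.spec.seed,
            "path": c.spec.case_id,
        }
        for c in cases
    ]
    path = Path(out_dir) / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
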