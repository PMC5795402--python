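"""Semi-synthetic paired pre-/post-surgery breast cloud generator.

Real paired data for breast-conserving surgery (BCS) outcome modelling is
not publicly available, and physically faithful wound-healing simulation
requires a coupled finite-element pipeline far outside this package's scope.
This module instead generates breast-like point clouds and imposes a
contraction displacement field with the qualitative structure clinically
reported for post-BCS healing:

* displacement magnitude decays exponentially with distance from the
  excised (cylindrical) volume,
* magnitude decreases with BI-RADS breast density (A > B > C > D — denser,
  more glandular breasts deform less),
* magnitude grows with excised tumor size (L > M > S),
* displacement directions mirror between left and right breasts.

The generated dataset enumerates the full factorial of patients x density
x tumor quadrant x tumor size (6 x 4 x 4 x 3 = 288 cases by default), with
per-case seeds so every case is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    QUADRANTS,
    BreastPCL,
    ExcisionCylinder,
    QuadrantPlanes,
    build_quadrant_planes,
    label_damaged,
    make_excision_cylinder,
    sample_tumor_center,
)

DENSITIES: tuple[str, ...] = ("A", "B", "C", "D")
TUMOR_SIZES: tuple[str, ...] = ("S", "M", "L")
SIZE_CLASSES: tuple[str, ...] = ("Small", "Medium", "Large")

#: Excised volume as a fraction of total breast volume per tumor size class.
VOLUME_FRACTIONS: dict[str, float] = {"S": 0.05, "M": 0.075, "L": 0.10}

#: Fibroglandular tissue fraction per BI-RADS density category.
FIBROGLANDULAR_FRACTION: dict[str, float] = {"A": 0.10, "B": 0.35, "C": 0.60, "D": 0.85}

# Mooney-Rivlin c1 (Pa) and mass density rho0 (kg m^-3) of the two tissues.
_C1_FIBROGLANDULAR, _C1_FAT = 120.0, 80.0
_RHO_FIBROGLANDULAR, _RHO_FAT = 1020.0, 910.0

#: Half-ellipsoid target breast volumes (mm^3) per size class.
TARGET_VOLUMES: dict[str, float] = {
    "Small": 520_000.0,
    "Medium": 900_000.0,
    "Large": 1_280_000.0,
}

# Default patient roster (size class, laterality), balanced as 2 small /
# 2 medium / 2 large and 3 left / 3 right.
DEFAULT_ROSTER: tuple[tuple[str, str], ...] = (
    ("Small", "L"),
    ("Medium", "L"),
    ("Large", "R"),
    ("Medium", "L"),
    ("Large", "R"),
    ("Small", "R"),
)


def stable_hash(*parts: object, bits: int = 31) -> int:
    """Deterministic cross-run integer hash of the given parts."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) % (1 << bits)


@dataclass(frozen=True)
class MaterialProperties:
    """Density-weighted Mooney-Rivlin parameters of the breast tissue mix."""

    c1: float  # Pa
    c2: float  # Pa
    rho0: float  # kg m^-3


def weighted_material_properties(density: str) -> MaterialProperties:
    """Tissue-mix-weighted material properties for a BI-RADS category.

    The breast is treated as a homogeneous mix of fibroglandular and fat
    tissue with the category's fibroglandular fraction ``w``:
    ``c1 = w*120 + (1-w)*80`` Pa, ``rho0 = w*1020 + (1-w)*910`` kg m^-3,
    ``c2 = 0``.
    """
    try:
        w = FIBROGLANDULAR_FRACTION[density]
    except KeyError:
        raise ValueError(f"unknown density category {density!r}") from None
    return MaterialProperties(
        c1=w * _C1_FIBROGLANDULAR + (1 - w) * _C1_FAT,
        c2=0.0,
        rho0=w * _RHO_FIBROGLANDULAR + (1 - w) * _RHO_FAT,
    )


@dataclass(frozen=True)
class CaseSpec:
    """One dataset case: a patient breast with a density / quadrant / size combo."""

    patient_id: str
    size_class: str
    laterality: str
    density: str
    quadrant: str
    tumor_size: str
    seed: int

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.laterality not in ("R", "L"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.density not in DENSITIES:
            raise ValueError(f"unknown density {self.density!r}")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if self.tumor_size not in TUMOR_SIZES:
            raise ValueError(f"unknown tumor size {self.tumor_size!r}")

    @property
    def volume_fraction(self) -> float:
        return VOLUME_FRACTIONS[self.tumor_size]

    @property
    def case_id(self) -> str:
        return f"{self.patient_id}-{self.density}-{self.quadrant}-{self.tumor_size}"


def _default_quadrant_settle() -> dict[str, tuple[float, float, float]]:
    # posterior-inferior settling, mm, for a right breast (x mirrored for left)
    return {
        "UOQ": (0.3, -0.9, -0.5),
        "UIQ": (-0.2, -0.8, -0.4),
        "LOQ": (0.3, -1.0, -0.3),
        "LIQ": (-0.2, -0.7, -0.2),
    }


@dataclass(frozen=True)
class DeformationParams:
    """Parameters of the synthetic healing displacement field.

    The field superposes two components:

    * a *local contraction*: each point moves towards the excision cavity
      (the cylinder axis, biased posteriorly by ``settle_axial_bias``) by
      ``A * exp(-d / decay_length) * (1 + eps)`` mm, never past the target,
      where ``d`` is the point's distance to the excised cylinder,
      ``A = base_amplitude * density_factor * size_factor`` and ``eps`` is
      clipped Gaussian relative noise;
    * a *settling shift*: a per-quadrant constant displacement
      (``quadrant_settle``, posterior–inferior, mirrored in x for left
      breasts) shared by all cases; in the quadrant containing the tumor it
      is additionally scaled by ``density_factor * size_factor`` — the
      operated quadrant settles in proportion to the excised volume and
      inversely with tissue stiffness.

    Magnitudes thereby decay with distance from the excision, decrease with
    BI-RADS density A→D, grow with tumor size S→L and mirror with
    laterality.
    """

    base_amplitude: float = 2.0  # mm
    decay_length: float = 25.0  # mm
    noise_rel: float = 0.05  # relative sd of the multiplicative noise
    settle_axial_bias: float = 0.5  # 0 = purely radial contraction target
    density_factor: dict[str, float] = field(
        default_factory=lambda: {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}
    )
    size_factor: dict[str, float] = field(
        default_factory=lambda: {"L": 3.0, "M": 2.0, "S": 1.0}
    )
    quadrant_settle: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_quadrant_settle
    )

    def amplitude(self, density: str, tumor_size: str) -> float:
        return (
            self.base_amplitude
            * self.density_factor[density]
            * self.size_factor[tumor_size]
        )


def enumerate_cases(n_patients: int = 6, root_seed: int = 0) -> list[CaseSpec]:
    """Full factorial of patients x 4 densities x 4 quadrants x 3 tumor sizes.

    Patient roster alternates breast size and laterality (2 small / 2 medium
    / 2 large; 3 left / 3 right for the default six patients).  Order is
    deterministic: patients, then densities A–D, then quadrants, then sizes
    S/M/L.  Per-case seeds derive from the root seed and case identity.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cases = []
    for i in range(n_patients):
        size_class, laterality = DEFAULT_ROSTER[i % len(DEFAULT_ROSTER)]
        pid = f"P{i + 1}"
        for density in DENSITIES:
            for quadrant in QUADRANTS:
                for tumor_size in TUMOR_SIZES:
                    cases.append(
                        CaseSpec(
                            patient_id=pid,
                            size_class=size_class,
                            laterality=laterality,
                            density=density,
                            quadrant=quadrant,
                            tumor_size=tumor_size,
                            seed=stable_hash(root_seed, pid, density, quadrant, tumor_size),
                        )
                    )
    return cases


def _patient_volume(spec: CaseSpec) -> float:
    """Target breast volume with a reproducible per-patient jitter (+-8%)."""
    base = TARGET_VOLUMES[spec.size_class]
    u = stable_hash("volume", spec.patient_id) / float(1 << 31)
    return base * (1.0 + 0.16 * (u - 0.5))


def generate_breast_pcl(
    spec: CaseSpec, n_surface: int = 400, n_interior: int = 600
) -> BreastPCL:
    """Generate a breast-like cloud: half-ellipsoid skin over a flat chest wall.

    The chest wall is the plane ``y = 0``; the breast protrudes towards
    ``+y`` with the nipple at the apex.  Surface points sample the
    half-ellipsoid skin, interior points are uniform in the enclosed volume.
    Left breasts are mirrored through ``x = 0``.  Reproducible from the
    patient identity (the same patient always has the same breast).
    """
    if n_surface < 50 or n_interior < 50:
        raise ValueError("need at least 50 surface and 50 interior points")
    rng = np.random.default_rng(stable_hash("pcl", spec.patient_id, n_surface, n_interior))
    volume = _patient_volume(spec)
    # half-ellipsoid volume (2/3) pi a b c with b = 0.75 a, c = a
    a = (volume / (0.5 * np.pi)) ** (1.0 / 3.0)
    b, c = 0.75 * a, a

    u = rng.normal(size=(n_surface - 1, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[:, 1] = np.abs(u[:, 1])
    surface = u * np.array([a, b, c])
    surface = np.vstack([np.array([0.0, b, 0.0]), surface])  # nipple first

    interior = np.empty((0, 3))
    while len(interior) < n_interior:
        cand = rng.uniform([-a, 0.0, -c], [a, b, c], size=(2 * n_interior, 3))
        inside = np.sum((cand / np.array([a, b, c])) ** 2, axis=1) <= 1.0
        interior = np.vstack([interior, cand[inside]])
    interior = interior[:n_interior]

    points = np.vstack([surface, interior])
    nipple = np.array([0.0, b, 0.0])
    corners = np.array([[-0.9 * a, 0.0, 0.8 * c], [0.9 * a, 0.0, 0.8 * c], [0.0, 0.0, -0.9 * c]])
    if spec.laterality == "L":
        points = points * np.array([-1.0, 1.0, 1.0])
        nipple = nipple * np.array([-1.0, 1.0, 1.0])
        corners = corners * np.array([-1.0, 1.0, 1.0])
    return BreastPCL(
        points=points,
        n_surface=n_surface,
        n_interior=n_interior,
        laterality=spec.laterality,
        nipple=nipple,
        pectoral_corners=corners,
        breast_volume=volume,
        patient_id=spec.patient_id,
        metadata={"semi_axes_mm": [a, b, c], "size_class": spec.size_class},
    )


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 integer hash (uint64 in, uint64 out)."""
    with np.errstate(over="ignore"):
        z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _geometry_keyed_noise(points: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Clipped Gaussian noise keyed to point coordinates, not point order.

    Hashing the (quantised) coordinates makes the noise a function of the
    geometry alone, so the simulated displacement field is invariant under
    re-ordering of the cloud.
    """
    if sd == 0:
        return np.zeros(len(points))
    q = np.round(np.asarray(points, dtype=float) * 1e6).astype(np.int64).view(np.uint64)
    with np.errstate(over="ignore"):
        key = _splitmix64(q[:, 0] ^ _splitmix64(q[:, 1] ^ _splitmix64(q[:, 2] + np.uint64(seed))))
    u1 = (_splitmix64(key) >> np.uint64(11)).astype(float) / float(1 << 53)
    u2 = (_splitmix64(key + np.uint64(1)) >> np.uint64(11)).astype(float) / float(1 << 53)
    u1 = np.clip(u1, 1e-12, 1.0)
    normal = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
    return np.clip(sd * normal, -0.5, 0.5)


def settling_field(
    pcl: BreastPCL,
    params: DeformationParams,
    tumor_quadrant: str,
    density: str,
    tumor_size: str,
    planes: QuadrantPlanes | None = None,
) -> np.ndarray:
    """Per-quadrant constant settling shift (scaled in the tumor quadrant).

    On its own (``base_amplitude = 0``) this produces exactly a
    per-quadrant-constant displacement field whose tumor-quadrant vectors
    carry the density x size multipliers.
    """
    from .geometry import assign_quadrant  # local import to avoid cycle noise

    if planes is None:
        planes = build_quadrant_planes(pcl)
    quadrants = assign_quadrant(pcl.points, planes, pcl.laterality)
    mirror = np.array([-1.0, 1.0, 1.0]) if pcl.laterality == "L" else np.ones(3)
    factor = params.density_factor[density] * params.size_factor[tumor_size]
    shift = np.empty_like(pcl.points)
    for q, vec in params.quadrant_settle.items():
        mask = quadrants == q
        v = np.asarray(vec, dtype=float) * mirror
        shift[mask] = v * factor if q == tumor_quadrant else v
    return shift


def simulate_post_surgery(
    pcl: BreastPCL,
    cyl: ExcisionCylinder,
    params: DeformationParams,
    density: str,
    tumor_size: str,
    seed: int = 0,
    planes: QuadrantPlanes | None = None,
) -> tuple[BreastPCL, np.ndarray]:
    """Apply the synthetic healing displacement; returns (post cloud, field).

    The local contraction moves every point towards its target on the
    cylinder axis — the nearest axis point pulled towards the cylinder base
    by ``settle_axial_bias`` — by ``A * exp(-d/decay) * (1 + eps)`` mm,
    where ``d`` is the distance to the excised cylinder (zero inside, so
    damaged points collapse towards the axis with the full amplitude),
    never overshooting the target.  The per-quadrant settling shift is
    added on top.  Index correspondence with the pre-surgery cloud is
    preserved and the field is a function of geometry and seed only.
    """
    if planes is None:
        planes = build_quadrant_planes(pcl)
    from .geometry import assign_quadrant

    tumor_quadrant = assign_quadrant(
        cyl.tumor_center[None, :], planes, pcl.laterality
    )[0]
    pts = pcl.points
    d = cyl.distance_to_solid(pts)
    amp = params.amplitude(density, tumor_size)
    # key the noise on canonical right-breast coordinates so mirrored
    # clouds receive mirrored (not independent) noise
    key_pts = pts * np.array([-1.0, 1.0, 1.0]) if pcl.laterality == "L" else pts
    eps = _geometry_keyed_noise(key_pts, params.noise_rel, seed)
    magnitude = np.maximum(amp * np.exp(-d / params.decay_length) * (1.0 + eps), 0.0)

    axial, _ = cyl.cylindrical_coords(pts)
    t = np.clip(axial, 0.0, cyl.height) * (1.0 - params.settle_axial_bias)
    target = cyl.base_point + np.outer(t, cyl.axis)
    to_target = target - pts
    dist = np.linalg.norm(to_target, axis=1)
    step = np.minimum(magnitude, dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(dist[:, None] > 0, to_target / np.maximum(dist[:, None], 1e-12), 0.0)
    contraction = step[:, None] * direction
    shift = settling_field(pcl, params, tumor_quadrant, density, tumor_size, planes)
    displacement = contraction + shift
    return pcl.with_points(pts + displacement), displacement


@dataclass
class CaseData:
    """A fully realised dataset case: geometry, pairing and labels."""

    spec: CaseSpec
    pre: BreastPCL
    post: BreastPCL
    cylinder: ExcisionCylinder
    planes: QuadrantPlanes
    damaged: np.ndarray
    displacement: np.ndarray
    features: "object | None" = None  # lazily attached pandas feature table


def build_case(
    spec: CaseSpec,
    n_surface: int = 400,
    n_interior: int = 600,
    params: DeformationParams | None = None,
) -> CaseData:
    """Generate a complete paired case from its specification."""
    import dataclasses

    params = params or DeformationParams()
    pre = generate_breast_pcl(spec, n_surface, n_interior)
    planes = build_quadrant_planes(pre)
    rng = np.random.default_rng(spec.seed)
    # sample the tumor in the canonical right-breast frame and mirror it, so
    # the same patient/seed yields the same anatomical tumor position for
    # either laterality (displacements then mirror exactly)
    if spec.laterality == "L":
        spec_r = dataclasses.replace(spec, laterality="R")
        pre_r = generate_breast_pcl(spec_r, n_surface, n_interior)
        planes_r = build_quadrant_planes(pre_r)
        tumor = sample_tumor_center(
            pre_r, spec.quadrant, spec.volume_fraction, rng, planes_r
        ) * np.array([-1.0, 1.0, 1.0])
    else:
        tumor = sample_tumor_center(pre, spec.quadrant, spec.volume_fraction, rng, planes)
    cyl = make_excision_cylinder(pre, tumor, spec.volume_fraction, planes)
    damaged = label_damaged(pre, cyl)
    post, disp = simulate_post_surgery(
        pre, cyl, params, spec.density, spec.tumor_size, seed=spec.seed, planes=planes
    )
    return CaseData(
        spec=spec,
        pre=pre,
        post=post,
        cylinder=cyl,
        planes=planes,
        damaged=damaged,
        displacement=disp,
    )


def build_dataset(
    cases: Iterable[CaseSpec] | None = None,
    n_patients: int = 6,
    n_surface: int = 400,
    n_interior: int = 600,
    params: DeformationParams | None = None,
    root_seed: int = 0,
) -> list[CaseData]:
    """Realise a whole dataset (default: the 288-case factorial)."""
    if cases is None:
        cases = enumerate_cases(n_patients=n_patients, root_seed=root_seed)
    return [build_case(spec, n_surface, n_interior, params) for spec in cases]
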