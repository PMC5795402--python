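"""Shared fixtures: small synthetic cases generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from bcsdeform.geometry import BreastPCL
from bcsdeform.synthetic import (
    CaseSpec,
    DeformationParams,
    build_case,
    build_dataset,
    enumerate_cases,
)


def make_box_pcl(laterality: str = "R") -> BreastPCL:
    """A hand-constructed cloud with trivially checkable geometry.

    Chest wall at y = 0, skin surface a flat grid at y = 50 mm, interior on
    a regular lattice; nipple at (0, 50, 0).  Breast volume set to 1e6 mm^3
    so cylinder radii have closed forms.
    """
    xs = np.linspace(-50, 50, 11)
    zs = np.linspace(-50, 50, 11)
    gx, gz = np.meshgrid(xs, zs)
    surface = np.column_stack([gx.ravel(), np.full(gx.size, 50.0), gz.ravel()])
    ix, iy, iz = np.meshgrid(
        np.linspace(-45, 45, 7), np.linspace(5, 45, 5), np.linspace(-45, 45, 7)
    )
    interior = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
    points = np.vstack([surface, interior])
    return BreastPCL(
        points=points,
        n_surface=len(surface),
        n_interior=len(interior),
        laterality=laterality,
        nipple=np.array([0.0, 50.0, 0.0]),
        pectoral_corners=np.array([[-50.0, 0.0, 40.0], [50.0, 0.0, 40.0], [0.0, 0.0, -45.0]]),
        breast_volume=1_000_000.0,
        patient_id="BOX",
    )


@pytest.fixture
def box_pcl() -> BreastPCL:
    return make_box_pcl()


@pytest.fixture
def small_spec() -> CaseSpec:
    return CaseSpec(
        patient_id="P1",
        size_class="Small",
        laterality="L",
        density="B",
        quadrant="UOQ",
        tumor_size="M",
        seed=1234,
    )


@pytest.fixture
def small_case(small_spec):
    return build_case(small_spec, n_surface=80, n_interior=120)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three patients x 48 cases at desk-minimal point counts."""
    return build_dataset(n_patients=3, n_surface=60, n_interior=90, root_seed=11)


@pytest.fixture(scope="session")
def quadrant_constant_dataset():
    """Dataset whose field is exactly per-quadrant constants with multipliers."""
    params = DeformationParams(base_amplitude=0.0, noise_rel=0.0)
    cases = enumerate_cases(n_patients=2, root_seed=5)
    return [build_case(s, n_surface=60, n_interior=90, params=params) for s in cases]
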