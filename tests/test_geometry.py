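"""Quadrant planes, quadrant assignment and excision-cylinder geometry."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcsdeform.geometry import (
    QUADRANTS,
    BreastPCL,
    DegenerateGeometryError,
    ExcisionCylinder,
    assign_quadrant,
    build_quadrant_planes,
    label_damaged,
    make_excision_cylinder,
    sample_tumor_center,
)

from conftest import make_box_pcl


def _pcl_with(corners, nipple) -> BreastPCL:
    pcl = make_box_pcl()
    return BreastPCL(
        points=pcl.points,
        n_surface=pcl.n_surface,
        n_interior=pcl.n_interior,
        laterality="R",
        nipple=np.asarray(nipple, dtype=float),
        pectoral_corners=np.asarray(corners, dtype=float),
        breast_volume=pcl.breast_volume,
    )


class TestQuadrantPlanes:
    def test_worked_example(self):
        """Corners in the xz-plane give a +-y pectoral normal; both nipple
        planes are axis-aligned through the nipple."""
        pcl = _pcl_with([(0, 0, 0), (100, 0, 0), (0, 0, 100)], (50, 60, 50))
        planes = build_quadrant_planes(pcl)
        assert np.allclose(np.abs(planes.pectoral_plane.normal), [0, 1, 0])
        # superior-inferior plane: z = 50
        assert np.allclose(np.abs(planes.superior_inferior_plane.normal), [0, 0, 1])
        assert planes.superior_inferior_plane.offset == pytest.approx(50.0)
        # lateral-medial plane: x = 50
        assert np.allclose(np.abs(planes.lateral_medial_plane.normal), [1, 0, 0])
        assert abs(planes.lateral_medial_plane.offset) == pytest.approx(50.0)

    def test_nipple_lies_on_both_nipple_planes(self, box_pcl):
        planes = build_quadrant_planes(box_pcl)
        for plane in (planes.superior_inferior_plane, planes.lateral_medial_plane):
            assert abs(plane.signed_distance(box_pcl.nipple)[0]) < 1e-9

    def test_orthogonality_invariant(self, box_pcl):
        planes = build_quadrant_planes(box_pcl)
        dot = planes.lateral_medial_plane.normal @ planes.pectoral_plane.normal
        assert abs(dot) < 1e-9

    def test_corner_permutation_gives_same_plane_up_to_sign(self):
        corners = [(0, 0, 0), (100, 0, 0), (0, 0, 100)]
        nipple = (50, 60, 50)
        ref = build_quadrant_planes(_pcl_with(corners, nipple))
        for perm in itertools.permutations(corners):
            planes = build_quadrant_planes(_pcl_with(list(perm), nipple))
            assert np.allclose(
                np.abs(planes.pectoral_plane.normal), np.abs(ref.pectoral_plane.normal)
            )

    def test_collinear_corners_raise(self):
        with pytest.raises(DegenerateGeometryError):
            _pcl_with([(0, 0, 0), (1, 0, 0), (2, 0, 0)], (0, 10, 0))


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "point,laterality,expected",
        # box_pcl: nipple (0, 50, 0); superior = z >= 0; lateral = +x for R
        [
            ((30, 25, 30), "R", "UOQ"),
            ((-30, 25, 30), "R", "UIQ"),
            ((30, 25, -30), "R", "LOQ"),
            ((-30, 25, -30), "R", "LIQ"),
            ((30, 25, 30), "L", "UIQ"),
            ((-30, 25, 30), "L", "UOQ"),
            ((30, 25, -30), "L", "LIQ"),
            ((-30, 25, -30), "L", "LOQ"),
        ],
    )
    def test_all_sign_pairs_and_lateralities(self, box_pcl, point, laterality, expected):
        planes = build_quadrant_planes(box_pcl)
        assert assign_quadrant(np.array([point]), planes, laterality)[0] == expected

    def test_boundary_goes_superior_and_lateral(self, box_pcl):
        planes = build_quadrant_planes(box_pcl)
        on_both = np.array([[0.0, 25.0, 0.0]])
        assert assign_quadrant(on_both, planes, "R")[0] == "UOQ"
        assert assign_quadrant(on_both, planes, "L")[0] == "UOQ"

    def test_partition_counts_sum_to_n(self, small_case):
        labels = assign_quadrant(
            small_case.pre.points, small_case.planes, small_case.pre.laterality
        )
        counts = {q: int((labels == q).sum()) for q in QUADRANTS}
        assert sum(counts.values()) == len(small_case.pre.points)

    def test_mirroring_swaps_outer_and_inner(self, box_pcl):
        planes = build_quadrant_planes(box_pcl)
        rng = np.random.default_rng(3)
        pts = rng.uniform([-50, 5, -50], [50, 50, 50], size=(200, 3))
        labels = assign_quadrant(pts, planes, "R")
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        mirror_labels = assign_quadrant(mirrored, planes, "R")
        swap = {"UOQ": "UIQ", "UIQ": "UOQ", "LOQ": "LIQ", "LIQ": "LOQ"}
        off_plane = np.abs(pts[:, 0]) > 1e-9  # tie rule breaks the symmetry on x=0
        assert all(
            mirror_labels[i] == swap[labels[i]] for i in range(len(pts)) if off_plane[i]
        )


class TestExcisionCylinder:
    def test_radius_closed_form(self, box_pcl):
        """1e6 mm^3 breast, 10% excision, 50 mm height -> r = sqrt(1e5/(50 pi))."""
        cyl = make_excision_cylinder(box_pcl, np.array([0.0, 20.0, 0.0]), 0.10)
        assert cyl.height == pytest.approx(50.0)
        assert cyl.radius == pytest.approx(np.sqrt(100_000.0 / (50.0 * np.pi)), rel=1e-9)
        assert cyl.radius == pytest.approx(25.2313, abs=1e-3)

    def test_fraction_scaling_is_sqrt2(self, box_pcl):
        tumor = np.array([0.0, 20.0, 0.0])
        r05 = make_excision_cylinder(box_pcl, tumor, 0.05).radius
        r10 = make_excision_cylinder(box_pcl, tumor, 0.10).radius
        assert r10 / r05 == pytest.approx(np.sqrt(2.0), rel=1e-12)

    @given(
        fraction=st.floats(0.01, 0.20),
        height=st.floats(10.0, 80.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_volume_identity(self, fraction, height):
        breast_volume = 1_000_000.0
        radius = np.sqrt(fraction * breast_volume / (np.pi * height))
        cyl = ExcisionCylinder(
            base_point=np.zeros(3),
            axis=np.array([0.0, 1.0, 0.0]),
            height=height,
            radius=radius,
            volume_fraction=fraction,
            tumor_center=np.array([0.0, height / 2, 0.0]),
        )
        assert cyl.volume / breast_volume == pytest.approx(fraction, rel=1e-6)

    def test_axis_is_unit_and_perpendicular_to_chest_wall(self, box_pcl):
        cyl = make_excision_cylinder(box_pcl, np.array([10.0, 25.0, 10.0]), 0.075)
        assert np.linalg.norm(cyl.axis) == pytest.approx(1.0)
        assert np.allclose(np.abs(cyl.axis), [0, 1, 0])

    def test_fraction_above_bcs_bound_rejected(self, box_pcl):
        with pytest.raises(ValueError):
            make_excision_cylinder(box_pcl, np.array([0.0, 20.0, 0.0]), 0.25)


class TestLabelDamaged:
    def test_axis_midpoint_damaged_and_outside_radius_healthy(self, box_pcl):
        cyl = make_excision_cylinder(box_pcl, np.array([0.0, 20.0, 0.0]), 0.10)
        mid = cyl.base_point + 0.5 * cyl.height * cyl.axis
        outside = mid + np.array([cyl.radius + 1e-6, 0.0, 0.0])
        probe = BreastPCL(
            points=np.vstack([box_pcl.points, mid, outside]),
            n_surface=box_pcl.n_surface,
            n_interior=box_pcl.n_interior + 2,
            laterality="R",
            nipple=box_pcl.nipple,
            pectoral_corners=box_pcl.pectoral_corners,
            breast_volume=box_pcl.breast_volume,
        )
        labels = label_damaged(probe, cyl)
        assert labels[-2] and not labels[-1]

    def test_matches_brute_force_oracle(self, small_case):
        cyl = small_case.cylinder
        expected = []
        for p in small_case.pre.points:
            rel = p - cyl.base_point
            t = float(rel @ cyl.axis)
            radial = float(np.linalg.norm(rel - t * cyl.axis))
            expected.append(0 <= t <= cyl.height and radial <= cyl.radius)
        assert np.array_equal(label_damaged(small_case.pre, cyl), np.array(expected))


class TestTumorSampler:
    @pytest.mark.parametrize("quadrant", QUADRANTS)
    def test_sampled_center_is_in_requested_quadrant(self, box_pcl, quadrant):
        planes = build_quadrant_planes(box_pcl)
        rng = np.random.default_rng(7)
        center = sample_tumor_center(box_pcl, quadrant, 0.05, rng, planes)
        assert assign_quadrant(center[None, :], planes, "R")[0] == quadrant
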