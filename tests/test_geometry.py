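"""Coral shapes, analytic areas/volumes, and mesh zone tagging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraltherm import geometry as G


class TestShapes:
    def test_hemisphere_area_volume(self):
        r = 0.0175
        c = G.CoralShape(G.HEMISPHERE, r)
        assert G.surface_area(c) == pytest.approx(3 * math.pi * r**2)
        assert G.volume(c) == pytest.approx((2 / 3) * math.pi * r**3)
        assert G.volume(c) == pytest.approx(1.1225e-5, rel=1e-3)

    def test_cylinder_area_volume(self):
        c = G.CoralShape(G.CYLINDER, 0.003, height=0.006)
        assert G.volume(c) == pytest.approx(1.696e-7, rel=1e-3)
        assert G.surface_area(c) == pytest.approx(
            2 * math.pi * 0.003 * 0.006 + 2 * math.pi * 0.003**2
        )

    @pytest.mark.parametrize(
        "shape,expected",
        [
            (G.CoralShape(G.HEMISPHERE, 0.0175), 257.14),
            (G.CoralShape(G.HEMISPHERE, 0.025), 180.0),
            (G.CoralShape(G.CYLINDER, 0.003, height=0.006), 1000.0),
        ],
    )
    def test_av_ratio(self, shape, expected):
        assert G.av_ratio(shape) == pytest.approx(expected, rel=1e-3)

    @given(r=st.floats(min_value=1e-4, max_value=1.0))
    @settings(deadline=None, max_examples=50)
    def test_hemisphere_av_times_r_is_constant(self, r):
        c = G.CoralShape(G.HEMISPHERE, r, tissue_thickness=r / 10)
        assert G.av_ratio(c) * r == pytest.approx(4.5)

    @given(r=st.floats(min_value=1e-4, max_value=0.5), z=st.floats(min_value=1e-4, max_value=0.5))
    @settings(deadline=None, max_examples=50)
    def test_cylinder_av_closed_form(self, r, z):
        c = G.CoralShape(G.CYLINDER, r, height=z, tissue_thickness=r / 10)
        assert G.av_ratio(c) == pytest.approx(2 / r + 2 / z)

    def test_degenerate_radius_shrinks_area_and_volume(self):
        # A, V -> 0 continuously as r -> 0
        for r in (1e-3, 1e-5, 1e-7):
            c = G.CoralShape(G.HEMISPHERE, r, tissue_thickness=r / 4)
            assert G.surface_area(c) < 3 * math.pi * 1e-5
            assert G.volume(c) < 1e-8 or r > 1e-4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="hemisphere", radius=-0.01),
            dict(kind="hemisphere", radius=0.0),
            dict(kind="cylinder", radius=0.01),  # missing height
            dict(kind="cylinder", radius=0.01, height=-0.01),
            dict(kind="hemisphere", radius=0.01, tissue_thickness=0.02),
            dict(kind="cone", radius=0.01),
        ],
    )
    def test_invalid_shapes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            G.CoralShape(**kwargs)


class TestMesh:
    def test_zone_volume_matches_analytic_hemisphere(self):
        coral = G.CoralShape(G.HEMISPHERE, 0.0175)
        mesh = G.build_mesh(G.ChamberDomain(), coral, (56, 30, 30))
        v = mesh.zone_volume(G.TISSUE, G.SKELETON)
        assert v == pytest.approx(G.volume(coral), rel=0.05)

    def test_zone_volume_converges_under_refinement(self):
        coral = G.CoralShape(G.HEMISPHERE, 0.0175)
        errs = []
        for res in [(50, 26, 26), (64, 34, 34)]:
            mesh = G.build_mesh(G.ChamberDomain(), coral, res)
            v = mesh.zone_volume(G.TISSUE, G.SKELETON)
            errs.append(abs(v / G.volume(coral) - 1))
        assert errs[1] < errs[0]

    def test_cylinder_zone_is_vertical_column_on_floor(self):
        coral = G.CoralShape(G.CYLINDER, 0.003, height=0.006)
        mesh = G.build_mesh(G.ChamberDomain(), coral, (52, 36, 34))
        zmask = mesh.coral_mask()
        # coral occupies cells from the floor up to ~6 mm and nowhere above
        k_top = np.nonzero(zmask.any(axis=(0, 1)))[0].max()
        assert mesh.zc[k_top] < 0.006
        assert mesh.zc[k_top] > 0.006 - 2 * mesh.dz[k_top]
        assert zmask[:, :, 0].any()  # sits on the floor
        v = mesh.zone_volume(G.TISSUE, G.SKELETON)
        assert v == pytest.approx(G.volume(coral), rel=0.25)

    def test_tissue_forms_shell_over_skeleton(self):
        coral = G.CoralShape(G.HEMISPHERE, 0.0175)
        mesh = G.build_mesh(G.ChamberDomain(), coral, (56, 30, 30))
        assert (mesh.zone == G.TISSUE).any()
        assert (mesh.zone == G.SKELETON).any()
        # every surface cell (coral cell with a fluid neighbour) is tissue
        surf, _ = mesh.surface_cells()
        assert (mesh.zone[surf] == G.TISSUE).mean() > 0.9

    def test_zone_labels_partition_cells(self):
        coral = G.CoralShape(G.HEMISPHERE, 0.0175)
        mesh = G.build_mesh(G.ChamberDomain(), coral, (56, 30, 30))
        assert set(np.unique(mesh.zone)) <= {G.FLUID, G.TISSUE, G.SKELETON}

    def test_oversized_coral_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            G.build_mesh(G.ChamberDomain(), G.CoralShape(G.HEMISPHERE, 0.04), (56, 30, 30))

    def test_coarse_resolution_rejected(self):
        coral = G.CoralShape(G.CYLINDER, 0.0015, height=0.006)
        with pytest.raises(ValueError, match="too coarse"):
            G.build_mesh(G.ChamberDomain(), coral, (20, 10, 10))

    def test_patch_areas_cover_outer_surface(self):
        dom = G.ChamberDomain()
        mesh = G.build_empty_mesh(dom, (12, 6, 6))
        # outer surface: 2*(LW + LH + WH)
        L, W, H = dom.length, dom.width, dom.height
        outer = 2 * (L * W + L * H + W * H)
        dx, dy, dz = mesh.dx, mesh.dy, mesh.dz
        patch = (
            2 * np.outer(dy, dz).sum()  # inlet + outlet
            + 2 * np.outer(dx, dz).sum()  # sides
            + 2 * np.outer(dx, dy).sum()  # bottom + top
        )
        assert patch == pytest.approx(outer)

    def test_graded_axis_ratio_bounded(self):
        nodes = G.graded_axis(0.25, (0.09, 0.14), 40, ratio=1.2)
        d = np.diff(nodes)
        ratios = np.maximum(d[1:] / d[:-1], d[:-1] / d[1:])
        assert ratios.max() <= 1.2 * 1.35  # rescaling slack at side junctions
        assert nodes[0] == 0.0 and nodes[-1] == pytest.approx(0.25)

    def test_refinement_near_coral(self):
        coral = G.CoralShape(G.HEMISPHERE, 0.0175)
        mesh = G.build_mesh(G.ChamberDomain(), coral, (56, 30, 30))
        assert mesh.fine_spacing() * 2 <= mesh.dx.max()
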