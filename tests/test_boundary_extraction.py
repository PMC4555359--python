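import numpy as np
import pytest

import phasecell as pc
from conftest import random_embedded_nucleus
from phasecell.boundary_extraction import (
    BoundaryContour,
    NoNucleusError,
    extract_contours,
    inflexion_field,
    phase_center_centroid,
    phase_center_extremum,
    reconcile_centers,
)
from phasecell.phase_forward import PhaseMap


def fit_ellipse_axes(points):
    """Centre and axis-aligned semi-axes of a near-axis-aligned ellipse."""
    c = points[:-1].mean(axis=0)
    d = points - c
    coef, *_ = np.linalg.lstsq(d**2, np.ones(len(points)), rcond=None)
    return c, 1.0 / np.sqrt(coef)


class TestInflexionField:
    def test_constant_map_gives_zero_field(self):
        pm = PhaseMap(values=np.full((64, 64), 2.5), plane="xy",
                      pixel_size=0.1, origin=np.zeros(2), wavelength=0.488)
        np.testing.assert_array_equal(inflexion_field(pm), 0.0)

    def test_rejects_wrapped_input(self, monocyte_maps):
        w = pc.wrap_phase(monocyte_maps[0])
        with pytest.raises(ValueError):
            inflexion_field(w)

    def test_negative_sigma_rejected(self, monocyte_maps):
        with pytest.raises(ValueError):
            inflexion_field(monocyte_maps[0], smoothing_sigma=-1.0)

    def test_homogeneous_ellipsoid_ridge_on_silhouette(self):
        # the extracted boundary must coincide with the projected ellipse to
        # sub-pixel accuracy
        sc = pc.build_two_ellipsoid_cell(
            membrane_semiaxes=(3.4, 3.7, 3.0), nucleus_semiaxes=(1, 1, 1),
        )
        sc.parts = sc.parts[:1]  # membrane only: homogeneous ellipsoid
        pm = pc.project_phase(sc, "xy")
        cs = extract_contours(inflexion_field(pm), pm)
        assert len(cs) == 1 and cs[0].label == "cell"
        r = np.sqrt((cs[0].points[:, 0] / 3.4) ** 2
                    + (cs[0].points[:, 1] / 3.7) ** 2)
        assert np.abs(r - 1.0).max() * 3.4 < pm.pixel_size


class TestExtractContours:
    def test_monocyte_two_nested_loops_per_view(self, monocyte_contours):
        for plane, cs in monocyte_contours.items():
            labels = sorted(c.label for c in cs)
            assert labels == ["cell", "nucleus"]
            cell = next(c for c in cs if c.label == "cell")
            nuc = next(c for c in cs if c.label == "nucleus")
            assert cell.contains(nuc)
            assert all(len(c.points) >= 17 for c in cs)

    def test_monocyte_xy_nucleus_matches_preset_ellipse(self, monocyte_contours):
        nuc = next(c for c in monocyte_contours["xy"] if c.label == "nucleus")
        c, semi = fit_ellipse_axes(nuc.points)
        np.testing.assert_allclose(c, [0, 0], atol=0.05)
        np.testing.assert_allclose(semi, [3.4, 3.7], atol=0.1)

    def test_homogeneous_sphere_has_cell_contour_only(self):
        sc = pc.build_two_ellipsoid_cell(nucleus_semiaxes=(1, 1, 1))
        sc.parts = sc.parts[:1]
        pm = pc.project_phase(sc, "xy")
        cs = extract_contours(inflexion_field(pm), pm)
        assert [c.label for c in cs] == ["cell"]

    def test_two_ellipsoid_model_has_contours_on_both_planes(self):
        sc = pc.build_two_ellipsoid_cell()
        for plane in ("xy", "xz"):
            pm = pc.project_phase(sc, plane)
            labels = {c.label for c in extract_contours(inflexion_field(pm), pm)}
            assert labels == {"cell", "nucleus"}

    def test_flat_map_raises(self):
        pm = PhaseMap(values=np.zeros((64, 64)), plane="xy", pixel_size=0.1,
                      origin=np.zeros(2), wavelength=0.488)
        with pytest.raises(NoNucleusError):
            extract_contours(np.zeros((64, 64)), pm)

    def test_ellipse_recovery_sweep(self):
        # ten random nucleus placements: contour-fit centre and semi-axes
        # within two pixels of truth
        rng = np.random.default_rng(21)
        tol = 2 * 0.0625
        for _ in range(10):
            semi, cen, sc = random_embedded_nucleus(rng)
            pm = pc.project_phase(sc, "xy")
            cs = extract_contours(inflexion_field(pm), pm)
            nuc = min((c for c in cs if c.label == "nucleus"),
                      key=lambda c: c.area)
            c, ab = fit_ellipse_axes(nuc.points)
            assert np.abs(c - cen[:2]).max() < tol
            assert np.abs(ab - semi[:2]).max() < tol

    def test_nesting_preserved_under_rotation(self, monocyte_maps):
        # 90° image rotation must not change the contour topology
        pm = monocyte_maps[0]
        rot = PhaseMap(values=np.rot90(pm.values).copy(), plane=pm.plane,
                       pixel_size=pm.pixel_size, origin=pm.origin,
                       wavelength=pm.wavelength)
        cs0 = extract_contours(inflexion_field(pm), pm)
        cs1 = extract_contours(inflexion_field(rot), rot)
        assert sorted(c.label for c in cs0) == sorted(c.label for c in cs1)
        for a, b in zip(sorted(c.area for c in cs0), sorted(c.area for c in cs1)):
            assert a == pytest.approx(b, rel=0.01)


class TestPhaseCenters:
    def test_extremum_monocyte_xy_at_origin(self, monocyte_maps, monocyte_contours):
        ctr = phase_center_extremum(monocyte_maps[0], monocyte_contours["xy"])
        np.testing.assert_allclose(ctr.coordinates, [0, 0], atol=0.0625)

    def test_extremum_symmetric_model_exact(self):
        sc = pc.build_two_ellipsoid_cell()
        pm = pc.project_phase(sc, "xy")
        ctr = phase_center_extremum(pm)
        np.testing.assert_allclose(ctr.coordinates, [0, 0], atol=1e-9)

    def test_extremum_monocyte_xz_inside_nucleus(self, monocyte_maps, monocyte_contours):
        # the x-z phase maximum is pulled towards the membrane equator but
        # must stay inside the nucleus contour (z between 0 and 6)
        ctr = phase_center_extremum(monocyte_maps[1], monocyte_contours["xz"])
        assert abs(ctr.coordinates[0]) < 0.1
        assert 0.0 < ctr.coordinates[1] < 6.0

    def test_centroid_and_extremum_agree_for_symmetric_model(self):
        sc = pc.build_two_ellipsoid_cell()
        pm = pc.project_phase(sc, "xy")
        cs = extract_contours(inflexion_field(pm), pm)
        nuc = next(c for c in cs if c.label == "nucleus")
        ce = phase_center_extremum(pm, cs).coordinates
        cc = phase_center_centroid(nuc).coordinates
        assert np.abs(ce - cc).max() < 2 * pm.pixel_size

    def test_centroid_reference_shapes(self):
        t = np.linspace(0, 2 * np.pi, 181)
        ellipse = BoundaryContour(
            plane="xz",
            points=np.stack([2 * np.cos(t), 3.0 + np.sin(t)], axis=1),
        )
        np.testing.assert_allclose(
            phase_center_centroid(ellipse).coordinates, [0, 3.0], atol=1e-9
        )
        s = np.linspace(0, 1, 6)[:-1]
        square = np.concatenate([
            np.stack([s, np.zeros_like(s)], 1),
            np.stack([np.ones_like(s), s], 1),
            np.stack([1 - s, np.ones_like(s)], 1),
            np.stack([np.zeros_like(s), 1 - s], 1),
            [[0, 0]],
        ])
        sq = BoundaryContour(plane="xy", points=square)
        np.testing.assert_allclose(
            phase_center_centroid(sq).coordinates, [0.5, 0.5], atol=1e-12
        )

    def test_monocyte_xz_centroid_near_preset_z(self, monocyte_contours):
        nuc = next(c for c in monocyte_contours["xz"] if c.label == "nucleus")
        ctr = phase_center_centroid(nuc)
        assert ctr.coordinates[0] == pytest.approx(0.0, abs=0.05)
        assert ctr.coordinates[1] == pytest.approx(3.0, abs=0.1)


class TestReconcileCenters:
    def test_monocyte_reconciles_to_preset_centre(self, monocyte_contours):
        nxy = next(c for c in monocyte_contours["xy"] if c.label == "nucleus")
        nxz = next(c for c in monocyte_contours["xz"] if c.label == "nucleus")
        centre = reconcile_centers(
            phase_center_centroid(nxy), phase_center_centroid(nxz)
        )
        np.testing.assert_allclose(centre, [0, 0, 3.0], atol=0.1)

    def test_identical_centres_merge_exactly(self):
        from phasecell.boundary_extraction import PhaseCenter

        a = PhaseCenter(plane="xy", coordinates=(0.3, -0.2), method="centroid")
        b = PhaseCenter(plane="xz", coordinates=(0.3, 1.1), method="centroid")
        np.testing.assert_array_equal(
            reconcile_centers(a, b), [0.3, -0.2, 1.1]
        )

    def test_inconsistent_x_raises(self):
        from phasecell.boundary_extraction import PhaseCenter

        a = PhaseCenter(plane="xy", coordinates=(0.0, 0.0), method="centroid")
        b = PhaseCenter(plane="xz", coordinates=(1.0, 0.0), method="centroid")
        with pytest.raises(NoNucleusError):
            reconcile_centers(a, b, tol=0.2)
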