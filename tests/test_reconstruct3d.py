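import numpy as np
import pytest

import phasecell as pc
from phasecell.boundary_extraction import BoundaryContour
from phasecell.phase_forward import PhaseMap, ThicknessMap
from phasecell.reconstruct3d import (
    ContainmentError,
    _loft,
    fit_ellipsoid,
    merge_orthogonal,
    nucleus_thickness_from_mesh,
    outer_surface_thickness,
    rotate_outline,
)


def circle_contour(r=3.0, n=721, cx=0.0, cy=0.0, plane="xy"):
    t = np.linspace(0, 2 * np.pi, n)
    return BoundaryContour(
        plane=plane, points=np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], 1)
    )


def ellipse_contour(a, b, plane="xy", n=721):
    t = np.linspace(0, 2 * np.pi, n)
    return BoundaryContour(plane=plane, points=np.stack([a * np.cos(t), b * np.sin(t)], 1))


class TestRotateOutline:
    def test_circle_gives_sphere_volume(self):
        mesh = rotate_outline(circle_contour(3.0), n_steps=180, n_stations=180)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(36 * np.pi, rel=0.01)

    def test_ellipse_about_major_axis_gives_prolate_spheroid(self):
        mesh = rotate_outline(ellipse_contour(3.4, 3.0), n_steps=180, n_stations=180)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 3.4 * 3.0**2, rel=0.01)

    def test_outline_crossing_axis_many_times_rejected(self):
        t = np.linspace(0, 2 * np.pi, 361)
        wavy = np.stack([3 * np.cos(t), 0.4 * np.sin(3 * t)], 1)
        contour = BoundaryContour(plane="xy", points=wavy)
        with pytest.raises(ValueError):
            rotate_outline(contour, axis_offset=0.0)


class TestMergeOrthogonal:
    def test_congruent_circles_reduce_to_rotation(self):
        c = circle_contour(2.5)
        merged = merge_orthogonal(c, circle_contour(2.5, plane="xz"))
        rotated = rotate_outline(c, axis_offset=0.0)
        assert merged.volume == pytest.approx(rotated.volume, rel=0.005)
        assert merged.volume == pytest.approx(4 / 3 * np.pi * 2.5**3, rel=0.01)

    def test_ellipse_pair_gives_triaxial_ellipsoid(self):
        m = merge_orthogonal(ellipse_contour(3.4, 3.7),
                             ellipse_contour(3.4, 3.0, plane="xz"))
        assert m.is_watertight
        assert m.volume == pytest.approx(4 / 3 * np.pi * 3.4 * 3.7 * 3.0, rel=0.01)

    def test_disjoint_x_ranges_rejected(self):
        far = circle_contour(1.0, cx=10.0, plane="xz")
        with pytest.raises(ValueError):
            merge_orthogonal(circle_contour(1.0), far)


class TestFitEllipsoid:
    def test_exact_ellipsoid_mesh_recovered(self):
        m = merge_orthogonal(ellipse_contour(3.40, 3.70),
                             ellipse_contour(3.40, 3.00, plane="xz"))
        rep = fit_ellipsoid(mesh=m, center=(0, 0, 0))
        np.testing.assert_allclose(rep.semi_axes, [3.40, 3.70, 3.00], atol=0.01)
        assert rep.equivalent_volume == pytest.approx(158.06, abs=1.0)
        assert rep.residual < 1e-3

    def test_unit_sphere_ratios(self):
        m = rotate_outline(circle_contour(1.0), n_steps=120, n_stations=120)
        rep = fit_ellipsoid(mesh=m, center=(0, 0, 0))
        np.testing.assert_allclose(rep.semi_axes, 1.0, atol=0.01)
        np.testing.assert_allclose(rep.ellipsoidal_degree, 1.0, atol=0.01)

    def test_contour_pair_input(self):
        rep = fit_ellipsoid(contours=(ellipse_contour(3.0, 2.0),
                                      ellipse_contour(3.0, 2.5, plane="xz")),
                            center=(0, 0, 0))
        np.testing.assert_allclose(rep.semi_axes, [3.0, 2.0, 2.5], atol=0.02)

    def test_non_ellipsoidal_surface_warns(self):
        # lumpy star-shaped surface: residual above 10% of the mean semi-axis
        t = np.linspace(0, 2 * np.pi, 721)
        r = 2.0 + 0.9 * np.cos(4 * t)
        lumpy = BoundaryContour(plane="xy",
                                points=np.stack([r * np.cos(t), r * np.sin(t)], 1))
        mesh = rotate_outline(lumpy, axis_offset=0.0)
        with pytest.warns(UserWarning, match="non-ellipsoidal"):
            fit_ellipsoid(mesh=mesh, center=(0, 0, 0))


class TestThicknessFromMesh:
    def test_sphere_chords_and_volume_consistency(self):
        mesh = rotate_outline(circle_contour(3.0), n_steps=180, n_stations=180)
        tm = nucleus_thickness_from_mesh(mesh, "xy", pixel_size=0.05, field=8.0)
        i = np.argmin(np.abs(tm.coords()[0]))
        j = np.argmin(np.abs(tm.coords()[1]))
        assert tm.values[j, i] == pytest.approx(6.0, abs=0.02)
        assert tm.values[0, 0] == 0.0
        assert tm.integral() == pytest.approx(mesh.volume, rel=0.01)

    def test_non_watertight_mesh_rejected(self):
        mesh = rotate_outline(circle_contour(2.0))
        broken = mesh.copy()
        broken.faces = broken.faces[:-1]
        with pytest.raises(ValueError):
            nucleus_thickness_from_mesh(broken)


class TestOuterSurfaceThickness:
    n1, n2, nm, lam = 1.37, 1.39, 1.003, 0.488

    def synth(self, h1, h2):
        phi = 2 * np.pi * ((self.n1 - self.nm) * h1 + (self.n2 - self.n1) * h2) / self.lam
        pm = PhaseMap(values=phi, plane="xy", pixel_size=0.1,
                      origin=np.zeros(2), wavelength=self.lam)
        tm = ThicknessMap(values=h2, plane="xy", pixel_size=0.1, origin=np.zeros(2))
        return pm, tm

    def test_algebraic_round_trip(self):
        rng = np.random.default_rng(8)
        h1 = np.abs(rng.normal(5, 1, (48, 48)))
        h2 = np.abs(rng.normal(2, 0.5, (48, 48)))
        pm, tm = self.synth(h1, h2)
        rec = outer_surface_thickness(pm, tm, self.n1, self.n2, self.nm)
        assert np.abs(rec.values - h1).max() < 1e-6

    def test_zero_nucleus_limit(self):
        h1 = np.full((16, 16), 4.0)
        pm, tm = self.synth(h1, np.zeros((16, 16)))
        rec = outer_surface_thickness(pm, tm, self.n1, self.n2, self.nm)
        expected = self.lam * pm.values / (2 * np.pi * (self.n1 - self.nm))
        np.testing.assert_allclose(rec.values, expected, atol=1e-12)

    def test_index_contract(self):
        pm, tm = self.synth(np.ones((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            outer_surface_thickness(pm, tm, n1=1.0, n2=1.39, nm=1.003)

    def test_monocyte_centre_pixel_recovers_membrane_chord(self, monocyte_result):
        h1 = monocyte_result.maps["h1_xy"]
        i = np.argmin(np.abs(h1.coords()[0]))
        j = np.argmin(np.abs(h1.coords()[1]))
        assert h1.values[j, i] == pytest.approx(10.0, abs=0.1)


class TestAssembleCell:
    def test_monocyte_pipeline_containment_holds(self, monocyte_result):
        assert monocyte_result.membrane_mesh is not None
        # membrane volume against the analytic two-half-ellipsoid volume
        true_vol = 2 / 3 * np.pi * 36 * (6.5 + 3.5)
        assert monocyte_result.membrane_mesh.volume == pytest.approx(
            true_vol, rel=0.02
        )

    def test_inflated_nucleus_raises(self, monocyte_result):
        big = monocyte_result.nucleus_mesh.copy()
        big.vertices = big.vertices * 2.0
        with pytest.raises(ContainmentError, match="μm"):
            pc.assemble_cell(monocyte_result.membrane_mesh, big,
                             monocyte_result.center_centroid)

    def test_thickness_map_pair_input(self, monocyte):
        h_xy = pc.thickness_map(monocyte, "xy", compartment="membrane")
        h_xz = pc.thickness_map(monocyte, "xz", compartment="membrane")
        nucleus = pc.thickness_map(monocyte, "xy", compartment="nucleus")
        small = rotate_outline(circle_contour(1.0, cy=0.0), n_steps=60,
                               n_stations=60)
        small.vertices = small.vertices + np.array([0, 0, 3.0])
        out = pc.assemble_cell((h_xy, h_xz), small, np.array([0, 0, 3.0]))
        assert set(out) == {"membrane", "nucleus"}
        true_vol = 2 / 3 * np.pi * 36 * (6.5 + 3.5)
        assert out["membrane"].volume == pytest.approx(true_vol, rel=0.02)


def test_volume_consistency_through_pipeline(monocyte_result):
    rep = monocyte_result.report
    h2 = monocyte_result.maps["h2_xy"]
    assert rep.mesh_volume == pytest.approx(rep.equivalent_volume, rel=0.02)
    assert h2.integral() == pytest.approx(rep.mesh_volume, rel=0.02)


def test_loft_orientation_always_outward():
    xs = np.array([0, 0.5, 1.5, 2.0])
    m = _loft(xs, np.zeros(4), np.zeros(4), np.array([0, 1, 1, 0.0]),
              np.array([0, 1, 1, 0.0]), 32)
    assert m.is_watertight and m.volume > 0
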