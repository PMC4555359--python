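import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasecell as pc
from phasecell.cell_models import Ellipsoid, RefractiveIndexScene
from phasecell.phase_forward import (
    PhaseMap,
    _union_length,
    brute_force_phase,
    ray_phase,
)

K488 = 2 * np.pi / 0.488


def sphere_scene(radius=6.0, n=1.37, nm=1.003):
    part = Ellipsoid(center=(0, 0, 0), refractive_index=n, priority=1,
                     semi_axes=(radius, radius, radius))
    return RefractiveIndexScene([part], medium_index=nm)


class TestProjectPhase:
    def test_homogeneous_sphere_centre_value(self):
        # (2π/0.488)·(1.37−1.003)·12 = 56.70 rad
        pm = pc.project_phase(sphere_scene(), "xy")
        i = np.argmin(np.abs(pm.coords()[0]))
        j = np.argmin(np.abs(pm.coords()[1]))
        assert pm.values[j, i] == pytest.approx(K488 * 0.367 * 12.0, rel=1e-12)
        assert pm.values[j, i] == pytest.approx(56.70, abs=0.01)

    def test_far_field_pixels_exactly_zero(self, monocyte_maps):
        pm = monocyte_maps[0]
        assert pm.values[0, 0] == 0.0
        assert pm.values[:5].max() == 0.0

    def test_monocyte_centre_matches_phase_composition(self, monocyte, monocyte_maps):
        # φ = (2π/λ)[(n1−nm)h1 + (n2−n1)h2] with h1 = 10 μm, h2 = 6 μm
        pm = monocyte_maps[0]
        i = np.argmin(np.abs(pm.coords()[0]))
        j = np.argmin(np.abs(pm.coords()[1]))
        expected = K488 * ((1.37 - 1.003) * 10.0 + (1.39 - 1.37) * 6.0)
        assert pm.values[j, i] == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_plane_and_pixel(self, monocyte):
        with pytest.raises(ValueError):
            pc.project_phase(monocyte, "diagonal")
        with pytest.raises(ValueError):
            pc.project_phase(monocyte, "xy", pixel_size=0.0)


class TestChordLength:
    def test_ellipsoid_axis_chords(self):
        e = Ellipsoid(center=(0, 0, 0), refractive_index=1.39, priority=1,
                      semi_axes=(3.4, 3.7, 3.0))
        assert pc.chord_length(e, (0, 0, 0), "z") == pytest.approx(6.0)
        assert pc.chord_length(e, (3.4, 0, 0), "z") == pytest.approx(0.0, abs=1e-9)
        assert pc.chord_length(e, (1.7, 0, 0), "z") == pytest.approx(
            2 * 3.0 * np.sqrt(1 - 0.25)
        )

    def test_rejects_non_coordinate_axis(self):
        e = Ellipsoid(center=(0, 0, 0), refractive_index=1.39, priority=1,
                      semi_axes=(1, 1, 1))
        with pytest.raises(ValueError):
            pc.chord_length(e, (0, 0, 0), "w")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.5, 5), b=st.floats(0.5, 5), c=st.floats(0.5, 5),
        x=st.floats(-6, 6), y=st.floats(-6, 6),
    )
    def test_chord_matches_dense_sampling(self, a, b, c, x, y):
        e = Ellipsoid(center=(0.3, -0.2, 0.5), refractive_index=1.39, priority=1,
                      semi_axes=(a, b, c))
        z = np.linspace(-7, 7, 200001)
        pts = np.stack([np.full_like(z, x), np.full_like(z, y), z], axis=1)
        dense = e.contains(pts).sum() * (z[1] - z[0])
        assert pc.chord_length(e, (x, y, 0), "z") == pytest.approx(dense, abs=2e-4)


class TestForwardOracle:
    @pytest.mark.parametrize("name", sorted(pc.BUILDERS))
    def test_analytic_vs_brute_force_rays(self, name):
        # independent line-integral oracle (membership only, bisection-refined
        # boundaries) on seeded random coordinate-axis rays
        scene = pc.BUILDERS[name]()
        rng = np.random.default_rng(11)
        for _ in range(20):
            axis = int(rng.integers(0, 3))
            origin = rng.uniform(-5.5, 5.5, 3)
            analytic = ray_phase(scene, origin, axis)
            brute = brute_force_phase(scene, origin, axis)
            assert abs(analytic - brute) < 1e-3

    def test_two_part_linearity_with_overlap_correction(self, monocyte):
        # φ = (2π/λ)[(n1−nm)·chord_mem + (n2−n1)·chord_nuc] for a nucleus
        # fully inside the membrane
        mem, nuc = monocyte.parts
        rng = np.random.default_rng(12)
        for _ in range(20):
            origin = rng.uniform(-4, 4, 3)
            expected = K488 * (
                (1.37 - 1.003) * pc.chord_length(mem, origin, "z")
                + (1.39 - 1.37) * pc.chord_length(nuc, origin, "z")
            )
            assert ray_phase(monocyte, origin, "z") == pytest.approx(
                expected, abs=1e-9
            )


class TestWrapPhase:
    def test_reference_values(self):
        vals = np.array([[0.0, 56.70, np.pi, np.pi + 1e-6, -np.pi]])
        pm = PhaseMap(values=vals, plane="xy", pixel_size=1.0,
                      origin=np.zeros(2), wavelength=0.488)
        w = pc.wrap_phase(pm).values[0]
        assert w[0] == 0.0
        assert w[1] == pytest.approx(56.70 - 18 * np.pi)
        assert w[2] == pytest.approx(np.pi)
        assert w[3] == pytest.approx(-np.pi + 1e-6)
        assert w[4] == pytest.approx(np.pi)

    def test_wrap_of_wrapped_rejected(self, monocyte_maps):
        w = pc.wrap_phase(monocyte_maps[0])
        with pytest.raises(ValueError):
            pc.wrap_phase(w)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-1e4, 1e4))
    def test_wrap_properties(self, phi):
        pm = PhaseMap(values=np.full((1, 1), phi), plane="xy", pixel_size=1.0,
                      origin=np.zeros(2), wavelength=0.488)
        w = float(pc.wrap_phase(pm).values[0, 0])
        assert -np.pi < w <= np.pi + 1e-12
        k = (phi - w) / (2 * np.pi)
        assert k == pytest.approx(round(k), abs=1e-6)


class TestThicknessMap:
    def test_nucleus_chords_and_volume(self, monocyte):
        tm = pc.thickness_map(monocyte, "xy", compartment="nucleus")
        i = np.argmin(np.abs(tm.coords()[0]))
        j = np.argmin(np.abs(tm.coords()[1]))
        assert tm.values[j, i] == pytest.approx(6.0)
        assert tm.values[0, 0] == 0.0
        true_vol = 4 / 3 * np.pi * 3.4 * 3.7 * 3.0
        assert tm.integral() == pytest.approx(true_vol, rel=0.01)

    def test_unknown_compartment_raises(self, monocyte):
        with pytest.raises(ValueError):
            pc.thickness_map(monocyte, "xy", compartment=1.55)


class TestAddNoise:
    def test_zero_sigma_identity_and_determinism(self, monocyte_maps):
        pm = monocyte_maps[0]
        same = pc.add_noise(pm, 0.0, seed=1)
        np.testing.assert_array_equal(same.values, pm.values)
        a = pc.add_noise(pm, 0.05, seed=42)
        b = pc.add_noise(pm, 0.05, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_variance(self):
        pm = PhaseMap(values=np.zeros((1000, 1000)), plane="xy", pixel_size=1.0,
                      origin=np.zeros(2), wavelength=0.488)
        noisy = pc.add_noise(pm, sigma=0.3, seed=9)
        assert np.var(noisy.values) == pytest.approx(0.09, rel=0.02)

    def test_negative_sigma_rejected(self, monocyte_maps):
        with pytest.raises(ValueError):
            pc.add_noise(monocyte_maps[0], -0.1)


class TestCrossViewConsistency:
    def test_nucleus_x_extent_agrees_between_views(self, monocyte_contours):
        # the two orthogonal views share the x axis: the nucleus silhouette
        # must project to the same x interval in both
        nxy = next(c for c in monocyte_contours["xy"] if c.label == "nucleus")
        nxz = next(c for c in monocyte_contours["xz"] if c.label == "nucleus")
        for f in (np.min, np.max, np.mean):
            assert f(nxy.points[:, 0]) == pytest.approx(
                f(nxz.points[:, 0]), abs=0.15
            )


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_union_length_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 6))
    iv = np.sort(rng.uniform(0, 10, size=(1, k, 2)), axis=2)
    drop = rng.random((1, k)) < 0.3
    iv[drop] = np.nan
    grid = np.linspace(0, 10, 200001)
    covered = np.zeros_like(grid, dtype=bool)
    for a, b in iv[0]:
        if np.isfinite(a):
            covered |= (grid >= a) & (grid <= b)
    assert _union_length(iv)[0] == pytest.approx(
        covered.sum() * (grid[1] - grid[0]), abs=2e-3
    )
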