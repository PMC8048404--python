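"""Gauge-block step heights, mesh area/volume, longest axis."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

import scanforge as sf
from scanforge.metrology import RegionSpec


class TestStepHeight:
    @pytest.mark.parametrize("heights,expected", [
        ((1.50, 1.00), 0.500),
        ((1.10, 1.00), 0.100),
        ((1.05, 1.00), 0.050),
    ])
    def test_ideal_gauge_pairs_exact(self, heights, expected):
        fx = sf.make_step_cubes(heights, noise_sd=0.0, n_vertices=2_500)
        mean, sd, n_top, n_ref = sf.step_height(
            fx.mesh, fx.top_region, fx.ref_region
        )
        assert mean == pytest.approx(expected, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert n_top > 0 and n_ref > 0

    def test_noisy_gauge_mean_and_sd(self):
        # i.i.d. vertical noise sigma = 5 um on 10^4 vertices per plane:
        # the grand mean over seeds stays within 3*sigma/sqrt(n) of nominal
        # and the per-pair sd approaches sigma*sqrt(2)
        sigma, n = 0.005, 10_000
        means, sds = [], []
        for seed in range(30):
            fx = sf.make_step_cubes((1.50, 1.00), noise_sd=sigma,
                                    n_vertices=n, seed=seed)
            m, sd, _, _ = sf.step_height(fx.mesh, fx.top_region, fx.ref_region)
            means.append(m)
            sds.append(sd)
        assert abs(np.mean(means) - 0.500) < 3 * sigma / np.sqrt(n)
        assert np.mean(sds) == pytest.approx(sigma * np.sqrt(2), rel=0.2)

    def test_top_equals_reference_gives_zero(self):
        fx = sf.make_step_cubes((1.50, 1.00), n_vertices=400)
        mean, _, _, _ = sf.step_height(fx.mesh, fx.top_region, fx.top_region)
        assert mean == 0.0

    def test_antisymmetric_in_regions(self):
        fx = sf.make_step_cubes((1.50, 1.00), noise_sd=0.002, n_vertices=900,
                                seed=4)
        fwd, _, _, _ = sf.step_height(fx.mesh, fx.top_region, fx.ref_region)
        rev, _, _, _ = sf.step_height(fx.mesh, fx.ref_region, fx.top_region)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(-100, 100, allow_nan=False))
    def test_translation_invariance(self, offset):
        fx = sf.make_step_cubes((1.50, 1.00), n_vertices=400)
        base, _, _, _ = sf.step_height(fx.mesh, fx.top_region, fx.ref_region)
        shifted = fx.mesh.copy()
        shifted.vertices = shifted.vertices + offset
        top = RegionSpec(
            tuple(np.array(fx.top_region.min_corner) + offset),
            tuple(np.array(fx.top_region.max_corner) + offset),
        )
        ref = RegionSpec(
            tuple(np.array(fx.ref_region.min_corner) + offset),
            tuple(np.array(fx.ref_region.max_corner) + offset),
        )
        moved, _, _, _ = sf.step_height(shifted, top, ref)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_empty_region_names_region(self):
        fx = sf.make_step_cubes((1.50, 1.00), n_vertices=400)
        empty = RegionSpec((900, 900, 900), (901, 901, 901), label="top")
        with pytest.raises(sf.InvalidInputError, match="top"):
            sf.step_height(fx.mesh, empty, fx.ref_region)


class TestSurfaceAndVolume:
    def test_unit_cube(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        area, volume = sf.surface_and_volume(cube)
        assert area == pytest.approx(6.0, abs=1e-12)
        assert volume == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_converges_to_closed_form(self):
        r = 2.0
        ico = trimesh.creation.icosphere(subdivisions=4, radius=r)
        area, volume = sf.surface_and_volume(ico)
        assert area == pytest.approx(4 * np.pi * r**2, rel=0.005)
        assert volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.005)

    def test_open_mesh_area_returned_volume_refused(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(
            vertices=cube.vertices, faces=cube.faces[:-1], process=False
        )
        assert sf.surface_area(open_mesh) == pytest.approx(5.5)
        with pytest.raises(sf.NotWatertightError) as err:
            sf.enclosed_volume(open_mesh)
        assert err.value.surface_area == pytest.approx(5.5)

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_scaling_laws(self, s):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        a0, v0 = sf.surface_and_volume(ico)
        scaled = ico.copy()
        scaled.vertices = scaled.vertices * s
        a1, v1 = sf.surface_and_volume(scaled)
        assert a1 == pytest.approx(a0 * s**2, rel=1e-9)
        assert v1 == pytest.approx(v0 * s**3, rel=1e-9)

    def test_volume_orientation_independent(self):
        cube = trimesh.creation.box(extents=(2, 1, 1))
        flipped = trimesh.Trimesh(
            vertices=cube.vertices, faces=cube.faces[:, ::-1], process=False
        )
        assert sf.enclosed_volume(flipped) == pytest.approx(
            sf.enclosed_volume(cube)
        )


class TestLongestAxis:
    def test_unit_cube_diagonal(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        assert sf.longest_axis(cube) == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_two_point_distance(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [0, 0, 36.3], [0, 0.01, 18.0]],
            faces=[[0, 1, 2]], process=False,
        )
        assert sf.longest_axis(mesh) == pytest.approx(36.3)

    def test_hull_path_matches_brute_force(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(200, 3))
        mesh = trimesh.Trimesh(
            vertices=pts, faces=[[0, 1, 2]], process=False
        )
        brute = np.sqrt(
            ((pts[:, None] - pts[None]) ** 2).sum(-1).max()
        )
        assert sf.longest_axis(mesh, exact_below=10) == pytest.approx(brute)
        assert sf.longest_axis(mesh, exact_below=10_000) == pytest.approx(brute)
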