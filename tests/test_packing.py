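"""Plane intersections, plane-frame rotation, Voronoi packing and RDF."""

import numpy as np
import pytest

from quasicryst.eigenplane import Eigenplane, fit_eigenplane
from quasicryst.model_io import SimulationBox
from quasicryst.packing import (com_rdf, neighbor_distance_histogram,
                                plane_line_intersection,
                                rotation_to_plane_frame, to_plane_2d,
                                voronoi_tessellate)
from quasicryst.synthetic import (CrystalliteSpec, generate_crystallite,
                                  hexagonal_spacing)

SQRT3 = np.sqrt(3.0)


def random_unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestPlaneLineIntersection:
    def test_vertical_line_horizontal_plane(self):
        plane = Eigenplane(np.array([0.0, 0.0, 1.0]), 5.0)
        p, l = plane_line_intersection([1.0, 1.0, 0.0], [1.0, 1.0, 2.0], plane)
        assert l == pytest.approx(2.5)
        np.testing.assert_allclose(p, [1.0, 1.0, 5.0])

    def test_start_point_on_plane_gives_l_zero(self):
        plane = Eigenplane(np.array([0.0, 0.0, 1.0]), 0.0)
        p, l = plane_line_intersection([2.0, 3.0, 0.0], [2.0, 3.0, 1.0], plane)
        assert l == 0.0
        np.testing.assert_allclose(p, [2.0, 3.0, 0.0])

    def test_oblique_plane(self):
        plane = Eigenplane(np.full(3, 1 / SQRT3), SQRT3)  # x+y+z = 3
        p, _ = plane_line_intersection([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], plane)
        np.testing.assert_allclose(p, [1.0, 1.0, 1.0], atol=1e-12)

    def test_parallel_line_raises(self):
        plane = Eigenplane(np.array([0.0, 0.0, 1.0]), 0.0)
        with pytest.raises(ValueError, match="in the plane"):
            plane_line_intersection([0, 0, 1.0], [1.0, 0, 1.0], plane)

    def test_postcondition_on_random_lines_and_planes(self, rng):
        """Intersection points satisfy the plane equation (1000 draws)."""
        normals = random_unit(rng, 1000)
        ds = rng.uniform(-5, 5, 1000)
        c3 = rng.uniform(-5, 5, (1000, 3))
        c13 = c3 + random_unit(rng, 1000) * 1.27
        for n, d, a, b in zip(normals, ds, c3, c13):
            if abs((b - a) @ n) < 1e-6:
                continue
            p, _ = plane_line_intersection(a, b, Eigenplane(n, d))
            assert abs(p @ n - d) < 1e-9


class TestRotationToPlaneFrame:
    def test_z_normal_is_identity(self):
        plane = Eigenplane(np.array([0.0, 0.0, 1.0]), 0.0)
        np.testing.assert_allclose(rotation_to_plane_frame(plane), np.eye(3))

    def test_x_normal(self):
        plane = Eigenplane(np.array([1.0, 0.0, 0.0]), 0.0)
        R = rotation_to_plane_frame(plane)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_hundred_random_normals(self, rng):
        for n in random_unit(rng, 100):
            R = rotation_to_plane_frame(Eigenplane(n, 0.0))
            np.testing.assert_allclose(R @ n, [0, 0, 1], atol=1e-12)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_in_plane_points_land_on_z_zero(self, rng):
        n = random_unit(rng, 1)[0]
        plane = Eigenplane(n, 1.7)
        # random in-plane points
        basis = np.linalg.svd(n[None, :])[2][1:]
        pts = 1.7 * n + rng.normal(size=(20, 2)) @ basis
        R = rotation_to_plane_frame(plane)
        assert np.allclose((pts @ R.T)[:, 2], 1.7, atol=1e-9)


def hex_lattice(n, a):
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pts = np.stack([i * a + j * a / 2, j * a * SQRT3 / 2], axis=-1)
    return pts.reshape(-1, 2)


class TestVoronoi:
    def test_hexagonal_lattice_oracle(self):
        a = hexagonal_spacing(0.195)
        cells = voronoi_tessellate(hex_lattice(10, a))
        interior = [c for c in cells if not c.is_boundary]
        assert len(interior) > 0
        for c in interior:
            assert len(c.neighbor_ids) == 6
            assert c.area == pytest.approx(0.195, rel=1e-9)
            np.testing.assert_allclose(c.neighbor_distances, a, atol=1e-9)

    def test_hexagonal_neighbors_match_brute_force(self):
        a = 1.0
        pts = hex_lattice(8, a)
        cells = voronoi_tessellate(pts)
        for c in cells:
            if c.is_boundary:
                continue
            # oracle: neighbors of a hexagonal site are exactly the
            # points at distance a
            d = np.linalg.norm(pts - pts[c.molecule_id], axis=1)
            oracle = set(np.flatnonzero(np.abs(d - a) < 1e-9).tolist())
            assert set(c.neighbor_ids.tolist()) == oracle
            assert c.area == pytest.approx(SQRT3 / 2, rel=1e-9)

    def test_square_lattice_corner_touching_cells_are_not_neighbors(self):
        i, j = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
        pts = np.stack([i, j], axis=-1).reshape(-1, 2).astype(float)
        cells = voronoi_tessellate(pts)
        interior = [c for c in cells if not c.is_boundary]
        assert len(interior) > 0
        for c in interior:
            assert len(c.neighbor_ids) == 4
            assert c.area == pytest.approx(1.0, rel=1e-9)

    def test_rotation_equivariance(self, rng):
        pts = hex_lattice(6, 0.5) + rng.normal(0, 0.01, (36, 2))
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        c0 = voronoi_tessellate(pts)
        c1 = voronoi_tessellate(pts @ R.T)
        for a, b in zip(c0, c1):
            assert a.is_boundary == b.is_boundary
            np.testing.assert_array_equal(a.neighbor_ids, b.neighbor_ids)
            if not a.is_boundary:
                assert a.area == pytest.approx(b.area, abs=1e-9)
                np.testing.assert_allclose(a.neighbor_distances,
                                           b.neighbor_distances, atol=1e-9)

    def test_collinear_points_raise(self):
        with pytest.raises(ValueError):
            voronoi_tessellate(np.column_stack([np.arange(5.0), np.arange(5.0)]))

    def test_intersections_reproduce_generator_lattice(self):
        """Noiseless crystallite: in-plane key points = the 2D lattice."""
        spec = CrystalliteSpec(n_a=5, n_b=5, tilt_deg=12.0,
                               rotation=(30, 50, 70))
        frame, table, truth = generate_crystallite(spec)
        plane = fit_eigenplane(frame.coords[table.position_indices(8)])
        pts3, _ = plane_line_intersection(frame.coords[table.position_indices(3)],
                                          frame.coords[table.position_indices(13)],
                                          plane)
        pts2 = to_plane_2d(pts3, plane)
        a = hexagonal_spacing(spec.area_per_molecule)
        i, j = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        ref = np.stack([i * a + j * a / 2, j * a * SQRT3 / 2],
                       axis=-1).reshape(-1, 2)

        def dist_multiset(p):
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            return np.sort(d[np.triu_indices(len(p), 1)])

        np.testing.assert_allclose(dist_multiset(pts2), dist_multiset(ref),
                                   atol=1e-9)


class TestNeighborHistogram:
    def test_ideal_lattice_single_distance(self):
        cells = voronoi_tessellate(hex_lattice(8, 1.0))
        centers, w = neighbor_distance_histogram([cells], bin_width=0.01)
        nz = centers[w > 0]
        # all mass within one bin width of the unique lattice distance
        # (it may straddle a bin edge at machine precision)
        assert 1 <= len(nz) <= 2
        assert np.all(np.abs(nz - 1.0) <= 0.01)
        assert w.sum() == pytest.approx(1.0)

    def test_distorted_lattice_is_bimodal(self):
        spec = CrystalliteSpec(lattice="distorted_hexagonal", n_a=8, n_b=8,
                               distortion=1.15)
        frame, table, truth = generate_crystallite(spec)
        plane = fit_eigenplane(frame.coords[table.position_indices(8)])
        pts3, _ = plane_line_intersection(frame.coords[table.position_indices(3)],
                                          frame.coords[table.position_indices(13)],
                                          plane)
        cells = voronoi_tessellate(to_plane_2d(pts3, plane))
        centers, w = neighbor_distance_histogram([cells], bin_width=0.002)
        peaks = centers[w > 0]
        for spacing in truth.spacings:
            assert np.min(np.abs(peaks - spacing)) < 0.002

    def test_all_boundary_warns_and_returns_empty(self, caplog):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.2]])
        cells = voronoi_tessellate(pts)
        with caplog.at_level("WARNING"):
            centers, w = neighbor_distance_histogram([cells])
        assert centers.size == 0 and "no interior" in caplog.text


class TestComRdf:
    def test_delta_pair(self):
        box = SimulationBox(10, 10, 10)
        pts = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 3.5]])
        rdf = com_rdf([pts], box, bin_width=0.1)
        nz = rdf.bin_centers[rdf.g > 0]
        assert len(nz) == 1 and abs(nz[0] - 2.5) < 0.1

    def test_uniform_points_give_unit_g(self, rng):
        box = SimulationBox(5, 5, 5)
        frames = [rng.uniform(0, 5, (200, 3)) for _ in range(10)]
        rdf = com_rdf(frames, box, bin_width=0.1)
        mask = rdf.bin_centers > 1.0
        assert np.all(np.abs(rdf.g[mask] - 1.0) < 0.15)

    def test_lattice_first_peak_at_spacing(self):
        spec = CrystalliteSpec(n_a=8, n_b=8)
        frame, table, truth = generate_crystallite(spec)
        from quasicryst.model_io import molecule_com
        com = molecule_com(frame, table)
        rdf = com_rdf([com], frame.box, bin_width=0.01)
        a = truth.spacings[0]
        first = rdf.bin_centers[np.flatnonzero(rdf.g > 0)[0]]
        assert abs(first - a) < 0.01

    def test_normalization_integral_counts_neighbors(self):
        spec = CrystalliteSpec(n_a=6, n_b=6)
        frame, table, _ = generate_crystallite(spec)
        from quasicryst.model_io import molecule_com
        com = molecule_com(frame, table)
        box = frame.box
        rdf = com_rdf([com], box, bin_width=0.01)
        density = len(com) / np.prod(box.lengths)
        integral = np.sum(rdf.g * density * 4 * np.pi
                          * rdf.bin_centers ** 2 * rdf.bin_width)
        # oracle: direct minimum-image pair count within r_max
        d = com[:, None] - com[None, :]
        d -= np.round(d / box.lengths) * box.lengths
        dist = np.linalg.norm(d, axis=-1)
        expected = (dist[np.triu_indices(len(com), 1)] <= rdf.r_max).sum() \
            * 2 / len(com)
        assert integral == pytest.approx(expected, rel=0.05)

    def test_r_max_validation(self):
        box = SimulationBox(4, 4, 4)
        with pytest.raises(ValueError):
            com_rdf([np.zeros((3, 3))], box, r_max=3.0)
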