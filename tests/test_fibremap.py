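"""Strand-to-element fibre mapping, RBF smoothing and ortho-card export."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from myofe import (
    DataError,
    ElementFibreField,
    FibreStrand,
    TetMesh,
    effective_direction,
    line_of_best_fit,
    map_fibres,
    smooth_fibre_field,
    strand_segments_in_element,
)
from myofe.fibremap import FibreRun, export_element_solid_ortho, run_weights
from myofe.meshkit import bounding_box_diagonal, element_centroids_volumes
from myofe.phantoms import make_box_mesh, make_cylinder_mesh, make_strands


def single_tet():
    nodes = np.array(
        [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], float
    )
    return TetMesh(nodes, np.array([[0, 1, 2, 3]]))


class TestStrandSegments:
    def test_strand_fully_inside_is_one_run(self):
        mesh = single_tet()
        pts = np.column_stack([np.linspace(1, 3, 6), np.ones(6), np.ones(6)])
        runs = strand_segments_in_element(FibreStrand(pts, 1), mesh, 0)
        assert len(runs) == 1
        assert runs[0].n_points == 6

    def test_in_out_in_gives_two_runs(self):
        """Brute-force point classification splits the strand correctly."""
        mesh = single_tet()
        # x path: inside, inside, outside (x>10), inside, inside
        xs = [1.0, 2.0, 30.0, 2.0, 1.0]
        pts = np.column_stack([xs, np.full(5, 0.5), np.full(5, 0.5)])
        runs = strand_segments_in_element(FibreStrand(pts, 1), mesh, 0)
        assert [r.n_points for r in runs] == [2, 2]
        # oracle: explicit barycentric classification
        from myofe.fibremap import points_in_tet

        inside = points_in_tet(mesh.nodes[mesh.elements[0]], pts)
        np.testing.assert_array_equal(inside, [True, True, False, True, True])

    def test_no_points_inside_gives_empty(self):
        mesh = single_tet()
        pts = np.column_stack([np.linspace(50, 60, 4), np.zeros(4), np.zeros(4)])
        assert strand_segments_in_element(FibreStrand(pts, 1), mesh, 0) == []

    def test_boundary_point_counts_as_inside(self):
        mesh = single_tet()
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])  # vertex + interior
        runs = strand_segments_in_element(FibreStrand(pts, 1), mesh, 0)
        assert runs and runs[0].n_points == 2


class TestLineOfBestFit:
    def test_collinear_points_exact(self):
        d = np.array([1.0, 2.0, 2.0]) / 3.0
        pts = np.outer(np.arange(5), d)
        np.testing.assert_allclose(line_of_best_fit(pts), d, atol=1e-12)

    def test_two_points_give_normalised_difference(self):
        pts = np.array([[0, 0, 0], [3.0, 0, 4.0]])
        np.testing.assert_allclose(line_of_best_fit(pts), [0.6, 0, 0.8])

    def test_noisy_line_within_one_degree(self, rng):
        d = np.array([0.0, 0.0, 1.0])
        t = np.linspace(0, 10, 100)
        pts = np.outer(t, d) + rng.normal(0, 0.01, (100, 3))
        g = line_of_best_fit(pts)
        angle = np.degrees(np.arccos(min(abs(np.dot(g, d)), 1.0)))
        assert angle < 1.0

    def test_sign_follows_traversal(self):
        pts = np.outer(np.arange(5)[::-1], [0, 0, 1.0])  # traversed downward
        g = line_of_best_fit(pts)
        assert g[2] < 0


class TestEffectiveDirection:
    def test_weights_three_one(self):
        """Runs with n = (3, 1) points weight as (0.9, 0.1)."""
        runs = [
            FibreRun(np.array([0.0, 0, 1.0]), 3),
            FibreRun(np.array([0.0, 1.0, 0]), 1),
        ]
        np.testing.assert_allclose(run_weights(runs), [0.9, 0.1])

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            ns = rng.integers(1, 30, rng.integers(1, 8))
            runs = [FibreRun(np.array([0.0, 0, 1.0]), int(n)) for n in ns]
            assert run_weights(runs).sum() == pytest.approx(1.0)

    def test_single_run_returns_its_direction(self):
        g = np.array([0.6, 0.0, 0.8])
        runs = [FibreRun(g, 5)]
        np.testing.assert_allclose(effective_direction(runs), g)

    def test_antiparallel_runs_resolve_to_common_axis(self):
        runs = [
            FibreRun(np.array([0.0, 0, 1.0]), 4),
            FibreRun(np.array([0.0, 0, -1.0]), 4),
        ]
        d = effective_direction(runs)
        np.testing.assert_allclose(np.abs(d), [0, 0, 1.0], atol=1e-12)

    def test_result_is_unit_and_weighted(self):
        a = np.array([1.0, 0, 0])
        b = np.array([0.0, 1.0, 0])
        d = effective_direction([FibreRun(a, 3), FibreRun(b, 1)])
        expect = 0.9 * a + 0.1 * b
        np.testing.assert_allclose(d, expect / np.linalg.norm(expect))


class TestMapFibres:
    def test_axial_strands_on_cylinder(self):
        mesh = make_cylinder_mesh(6, 12, 2.5)
        strands = make_strands(
            "line", n_strands=6, n_points=14, spacing=1.2,
            step=1.0, direction=(0, 0, 1), origin=(-3, 0, -0.5),
        )
        field = map_fibres(mesh, strands)
        hit = ~field.missing
        assert hit.sum() > 0
        np.testing.assert_allclose(
            np.abs(field.directions[hit][:, 2]), 1.0, atol=1e-9
        )


class TestSmoothing:
    def _constant_field(self, mesh, d):
        n = mesh.n_elements
        dirs = np.tile(np.asarray(d, float), (n, 1))
        return ElementFibreField(dirs, np.ones(n, int))

    def test_constant_field_identity(self, cylinder_mesh):
        d = np.array([0.0, 0.0, 1.0])
        field = self._constant_field(cylinder_mesh, d)
        out = smooth_fibre_field(cylinder_mesh, field)
        np.testing.assert_allclose(np.abs(out.directions @ d), 1.0, atol=1e-12)

    def test_missing_element_filled_from_constant_surroundings(self, cylinder_mesh):
        d = np.array([0.0, 0.0, 1.0])
        field = self._constant_field(cylinder_mesh, d)
        field.directions[7] = np.nan
        field.source_counts[7] = 0
        out = smooth_fibre_field(cylinder_mesh, field)
        assert not out.missing.any()
        np.testing.assert_allclose(np.abs(out.directions[7] @ d), 1.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        """Kernel-weighted average equals the O(N^2) oracle to 1e-12."""
        mesh = make_box_mesh(2, 2, 2)
        n = mesh.n_elements
        dirs = rng.standard_normal((n, 3))
        # hemisphere-align everything to +z so sign flips cannot differ
        dirs[dirs[:, 2] < 0] *= -1
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        field = ElementFibreField(dirs, np.ones(n, int))
        p = 20.0
        out = smooth_fibre_field(mesh, field, p=p)

        centroids, _ = element_centroids_volumes(mesh)
        L = bounding_box_diagonal(mesh.nodes)
        for i in range(n):
            total = np.zeros(3)
            for e in range(n):
                r = np.linalg.norm(centroids[i] - centroids[e])
                phi = np.exp(-((p * r / L) ** 2))
                sign = 1.0 if dirs[e] @ dirs[i] >= 0 else -1.0
                total += phi * sign * dirs[e]
            total /= np.linalg.norm(total)
            np.testing.assert_allclose(out.directions[i], total, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        mesh = make_box_mesh(2, 2, 2)
        n = mesh.n_elements
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        field = ElementFibreField(dirs.copy(), np.ones(n, int))
        # fixed kernel width: the AABB diagonal itself is orientation
        # dependent, the kernel average is not
        out = smooth_fibre_field(mesh, field, p=1.0, length_scale=1.0)

        R = Rotation.from_euler("xyz", [0.4, -0.2, 0.9]).as_matrix()
        rot_mesh = TetMesh(mesh.nodes @ R.T, mesh.elements, mesh.part_labels)
        rot_field = ElementFibreField(dirs @ R.T, np.ones(n, int))
        rot_out = smooth_fibre_field(rot_mesh, rot_field, p=1.0, length_scale=1.0)
        # neighbours genuinely mix at this kernel width
        assert np.abs(np.einsum("ij,ij->i", out.directions, dirs)).min() < 1 - 1e-6
        np.testing.assert_allclose(rot_out.directions, out.directions @ R.T,
                                   atol=1e-9)

    def test_no_seeded_direction_leaves_part_missing(self, cylinder_mesh):
        n = cylinder_mesh.n_elements
        field = ElementFibreField(np.full((n, 3), np.nan), np.zeros(n, int))
        out = smooth_fibre_field(cylinder_mesh, field)
        assert out.missing.all()


def parse_ortho_deck(path):
    """Independent minimal parser for *ELEMENT_SOLID_ORTHO cards."""
    cards = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if not l.startswith("*")]
    for i in range(0, len(lines), 3):
        head = [int(lines[i][j : j + 8]) for j in range(0, len(lines[i]), 8)]
        a = [float(t) for t in lines[i + 1].split()]
        d = [float(t) for t in lines[i + 2].split()]
        cards.append((head[0], head[1], head[2:6], np.array(a), np.array(d)))
    return cards


class TestOrthoExport:
    def test_single_element_round_trip(self, tmp_path):
        mesh = single_tet()
        d = np.array([[0.6, 0.0, 0.8]])
        field = ElementFibreField(d, np.array([1]))
        path = tmp_path / "ortho.k"
        export_element_solid_ortho(mesh, field, path)
        cards = parse_ortho_deck(path)
        assert len(cards) == 1
        eid, pid, conn, a, dvec = cards[0]
        assert eid == 1 and pid == 1
        assert conn == [1, 2, 3, 4]  # 1-based ids preserved
        np.testing.assert_allclose(a, d[0], atol=1e-8)
        assert abs(np.dot(a, dvec)) < 1e-8  # second axis orthogonal
        assert np.linalg.norm(dvec) == pytest.approx(1.0, abs=1e-8)

    def test_missing_direction_falls_back_with_warning(self, tmp_path, caplog):
        mesh = single_tet()
        field = ElementFibreField(np.full((1, 3), np.nan), np.array([0]))
        path = tmp_path / "ortho.k"
        import logging

        with caplog.at_level(logging.WARNING, logger="myofe.fibremap"):
            export_element_solid_ortho(mesh, field, path)
        assert any("fallback" in r.message for r in caplog.records)
        _, _, _, a, _ = parse_ortho_deck(path)[0]
        np.testing.assert_allclose(a, [1.0, 0.0, 0.0])
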