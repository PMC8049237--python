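"""Quality-metric oracles: scaled Jacobian, Stokes volumes, edge stats."""

import numpy as np
import pytest

from cardioshape.mesh import TetMesh
from cardioshape.mesh_metrics import (
    cavity_volume_stokes,
    edge_length_stats,
    lumped_anatomy,
    scaled_jacobian,
    tet_volumes,
    unique_edges,
)

from conftest import random_tet_mesh
from test_io_formats import REGULAR_TET


# ----------------------------------------------------------------------
# independent oracle: per-corner determinant / edge-product formula
# ----------------------------------------------------------------------
def sj_oracle(p):
    """Scaled Jacobian of one tetrahedron, coded from the definition."""
    vals = []
    for v in range(4):
        others = [o for o in range(4) if o != v]
        # order the edge triple to keep the element's signed volume
        det = np.linalg.det(np.array([p[o] - p[v] for o in others]))
        if v in (1, 3):
            det = -det
        prod = np.prod([np.linalg.norm(p[o] - p[v]) for o in others])
        vals.append(0.0 if prod == 0 else det / prod)
    return np.sqrt(2.0) * min(vals)


def test_regular_tet_scores_one():
    mesh = TetMesh(points=REGULAR_TET, tets=[[0, 1, 2, 3]])
    assert scaled_jacobian(mesh)[0] == pytest.approx(1.0, abs=1e-12)


def test_coplanar_tet_scores_zero():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    mesh = TetMesh(points=pts, tets=[[0, 1, 2, 3]])
    assert scaled_jacobian(mesh)[0] == pytest.approx(0.0, abs=1e-12)


def test_repeated_vertices_warn_not_raise():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    mesh = TetMesh(points=pts, tets=[[0, 1, 2, 2]])
    with pytest.warns(RuntimeWarning):
        assert scaled_jacobian(mesh)[0] == 0.0


def test_sj_matches_independent_formula(rng):
    mesh = random_tet_mesh(rng, n_tets=100)
    sj = scaled_jacobian(mesh)
    expected = [sj_oracle(mesh.points[t]) for t in mesh.tets]
    assert np.allclose(sj, expected, atol=1e-12)


def test_sj_invariant_under_rigid_motion_and_scaling(rng):
    from scipy.spatial.transform import Rotation

    mesh = random_tet_mesh(rng, n_tets=20)
    sj0 = scaled_jacobian(mesh)
    rot = Rotation.random(random_state=1).as_matrix()
    moved = mesh.with_points(3.7 * (mesh.points @ rot.T) + np.array([5.0, -2.0, 1.0]))
    assert np.allclose(scaled_jacobian(moved), sj0, atol=1e-10)


# ----------------------------------------------------------------------
# Stokes volumes
# ----------------------------------------------------------------------
def unit_cube_surface():
    pts = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    quads = [
        (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
        (2, 3, 7, 6), (1, 2, 6, 5), (0, 4, 7, 3),
    ]
    tris = []
    for a, b, c, d in quads:
        tris += [[a, b, c], [a, c, d]]
    return pts, np.array(tris)


def icosphere(radius, subdivisions):
    t = (1 + np.sqrt(5)) / 2
    pts = np.array(
        [[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
         [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
         [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    pts = [p / np.linalg.norm(p) for p in pts]
    for _ in range(subdivisions):
        cache, new_faces = {}, []

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = pts[i] + pts[j]
                pts.append(m / np.linalg.norm(m))
                cache[key] = len(pts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return radius * np.array(pts), np.array(faces)


def test_unit_cube_volume():
    pts, tris = unit_cube_surface()
    assert cavity_volume_stokes(pts, tris) == pytest.approx(0.001, rel=1e-12)


def test_icosphere_volume_within_one_percent():
    pts, tris = icosphere(10.0, 4)
    analytic = 4.0 / 3.0 * np.pi * 1000.0 / 1000.0  # mL
    assert cavity_volume_stokes(pts, tris) == pytest.approx(analytic, rel=0.01)


def test_inward_orientation_raises():
    pts, tris = icosphere(10.0, 2)
    with pytest.raises(ValueError, match="orientation"):
        cavity_volume_stokes(pts, tris[:, [0, 2, 1]])


def test_open_surface_raises():
    pts, tris = unit_cube_surface()
    with pytest.raises(ValueError, match="not closed"):
        cavity_volume_stokes(pts, tris[:-1])


def test_stokes_equals_signed_tet_decomposition(rng):
    """Divergence-theorem volume == fan tetrahedral decomposition volume."""
    pts, tris = icosphere(7.0, 2)
    fan_tets = np.column_stack([np.full(len(tris), len(pts)), tris])
    fan_pts = np.vstack([pts, rng.uniform(-3, 3, 3)])
    fan = np.abs(tet_volumes(fan_pts, fan_tets).sum()) / 1000.0
    assert cavity_volume_stokes(pts, tris) == pytest.approx(fan, rel=1e-10)


# ----------------------------------------------------------------------
# edges
# ----------------------------------------------------------------------
def test_single_regular_tet_edge_stats():
    mesh = TetMesh(points=REGULAR_TET, tets=[[0, 1, 2, 3]])
    mean, sd, lo, hi = edge_length_stats(mesh)
    assert mean == pytest.approx(1.0, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_edge_stats_scale_linearly():
    mesh = TetMesh(points=REGULAR_TET, tets=[[0, 1, 2, 3]])
    doubled = mesh.with_points(2.0 * mesh.points)
    assert edge_length_stats(doubled)[0] == pytest.approx(
        2.0 * edge_length_stats(mesh)[0]
    )


def test_two_tets_sharing_face_have_nine_unique_edges():
    pts = np.vstack([REGULAR_TET, [[0.5, np.sqrt(3) / 6, -np.sqrt(2.0 / 3.0)]]])
    tets = np.array([[0, 1, 2, 3], [0, 1, 2, 4]])
    assert unique_edges(tets).shape[0] == 9


# ----------------------------------------------------------------------
# lumped anatomy
# ----------------------------------------------------------------------
def test_thick_shell_wall_volume_within_two_percent():
    """Tet-summed wall volume of an icosphere shell vs the analytic shell."""
    r_in, r_out = 25.0, 35.0
    pts_i, tris = icosphere(r_in, 3)
    pts_o = pts_i * (r_out / r_in)
    n = len(pts_i)
    pts = np.vstack([pts_i, pts_o])
    tets = []
    for a, b, c in tris:  # prisms between matched surfaces -> 3 tets
        tets += [[a, b, c, a + n], [b, c, a + n, b + n], [c, a + n, b + n, c + n]]
    vol = np.abs(tet_volumes(pts, np.array(tets))).sum()
    analytic = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
    assert vol == pytest.approx(analytic, rel=0.02)


def test_mass_is_density_times_wall_volume(template):
    an = lumped_anatomy(template, density=1.05)
    assert an.lv.mass == pytest.approx(an.lv.wall_volume * 1.05, rel=1e-12)
    # the published-cohort arithmetic convention: mass/density = wall volume
    assert 139.68 / 1.05 == pytest.approx(133.028, abs=1e-3)


def test_cavity_volume_scales_cubically(template):
    from cardioshape.synthetic_anatomy import AnatomyParams, deform_template

    base = lumped_anatomy(template)
    scaled = lumped_anatomy(deform_template(template, AnatomyParams(scale=1.3)))
    assert scaled.lv.edv == pytest.approx(base.lv.edv * 1.3**3, rel=1e-6)
    assert scaled.rv.edv == pytest.approx(base.rv.edv * 1.3**3, rel=1e-6)


def test_lumped_anatomy_requires_labels(template):
    bare = template.copy()
    bare.cell_labels = None
    with pytest.raises(ValueError, match="labels"):
        lumped_anatomy(bare)
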