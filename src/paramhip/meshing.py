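"""Low-level spherical-patch meshing.

The parameterised surfaces are all spherical patches bounded by analytic cut
curves (sphere-plane and sphere-cylinder intersections).  Instead of a
general boolean CSG engine, patches are triangulated directly:

* a polar grid over a spherical cap (rings of near-equal edge length around
  the cap axis), whose last ring lies exactly on the rim-plane cut circle;
* a marching-triangle clipper that removes the region on one side of a
  scalar field and snaps every newly created boundary vertex exactly (to
  machine precision) onto the analytic cut curve.

Exact boundary vertices are what makes parameter round-trips from generated
geometry well-posed: the labelled edge rings lie on their defining
primitives to ~1e-12 mm.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "spherical_cap_mesh",
    "clip_mesh",
    "project_to_sphere",
    "cylinder_x_projector",
    "cylinder_z_projector",
    "plane_y_projector",
    "vertex_areas",
    "orthonormal_tangents",
]

_DEGENERATE_AREA = 1e-12  # mm^2; faces below this are discarded after a clip


def orthonormal_tangents(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed tangent pair (e1, e2) perpendicular to axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - axis * (seed @ axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _stitch_rings(ring_a: np.ndarray, ring_b: np.ndarray,
                  m_a: int, m_b: int) -> list[tuple[int, int, int]]:
    """Triangulate the annulus between two concentric vertex rings.

    Rings are index arrays of length ``m_a``/``m_b``; vertices sit at evenly
    spaced azimuths starting at zero.  A two-pointer merge on azimuth yields
    ``m_a + m_b`` well-shaped triangles regardless of the count ratio.
    """
    faces = []
    i = j = 0
    while i < m_a or j < m_b:
        next_a = (i + 1) / m_a
        next_b = (j + 1) / m_b
        if j >= m_b or (i < m_a and next_a <= next_b):
            faces.append((ring_a[i % m_a], ring_b[j % m_b], ring_a[(i + 1) % m_a]))
            i += 1
        else:
            faces.append((ring_a[i % m_a], ring_b[(j + 1) % m_b], ring_b[j % m_b]))
            j += 1
    return faces


def spherical_cap_mesh(radius: float, pole_axis: np.ndarray, theta_max: float,
                       n_rings: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the cap {v : |v| = radius, angle(v, pole_axis) <= theta_max}.

    Vertices on ring ``j`` lie at colatitude ``theta_max * j / n_rings``; the
    last ring is exactly the cap boundary circle.  Ring vertex counts scale
    with ``sin(theta)`` so triangle edges stay near-uniform.

    Returns ``(vertices (N,3), faces (M,3))`` with faces wound so that face
    normals point toward the sphere centre (the articular "outward" side).
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    if not (0 < theta_max <= np.pi):
        raise ValueError("theta_max must lie in (0, pi]")
    pole = np.asarray(pole_axis, dtype=float)
    pole = pole / np.linalg.norm(pole)
    e1, e2 = orthonormal_tangents(pole)

    d_theta = theta_max / n_rings
    verts = [radius * pole]
    rings: list[np.ndarray] = [np.array([0])]
    counts = [1]
    for j in range(1, n_rings + 1):
        theta = theta_max * j / n_rings
        m = max(6, int(round(2.0 * np.pi * np.sin(theta) / d_theta)))
        phi = 2.0 * np.pi * np.arange(m) / m
        ring = radius * (
            np.cos(theta) * pole[None, :]
            + np.sin(theta) * (np.cos(phi)[:, None] * e1[None, :]
                               + np.sin(phi)[:, None] * e2[None, :])
        )
        start = len(verts)
        verts.extend(ring)
        rings.append(start + np.arange(m))
        counts.append(m)

    faces: list[tuple[int, int, int]] = []
    # pole fan
    m1 = counts[1]
    for k in range(m1):
        faces.append((0, rings[1][k], rings[1][(k + 1) % m1]))
    for j in range(1, n_rings):
        faces.extend(_stitch_rings(rings[j], rings[j + 1], counts[j], counts[j + 1]))

    vertices = np.asarray(verts, dtype=float)
    faces_arr = np.asarray(faces, dtype=np.int64)
    # orient normals anti-radially (toward the sphere centre)
    v0, v1, v2 = (vertices[faces_arr[:, k]] for k in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    centroid = (v0 + v1 + v2) / 3.0
    flip = np.einsum("ij,ij->i", n, centroid) > 0
    faces_arr[flip] = faces_arr[flip][:, ::-1]
    return vertices, faces_arr


def clip_mesh(vertices: np.ndarray, faces: np.ndarray, signed: np.ndarray,
              project: Callable[[np.ndarray], np.ndarray],
              tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, bool]:
    """Remove the mesh region where ``signed > tol``.

    ``signed`` is a per-vertex scalar field, negative on the kept side and
    zero on the cut surface.  Triangles straddling the zero level set are
    split along it; each interpolated crossing point is passed through
    ``project``, which must return the exact nearest point on the analytic
    cut curve (cut surface intersected with the sphere).

    Returns ``(vertices, faces, changed)`` with unreferenced vertices
    compacted.  ``changed`` is False when the field never exceeded ``tol``
    (the cut missed the mesh entirely).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    signed = np.asarray(signed, dtype=float)
    outside = signed > tol
    if not outside.any():
        return vertices, faces, False

    n_out = outside[faces].sum(axis=1)
    keep_faces = list(faces[n_out == 0])
    mixed = faces[(n_out == 1) | (n_out == 2)]

    new_vertices = list(vertices)
    edge_cache: dict[tuple[int, int], int] = {}

    def crossing(vi: int, vo: int) -> int:
        key = (vi, vo) if vi < vo else (vo, vi)
        idx = edge_cache.get(key)
        if idx is not None:
            return idx
        si, so = signed[vi], signed[vo]
        t = si / (si - so)  # si <= tol < so, so denominator > 0
        p = vertices[vi] + np.clip(t, 0.0, 1.0) * (vertices[vo] - vertices[vi])
        p = project(p)
        idx = len(new_vertices)
        new_vertices.append(np.asarray(p, dtype=float))
        edge_cache[key] = idx
        return idx

    for tri in mixed:
        out_mask = outside[tri]
        if out_mask.sum() == 2:
            # one kept vertex: a single smaller triangle survives
            k = int(np.flatnonzero(~out_mask)[0])
            a = int(tri[k]); b = int(tri[(k + 1) % 3]); c = int(tri[(k + 2) % 3])
            keep_faces.append((a, crossing(a, b), crossing(a, c)))
        else:
            # one removed vertex: the kept quad splits into two triangles
            k = int(np.flatnonzero(out_mask)[0])
            a = int(tri[k]); b = int(tri[(k + 1) % 3]); c = int(tri[(k + 2) % 3])
            pab = crossing(b, a)
            pca = crossing(c, a)
            keep_faces.append((b, c, pca))
            keep_faces.append((b, pca, pab))

    all_vertices = np.asarray(new_vertices, dtype=float)
    faces_arr = np.asarray(keep_faces, dtype=np.int64).reshape(-1, 3)

    # drop degenerate slivers created by crossings that landed on a vertex
    v0, v1, v2 = (all_vertices[faces_arr[:, k]] for k in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    faces_arr = faces_arr[areas > _DEGENERATE_AREA]

    used = np.zeros(len(all_vertices), dtype=bool)
    used[faces_arr.ravel()] = True
    remap = -np.ones(len(all_vertices), dtype=np.int64)
    remap[used] = np.arange(used.sum())
    return all_vertices[used], remap[faces_arr], True


# -- exact projectors onto cut-curve intersections ---------------------------

def project_to_sphere(radius: float) -> Callable[[np.ndarray], np.ndarray]:
    def proj(p: np.ndarray) -> np.ndarray:
        return p * (radius / np.linalg.norm(p))
    return proj


def cylinder_x_projector(center_yz, r: float, sphere_radius: float):
    """Project onto the intersection of sphere |p| = R with the cylinder of
    radius r about the x-directed axis through (y, z) = center_yz."""
    cy, cz = center_yz

    def proj(p: np.ndarray) -> np.ndarray:
        psi = np.arctan2(p[2] - cz, p[1] - cy)
        y = cy + r * np.cos(psi)
        z = cz + r * np.sin(psi)
        x2 = sphere_radius ** 2 - y ** 2 - z ** 2
        x = np.sign(p[0]) * np.sqrt(max(x2, 0.0))
        return np.array([x, y, z])

    return proj


def cylinder_z_projector(center_xy, r: float, sphere_radius: float):
    """As :func:`cylinder_x_projector` for a z-directed (lateral) cylinder."""
    cx, cy = center_xy

    def proj(p: np.ndarray) -> np.ndarray:
        psi = np.arctan2(p[1] - cy, p[0] - cx)
        x = cx + r * np.cos(psi)
        y = cy + r * np.sin(psi)
        z2 = sphere_radius ** 2 - x ** 2 - y ** 2
        z = np.sign(p[2]) * np.sqrt(max(z2, 0.0))
        return np.array([x, y, z])

    return proj


def plane_y_projector(y0: float, sphere_radius: float):
    """Project onto the circle sphere(R) intersect plane y = y0."""
    rho = np.sqrt(max(sphere_radius ** 2 - y0 ** 2, 0.0))

    def proj(p: np.ndarray) -> np.ndarray:
        xz = np.array([p[0], p[2]])
        nrm = np.linalg.norm(xz)
        if nrm == 0.0:
            xz = np.array([rho, 0.0])
        else:
            xz = xz * (rho / nrm)
        return np.array([xz[0], y0, xz[1]])

    return proj


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric lumped vertex areas (one third of each adjacent facet)."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    fa = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    va = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(va, faces[:, k], fa / 3.0)
    return va
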