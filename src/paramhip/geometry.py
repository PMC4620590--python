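"""Constructive generation of the parameterised acetabulum and cartilage.

The generation pipeline mirrors the five constructive steps of the model:

1. a 70 x 85 x 80 mm cuboid block standing in for the pelvis;
2. a spherical cut creating the acetabular cavity (radius ``cavity_radius``);
3. a plane cut with the desired inclination/anteversion creating the
   posterior rim, at signed distance ``depth_d`` from the cavity centre;
4. an anterior cut by a cylinder (axis perpendicular to the coronal plane)
   with centre ``o1`` and radius ``r1``;
5. cartilage extruded radially inward from the cavity surface, then cut by a
   lateral-axis cylinder (centre ``o2``, radius ``r2``) to create the fossa,
   with the acetabular notch approximated by a plane cut tangent to the
   inferior side of the fossa cylinder.

All cut curves are exact sphere-plane / sphere-cylinder intersections, so
labelled edge rings (posterior rim, anterior edge, fossa edge) lie on their
defining primitives to machine precision.  Everything is generated in the
canonical right-hip frame (x anterior, y superior, z lateral, origin at the
cavity centre); left hips are mirrored through the sagittal plane at the end.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import trimesh

from .errors import DomainError
from .meshing import (
    clip_mesh,
    cylinder_x_projector,
    cylinder_z_projector,
    plane_y_projector,
    spherical_cap_mesh,
    vertex_areas,
)
from .orientation import orientation_from_angles
from .params import AcetabularParameterSet

__all__ = [
    "ModelGeometry",
    "FemoralHead",
    "LabelledSurface",
    "build_bone_block",
    "apply_anterior_cut",
    "extrude_cartilage",
    "apply_fossa_and_notch_cut",
    "build_femoral_head",
    "build_model",
    "labelled_surface",
    "rings_for_facets",
]

CUBOID_DIMENSIONS = (70.0, 85.0, 80.0)  # mm, anterior x superior x lateral
DEFAULT_N_RINGS = 58  # ~13,000 facets on the lunate articular surface
LABEL_TOL = 1e-9  # mm, geometric predicate tolerance for edge labelling

REQUIRED_LABELS = ("articular", "posterior_rim", "anterior_edge", "fossa_edge")


@dataclasses.dataclass(frozen=True)
class FemoralHead:
    """Spherical femoral side: articular cartilage sphere over a bone sphere."""

    center: np.ndarray
    articular_radius: float
    bone_radius: float

    def mesh(self, subdivisions: int = 4) -> trimesh.Trimesh:
        m = trimesh.creation.icosphere(subdivisions=subdivisions,
                                       radius=self.articular_radius)
        m.apply_translation(self.center)
        return m


@dataclasses.dataclass
class LabelledSurface:
    """Point set with named anatomical region labels.

    ``labels`` maps region name to indices into ``points``; regions may
    overlap (edge rings are subsets of the surfaces they bound).
    """

    points: np.ndarray
    labels: dict[str, np.ndarray]
    side: str = "right"

    def region(self, name: str) -> np.ndarray:
        from .errors import LabelledInputError

        if name not in self.labels:
            raise LabelledInputError(
                f"surface is missing required region label {name!r}; "
                f"present: {sorted(self.labels)}")
        return self.points[self.labels[name]]


@dataclasses.dataclass
class ModelGeometry:
    """Labelled triangle meshes of one parameterised acetabulum model.

    Meshes live in the canonical frame until ``mirrored`` is set (left hips).
    ``bone_cavity`` is the spherical cavity surface of the pelvis block
    (radius ``cavity_radius``); ``articular`` is the cartilage articular
    surface (radius ``cavity_radius - t``), which after the fossa/notch cut
    is the lunate surface used for contact.
    """

    params: AcetabularParameterSet
    cup_axis: np.ndarray
    n_rings: int
    bone_cavity: trimesh.Trimesh
    bone_block: trimesh.Trimesh | None = None
    articular: trimesh.Trimesh | None = None
    cartilage: trimesh.Trimesh | None = None
    femoral_head: FemoralHead | None = None
    labels: dict[str, dict[str, np.ndarray]] = dataclasses.field(default_factory=dict)
    anterior_cut_applied: bool = False
    fossa_cut_applied: bool = False
    notch_cut_applied: bool = False
    mirrored: bool = False

    @property
    def frame(self) -> dict:
        return {
            "origin": "acetabular cavity centre",
            "axes": {"x": "anterior", "y": "superior", "z": "lateral (right hip)"},
            "side": self.params.side,
            "mirrored": self.mirrored,
        }

    def copy(self) -> "ModelGeometry":
        return dataclasses.replace(
            self,
            labels={m: dict(d) for m, d in self.labels.items()},
        )

    def lunate_area(self) -> float:
        if self.articular is None:
            raise DomainError("articular surface has not been generated yet")
        return float(self.articular.area)


def _as_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _cuboid_block() -> trimesh.Trimesh:
    box = trimesh.creation.box(extents=CUBOID_DIMENSIONS)
    # place the cavity centre (origin) 25 mm inside the lateral (+z) face so
    # the cavity sphere is contained in the block
    box.apply_translation([0.0, 0.0, -CUBOID_DIMENSIONS[2] / 2.0 + 25.0])
    return box


def build_bone_block(params: AcetabularParameterSet,
                     n_rings: int = DEFAULT_N_RINGS) -> ModelGeometry:
    """Stages 1-3: cuboid block, spherical cavity, posterior rim plane cut.

    The cavity surface is a spherical cap about the cup axis; its boundary
    ring (on the rim plane at signed distance ``depth_d`` from the cavity
    centre) is labelled ``posterior_rim``.
    """
    params.validate()
    R = params.cavity_radius
    d = params.depth_d
    if not abs(d) < R:
        raise DomainError("rim plane does not intersect the cavity sphere")
    axis = orientation_from_angles(params.inclination_deg, params.anteversion_deg,
                                   side="right")
    theta_max = float(np.arccos(-d / R))
    verts, faces = spherical_cap_mesh(R, -axis, theta_max, n_rings)
    cavity = _as_mesh(verts, faces)
    geo = ModelGeometry(params=params, cup_axis=axis, n_rings=n_rings,
                        bone_cavity=cavity, bone_block=_cuboid_block())
    _relabel_bone(geo)
    return geo


def _relabel_bone(geo: ModelGeometry) -> None:
    p = geo.params
    v = geo.bone_cavity.vertices
    labels: dict[str, np.ndarray] = {}
    rim = np.abs(v @ geo.cup_axis - p.depth_d) <= LABEL_TOL
    labels["posterior_rim"] = np.flatnonzero(rim)
    if geo.anterior_cut_applied:
        cy, cz = p.anterior_cut_center_o1
        dist = np.hypot(v[:, 1] - cy, v[:, 2] - cz)
        labels["anterior_edge"] = np.flatnonzero(
            np.abs(dist - p.anterior_cut_radius_r1) <= LABEL_TOL)
    geo.labels["bone_cavity"] = labels


def _relabel_articular(geo: ModelGeometry) -> None:
    p = geo.params
    v = geo.articular.vertices
    labels: dict[str, np.ndarray] = {"articular": np.arange(len(v))}
    if geo.fossa_cut_applied:
        cx, cy = p.fossa_center_o2
        dist = np.hypot(v[:, 0] - cx, v[:, 1] - cy)
        labels["fossa_edge"] = np.flatnonzero(
            np.abs(dist - p.fossa_radius_r2) <= LABEL_TOL)
    if geo.notch_cut_applied:
        y0 = p.fossa_center_o2[1] - p.fossa_radius_r2
        labels["notch_edge"] = np.flatnonzero(np.abs(v[:, 1] - y0) <= LABEL_TOL)
    geo.labels["articular"] = labels


def apply_anterior_cut(geo: ModelGeometry, o1=None, r1=None) -> ModelGeometry:
    """Stage 4: trim the acetabular rim with the anterior cut cylinder.

    Material outside the cylinder (radius ``r1``, axis along x through
    ``o1`` in the coronal plane) is removed; the new edge ring is labelled
    ``anterior_edge`` and lies exactly on the cylinder.
    """
    p = geo.params
    o1 = tuple(p.anterior_cut_center_o1 if o1 is None else o1)
    r1 = float(p.anterior_cut_radius_r1 if r1 is None else r1)
    if r1 <= 0:
        raise DomainError("anterior cut radius must be > 0")
    geo = geo.copy()
    v = geo.bone_cavity.vertices
    signed = np.hypot(v[:, 1] - o1[0], v[:, 2] - o1[1]) - r1
    outside = signed > LABEL_TOL
    if not outside.any() or outside.all():
        # the cylinder surface misses the cavity entirely: nothing to cut
        warnings.warn("anterior cut cylinder does not intersect the cavity; "
                      "geometry unchanged", stacklevel=2)
        return geo
    verts, faces, changed = clip_mesh(
        v, geo.bone_cavity.faces, signed,
        cylinder_x_projector(o1, r1, p.cavity_radius))
    if not changed:
        return geo
    geo.bone_cavity = _as_mesh(verts, faces)
    geo.anterior_cut_applied = True
    _relabel_bone(geo)
    if geo.articular is not None:
        geo = extrude_cartilage(geo, p.cartilage_thickness_t)
    return geo


def extrude_cartilage(geo: ModelGeometry, t: float | None = None) -> ModelGeometry:
    """Stage 5a: extrude the cavity surface radially inward by ``t``.

    Radial extrusion maps the rim-plane and anterior-cylinder cuts at the
    cavity radius R onto the scaled plane/cylinder at the articular radius
    R - t, so the articular patch is generated directly as an exactly-cut
    cap at radius R - t.  The cartilage solid shell (inner surface, outer
    surface and radial side walls) is assembled from it.
    """
    p = geo.params
    t = float(p.cartilage_thickness_t if t is None else t)
    if t >= p.cavity_radius:
        raise DomainError("cartilage thickness must be smaller than the cavity radius")
    if t <= 0:
        raise DomainError("cartilage thickness must be > 0")
    geo = geo.copy()
    R = p.cavity_radius
    Ra = R - t
    scale = Ra / R
    theta_max = float(np.arccos(-p.depth_d / R))
    verts, faces = spherical_cap_mesh(Ra, -geo.cup_axis, theta_max, geo.n_rings)
    if geo.anterior_cut_applied:
        o1 = np.asarray(p.anterior_cut_center_o1) * scale
        r1 = p.anterior_cut_radius_r1 * scale
        signed = np.hypot(verts[:, 1] - o1[0], verts[:, 2] - o1[1]) - r1
        verts, faces, _ = clip_mesh(verts, faces, signed,
                                    cylinder_x_projector(o1, r1, Ra))
    geo.articular = _as_mesh(verts, faces)
    geo.fossa_cut_applied = False
    geo.notch_cut_applied = False
    _relabel_articular(geo)
    _rebuild_cartilage_shell(geo)
    return geo


def _boundary_edges(faces: np.ndarray) -> np.ndarray:
    """Directed boundary edges (those without an opposite twin), (B,2)."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keys = {(int(a), int(b)) for a, b in edges}
    return np.array([e for e in edges if (int(e[1]), int(e[0])) not in keys],
                    dtype=np.int64).reshape(-1, 2)


def _rebuild_cartilage_shell(geo: ModelGeometry) -> None:
    """Assemble the cartilage shell by radial extrusion of the articular patch."""
    p = geo.params
    Ra = p.articular_radius
    scale = p.cavity_radius / Ra
    inner = geo.articular
    n = len(inner.vertices)
    outer_v = inner.vertices * scale
    verts = np.vstack([inner.vertices, outer_v])
    inner_f = inner.faces
    outer_f = inner_f[:, ::-1] + n
    walls = []
    for a, b in _boundary_edges(inner_f):
        # traverse the shared boundary edge opposite to the inner face so the
        # shell winding stays globally consistent
        walls.append((b, a, a + n))
        walls.append((b, a + n, b + n))
    faces = np.vstack([inner_f, outer_f,
                       np.asarray(walls, dtype=np.int64).reshape(-1, 3)])
    geo.cartilage = _as_mesh(verts, faces)


def apply_fossa_and_notch_cut(geo: ModelGeometry, o2=None, r2=None,
                              notch: bool = True) -> ModelGeometry:
    """Stage 5b: cut the fossa and (optionally) the inferior notch.

    Cartilage inside the fossa cylinder (axis along z through ``o2`` in the
    sagittal plane) is removed, leaving the lunate surface; the new edge is
    labelled ``fossa_edge``.  The notch is a plane cut tangent to the fossa
    cylinder on its inferior side (y = o2_y - r2), joining the fossa opening
    to the inferior rim.
    """
    p = geo.params
    if geo.articular is None:
        raise DomainError("cartilage must be extruded before the fossa cut")
    o2 = tuple(p.fossa_center_o2 if o2 is None else o2)
    r2 = float(p.fossa_radius_r2 if r2 is None else r2)
    if r2 >= p.cavity_radius:
        raise DomainError("fossa radius must be smaller than the cavity radius")
    if r2 < 0:
        raise DomainError("fossa radius must be >= 0")
    geo = geo.copy()
    Ra = p.articular_radius
    if r2 > 0.0:
        v = geo.articular.vertices
        signed = r2 - np.hypot(v[:, 0] - o2[0], v[:, 1] - o2[1])
        if (signed > LABEL_TOL).all():
            raise DomainError("fossa cylinder swallows the whole cartilage")
        verts, faces, changed = clip_mesh(v, geo.articular.faces, signed,
                                          cylinder_z_projector(o2, r2, Ra))
        if changed:
            geo.articular = _as_mesh(verts, faces)
            geo.fossa_cut_applied = True
    if notch and r2 > 0.0:
        y0 = o2[1] - r2
        v = geo.articular.vertices
        signed = y0 - v[:, 1]
        if (signed > LABEL_TOL).all():
            raise DomainError("notch plane removes the whole cartilage")
        verts, faces, changed = clip_mesh(v, geo.articular.faces, signed,
                                          plane_y_projector(y0, Ra))
        if changed:
            geo.articular = _as_mesh(verts, faces)
            geo.notch_cut_applied = True
    _relabel_articular(geo)
    _rebuild_cartilage_shell(geo)
    return geo


def build_femoral_head(cavity_radius: float, t: float, clearance: float,
                       center=(0.0, 0.0, 0.0)) -> FemoralHead:
    """Femoral sphere radii from radial-clearance bookkeeping.

    The femoral articular radius is ``(cavity_radius - t) - clearance`` and
    the femoral bone radius is one cartilage thickness smaller again.
    """
    if clearance < 0:
        raise DomainError("radial clearance must be >= 0")
    articular = (cavity_radius - t) - clearance
    bone = articular - t
    if bone <= 0:
        raise DomainError("femoral radii must be positive; check radii/thickness")
    return FemoralHead(center=np.asarray(center, dtype=float),
                       articular_radius=articular, bone_radius=bone)


def _mirror_geometry(geo: ModelGeometry) -> ModelGeometry:
    geo = geo.copy()
    for name in ("bone_cavity", "bone_block", "articular", "cartilage"):
        mesh = getattr(geo, name)
        if mesh is None:
            continue
        v = mesh.vertices.copy()
        v[:, 2] *= -1.0
        setattr(geo, name, _as_mesh(v, mesh.faces[:, ::-1]))
    axis = geo.cup_axis.copy()
    axis[2] *= -1.0
    geo.cup_axis = axis
    geo.mirrored = True
    return geo


def build_model(params: AcetabularParameterSet,
                n_rings: int = DEFAULT_N_RINGS,
                notch: bool = True,
                mirror: bool = True) -> ModelGeometry:
    """Run the full constructive pipeline for one parameter set.

    Left-side models are generated in the canonical right-hip frame and
    mirrored through the sagittal plane at the end (``mirror=False`` keeps
    the canonical frame, which is what the fitting round-trip tests use).
    """
    geo = build_bone_block(params, n_rings=n_rings)
    geo = apply_anterior_cut(geo)
    geo = extrude_cartilage(geo)
    geo = apply_fossa_and_notch_cut(geo, notch=notch)
    geo.femoral_head = build_femoral_head(params.cavity_radius,
                                          params.cartilage_thickness_t,
                                          params.radial_clearance)
    if mirror and params.side == "left":
        geo = _mirror_geometry(geo)
    return geo


def labelled_surface(geo: ModelGeometry) -> LabelledSurface:
    """Combine the labelled regions needed for parameter extraction.

    Points are the articular (lunate) vertices followed by the bone-side
    posterior rim and anterior edge rings; labels index into that array.
    """
    if geo.articular is None:
        raise DomainError("model has no articular surface yet")
    art = geo.articular.vertices
    art_labels = geo.labels.get("articular", {})
    bone_labels = geo.labels.get("bone_cavity", {})
    rim = geo.bone_cavity.vertices[bone_labels.get("posterior_rim", np.array([], dtype=int))]
    ant = geo.bone_cavity.vertices[bone_labels.get("anterior_edge", np.array([], dtype=int))]
    points = np.vstack([art, rim, ant])
    labels = {"articular": np.arange(len(art))}
    for name in ("fossa_edge", "notch_edge"):
        if name in art_labels:
            labels[name] = np.asarray(art_labels[name])
    labels["posterior_rim"] = len(art) + np.arange(len(rim))
    labels["anterior_edge"] = len(art) + len(rim) + np.arange(len(ant))
    return LabelledSurface(points=points, labels=labels, side=geo.params.side)


def rings_for_facets(params: AcetabularParameterSet, target_facets: int,
                     probe_rings: int = 24) -> int:
    """Ring count whose lunate facet count is close to ``target_facets``.

    Facet count scales quadratically with ring count, so one coarse probe
    build suffices.
    """
    if target_facets < 50:
        raise DomainError("target_facets unreasonably small")
    probe = build_model(params, n_rings=probe_rings, mirror=False)
    f0 = len(probe.articular.faces)
    return max(8, int(round(probe_rings * np.sqrt(target_facets / f0))))


def solid_angle(geo: ModelGeometry) -> float:
    """Solid angle (sr) subtended by the retained cavity patch."""
    return float(geo.bone_cavity.area / geo.params.cavity_radius ** 2)


def articular_vertex_areas(geo: ModelGeometry) -> np.ndarray:
    return vertex_areas(geo.articular.vertices, geo.articular.faces)
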