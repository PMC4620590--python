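"""Least-squares primitive fitting and five-parameter extraction.

Sphere and circle fits use an algebraic (Kasa-style) linear solve as the
initialiser followed by geometric (orthogonal-distance) Gauss-Newton
refinement; the plane fit is the exact total-least-squares solution via SVD.
``extract_parameters`` applies these to a labelled segmentation-like surface
to recover the five acetabular parameters, i.e. the best-fit measurement
step that turns a segmented hip into a parameterised model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, SingularConfigurationError
from .geometry import LabelledSurface
from .orientation import angles_from_axis, mirror_matrix
from .params import AcetabularParameterSet

__all__ = ["FitResult", "fit_sphere", "fit_plane", "fit_circle2d",
           "extract_parameters", "ExtractionResult"]

_REFINE_TOL = 1e-12
_PROJECTIONS = {
    "coronal": (1, 2),   # drop x: coordinates are (y, z)
    "sagittal": (0, 1),  # drop z: coordinates are (x, y)
}


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Fitted primitive parameters with residual statistics (lengths in mm)."""

    primitive_kind: str
    parameters: dict
    rms_residual: float
    n_points: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["parameters"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.parameters.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _check_points(points, min_n: int, dim: int = 3) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != dim:
        raise DomainError(f"expected an (N, {dim}) point array, got shape {pts.shape}")
    if len(pts) < min_n:
        raise DomainError(f"need at least {min_n} points, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise DomainError("points must be finite")
    return pts


def fit_sphere(points) -> FitResult:
    """Least-squares sphere: centre and radius minimising radial distances.

    Requires at least four non-coplanar points.  The algebraic solution is
    refined by Gauss-Newton on the geometric residual ``|p - c| - R``.
    """
    pts = _check_points(points, 4)
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] <= 1e-9 * max(sv[0], 1.0):
        raise SingularConfigurationError("points are coplanar; sphere fit is singular")

    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0, k = sol[:3], sol[3]
    r0 = float(np.sqrt(max(k + c0 @ c0, 0.0)))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.r_[c0, r0], method="lm",
                        xtol=_REFINE_TOL, ftol=_REFINE_TOL, gtol=_REFINE_TOL)
    centre, radius = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return FitResult("sphere", {"center": centre, "radius": radius}, rms, len(pts))


def fit_plane(points, orient_toward=None) -> FitResult:
    """Total-least-squares plane (smallest principal component direction).

    ``orient_toward`` optionally fixes the sign of the unit normal (it is
    flipped to have a positive dot product with the given vector, e.g. the
    cup-axis hemisphere).  Returns the unit normal, a point on the plane
    (the centroid) and the signed offset ``normal . centroid``.
    """
    pts = _check_points(points, 3)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if len(pts) > 3 and sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise SingularConfigurationError("points are collinear; plane fit is singular")
    if len(pts) == 3 and sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise SingularConfigurationError("points are collinear; plane fit is singular")
    normal = vt[-1]
    if orient_toward is not None and normal @ np.asarray(orient_toward, dtype=float) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return FitResult("plane",
                     {"normal": normal, "point": centroid,
                      "offset": float(normal @ centroid)},
                     rms, len(pts))


def fit_circle2d(points, projection_plane: str = "coronal") -> FitResult:
    """Circle fit after orthogonal projection onto a named anatomical plane.

    ``projection_plane`` is ``"coronal"`` (anterior-edge cut; keeps (y, z))
    or ``"sagittal"`` (fossa cut; keeps (x, y)).  Points may also be given
    directly as an (N, 2) array, in which case no projection is applied.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[1] == 3:
        if projection_plane not in _PROJECTIONS:
            raise DomainError(
                f"projection_plane must be 'coronal' or 'sagittal', got {projection_plane!r}")
        uv = pts[:, _PROJECTIONS[projection_plane]]
    else:
        uv = _check_points(pts, 3, dim=2)
    uv = _check_points(uv, 3, dim=2)
    centred = uv - uv.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] <= 1e-9 * max(sv[0], 1.0):
        raise SingularConfigurationError("projected points are collinear; circle fit is singular")

    A = np.column_stack([2.0 * uv, np.ones(len(uv))])
    b = np.einsum("ij,ij->i", uv, uv)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0, k = sol[:2], sol[2]
    r0 = float(np.sqrt(max(k + c0 @ c0, 0.0)))

    def resid(x):
        return np.linalg.norm(uv - x[:2], axis=1) - x[2]

    out = least_squares(resid, np.r_[c0, r0], method="lm",
                        xtol=_REFINE_TOL, ftol=_REFINE_TOL, gtol=_REFINE_TOL)
    centre, radius = out.x[:2], float(out.x[2])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return FitResult("circle2d",
                     {"center": centre, "radius": radius,
                      "projection_plane": projection_plane if uv is not pts else "given"},
                     rms, len(uv))


@dataclasses.dataclass
class ExtractionResult:
    """Recovered parameter set plus the underlying primitive fits."""

    params: AcetabularParameterSet
    fits: dict[str, FitResult]


def extract_parameters(surface: LabelledSurface,
                       cartilage_thickness: float = 2.0,
                       radial_clearance: float = 0.5,
                       side: str | None = None) -> ExtractionResult:
    """Measure the five acetabular parameters from a labelled surface.

    Required region labels: ``articular`` (points on the articular sphere),
    ``posterior_rim``, ``anterior_edge`` and ``fossa_edge`` rings.  The
    cartilage thickness and radial clearance are controlled quantities and
    are supplied, not measured.

    The cavity centre and articular radius come from the sphere fit of the
    articular region (cavity radius = articular radius + thickness); the rim
    plane gives both the cup axis (its normal, oriented away from the
    articular centroid) and the signed depth; the anterior edge and fossa
    edge rings give (o1, r1) and (o2, r2) by circle fits in the coronal and
    sagittal projections.
    """
    side = surface.side if side is None else side
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")

    def pts(name):
        p = surface.region(name)
        return p @ mirror_matrix() if side == "left" else p

    articular = pts("articular")
    rim = pts("posterior_rim")
    anterior = pts("anterior_edge")
    fossa = pts("fossa_edge")

    sphere = fit_sphere(articular)
    centre = sphere.parameters["center"]
    cavity_radius = sphere.parameters["radius"] + cartilage_thickness

    # the cup axis points away from the articular material
    art_dir = articular.mean(axis=0) - centre
    plane = fit_plane(rim - centre, orient_toward=-art_dir)
    axis = plane.parameters["normal"]
    depth = float(plane.parameters["offset"])
    inclination, anteversion = angles_from_axis(axis, side="right")

    anterior_fit = fit_circle2d(anterior - centre, "coronal")
    fossa_fit = fit_circle2d(fossa - centre, "sagittal")

    params = AcetabularParameterSet(
        depth_d=depth,
        anterior_cut_center_o1=tuple(anterior_fit.parameters["center"]),
        anterior_cut_radius_r1=anterior_fit.parameters["radius"],
        fossa_center_o2=tuple(fossa_fit.parameters["center"]),
        fossa_radius_r2=fossa_fit.parameters["radius"],
        cavity_radius=float(cavity_radius),
        cartilage_thickness_t=cartilage_thickness,
        radial_clearance=radial_clearance,
        inclination_deg=float(np.clip(inclination, 0.0, 90.0)),
        anteversion_deg=float(np.clip(anteversion, 0.0, 90.0)),
        side=side,
    )
    fits = {"articular_sphere": sphere, "posterior_rim_plane": plane,
            "anterior_edge_circle": anterior_fit, "fossa_edge_circle": fossa_fit}
    return ExtractionResult(params=params, fits=fits)
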