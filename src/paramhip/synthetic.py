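"""Synthetic segmentation-like surfaces with known ground truth.

Real segmentation-based models show irregular morphology at the cartilage
edges (especially the fossa edge) and point-level noise from imaging and
surface reconstruction.  This module emulates both on top of the exactly
generated parametric geometry: smooth band-limited radial perturbation of
the fossa and anterior edge curves, plus isotropic Gaussian noise on every
vertex.  Ground-truth parameters are carried along, so parameter-recovery
experiments (generate -> perturb -> extract) are fully controlled.

The default point noise (0.074 mm) is of the order of a micro-CT voxel,
a plausible noise floor for a careful segmentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DomainError
from .geometry import LabelledSurface, build_model, labelled_surface, rings_for_facets
from .orientation import mirror_matrix
from .params import AcetabularParameterSet

__all__ = ["SyntheticSpec", "sample_primitive", "make_segmentation_like",
           "SpherePrimitive", "PlanePrimitive", "CirclePrimitive"]

DEFAULT_POINT_NOISE_SD = 0.074  # mm


# -- primitive samplers ------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpherePrimitive:
    center: tuple[float, float, float]
    radius: float
    min_points = 4

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        return np.asarray(self.center) + self.radius * v


@dataclasses.dataclass(frozen=True)
class PlanePrimitive:
    """Bounded planar patch: ``extent`` x ``extent`` square about ``point``."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    extent: float = 20.0
    min_points = 3

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        from .meshing import orthonormal_tangents

        nrm = np.asarray(self.normal, dtype=float)
        nrm = nrm / np.linalg.norm(nrm)
        e1, e2 = orthonormal_tangents(nrm)
        uv = rng.uniform(-self.extent / 2.0, self.extent / 2.0, size=(n, 2))
        return np.asarray(self.point) + uv[:, :1] * e1 + uv[:, 1:] * e2


@dataclasses.dataclass(frozen=True)
class CirclePrimitive:
    """Circle in a coordinate plane, embedded in 3-D.

    ``plane`` follows the fitting conventions: ``"coronal"`` (circle in
    (y, z) at x = offset) or ``"sagittal"`` (circle in (x, y) at z = offset).
    """

    center: tuple[float, float]
    radius: float
    plane: str = "sagittal"
    offset: float = 0.0
    min_points = 3

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        u = self.center[0] + self.radius * np.cos(psi)
        v = self.center[1] + self.radius * np.sin(psi)
        w = np.full(n, self.offset)
        if self.plane == "coronal":
            return np.column_stack([w, u, v])
        if self.plane == "sagittal":
            return np.column_stack([u, v, w])
        raise DomainError(f"plane must be 'coronal' or 'sagittal', got {self.plane!r}")


def sample_primitive(primitive, n: int, noise_sd: float = 0.0,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform-on-surface samples of a primitive plus isotropic Gaussian noise.

    Reproducible: the same seed yields the same cloud.
    """
    if n < primitive.min_points:
        raise DomainError(
            f"need at least {primitive.min_points} points for a "
            f"{type(primitive).__name__}, got {n}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = primitive.sample(n, rng)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts


# -- segmentation-like labelled surfaces -------------------------------------

@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic segmentation-like surface."""

    truth: AcetabularParameterSet
    point_noise_sd: float = DEFAULT_POINT_NOISE_SD   # mm
    edge_irregularity_amplitude: float = 1.0         # mm, radial, peak
    edge_irregularity_wavelength: float = 10.0       # mm along the edge curve
    n_points: int = 8000                             # approximate vertex count
    seed: int = 0

    def __post_init__(self):
        if self.point_noise_sd < 0 or self.edge_irregularity_amplitude < 0:
            raise DomainError("noise and irregularity amplitude must be >= 0")
        if self.edge_irregularity_amplitude >= self.truth.fossa_radius_r2:
            raise DomainError("edge irregularity amplitude must be smaller than "
                              "the fossa radius")
        if self.edge_irregularity_wavelength <= 0:
            raise DomainError("edge irregularity wavelength must be > 0")


def _perturb_ring(points: np.ndarray, center2d, axes: tuple[int, int],
                  recompute_axis: int, sphere_radius: float,
                  amplitude: float, wavelength: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Radially displace an edge ring (in its projection plane) by a smooth
    periodic profile, keeping points on the articular sphere."""
    pts = points.copy()
    u = pts[:, axes[0]] - center2d[0]
    v = pts[:, axes[1]] - center2d[1]
    r = np.hypot(u, v)
    psi = np.arctan2(v, u)
    n_lobes = max(1, int(round(2.0 * np.pi * np.median(r) / wavelength)))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    phase2 = rng.uniform(0.0, 2.0 * np.pi)
    dr = amplitude * (np.sin(n_lobes * psi + phase)
                      + 0.35 * np.sin((n_lobes + 3) * psi + phase2)) / 1.35
    scale = (r + dr) / r
    pts[:, axes[0]] = center2d[0] + u * scale
    pts[:, axes[1]] = center2d[1] + v * scale
    # re-project onto the articular sphere along the remaining axis
    rho2 = sphere_radius ** 2 - pts[:, axes[0]] ** 2 - pts[:, axes[1]] ** 2
    pts[:, recompute_axis] = np.sign(points[:, recompute_axis]) * np.sqrt(
        np.clip(rho2, 0.0, None))
    return pts


def make_segmentation_like(spec: SyntheticSpec) -> tuple[LabelledSurface, AcetabularParameterSet]:
    """Generate a labelled segmentation-like surface from ground truth.

    Returns ``(surface, truth)``.  The surface keeps the full label set of
    the parametric geometry (articular, posterior_rim, anterior_edge,
    fossa_edge and, when present, notch_edge); edge irregularity is applied
    to the fossa and anterior edge rings and Gaussian noise to all points.
    Works in the canonical frame and mirrors at the end for left sides, so
    the output matches what a segmentation of that hip would look like.
    """
    truth = spec.truth
    rng = np.random.default_rng(spec.seed)
    n_rings = rings_for_facets(truth, max(300, int(spec.n_points * 1.9)))
    geo = build_model(truth, n_rings=n_rings, mirror=False)
    surf = labelled_surface(geo)
    pts = surf.points.copy()

    amp = spec.edge_irregularity_amplitude
    if amp > 0:
        Ra = truth.articular_radius
        R = truth.cavity_radius
        fossa_idx = surf.labels.get("fossa_edge", np.array([], dtype=int))
        if len(fossa_idx):
            pts[fossa_idx] = _perturb_ring(
                pts[fossa_idx], truth.fossa_center_o2, (0, 1), 2, Ra,
                amp, spec.edge_irregularity_wavelength, rng)
        ant_idx = surf.labels.get("anterior_edge", np.array([], dtype=int))
        if len(ant_idx):
            pts[ant_idx] = _perturb_ring(
                pts[ant_idx], truth.anterior_cut_center_o1, (1, 2), 0, R,
                amp, spec.edge_irregularity_wavelength, rng)

    if spec.point_noise_sd > 0:
        pts = pts + rng.normal(scale=spec.point_noise_sd, size=pts.shape)

    if truth.side == "left":
        pts = pts @ mirror_matrix()
    return LabelledSurface(points=pts, labels=dict(surf.labels),
                           side=truth.side), truth
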