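"""Frictionless elastic-foundation (bed-of-springs) contact of the hip.

The femoral head and the lunate cartilage are concentric spheres separated
by the radial clearance.  Cartilage is modelled as a thin linear-elastic
layer on a rigid backing: local contact pressure is proportional to the
local penetration of the (rigid) femoral articular sphere through the
undeformed cartilage surface,

    p = K * max(0, -gap),    K = E (1 - nu) / [(1 + nu)(1 - 2 nu) t_total],

with the confined-compression foundation modulus built from the cartilage
constants (E = 12 MPa, nu = 0.45) and the total thickness of the two
cartilage layers in series (t_total = 4 mm for 2 mm per layer).  Pressure
acts along the local surface normal only (frictionless contact).

Per quasi-static step, the femoral centre translation ``u`` (3 unknowns) is
found by damped Newton iteration so that the integrated pressure balances
the applied hip joint force.  This is a deliberate, documented stand-in for
a deformable-bone finite-element contact solve: bone is rigid backing here,
supported by the observation that changing pelvic support alters hip
contact results only by a few percent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DomainError, NoEquilibriumError, SolverError
from .geometry import ModelGeometry
from .loading import QuasiStaticSchedule
from .meshing import vertex_areas

__all__ = ["MaterialConfig", "PressureField", "ContactResult", "ContactConfig",
           "foundation_stiffness", "gap_function", "solve_equilibrium",
           "contact_area", "run_activity", "small_angle_peak_pressure",
           "small_angle_contact_area", "foundation_oracle_peak_pressure"]

PRESSURE_THRESHOLD = 0.1  # MPa, contact-area inclusion threshold


@dataclasses.dataclass(frozen=True)
class MaterialConfig:
    """Material constants (cartilage drives the foundation model; the bone
    constants are stored for provenance — bone is rigid backing here)."""

    cartilage_E: float = 12.0        # MPa
    cartilage_nu: float = 0.45
    cortical_E: float = 17.0         # GPa
    cortical_nu: float = 0.3
    cancellous_E: float = 0.8        # GPa
    cancellous_nu: float = 0.2
    cortical_shell_thickness: float = 1.5  # mm
    n_cartilage_layers: int = 2      # acetabular + femoral layer in series

    def __post_init__(self):
        for name in ("cartilage_E", "cortical_E", "cancellous_E"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("cartilage_nu", "cortical_nu", "cancellous_nu"):
            nu = getattr(self, name)
            if not (0.0 <= nu < 0.5):
                raise DomainError(f"{name} must lie in [0, 0.5)")

    def stiffness(self, layer_thickness: float) -> float:
        return foundation_stiffness(self.cartilage_E, self.cartilage_nu,
                                    self.n_cartilage_layers * layer_thickness)


@dataclasses.dataclass(frozen=True)
class ContactConfig:
    """Solver and post-processing settings."""

    pressure_threshold: float = PRESSURE_THRESHOLD  # MPa
    area_rule: str = "all"          # facet inclusion: "all" or "any" vertices
    force_rtol: float = 1e-3        # residual <= max(rtol*|F|, abs_tol)
    force_abs_tol: float = 1e-3     # N
    max_iterations: int = 100
    damping: float = 0.5


@dataclasses.dataclass
class PressureField:
    """Per-vertex contact pressure on the lunate mesh for one load step."""

    pressure: np.ndarray            # MPa, per articular vertex
    displacement: np.ndarray        # femoral centre translation, mm
    step_index: int = 0

    @property
    def max_pressure(self) -> float:
        return float(self.pressure.max(initial=0.0))


@dataclasses.dataclass
class ContactResult:
    """Per-step pressure fields and scalar summaries for one activity."""

    schedule: QuasiStaticSchedule
    fields: list[PressureField]
    max_pressure: np.ndarray        # MPa per step
    contact_area: np.ndarray        # mm^2 per step

    def __post_init__(self):
        n = len(self.schedule)
        if not (len(self.fields) == len(self.max_pressure)
                == len(self.contact_area) == n):
            raise DomainError("result lengths must equal the schedule length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "step": np.arange(len(self.fields)),
            "cycle_fraction": self.schedule.cycle_fractions,
            "max_pressure_MPa": self.max_pressure,
            "contact_area_mm2": self.contact_area,
        })


def foundation_stiffness(E: float, nu: float, t_total: float) -> float:
    """Confined-compression foundation modulus K (MPa/mm) of an elastic
    layer of total thickness ``t_total`` on a rigid backing."""
    if t_total <= 0:
        raise DomainError("t_total must be > 0")
    if not 0.0 <= nu < 0.5:
        raise DomainError("Poisson ratio must lie in [0, 0.5); nu = 0.5 is the "
                          "incompressible limit where the foundation modulus diverges")
    if E <= 0:
        raise DomainError("E must be > 0")
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * t_total)


def gap_function(geometry: ModelGeometry,
                 femoral_centre_displacement) -> np.ndarray:
    """Per-vertex radial gap (mm) between the displaced femoral articular
    sphere and the lunate surface; negative values are penetrations."""
    if geometry.articular is None or geometry.femoral_head is None:
        raise DomainError("geometry must carry an articular surface and femoral head")
    u = np.asarray(femoral_centre_displacement, dtype=float)
    v = geometry.articular.vertices
    centre = geometry.femoral_head.center + u
    return np.linalg.norm(v - centre, axis=1) - geometry.femoral_head.articular_radius


class _LunateCache:
    """Precomputed mesh quantities reused across the 13 steps of a cycle."""

    def __init__(self, geometry: ModelGeometry):
        self.vertices = geometry.articular.vertices
        self.areas = vertex_areas(self.vertices, geometry.articular.faces)
        self.head_centre = geometry.femoral_head.center
        self.head_radius = geometry.femoral_head.articular_radius


def _contact_state(cache: _LunateCache, K: float, u: np.ndarray):
    w = (cache.head_centre + u) - cache.vertices  # vertex -> femoral centre
    s = np.linalg.norm(w, axis=1)
    pen = cache.head_radius - s                   # positive = penetration
    active = pen > 0.0
    p = np.where(active, K * pen, 0.0)
    d = w / s[:, None]
    force = (p * cache.areas) @ d                 # contact force on the femur
    return p, d, s, active, force


def solve_equilibrium(geometry: ModelGeometry, K: float, F,
                      config: ContactConfig | None = None,
                      initial_displacement=None,
                      step_index: int = 0) -> PressureField:
    """Find the femoral centre displacement balancing the applied force.

    Solves ``F + integral(p n dA) = 0`` for the three displacement unknowns
    by damped Newton iteration with an analytic Jacobian; convergence is on
    the force residual (``<= max(force_rtol |F|, force_abs_tol)``).
    """
    config = config or ContactConfig()
    F = np.asarray(F, dtype=float)
    if F.shape != (3,) or not np.all(np.isfinite(F)):
        raise DomainError("F must be a finite 3-vector (newtons)")
    cache = _LunateCache(geometry)
    if len(cache.vertices) == 0:
        raise DomainError("lunate region is empty")
    Fmag = float(np.linalg.norm(F))
    nv = len(cache.vertices)
    if Fmag == 0.0:
        return PressureField(pressure=np.zeros(nv), displacement=np.zeros(3),
                             step_index=step_index)

    clearance = (geometry.params.articular_radius
                 - geometry.femoral_head.articular_radius)
    # deepest physically meaningful penetration: the full cartilage layers
    u_max = clearance + 2.0 * geometry.params.cartilage_thickness_t

    tol = max(config.force_rtol * Fmag, config.force_abs_tol)
    Fhat = F / Fmag
    if initial_displacement is not None and np.linalg.norm(initial_displacement) > 0:
        u = np.asarray(initial_displacement, dtype=float).copy()
    else:
        u = (clearance + 0.05) * Fhat

    p, d, s, active, fc = _contact_state(cache, K, u)
    res = F + fc
    rnorm = float(np.linalg.norm(res))
    for iteration in range(config.max_iterations):
        if rnorm <= tol:
            return PressureField(pressure=p, displacement=u, step_index=step_index)
        if not active.any():
            # no springs engaged: push along the load until first contact
            u = u + 0.25 * clearance * Fhat
        else:
            a = cache.areas[active]
            da = d[active]
            pa = p[active]
            sa = s[active]
            outer = np.einsum("ni,nj->nij", da, da)
            eye = np.eye(3)[None, :, :]
            J = np.einsum("n,nij->ij", a * K, -outer) \
                + np.einsum("n,nij->ij", a * pa / sa, eye - outer)
            try:
                step = np.linalg.solve(J, -res)
            except np.linalg.LinAlgError as exc:
                raise SolverError("singular contact Jacobian",
                                  {"iteration": iteration, "residual_N": rnorm}) from exc
            # damped line search: halve the step while the residual grows
            lam = 1.0
            for _ in range(12):
                u_new = u + lam * step
                p_n, d_n, s_n, act_n, fc_n = _contact_state(cache, K, u_new)
                r_new = float(np.linalg.norm(F + fc_n))
                if r_new < rnorm or not act_n.any():
                    break
                lam *= config.damping
            u = u_new
        if np.linalg.norm(u) > u_max:
            raise NoEquilibriumError(
                "no equilibrium within the cartilage layer: the load direction "
                "has no cartilage support (edge-of-coverage dislocation)",
                {"step_index": step_index, "|u|_mm": float(np.linalg.norm(u)),
                 "limit_mm": u_max})
        p, d, s, active, fc = _contact_state(cache, K, u)
        res = F + fc
        rnorm = float(np.linalg.norm(res))
    raise SolverError(
        f"no convergence in {config.max_iterations} iterations",
        {"step_index": step_index, "residual_N": rnorm, "tolerance_N": tol,
         "|u|_mm": float(np.linalg.norm(u))})


def contact_area(field: PressureField, mesh,
                 threshold: float = PRESSURE_THRESHOLD,
                 rule: str = "all") -> float:
    """Thresholded contact area (mm^2): sum of facet areas whose vertex
    pressures exceed ``threshold``.

    ``rule="all"`` (default, conservative) requires every facet vertex above
    the threshold; ``rule="any"`` requires at least one.
    """
    p = field.pressure if isinstance(field, PressureField) else np.asarray(field)
    faces = mesh.faces
    above = p[faces] > threshold
    if rule == "all":
        mask = above.all(axis=1)
    elif rule == "any":
        mask = above.any(axis=1)
    else:
        raise DomainError(f"rule must be 'all' or 'any', got {rule!r}")
    v = mesh.vertices
    tri = v[faces[mask]]
    if len(tri) == 0:
        return 0.0
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return float(areas.sum())


def run_activity(geometry: ModelGeometry, material: MaterialConfig,
                 schedule: QuasiStaticSchedule,
                 config: ContactConfig | None = None) -> ContactResult:
    """Solve every quasi-static step of an activity schedule.

    Steps are warm-started from the previous converged displacement; solver
    failures propagate with the offending step index attached.
    """
    config = config or ContactConfig()
    K = material.stiffness(geometry.params.cartilage_thickness_t)
    fields: list[PressureField] = []
    u_prev = None
    for idx, F in enumerate(schedule.forces):
        try:
            field = solve_equilibrium(geometry, K, F, config=config,
                                      initial_displacement=u_prev,
                                      step_index=idx)
        except SolverError as exc:
            exc.diagnostics.setdefault("step_index", idx)
            raise
        fields.append(field)
        if np.linalg.norm(field.displacement) > 0:
            u_prev = field.displacement
    max_p = np.array([f.max_pressure for f in fields])
    areas = np.array([
        contact_area(f, geometry.articular, config.pressure_threshold,
                     config.area_rule)
        for f in fields
    ])
    return ContactResult(schedule=schedule, fields=fields,
                         max_pressure=max_p, contact_area=areas)


# -- independent analytic references ----------------------------------------

def small_angle_peak_pressure(F: float, clearance: float, K: float,
                              radius: float) -> float:
    """Small-angle closed form p0 = sqrt(F c K / (pi R^2)) for a centred
    load whose contact patch stays far from the cartilage edges."""
    return float(np.sqrt(F * clearance * K / (np.pi * radius ** 2)))


def small_angle_contact_area(F: float, clearance: float, K: float,
                             radius: float) -> float:
    """Small-angle spherical-cap contact patch area 2 pi R^2 (1 - cos psi_c)
    with psi_c^2 = 2 delta0 / c."""
    delta0 = np.sqrt(F * clearance / (np.pi * radius ** 2 * K))
    psi_c = np.sqrt(2.0 * delta0 / clearance)
    return float(2.0 * np.pi * radius ** 2 * (1.0 - np.cos(psi_c)))


def foundation_oracle_peak_pressure(F: float, clearance: float, K: float,
                                    radius: float) -> float:
    """Exact 1-D foundation integral for a centred load on a full spherical
    cartilage bed (no edge effects): solves

        F = 2 pi R^2 K [ w (1 - x^3)/3 - c (1 - x^2)/2 ],  x = c / w

    for the centre approach ``w`` by bracketing, and returns the pole
    pressure K (w - c).  Valid at any load, unlike the small-angle form.
    """
    from scipy.optimize import brentq

    c = clearance

    def balance(w):
        x = c / w
        return 2.0 * np.pi * radius ** 2 * K * (
            w * (1.0 - x ** 3) / 3.0 - c * (1.0 - x ** 2) / 2.0) - F

    w = brentq(balance, c * (1.0 + 1e-12), c + 10.0, xtol=1e-14)
    return float(K * (w - c))
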