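"""Acetabular parameter sets.

The acetabulum and its cartilage are described by five free parameters —
acetabular depth ``d``, anterior edge cut centre/radius ``(o1, r1)`` and
cartilage fossa centre/radius ``(o2, r2)`` — plus the controlled quantities
(cavity radius, cartilage thickness, radial clearance, cup inclination and
anteversion, side).  Lengths are millimetres, angles degrees throughout.

Coordinate convention (right hip): origin at the acetabular cavity centre,
x anterior, y superior, z lateral.  The coronal plane is x = 0 and the
sagittal plane is z = 0.  ``o1`` is a (y, z) offset in the coronal plane,
``o2`` an (x, y) offset in the sagittal plane, both relative to the cavity
centre.  Left hips are handled by mirroring z.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import DomainError

__all__ = ["AcetabularParameterSet", "load_parameters", "save_parameters", "preset"]

_SIDES = ("left", "right")


@dataclasses.dataclass(frozen=True)
class AcetabularParameterSet:
    """The five-parameter acetabulum description plus controlled geometry.

    Parameters
    ----------
    depth_d : float
        Signed distance (mm) from the posterior rim plane to the cavity
        centre.  Positive depth means the retained cavity coverage exceeds a
        hemisphere.
    anterior_cut_center_o1 : (float, float)
        Centre of the anterior edge cut cylinder, as (y, z) offsets (mm) from
        the cavity centre in the coronal plane.  The cylinder axis is the
        anterior (x) axis.
    anterior_cut_radius_r1 : float
        Radius (mm) of the anterior cut cylinder.
    fossa_center_o2 : (float, float)
        Centre of the fossa cut cylinder, as (x, y) offsets (mm) from the
        cavity centre in the sagittal plane.  The cylinder axis is the
        lateral (z) axis.
    fossa_radius_r2 : float
        Radius (mm) of the fossa cylinder.
    cavity_radius : float
        Radius (mm) of the bony acetabular cavity sphere.
    cartilage_thickness_t : float
        Uniform cartilage thickness (mm); the articular surface lies at
        radius ``cavity_radius - cartilage_thickness_t``.
    radial_clearance : float
        Radial clearance (mm) between acetabular and femoral articular
        spheres.
    inclination_deg, anteversion_deg : float
        Radiographic cup orientation angles (degrees).
    side : {"left", "right"}
    """

    depth_d: float
    anterior_cut_center_o1: tuple[float, float]
    anterior_cut_radius_r1: float
    fossa_center_o2: tuple[float, float]
    fossa_radius_r2: float
    cavity_radius: float
    cartilage_thickness_t: float = 2.0
    radial_clearance: float = 0.5
    inclination_deg: float = 63.0
    anteversion_deg: float = 15.0
    side: str = "right"

    def __post_init__(self):
        object.__setattr__(
            self, "anterior_cut_center_o1", tuple(float(v) for v in self.anterior_cut_center_o1)
        )
        object.__setattr__(
            self, "fossa_center_o2", tuple(float(v) for v in self.fossa_center_o2)
        )
        self.validate()

    def validate(self) -> None:
        if self.side not in _SIDES:
            raise DomainError(f"side must be one of {_SIDES}, got {self.side!r}")
        for name in ("anterior_cut_radius_r1", "fossa_radius_r2",
                     "cavity_radius", "cartilage_thickness_t"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.radial_clearance < 0:
            raise DomainError("radial_clearance must be >= 0")
        if not self.fossa_radius_r2 < self.cavity_radius:
            raise DomainError("fossa_radius_r2 must be smaller than cavity_radius")
        if not abs(self.depth_d) < self.cavity_radius:
            raise DomainError("|depth_d| must be smaller than cavity_radius")
        if self.cartilage_thickness_t >= self.cavity_radius:
            raise DomainError("cartilage_thickness_t must be smaller than cavity_radius")
        for name in ("inclination_deg", "anteversion_deg"):
            ang = getattr(self, name)
            if not (0.0 <= ang <= 90.0):
                raise DomainError(f"{name} must lie in [0, 90] degrees, got {ang}")
        if len(self.anterior_cut_center_o1) != 2 or len(self.fossa_center_o2) != 2:
            raise DomainError("cut centres must be 2-vectors")
        if not np.all(np.isfinite(self.as_array())):
            raise DomainError("parameters must be finite")

    # -- derived quantities -------------------------------------------------

    @property
    def articular_radius(self) -> float:
        """Radius of the acetabular articular (cartilage inner) sphere, mm."""
        return self.cavity_radius - self.cartilage_thickness_t

    @property
    def femoral_articular_radius(self) -> float:
        return self.articular_radius - self.radial_clearance

    @property
    def femoral_bone_radius(self) -> float:
        return self.femoral_articular_radius - self.cartilage_thickness_t

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.depth_d, *self.anterior_cut_center_o1, self.anterior_cut_radius_r1,
             *self.fossa_center_o2, self.fossa_radius_r2, self.cavity_radius,
             self.cartilage_thickness_t, self.radial_clearance,
             self.inclination_deg, self.anteversion_deg],
            dtype=float,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anterior_cut_center_o1"] = list(d["anterior_cut_center_o1"])
        d["fossa_center_o2"] = list(d["fossa_center_o2"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AcetabularParameterSet":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


def load_parameters(path: str | Path) -> AcetabularParameterSet:
    """Read an :class:`AcetabularParameterSet` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DomainError(f"{path}: expected a YAML mapping of parameter fields")
    return AcetabularParameterSet.from_dict(data)


def save_parameters(params: AcetabularParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def preset(name: str) -> AcetabularParameterSet:
    """Load one of the bundled parameter presets (``"P1"`` or ``"P2"``)."""
    ref = resources.files("paramhip").joinpath(f"data/presets/{name}.yaml")
    if not ref.is_file():
        raise DomainError(f"unknown preset {name!r} (available: P1, P2)")
    return AcetabularParameterSet.from_dict(yaml.safe_load(ref.read_text()))
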