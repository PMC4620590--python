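"""Cup orientation: radiographic inclination/anteversion <-> cup axis.

The radiographic (Murray) convention is used: anteversion is the angle
between the cup axis and the coronal plane, and inclination is the angle
between the longitudinal (superior) axis and the projection of the cup axis
onto the coronal plane.  In the model frame (right hip: x anterior,
y superior, z lateral) the cup axis — the outward normal of the acetabular
opening plane — is

    n = (sin AV,  -cos AV * cos RI,  cos AV * sin RI)

so the opening faces anteriorly, inferiorly and laterally, as the natural
acetabulum does.  Left hips mirror the lateral (z) component.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["orientation_from_angles", "angles_from_axis", "mirror_matrix", "frame_matrix"]


def _check_side(side: str) -> None:
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")


def orientation_from_angles(inclination_deg: float, anteversion_deg: float,
                            side: str = "right") -> np.ndarray:
    """Unit cup-axis vector for radiographic inclination/anteversion.

    The returned axis is also the outward normal of the posterior rim plane.
    Angles must lie in [0, 90] degrees.
    """
    _check_side(side)
    for name, ang in (("inclination", inclination_deg), ("anteversion", anteversion_deg)):
        if not (0.0 <= ang <= 90.0):
            raise DomainError(f"{name} angle must lie in [0, 90] degrees, got {ang}")
    ri = np.deg2rad(inclination_deg)
    av = np.deg2rad(anteversion_deg)
    axis = np.array([np.sin(av), -np.cos(av) * np.cos(ri), np.cos(av) * np.sin(ri)])
    if side == "left":
        axis = mirror_matrix() @ axis
    return axis


def angles_from_axis(axis: np.ndarray, side: str = "right") -> tuple[float, float]:
    """Invert :func:`orientation_from_angles`.

    Returns ``(inclination_deg, anteversion_deg)`` for a unit cup axis.
    """
    _check_side(side)
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or n == 0:
        raise DomainError("axis must be a finite non-zero vector")
    axis = axis / n
    if side == "left":
        axis = mirror_matrix() @ axis
    av = np.arcsin(np.clip(axis[0], -1.0, 1.0))
    ri = np.arctan2(axis[2], -axis[1])
    return float(np.rad2deg(ri)), float(np.rad2deg(av))


def mirror_matrix() -> np.ndarray:
    """Reflection through the sagittal plane (z -> -z)."""
    return np.diag([1.0, 1.0, -1.0])


def frame_matrix(side: str = "right") -> np.ndarray:
    """Rows are the model axes (anterior, superior, lateral) in world coords.

    The canonical model frame coincides with the world frame for a right hip;
    a left hip mirrors the lateral axis.  Always right-handed for the right
    side; the left-side matrix is an improper rotation used only to mirror
    vector quantities.
    """
    _check_side(side)
    return mirror_matrix() if side == "left" else np.eye(3)
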