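"""Activity load cycles and quasi-static discretisation.

Hip joint reaction forces over one activity cycle are handled as
:class:`LoadProfile` objects: per-sample three-component forces on the
femoral head centre, expressed in the model frame (x anterior, y superior,
z lateral; right hip) as percent body weight in CSV files and converted to
newtons via the subject body weight.  For simulation a profile is
discretised into a fixed number of equally spaced quasi-static steps
(13 by default) spanning the full cycle.

Seven representative activity profiles are bundled (normal walking,
ascending/descending stairs, standing up, sitting down, one-legged standing
and knee bending).  They are synthetic curves constructed for this package:
smooth force-magnitude shapes with peak resultants taken from the
instrumented-prosthesis literature (e.g. walking ~233 %BW, descending
stairs ~260 %BW), directed into the acetabular roof.  They are stand-ins
for subject-measured data, which can be supplied as user CSVs with the same
schema.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, FormatError
from .orientation import mirror_matrix

__all__ = ["LoadProfile", "QuasiStaticSchedule", "read_profile_csv",
           "to_model_frame", "discretise", "bundled_activities", "load_activity",
           "GRAVITY"]

GRAVITY = 9.81  # m/s^2
DEFAULT_N_STEPS = 13
_CSV_COLUMNS = ("cycle_pct", "fx_pcBW", "fy_pcBW", "fz_pcBW")


@dataclasses.dataclass(frozen=True)
class LoadProfile:
    """One activity cycle of hip joint forces.

    ``samples``: array (N, 4) of (cycle_fraction in [0, 1], fx, fy, fz) with
    forces in newtons, cycle fractions strictly increasing.
    """

    activity: str
    samples: np.ndarray
    body_weight: float  # kg

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4 or len(s) < 2:
            raise DomainError("samples must be an (N>=2, 4) array")
        if not np.all(np.isfinite(s)):
            raise DomainError("forces must be finite")
        if np.any(np.diff(s[:, 0]) <= 0):
            raise FormatError("cycle fractions must be strictly increasing")
        if s[0, 0] < 0 or s[-1, 0] > 1:
            raise DomainError("cycle fractions must lie in [0, 1]")
        object.__setattr__(self, "samples", s)

    @property
    def cycle_fractions(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def forces(self) -> np.ndarray:
        return self.samples[:, 1:]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.forces, axis=1)


@dataclasses.dataclass(frozen=True)
class QuasiStaticSchedule:
    """Discretised loading: one force vector per quasi-static step."""

    activity: str
    cycle_fractions: np.ndarray
    forces: np.ndarray  # (n_steps, 3), newtons, model frame
    frame: str = "model"

    def __len__(self) -> int:
        return len(self.forces)

    @property
    def n_steps(self) -> int:
        return len(self.forces)


def read_profile_csv(path: str | Path, body_weight: float,
                     activity: str | None = None) -> LoadProfile:
    """Read an activity profile CSV (columns ``cycle_pct, fx_pcBW, fy_pcBW,
    fz_pcBW``; forces in percent body weight) and scale to newtons."""
    if body_weight <= 0:
        raise DomainError("body_weight must be > 0 kg")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty profile file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least two samples")
    cyc = df["cycle_pct"].to_numpy(dtype=float)
    if np.any(np.diff(cyc) <= 0):
        raise FormatError(f"{path}: cycle_pct must be strictly increasing")
    newton_per_pcbw = body_weight * GRAVITY / 100.0
    forces = df[["fx_pcBW", "fy_pcBW", "fz_pcBW"]].to_numpy(dtype=float) * newton_per_pcbw
    samples = np.column_stack([cyc / 100.0, forces])
    name = activity or Path(path).stem
    return LoadProfile(activity=name, samples=samples, body_weight=body_weight)


def to_model_frame(profile: LoadProfile, frame: np.ndarray,
                   side: str = "right") -> LoadProfile:
    """Rotate profile forces into the model frame; mirror for left hips.

    ``frame`` is a 3x3 orthonormal matrix whose rows are the model axes in
    the profile's source frame.  Rotation preserves per-sample force
    magnitudes; for a left hip the lateral (z) component is negated.
    """
    R = np.asarray(frame, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise DomainError("frame must be a 3x3 orthonormal matrix")
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")
    M = R if side == "right" else mirror_matrix() @ R
    forces = profile.forces @ M.T
    samples = np.column_stack([profile.cycle_fractions, forces])
    return dataclasses.replace(profile, samples=samples)


def discretise(profile: LoadProfile,
               n_steps: int = DEFAULT_N_STEPS) -> QuasiStaticSchedule:
    """Discretise a cycle into ``n_steps`` equally spaced quasi-static steps.

    Steps include both cycle endpoints; force components are linearly
    interpolated between profile samples.
    """
    if n_steps < 2:
        raise DomainError("n_steps must be >= 2")
    frac = np.linspace(profile.cycle_fractions[0], profile.cycle_fractions[-1],
                       n_steps)
    forces = np.column_stack([
        np.interp(frac, profile.cycle_fractions, profile.forces[:, k])
        for k in range(3)
    ])
    return QuasiStaticSchedule(activity=profile.activity,
                               cycle_fractions=frac, forces=forces)


def bundled_activities() -> list[str]:
    """Names of the bundled representative activity profiles."""
    reg = resources.files("paramhip").joinpath("data/activities.yaml")
    return sorted(yaml.safe_load(reg.read_text()))


def load_activity(activity: str, body_weight: float = 80.0,
                  side: str = "right") -> LoadProfile:
    """Load a bundled representative activity profile, scaled to newtons.

    Profiles are stored in the right-hip model frame; requesting a left hip
    mirrors the lateral force component.
    """
    reg = yaml.safe_load(
        resources.files("paramhip").joinpath("data/activities.yaml").read_text())
    if activity not in reg:
        raise DomainError(
            f"unknown activity {activity!r}; bundled: {sorted(reg)}")
    ref = resources.files("paramhip").joinpath(f"data/profiles/{reg[activity]}")
    with resources.as_file(ref) as path:
        profile = read_profile_csv(path, body_weight, activity=activity)
    if side == "left":
        profile = to_model_frame(profile, np.eye(3), side="left")
    return profile
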