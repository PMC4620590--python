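"""Model-to-model comparison metrics and mesh-convergence studies.

Two contact runs on the same quasi-static schedule are compared step by
step as percent differences of maximum contact pressure and of thresholded
contact area, relative to the reference model (the segmentation-equivalent
model in a parameterised-vs-segmented comparison).  The maximum difference
and the gait-cycle percentage at which it occurs are reported.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ContactConfig, ContactResult, MaterialConfig, run_activity
from .errors import DomainError
from .geometry import build_model, rings_for_facets
from .loading import QuasiStaticSchedule, discretise, load_activity
from .params import AcetabularParameterSet

__all__ = ["ComparisonReport", "percent_difference_series", "convergence_study"]


@dataclasses.dataclass
class ComparisonReport:
    """Per-step percent differences of two contact runs (test vs reference).

    Steps where the reference value is zero are flagged undefined (NaN) and
    excluded from the maxima.  The normalisation denominator is always the
    reference model value.
    """

    reference_id: str
    test_id: str
    cycle_pct: np.ndarray
    pressure_pct_diff: np.ndarray
    area_pct_diff: np.ndarray
    max_pressure_diff_pct: float
    max_pressure_diff_at_cycle_pct: float
    max_area_diff_pct: float
    max_area_diff_at_cycle_pct: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = [None if not np.isfinite(x) else float(x) for x in v]
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        arrays = {k: np.array([np.nan if v is None else v for v in d[k]], dtype=float)
                  for k in ("cycle_pct", "pressure_pct_diff", "area_pct_diff")}
        rest = {k: d[k] for k in d if k not in arrays}
        return cls(**rest, **arrays)


def _pct_diff(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.full(len(test), np.nan)
    ok = reference != 0
    out[ok] = 100.0 * np.abs(test[ok] - reference[ok]) / reference[ok]
    return out


def _series(result: ContactResult | pd.DataFrame):
    if isinstance(result, ContactResult):
        result = result.to_frame()
    return (result["cycle_fraction"].to_numpy() * 100.0,
            result["max_pressure_MPa"].to_numpy(),
            result["contact_area_mm2"].to_numpy())


def percent_difference_series(test, reference,
                              test_id: str = "test",
                              reference_id: str = "reference") -> ComparisonReport:
    """Percent differences per step, 100 |test - reference| / reference.

    Accepts :class:`ContactResult` objects or result data frames with
    columns ``cycle_fraction``, ``max_pressure_MPa``, ``contact_area_mm2``.
    Both runs must share the same schedule length and cycle grid.
    """
    cyc_t, p_t, a_t = _series(test)
    cyc_r, p_r, a_r = _series(reference)
    if len(p_t) != len(p_r):
        raise DomainError("results have different schedule lengths")
    if not np.allclose(cyc_t, cyc_r, atol=1e-9):
        raise DomainError("results are on different cycle grids")
    dp = _pct_diff(p_t, p_r)
    da = _pct_diff(a_t, a_r)

    def peak(diff):
        if not np.isfinite(diff).any():
            return float("nan"), float("nan")
        i = int(np.nanargmax(diff))
        return float(diff[i]), float(cyc_r[i])

    mp, mp_at = peak(dp)
    ma, ma_at = peak(da)
    return ComparisonReport(reference_id=reference_id, test_id=test_id,
                            cycle_pct=cyc_r, pressure_pct_diff=dp,
                            area_pct_diff=da,
                            max_pressure_diff_pct=mp,
                            max_pressure_diff_at_cycle_pct=mp_at,
                            max_area_diff_pct=ma,
                            max_area_diff_at_cycle_pct=ma_at)


def convergence_study(params: AcetabularParameterSet,
                      material: MaterialConfig,
                      activity: str | QuasiStaticSchedule,
                      density_levels: tuple[int, ...] = (2000, 13000, 107000),
                      body_weight: float = 80.0,
                      n_steps: int = 13,
                      config: ContactConfig | None = None) -> pd.DataFrame:
    """Mesh-convergence table over lunate facet-count levels.

    Runs the activity at each density, reports all-cycle maximum contact
    pressure and contact area per level, successive-pair percent
    differences, and a ``converged`` flag when the last pair differs by at
    most (3%, 1%) in (pressure, area).
    """
    if len(density_levels) < 2:
        raise DomainError("need at least two density levels")
    if isinstance(activity, QuasiStaticSchedule):
        schedule = activity
    else:
        schedule = discretise(load_activity(activity, body_weight,
                                            side=params.side), n_steps)
    rows = []
    for target in density_levels:
        n_rings = rings_for_facets(params, int(target))
        geo = build_model(params, n_rings=n_rings)
        res = run_activity(geo, material, schedule, config=config)
        rows.append({
            "target_facets": int(target),
            "actual_facets": len(geo.articular.faces),
            "peak_pressure_MPa": float(res.max_pressure.max()),
            "peak_area_mm2": float(res.contact_area.max()),
        })
    table = pd.DataFrame(rows)
    prev_p = table["peak_pressure_MPa"].shift(1)
    prev_a = table["peak_area_mm2"].shift(1)
    table["pressure_diff_pct"] = 100.0 * (table["peak_pressure_MPa"] - prev_p).abs() / prev_p
    table["area_diff_pct"] = 100.0 * (table["peak_area_mm2"] - prev_a).abs() / prev_a
    last = table.iloc[-1]
    table.attrs["converged"] = bool(last["pressure_diff_pct"] <= 3.0
                                    and last["area_diff_pct"] <= 1.0)
    return table
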