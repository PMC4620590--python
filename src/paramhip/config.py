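"""Run configuration schema (validated before any computation)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import FormatError

__all__ = ["RunConfig", "load_run_config", "validation_message"]


class RunConfig(BaseModel):
    """Everything needed to reproduce a simulation run.

    The resolved config is serialised into every output directory via the
    run manifest.
    """

    model_config = ConfigDict(extra="forbid")

    preset: str | None = None
    params_file: str | None = None
    activity: str = "walking"
    body_weight: float = Field(80.0, gt=0, description="kg")
    n_steps: int = Field(13, ge=2)
    density: int = Field(13000, ge=50, description="target lunate facet count")
    pressure_threshold: float = Field(0.1, ge=0, description="MPa")
    area_rule: str = Field("all", pattern="^(all|any)$")
    notch: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def params_source(self):
        from .params import load_parameters, preset as load_preset

        if self.params_file is not None:
            return load_parameters(self.params_file)
        return load_preset(self.preset or "P1")


def validation_message(exc: ValidationError) -> str:
    """Human-readable validation errors naming the offending field paths."""
    lines = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides
    (command-line flags override file values; ``None`` overrides ignored)."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: expected a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise FormatError(validation_message(exc)) from exc
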