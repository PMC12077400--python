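"""Pipeline configuration: defaults, TOML loading, and the effective echo.

The configuration is a flat TOML file with one section per stage::

    seed = 0
    [detector]
    log_sigma = 2.0
    [tracker]
    gate_px = 10.0
    [behavior]
    search_speed_min = 6.0
    [stats]
    n_spont_samples = 20000

Absent keys take the pipeline defaults (the assay's published constants);
unknown keys and out-of-range values are rejected with explicit messages.
:func:`dump_config` writes the full effective configuration, and loading
that echo reproduces the configuration exactly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .behavior_stats import BehaviorParams, StatsParams
from .detect import DetectorParams
from .track import TrackerParams
from .iocore import get_logger

__all__ = ["PipelineConfig", "load_config", "dump_config"]

_SECTIONS = {"detector": DetectorParams, "tracker": TrackerParams,
             "behavior": BehaviorParams, "stats": StatsParams}


class PipelineConfig(BaseModel):
    detector: DetectorParams = Field(default_factory=DetectorParams)
    tracker: TrackerParams = Field(default_factory=TrackerParams)
    behavior: BehaviorParams = Field(default_factory=BehaviorParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    seed: int = 0


def _check_keys(data: dict) -> None:
    valid_top = set(_SECTIONS) | {"seed"}
    unknown = set(data) - valid_top
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid_top)}"
        )
    for section, model in _SECTIONS.items():
        if section in data:
            if not isinstance(data[section], dict):
                raise ValueError(f"[{section}] must be a table of key = value pairs")
            bad = set(data[section]) - set(model.model_fields)
            if bad:
                raise ValueError(
                    f"unknown keys {sorted(bad)} in [{section}]; "
                    f"valid keys: {sorted(model.model_fields)}"
                )


def load_config(path: str | Path | None = None, echo: bool = True) -> PipelineConfig:
    """Load a TOML config file; with no path, return all defaults."""
    if path is None:
        cfg = PipelineConfig()
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        _check_keys(data)
        try:
            cfg = PipelineConfig(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"])
            raise ValueError(f"config value out of range: {loc}: {first['msg']}") from exc
    if echo:
        get_logger().info("effective configuration:\n%s", dump_config(cfg))
    return cfg


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    if v is None:
        raise TypeError
    return repr(v)


def dump_config(cfg: PipelineConfig) -> str:
    """Render the effective configuration as TOML (load(dump(c)) == c)."""
    lines = [f"seed = {cfg.seed}", ""]
    for section in _SECTIONS:
        model = getattr(cfg, section)
        lines.append(f"[{section}]")
        for name in type(model).model_fields:
            value = getattr(model, name)
            if value is None:
                continue    # optional, unset
            lines.append(f"{name} = {_fmt(value)}")
        lines.append("")
    return "\n".join(lines)
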