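"""Runtime configuration with validated defaults.

All tunables of the two pipelines live here: the default EDP estimate
(7.5 mmHg), the loop and averaged-beat sample counts (100 / 250), the
invasive low-pass cutoff (10 Hz), the ectopy RR tolerance (20% of the
median RR), and the EDP sensitivity grid. A YAML file can override any
subset; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["Config", "load_config", "save_config"]


@dataclass(frozen=True)
class Config:
    edp_default: float = 7.5            # mmHg
    loop_points: int = 100
    avg_beat_points: int = 250
    filter_cutoff_hz: float = 10.0
    rr_tolerance: float = 0.20          # fraction of median RR
    edp_grid: tuple = (3.0, 7.5, 10.0, 16.0, 25.0, 40.0)  # mmHg
    elastance_path: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "edp_default", "loop_points", "avg_beat_points",
            "filter_cutoff_hz", "rr_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        grid = tuple(float(v) for v in self.edp_grid)
        if any(v <= 0 for v in grid):
            raise ConfigError("edp_grid values must be positive")
        if list(grid) != sorted(grid):
            raise ConfigError("edp_grid must be sorted ascending")
        object.__setattr__(self, "edp_grid", grid)
        if self.elastance_path is not None and not Path(self.elastance_path).exists():
            raise ConfigError(f"elastance_path does not exist: {self.elastance_path}")


def load_config(path=None) -> Config:
    """Load a YAML config, merging with defaults; ``None`` yields defaults."""
    if path is None:
        return Config()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        return Config()
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = set(Config.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "edp_grid" in raw:
        raw["edp_grid"] = tuple(raw["edp_grid"])
    try:
        return Config(**raw)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def save_config(config: Config, path) -> None:
    """Write a config as YAML; round-trips through :func:`load_config`."""
    d = asdict(config)
    d["edp_grid"] = list(d["edp_grid"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
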