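"""Run configuration: YAML loading, validation, defaults and provenance.

Config files are flat YAML with optional sections ``geometry`` (lengths in
μm, pore density as a fraction), ``transport`` (SI), ``numerics``, ``sweep``,
``output`` and a top-level ``seed``. Every key is validated against the
corresponding parameter type before any computation; unknown keys are
rejected by name. An empty file yields the standard published parameter set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometryParams
from .sensitivity import STANDARD_VELOCITY_FRACTIONS, SWEEP_NAMES
from .transport import TransportParams

__all__ = ["ConfigError", "NumericsConfig", "SweepConfig", "OutputConfig", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration file is malformed or violates a parameter constraint."""


@dataclass(frozen=True)
class NumericsConfig:
    resolution_um: float = 10.0
    scheme: str = "imex"
    dt_s: float | None = None
    steady_tol: float = 1e-6
    mode: str = "steady"  # steady | transient
    t_end_s: float = 0.0
    output_times_s: tuple[float, ...] = ()
    bottom_bc: str = "no_flux"

    def __post_init__(self):
        if self.resolution_um <= 0:
            raise ConfigError("numerics.resolution_um must be positive")
        if self.scheme not in ("imex", "explicit", "implicit"):
            raise ConfigError(f"numerics.scheme {self.scheme!r} unknown")
        if self.mode not in ("steady", "transient"):
            raise ConfigError(f"numerics.mode {self.mode!r} unknown")
        if self.steady_tol <= 0:
            raise ConfigError("numerics.steady_tol must be positive")
        if self.t_end_s < 0:
            raise ConfigError("numerics.t_end_s must be nonnegative")
        if self.bottom_bc not in ("no_flux", "sink"):
            raise ConfigError(f"numerics.bottom_bc {self.bottom_bc!r} unknown")


@dataclass(frozen=True)
class SweepConfig:
    name: str = "velocity"
    values: tuple[float, ...] = tuple(6.5e-4 * f for f in STANDARD_VELOCITY_FRACTIONS)
    protocol: str = "steady"
    t_eval_s: float = 5000.0

    def __post_init__(self):
        if self.name not in SWEEP_NAMES:
            raise ConfigError(f"sweep.name {self.name!r} unknown; expected one of {SWEEP_NAMES}")
        if not self.values:
            raise ConfigError("sweep.values must be non-empty")
        if self.protocol not in ("steady", "horizon"):
            raise ConfigError(f"sweep.protocol {self.protocol!r} unknown")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "out"
    formats: tuple[str, ...] = ("csv", "h5")

    def __post_init__(self):
        for f in self.formats:
            if f not in ("csv", "h5"):
                raise ConfigError(f"output.formats entry {f!r} unknown")


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    transport: TransportParams = field(default_factory=TransportParams)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def effective_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {
            "geometry": enc(self.geometry),
            "transport": enc(self.transport),
            "numerics": enc(self.numerics),
            "sweep": enc(self.sweep),
            "output": enc(self.output),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.effective_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {
    "geometry": GeometryParams,
    "transport": TransportParams,
    "numerics": NumericsConfig,
    "sweep": SweepConfig,
    "output": OutputConfig,
}


def _build_section(name: str, cls, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in known:
            raise ConfigError(f"unknown key {name}.{key}")
    coerced = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()
    }
    try:
        return cls(**coerced)
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take the standard defaults.

    ``overrides`` is a nested dict applied on top of the file (used by the CLI
    for --resolution / --seed flags).
    """
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    for sect, payload in (overrides or {}).items():
        if isinstance(payload, dict):
            data.setdefault(sect, {})
            if not isinstance(data[sect], dict):
                raise ConfigError(f"section {sect!r} must be a mapping")
            data[sect].update(payload)
        else:
            data[sect] = payload

    known_top = set(_SECTIONS) | {"seed"}
    for key in data:
        if key not in known_top:
            raise ConfigError(f"unknown top-level key {key!r}")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    geo_payload = dict(data.get("geometry", {}))
    # the run seed doubles as the pore seed unless one is given explicitly
    geo_payload.setdefault("pore_seed", seed)
    sections = {"geometry": _build_section("geometry", GeometryParams, geo_payload)}
    for name in ("transport", "numerics", "sweep", "output"):
        sections[name] = _build_section(name, _SECTIONS[name], dict(data.get(name, {})))
    return RunConfig(seed=seed, **sections)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective config; a load round-trips to the identical config."""
    Path(path).write_text(yaml.safe_dump(cfg.effective_dict(), sort_keys=True))
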