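"""Run configuration: validated defaults plus optional YAML overrides.

Defaults are the reference parameter set of the analysis (L = 1000 nm,
D = 100 nm, Dab = 300 um^2/s, 0.8 s degradation horizon, 3000-molecule PIP2
budget, 11-point grid), so a bare run reproduces the reference tables.
Unknown keys in a config file are rejected with an explicit message rather
than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .allocation import TABLE3_CONDITIONS
from .errors import InvalidParameterError
from .geometry import CylinderGeometry, PhysicalConstants
from .oracle import DEFAULT_SEED
from .synthesis import DEFAULT_PIP2_BUDGET


@dataclass(frozen=True)
class RunConfig:
    """All knobs of an end-to-end run."""

    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    pip2_budget: int = DEFAULT_PIP2_BUDGET
    grid_points: int = 11
    #: (n_plc, kcat_per_s, tau) triples for summary tables.
    scenarios: tuple[tuple[int, float, float], ...] = TABLE3_CONDITIONS
    outdir: Path = Path(".")
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise InvalidParameterError(
                f"grid_points must be >= 2, got {self.grid_points}"
            )
        if self.pip2_budget < 0:
            raise InvalidParameterError("pip2_budget must be >= 0")
        object.__setattr__(self, "outdir", Path(self.outdir))


_GEOMETRY_KEYS = {"length_nm", "diameter_nm"}
_CONSTANT_KEYS = {"dab_um2_s", "degradation_horizon_s", "avogadro"}
_TOP_KEYS = {"geometry", "constants", "pip2_budget", "grid_points", "scenarios", "outdir", "seed"}
_SCENARIO_KEYS = {"n_plc", "kcat_per_s", "tau"}


def _check_keys(given: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise InvalidParameterError(
            f"unknown config key(s) in {where}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a nested mapping, rejecting unknown keys."""
    _check_keys(data, _TOP_KEYS, "top level")
    kwargs: dict[str, Any] = {}
    if "geometry" in data:
        geo = dict(data["geometry"] or {})
        _check_keys(geo, _GEOMETRY_KEYS, "geometry")
        kwargs["geometry"] = CylinderGeometry(**geo)
    if "constants" in data:
        con = dict(data["constants"] or {})
        _check_keys(con, _CONSTANT_KEYS, "constants")
        kwargs["constants"] = PhysicalConstants(**con)
    if "scenarios" in data:
        scenarios = []
        for i, entry in enumerate(data["scenarios"]):
            entry = dict(entry)
            _check_keys(entry, _SCENARIO_KEYS, f"scenarios[{i}]")
            try:
                scenarios.append(
                    (int(entry["n_plc"]), float(entry["kcat_per_s"]), float(entry["tau"]))
                )
            except KeyError as exc:
                raise InvalidParameterError(
                    f"scenarios[{i}] missing key {exc.args[0]!r}"
                ) from None
        kwargs["scenarios"] = tuple(scenarios)
    for key in ("pip2_budget", "grid_points", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "outdir" in data:
        kwargs["outdir"] = Path(data["outdir"])
    return RunConfig(**kwargs)


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a YAML config file (optional) and apply keyword overrides."""
    if path is None:
        cfg = RunConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise InvalidParameterError(f"config file {path} must contain a mapping")
        cfg = config_from_dict(raw)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    return replace(cfg, **overrides) if overrides else cfg
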