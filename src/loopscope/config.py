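"""Programming-free configuration surface.

A complete experiment is specified by three kinds of files, all plain
text: a master ``schedule.toml`` with the overall length and the imaging
and stimulation cadences, a multipoint position list (minimal XML or CSV)
naming each stage position and its coordinates, and one TOML per
position describing the modules to run there.  Parsing is strict about
required keys and units, and a fully cross-checked
:class:`ExperimentPlan` is the only object the orchestrator accepts.

Units: stage coordinates and pixel sizes are micrometres; all intervals
are seconds internally, with ``h``/``min``/``s``/``ms`` suffixes accepted
in TOML (bare numbers mean seconds).
"""

from __future__ import annotations

import csv
import io
import re
import tomllib
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import ConfigError, PlanError
from .registry import ModuleRegistry, default_registry

__all__ = [
    "ScheduleConfig",
    "StagePosition",
    "PositionConfig",
    "ExperimentPlan",
    "parse_duration",
    "parse_schedule",
    "serialize_schedule",
    "parse_multipoints",
    "parse_position_config",
    "build_experiment_plan",
]

_DURATION_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(h|min|s|ms)?\s*$")
_DURATION_SCALE = {"h": 3600.0, "min": 60.0, "s": 1.0, "ms": 1e-3, None: 1.0}


def parse_duration(value) -> float:
    """Convert ``16``, ``"16h"``, ``"5min"``, ``"30s"`` ... to seconds."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    m = _DURATION_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse duration {value!r}")
    return float(m.group(1)) * _DURATION_SCALE[m.group(2)]


@dataclass(frozen=True)
class ScheduleConfig:
    """Overall settings for the entire experiment."""

    experiment_length_s: float
    imaging_interval_s: float
    stimulation_interval_s: float
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_length_s < 0:
            raise ConfigError("experiment length must be non-negative")
        for key in ("imaging_interval_s", "stimulation_interval_s"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")


@dataclass(frozen=True)
class StagePosition:
    name: str
    x: float
    y: float
    z: float | None = None


@dataclass
class PositionConfig:
    """The experiment run at one stage position."""

    position_name: str
    pattern: dict
    segmentation: dict | None = None
    channels: list[dict] = dc_field(default_factory=lambda: [{"name": "nuclear", "exposure_ms": 50.0}])
    pixel_size_um: float = 0.65
    fov_shape: tuple[int, int] = (1024, 1024)
    simulate: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        self.fov_shape = tuple(int(v) for v in self.fov_shape)


@dataclass
class ExperimentPlan:
    """Validated union of schedule, stage positions and position configs."""

    schedule: ScheduleConfig
    positions: list[tuple[StagePosition, PositionConfig]]

    @property
    def position_names(self) -> list[str]:
        return [sp.name for sp, _ in self.positions]


# ---------------------------------------------------------------------------
# parsers


_SCHEDULE_KEYS = {"length", "imaging_interval", "stimulation_interval", "output_dir", "seed"}


def _load_toml(text: str) -> dict:
    try:
        return tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:  # message includes line/column
        raise ConfigError(f"malformed TOML: {exc}") from exc


def parse_schedule(toml_text: str) -> ScheduleConfig:
    """Parse a master schedule TOML (``[schedule]`` table or top level)."""
    data = _load_toml(toml_text)
    table = data.get("schedule", data)
    for key in ("length", "imaging_interval", "stimulation_interval"):
        if key not in table:
            raise ConfigError(f"schedule is missing required key {key!r}")
    unknown = set(table) - _SCHEDULE_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown schedule keys: {sorted(unknown)}", stacklevel=2)
    return ScheduleConfig(
        experiment_length_s=parse_duration(table["length"]),
        imaging_interval_s=parse_duration(table["imaging_interval"]),
        stimulation_interval_s=parse_duration(table["stimulation_interval"]),
        output_dir=str(table.get("output_dir", "results")),
        seed=int(table.get("seed", 0)),
    )


def serialize_schedule(cfg: ScheduleConfig) -> str:
    return (
        "[schedule]\n"
        f'length = "{cfg.experiment_length_s}s"\n'
        f'imaging_interval = "{cfg.imaging_interval_s}s"\n'
        f'stimulation_interval = "{cfg.stimulation_interval_s}s"\n'
        f'output_dir = "{cfg.output_dir}"\n'
        f"seed = {cfg.seed}\n"
    )


def parse_multipoints(text: str) -> list[StagePosition]:
    """Parse a multipoint list: minimal XML dialect, or CSV fallback.

    XML: ``<positions><position name="A1" x="0" y="0" [z="0"]/></positions>``.
    CSV: header ``name,x,y[,z]``.  Order is preserved; names must be
    unique.
    """
    stripped = text.lstrip()
    if stripped.startswith("<"):
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise ConfigError(f"malformed multipoints XML: {exc}") from exc
        rows = []
        for el in root.iter("position"):
            attrs = el.attrib
            rows.append((attrs.get("name"), attrs.get("x"), attrs.get("y"), attrs.get("z")))
    else:
        reader = csv.DictReader(io.StringIO(text))
        rows = [(r.get("name"), r.get("x"), r.get("y"), r.get("z")) for r in reader]

    out: list[StagePosition] = []
    seen: set[str] = set()
    for name, x, y, z in rows:
        if not name:
            raise ConfigError("every position needs a name")
        if name in seen:
            raise ConfigError(f"duplicate position name {name!r}")
        seen.add(name)
        try:
            out.append(
                StagePosition(
                    name=name,
                    x=float(x),
                    y=float(y),
                    z=float(z) if z not in (None, "") else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric coordinate for position {name!r}") from exc
    return out


def parse_position_config(toml_text: str) -> PositionConfig:
    """Parse one per-position TOML file."""
    data = _load_toml(toml_text)
    pos = data.get("position", {})
    if "name" not in pos:
        raise ConfigError("position config is missing [position] name")
    if "pattern" not in data or "module" not in data["pattern"]:
        raise ConfigError("position config is missing [pattern] module")
    segmentation = data.get("segmentation")
    if segmentation is not None and segmentation.get("module") in (None, "none"):
        segmentation = None
    return PositionConfig(
        position_name=str(pos["name"]),
        pattern=dict(data["pattern"]),
        segmentation=dict(segmentation) if segmentation else None,
        channels=[dict(c) for c in data.get("channels", [{"name": "nuclear", "exposure_ms": 50.0}])],
        pixel_size_um=float(pos.get("pixel_size_um", 0.65)),
        fov_shape=tuple(pos.get("fov", (1024, 1024))),
        simulate=dict(data.get("simulate", {})),
    )


def build_experiment_plan(
    schedule: ScheduleConfig,
    positions: list[StagePosition],
    configs: list[PositionConfig],
    registry: ModuleRegistry | None = None,
) -> ExperimentPlan:
    """Cross-validate and combine schedule, positions, and configs.

    Establishes a bijection between stage positions and configs
    (preserving stage-position order), resolves module names against the
    registry, and rejects closed-loop pattern modules configured without
    a segmenter.
    """
    registry = registry if registry is not None else default_registry()
    if not positions:
        raise PlanError("a plan needs at least one stage position")
    names = [p.name for p in positions]
    if len(set(names)) != len(names):
        raise PlanError("duplicate stage position names")
    by_name: dict[str, PositionConfig] = {}
    for cfg in configs:
        if cfg.position_name not in names:
            raise PlanError(f"config references unknown position {cfg.position_name!r}")
        if cfg.position_name in by_name:
            raise PlanError(f"position {cfg.position_name!r} has more than one config")
        by_name[cfg.position_name] = cfg
    missing = [n for n in names if n not in by_name]
    if missing:
        raise PlanError(f"positions without a config: {missing}")

    for cfg in configs:
        pattern_name = cfg.pattern.get("module")
        if registry.pattern_needs_masks(pattern_name) and cfg.segmentation is None:
            raise PlanError(
                f"pattern module {pattern_name!r} at position {cfg.position_name!r} "
                "requires segmentation masks but no segmentation module is configured"
            )
        if cfg.segmentation is not None:
            registry.resolve_segmenter(cfg.segmentation)  # absent backend fails here, not mid-run

    return ExperimentPlan(schedule=schedule, positions=[(p, by_name[p.name]) for p in positions])


def load_plan(
    schedule_path: str | Path,
    multipoints_path: str | Path,
    config_dir: str | Path,
    registry: ModuleRegistry | None = None,
) -> ExperimentPlan:
    """Load a complete plan from files: one TOML per position, named ``<position>.toml``."""
    schedule = parse_schedule(Path(schedule_path).read_text())
    positions = parse_multipoints(Path(multipoints_path).read_text())
    configs = []
    for pos in positions:
        path = Path(config_dir) / f"{pos.name}.toml"
        if not path.exists():
            raise PlanError(f"no config file for position {pos.name!r} (expected {path})")
        configs.append(parse_position_config(path.read_text()))
    return build_experiment_plan(schedule, positions, configs, registry)
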