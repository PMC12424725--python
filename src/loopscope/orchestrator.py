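"""Master scheduler and closed-loop event plumbing.

The orchestrator turns an :class:`~loopscope.config.ExperimentPlan` into
a deterministic event timeline (image / segment / compute_pattern /
stimulate per position) and executes it against anything implementing
:class:`MicroscopeInterface`.  The closed-loop ordering contract is the
heart of the design: the pattern projected at any stimulate event at
time t derives from the most recent completed segmentation whose source
frame time is <= t, and stimulation cadence is never broken — before a
first pattern exists, or when a module fails, an all-dark fallback (or
the most recent valid pattern) is projected instead.

Execution here is a single-threaded event loop over a simulated clock;
the ordering contract, not the threading mechanism, is what downstream
code may rely on.  ``validate_record`` replays any run record and checks
the contract independently.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentPlan, StagePosition
from .errors import StorageError
from .patterns import PatternManager, StimulusPattern
from .registry import ModuleRegistry, default_registry
from .segmentation import LabelMask, measure_cells

__all__ = [
    "Event",
    "Frame",
    "MicroscopeInterface",
    "ExperimentRecord",
    "generate_event_timeline",
    "run_loop",
    "validate_record",
    "outbox_store",
]

KIND_PRIORITY = {"stimulate": 0, "image": 1, "segment": 2, "compute_pattern": 3}


@dataclass(frozen=True)
class Event:
    time: float
    position_name: str
    kind: str
    sequence_index: int


@dataclass
class Frame:
    """One acquired image."""

    pixels: np.ndarray
    position_name: str = ""
    channel: str = ""
    time: float = 0.0
    frame_index: int = 0


class MicroscopeInterface(abc.ABC):
    """Contract between the orchestrator and a (virtual) microscope.

    Implementations: the simulator in :mod:`loopscope.simulate`, or a
    thin hardware adapter.  ``advance_to`` is an optional hook for
    simulated clocks; hardware implementations simply ignore it.
    """

    @abc.abstractmethod
    def move_to(self, position: StagePosition) -> None: ...

    @abc.abstractmethod
    def snap(self, channel: str, exposure_ms: float) -> Frame: ...

    @abc.abstractmethod
    def project(self, pattern: StimulusPattern, duration_ms: float) -> None: ...

    def advance_to(self, t: float) -> None:  # simulated-clock hook
        pass


@dataclass
class EventLog:
    time: float
    position_name: str
    kind: str
    status: str  # "ok", "fallback", or "error:<type>"
    detail: str = ""
    source_frame_time: float | None = None
    provenance: str = ""


@dataclass
class ExperimentRecord:
    """Per-position logs, per-cell tables, and (optionally) raw arrays."""

    position_names: list[str]
    events: list[EventLog] = dc_field(default_factory=list)
    cells_rows: list[dict] = dc_field(default_factory=list)
    observations: dict = dc_field(default_factory=dict)  # (position, time) -> list[CellObservation]
    segmentations: dict = dc_field(default_factory=dict)  # position -> list of completed frame times
    pattern_errors: dict = dc_field(default_factory=dict)  # position -> count
    frames: dict = dc_field(default_factory=dict)  # (position, channel, time) -> ndarray, if kept
    masks: dict = dc_field(default_factory=dict)  # (position, time) -> ndarray, if kept
    patterns: dict = dc_field(default_factory=dict)  # (position, time) -> ndarray, if kept
    keep_arrays: bool = True

    def cells_table(self) -> pd.DataFrame:
        cols = ["time_s", "position", "label", "x_px", "y_px", "area_px", "mean_intensity", "stimulated"]
        return pd.DataFrame(self.cells_rows, columns=cols)

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time_s": e.time,
                    "position": e.position_name,
                    "kind": e.kind,
                    "status": e.status,
                    "source_frame_time": e.source_frame_time,
                    "provenance": e.provenance,
                }
                for e in self.events
            ]
        )


def _times(length_s: float, interval_s: float) -> list[float]:
    n = int(length_s / interval_s + 1e-9)
    return [i * interval_s for i in range(n + 1)]


def generate_event_timeline(
    plan: ExperimentPlan, registry: ModuleRegistry | None = None
) -> list[Event]:
    """Deterministic event list for a plan.

    Image events fire at every multiple of the imaging interval and
    stimulate events at every multiple of the stimulation interval, both
    from t=0 through the experiment length inclusive.  Each image event
    is followed (same timestamp) by a segment event when segmentation is
    configured and a compute_pattern event when the position's pattern
    module is closed-loop.  Ties are broken by kind priority
    (stimulate < image < segment < compute_pattern) then position order,
    with one exception: at t=0 a closed-loop position's stimulate event
    runs last, so the very first stimulation can already use a mask.
    """
    registry = registry if registry is not None else default_registry()
    sched = plan.schedule
    entries: list[tuple[float, int, int, str, str]] = []
    for pos_index, (stage, cfg) in enumerate(plan.positions):
        closed_loop = registry.pattern_needs_masks(cfg.pattern["module"])
        for t in _times(sched.experiment_length_s, sched.stimulation_interval_s):
            prio = 9 if (t == 0 and closed_loop) else KIND_PRIORITY["stimulate"]
            entries.append((t, prio, pos_index, stage.name, "stimulate"))
        for t in _times(sched.experiment_length_s, sched.imaging_interval_s):
            entries.append((t, KIND_PRIORITY["image"], pos_index, stage.name, "image"))
            if cfg.segmentation is not None:
                entries.append((t, KIND_PRIORITY["segment"], pos_index, stage.name, "segment"))
            if closed_loop:
                entries.append((t, KIND_PRIORITY["compute_pattern"], pos_index, stage.name, "compute_pattern"))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    counters: dict[tuple[str, str], int] = {}
    out = []
    for t, _prio, _idx, name, kind in entries:
        seq = counters.get((name, kind), 0)
        counters[(name, kind)] = seq + 1
        out.append(Event(time=t, position_name=name, kind=kind, sequence_index=seq))
    return out


# ---------------------------------------------------------------------------
# outbox persistence


def outbox_store(out_root: str | Path, artifact, position_name: str, time_s: float, *, channel: str | None = None) -> Path:
    """Persist one artifact under the deterministic output tree.

    Frames and masks are written as 16-bit TIFF, patterns as 8-bit PNG;
    per-cell rows (a list of dicts) are appended to ``cells.csv``.
    Returns the artifact path.
    """
    import imageio.v3 as iio
    import tifffile

    root = Path(out_root)
    stamp = f"t{int(round(time_s)):06d}"
    try:
        if isinstance(artifact, Frame):
            path = root / position_name / "images" / (channel or artifact.channel) / f"{stamp}.tif"
            path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(path, np.clip(artifact.pixels, 0, 65535).astype(np.uint16))
        elif isinstance(artifact, LabelMask):
            path = root / position_name / "masks" / f"{stamp}.tif"
            path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(path, artifact.labels.astype(np.uint16))
        elif isinstance(artifact, StimulusPattern):
            path = root / position_name / "patterns" / f"{stamp}.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(path, np.round(artifact.intensity * 255).astype(np.uint8))
        elif isinstance(artifact, list):  # per-cell rows
            path = root / position_name / "cells.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            df = pd.DataFrame(artifact)
            df.to_csv(path, mode="a", header=not path.exists(), index=False)
        else:
            raise StorageError(f"cannot store artifact of type {type(artifact).__name__}")
    except OSError as exc:
        raise StorageError(f"cannot write artifact under {root}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# the loop


def run_loop(
    plan: ExperimentPlan,
    scope: MicroscopeInterface,
    registry: ModuleRegistry | None = None,
    out_dir: str | Path | None = None,
    stim_duration_ms: float = 500.0,
    keep_arrays: bool = False,
) -> ExperimentRecord:
    """Execute a plan's timeline against a microscope.

    Events run in timeline order on the experiment clock.  A failure in
    any module is logged and isolated: the event is marked failed and
    the loop continues, and a failing pattern module never interrupts
    stimulation cadence (the most recent valid pattern, or all-dark, is
    projected instead).
    """
    registry = registry if registry is not None else default_registry()
    timeline = generate_event_timeline(plan, registry)
    record = ExperimentRecord(position_names=plan.position_names, keep_arrays=keep_arrays)

    stages = {stage.name: stage for stage, _ in plan.positions}
    cfgs = {stage.name: cfg for stage, cfg in plan.positions}
    manager = PatternManager(fov_shapes={n: cfgs[n].fov_shape for n in stages})
    modules, segmenters = {}, {}
    for name, cfg in cfgs.items():
        module = registry.make_pattern_module(cfg.pattern, cfg.pixel_size_um, cfg.fov_shape)
        modules[name] = module
        if module.parametric:
            manager.register_parametric(name, module.evaluate)
        if cfg.segmentation is not None:
            segmenters[name] = registry.resolve_segmenter(cfg.segmentation)

    latest_frames: dict[str, dict[str, Frame]] = {n: {} for n in stages}
    latest_mask: dict[str, LabelMask | None] = {n: None for n in stages}
    latest_obs: dict[str, list] = {n: [] for n in stages}
    last_projected: dict[str, StimulusPattern | None] = {n: None for n in stages}
    frame_counter: dict[str, int] = {n: 0 for n in stages}

    for ev in timeline:
        scope.advance_to(ev.time)
        name = ev.position_name
        cfg = cfgs[name]
        try:
            if ev.kind == "image":
                scope.move_to(stages[name])
                for ch in cfg.channels:
                    frame = scope.snap(ch["name"], float(ch.get("exposure_ms", 50.0)))
                    frame.position_name, frame.time = name, ev.time
                    frame.frame_index = frame_counter[name]
                    latest_frames[name][ch["name"]] = frame
                    if keep_arrays:
                        record.frames[(name, ch["name"], ev.time)] = frame.pixels
                    if out_dir is not None:
                        outbox_store(out_dir, frame, name, ev.time)
                frame_counter[name] += 1
                record.events.append(EventLog(ev.time, name, "image", "ok"))

            elif ev.kind == "segment":
                seg_channel = (cfg.segmentation or {}).get("channel", "nuclear")
                frame = latest_frames[name].get(seg_channel)
                if frame is None:
                    raise RuntimeError(f"no frame on channel {seg_channel!r} to segment")
                seg_params = {
                    k: v
                    for k, v in (cfg.segmentation or {}).items()
                    if k in ("smooth_sigma", "min_area", "max_area")
                }
                mask = segmenters[name](frame.pixels, **seg_params)
                mask.frame_time, mask.position_name = frame.time, name
                latest_mask[name] = mask
                channel_imgs = {ch: f.pixels for ch, f in latest_frames[name].items()}
                obs = measure_cells(channel_imgs, mask)
                latest_obs[name] = obs
                record.observations[(name, ev.time)] = obs
                record.segmentations.setdefault(name, []).append(frame.time)
                meas_channel = cfg.pattern.get("channel", "fluor" if "fluor" in channel_imgs else seg_channel)
                rows = []
                pat = last_projected[name]
                for o in obs:
                    stim = 0
                    if pat is not None:
                        px = min(max(int(round(o.centroid[0])), 0), cfg.fov_shape[1] - 1)
                        py = min(max(int(round(o.centroid[1])), 0), cfg.fov_shape[0] - 1)
                        stim = int(pat.intensity[py, px] > 0)
                    rows.append(
                        {
                            "time_s": ev.time,
                            "position": name,
                            "label": o.label,
                            "x_px": o.centroid[0],
                            "y_px": o.centroid[1],
                            "area_px": o.area,
                            "mean_intensity": o.mean_intensity.get(meas_channel, np.nan),
                            "stimulated": stim,
                        }
                    )
                record.cells_rows.extend(rows)
                if keep_arrays:
                    record.masks[(name, ev.time)] = mask.labels
                if out_dir is not None:
                    outbox_store(out_dir, mask, name, ev.time)
                    outbox_store(out_dir, rows, name, ev.time)
                record.events.append(EventLog(ev.time, name, "segment", "ok", source_frame_time=frame.time))

            elif ev.kind == "compute_pattern":
                mask = latest_mask[name]
                if mask is None:
                    raise RuntimeError("no completed segmentation yet")
                pattern = modules[name].compute(ev.time, mask, latest_obs[name])
                pattern.position_name = name
                manager.submit(pattern)
                record.events.append(
                    EventLog(
                        ev.time, name, "compute_pattern", "ok",
                        source_frame_time=pattern.source_frame_time,
                        provenance=pattern.provenance,
                    )
                )

            elif ev.kind == "stimulate":
                pattern = manager.current(name, ev.time)
                scope.move_to(stages[name])
                scope.project(pattern, stim_duration_ms)
                last_projected[name] = pattern
                status = "fallback" if pattern.provenance == "fallback-dark" else "ok"
                if keep_arrays:
                    record.patterns[(name, ev.time)] = pattern.intensity
                if out_dir is not None:
                    outbox_store(out_dir, pattern, name, ev.time)
                record.events.append(
                    EventLog(
                        ev.time, name, "stimulate", status,
                        source_frame_time=pattern.source_frame_time,
                        provenance=pattern.provenance,
                    )
                )
        except Exception as exc:  # fault isolation: log and continue
            if ev.kind == "compute_pattern":
                record.pattern_errors[name] = record.pattern_errors.get(name, 0) + 1
            record.events.append(EventLog(ev.time, name, ev.kind, f"error:{type(exc).__name__}", detail=str(exc)))

    if out_dir is not None:
        path = Path(out_dir) / "events.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        record.events_table().to_csv(path, index=False)
    return record


# ---------------------------------------------------------------------------
# replay validation


def validate_record(record: ExperimentRecord, plan: ExperimentPlan, registry: ModuleRegistry | None = None) -> list[str]:
    """Independently re-check the closed-loop ordering contract on a record.

    Returns a list of human-readable violations (empty = contract holds):
    every stimulate event's pattern must derive from a completed
    segmentation of a frame at time <= the event time (and from the most
    recent one at pattern-computation time), stimulation cadence must be
    unbroken, and frame/segmentation conservation must hold.
    """
    registry = registry if registry is not None else default_registry()
    sched = plan.schedule
    violations: list[str] = []
    expected_stims = len(_times(sched.experiment_length_s, sched.stimulation_interval_s))
    for stage, cfg in plan.positions:
        name = stage.name
        evs = [e for e in record.events if e.position_name == name]
        stims = [e for e in evs if e.kind == "stimulate"]
        if len(stims) != expected_stims:
            violations.append(f"{name}: {len(stims)} stimulate events, expected {expected_stims}")
        seg_times = sorted(record.segmentations.get(name, []))
        closed_loop = registry.pattern_needs_masks(cfg.pattern["module"])
        for e in stims:
            if not e.status.startswith(("ok", "fallback")):
                violations.append(f"{name}: stimulate at t={e.time} failed ({e.status})")
            if closed_loop and e.status == "ok" and e.source_frame_time is not None:
                if e.source_frame_time > e.time:
                    violations.append(
                        f"{name}: stimulate at t={e.time} used future frame t={e.source_frame_time}"
                    )
                usable = [t for t in seg_times if t <= e.time]
                if not usable or e.source_frame_time not in usable:
                    violations.append(
                        f"{name}: stimulate at t={e.time} provenance t={e.source_frame_time} "
                        "does not match any completed segmentation"
                    )
        n_images_ok = sum(1 for e in evs if e.kind == "image" and e.status == "ok")
        n_segment_ok = sum(1 for e in evs if e.kind == "segment" and e.status == "ok")
        if n_segment_ok != len(seg_times):
            violations.append(f"{name}: segment log/record mismatch")
        if cfg.segmentation is not None and n_segment_ok > n_images_ok:
            violations.append(f"{name}: more segmentations than images")
    return violations
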