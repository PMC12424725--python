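"""Registry of pattern and segmentation modules.

An experiment plan names its modules by string; the registry maps those
names to factories and records each pattern module's dependencies (in
particular whether it consumes segmentation masks, i.e. is closed-loop).
Registering additional modules never invalidates an existing plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from . import patterns as pat
from . import segmentation as seg
from .errors import CapabilityError, LoopscopeError

__all__ = ["PatternModule", "ModuleRegistry", "default_registry"]


class PatternModule:
    """One configured pattern module bound to a stage position.

    Open-loop (``parametric``) modules evaluate a pattern from time
    alone; closed-loop modules derive one from the latest segmentation.
    """

    name: str = ""
    needs_masks: bool = False
    parametric: bool = False

    def evaluate(self, t: float) -> pat.StimulusPattern:  # open-loop path
        raise NotImplementedError

    def compute(self, t, mask, observations) -> pat.StimulusPattern:  # closed-loop path
        raise NotImplementedError


class BarsModule(PatternModule):
    name = "bars"
    parametric = True

    def __init__(self, params: dict, pixel_size_um: float, fov_shape: tuple[int, int]):
        self.p = pat.BarWaveParams(
            period_um=float(params["period_um"]),
            speed_um_per_h=float(params.get("speed_um_per_h", 0.0)),
            duty=float(params.get("duty", 0.5)),
            offset_um=float(params.get("offset_um", 0.0)),
        )
        self.pixel_size_um = pixel_size_um
        self.fov_shape = fov_shape

    def evaluate(self, t: float) -> pat.StimulusPattern:
        return pat.bar_wave_pattern(self.p, t, self.pixel_size_um, self.fov_shape)


class ConstantModule(PatternModule):
    name = "constant"
    parametric = True

    def __init__(self, params: dict, pixel_size_um: float, fov_shape: tuple[int, int]):
        self.intensity = float(params.get("intensity", 1.0))
        region = params.get("region")
        self.region = tuple(int(v) for v in region) if region is not None else None
        self.fov_shape = fov_shape

    def evaluate(self, t: float) -> pat.StimulusPattern:
        out = pat.constant_pattern(self.fov_shape, self.intensity, self.region, valid_from=t)
        return out


class VortexModule(PatternModule):
    name = "vortex"
    needs_masks = True

    def __init__(self, params: dict, pixel_size_um: float, fov_shape: tuple[int, int]):
        center = params.get("center")
        self.p = pat.VortexParams(
            center=tuple(float(v) for v in center) if center is not None else None,
            max_intensity=float(params.get("max_intensity", 1.0)),
            chirality=params.get("chirality", "ccw"),
            gradient_scope=params.get("gradient_scope", "cell"),
        )
        self.fov_shape = fov_shape

    def compute(self, t, mask: seg.LabelMask, observations) -> pat.StimulusPattern:
        cents = [(o.label, o.centroid[0], o.centroid[1]) for o in observations]
        if not cents:
            raise LoopscopeError("vortex pattern requires at least one segmented cell")
        regions = pat.voronoi_assign(cents, self.fov_shape)
        out = pat.vortex_gradient_pattern(cents, regions, self.p, valid_from=t)
        out.source_frame_time = mask.frame_time
        return out


class BangBangModule(PatternModule):
    name = "bangbang"
    needs_masks = True

    def __init__(self, params: dict, pixel_size_um: float, fov_shape: tuple[int, int]):
        setpoint = params.get("setpoint")
        if setpoint is None and "setpoint_image" in params:
            import tifffile

            setpoint = tifffile.imread(params["setpoint_image"])
        if setpoint is None:
            raise LoopscopeError("bangbang requires 'setpoint' or 'setpoint_image'")
        self.p = pat.BangBangParams(
            setpoint=np.asarray(setpoint, dtype=float) if not np.isscalar(setpoint) else float(setpoint),
            hysteresis_band=float(params.get("hysteresis", 0.0)),
            channel=params.get("channel", "fluor"),
        )

    def compute(self, t, mask: seg.LabelMask, observations) -> pat.StimulusPattern:
        out = pat.bang_bang_pattern(observations, mask.labels, self.p, valid_from=t)
        out.source_frame_time = mask.frame_time
        return out


@dataclass
class ModuleRegistry:
    """Name -> factory maps for pattern and segmentation modules."""

    pattern_modules: dict[str, type[PatternModule]] = dc_field(default_factory=dict)
    segmenters: dict[str, Callable[[dict], Callable]] = dc_field(default_factory=dict)

    def register_pattern(self, cls: type[PatternModule]) -> None:
        self.pattern_modules[cls.name] = cls

    def register_segmenter(self, name: str, resolver: Callable[[dict], Callable]) -> None:
        self.segmenters[name] = resolver

    def pattern_needs_masks(self, name: str) -> bool:
        if name not in self.pattern_modules:
            raise LoopscopeError(f"unknown pattern module {name!r}")
        return self.pattern_modules[name].needs_masks

    def make_pattern_module(self, spec: dict, pixel_size_um: float, fov_shape) -> PatternModule:
        name = spec.get("module")
        if name not in self.pattern_modules:
            raise LoopscopeError(f"unknown pattern module {name!r}")
        params = {k: v for k, v in spec.items() if k != "module"}
        return self.pattern_modules[name](params, pixel_size_um, tuple(fov_shape))

    def resolve_segmenter(self, spec: dict) -> Callable:
        name = spec.get("module", "threshold")
        if name not in self.segmenters:
            raise CapabilityError(f"unknown segmentation module {name!r}")
        return self.segmenters[name](spec)


def default_registry() -> ModuleRegistry:
    reg = ModuleRegistry()
    for cls in (BarsModule, ConstantModule, VortexModule, BangBangModule):
        reg.register_pattern(cls)
    reg.register_segmenter("threshold", seg.external_segmenter_adapter)
    reg.register_segmenter("cellpose_adapter", seg.external_segmenter_adapter)
    return reg
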