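"""Stimulation pattern engine.

This module generates the 2-D illumination maps that the (virtual) DMD
projects onto the sample: traveling bar waves, per-cell counter-clockwise
gradient "vortex" patterns built on a Voronoi tessellation of nuclear
centroids, thermostat-style bang-bang feedback patterns, and constant
regions.  A :class:`PatternManager` stores computed patterns per stage
position and serves the one valid at any requested time.

Conventions
-----------
Arrays are indexed ``[row, col]``; the physical frame shares the display
frame: x increases with column, y increases with row (downward on screen).
"Counter-clockwise" is counter-clockwise *on screen*, which in this
row-down frame means the tangent of a point at offset ``r = (rx, ry)``
from the rotation center is ``t = (ry, -rx) / |r|``.

All intensities are fractions of full DMD power in ``[0, 1]``; bar and
bang-bang patterns are binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import LoopscopeError

__all__ = [
    "StimulusPattern",
    "BarWaveParams",
    "VortexParams",
    "BangBangParams",
    "bar_wave_pattern",
    "wave_phase",
    "voronoi_assign",
    "vortex_gradient_pattern",
    "bang_bang_pattern",
    "constant_pattern",
    "PatternManager",
]


@dataclass
class StimulusPattern:
    """A 2-D illumination intensity map in [0, 1] with a validity time.

    ``provenance`` names the producing pattern module;
    ``source_frame_time`` is the acquisition time of the frame whose
    segmentation the pattern was derived from (None for open-loop
    modules such as bars or constant regions).
    """

    intensity: np.ndarray
    valid_from: float = 0.0
    position_name: str = ""
    provenance: str = ""
    source_frame_time: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        lo, hi = float(self.intensity.min(initial=0.0)), float(self.intensity.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise LoopscopeError(f"pattern intensities outside [0, 1]: min={lo}, max={hi}")


@dataclass(frozen=True)
class BarWaveParams:
    """Traveling horizontal bar wave.

    period_um
        Spatial period P between successive bar leading edges (um).
    speed_um_per_h
        Signed wave speed v; positive waves travel toward increasing y.
    duty
        Illuminated fraction of each period, in (0, 1].
    offset_um
        Phase offset y0: the leading edge of a bar sits at y0 at t = 0.
    """

    period_um: float
    speed_um_per_h: float
    duty: float = 0.5
    offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.period_um <= 0:
            raise LoopscopeError("bar wave period must be positive")
        if not 0 < self.duty <= 1:
            raise LoopscopeError("duty cycle must lie in (0, 1]")


@dataclass(frozen=True)
class VortexParams:
    """Per-cell rotational gradient stimulus.

    center is in pixel (x, y) coordinates; None means the FOV center.
    gradient_scope selects whether the linear ramp is normalized over
    each cell's own Voronoi region ("cell") or over the whole FOV
    ("fov").
    """

    center: tuple[float, float] | None = None
    max_intensity: float = 1.0
    chirality: str = "ccw"
    gradient_scope: str = "cell"

    def __post_init__(self) -> None:
        if self.chirality not in ("ccw", "cw"):
            raise LoopscopeError("chirality must be 'ccw' or 'cw'")
        if not 0 < self.max_intensity <= 1:
            raise LoopscopeError("max_intensity must lie in (0, 1]")
        if self.gradient_scope not in ("cell", "fov"):
            raise LoopscopeError("gradient_scope must be 'cell' or 'fov'")


@dataclass(frozen=True)
class BangBangParams:
    """Bang-bang (thermostat) feedback on per-cell intensity.

    setpoint is either a scalar (same target for every cell) or a 2-D
    grayscale image of local targets; a cell's set point is then the
    mean of that image over the cell's mask pixels.  A cell is lit at
    full power iff its measured mean intensity is below
    ``setpoint - hysteresis_band``.
    """

    setpoint: float | np.ndarray
    hysteresis_band: float = 0.0
    channel: str = "fluor"

    def __post_init__(self) -> None:
        sp = np.asarray(self.setpoint, dtype=float)
        if np.any(sp <= 0):
            raise LoopscopeError("set point must be positive everywhere")


# ---------------------------------------------------------------------------
# bar waves and wave phase


def _row_coords(n_rows: int, pixel_size_um: float) -> np.ndarray:
    # pixel-center convention: row r has physical y = r * pixel_size
    return np.arange(n_rows) * pixel_size_um


def bar_wave_pattern(
    p: BarWaveParams,
    t: float,
    pixel_size_um: float,
    fov_shape: tuple[int, int],
) -> StimulusPattern:
    """Binary traveling-bar pattern at experiment time ``t`` (seconds).

    A row at physical coordinate y is illuminated iff
    ``wrap(y - y0 - v*t, P) < duty * P``; the pattern is constant along x.
    """
    if t < 0:
        raise LoopscopeError("time must be non-negative")
    y = _row_coords(fov_shape[0], pixel_size_um)
    travel = p.speed_um_per_h * (t / 3600.0)
    lit = np.mod(y - p.offset_um - travel, p.period_um) < p.duty * p.period_um
    intensity = np.repeat(lit[:, None].astype(float), fov_shape[1], axis=1)
    return StimulusPattern(intensity, valid_from=t, provenance="bars")


def wave_phase(y: float | np.ndarray, t: float | np.ndarray, p: BarWaveParams) -> np.ndarray:
    """Signed wave phase of position y at time t, in cycles in [-0.5, 0.5).

    Phase zero means the bar is centered on the position.  Positive phase
    means the position lies ahead of the nearest bar center in the
    direction of wave travel.  With the leading-edge convention of
    :class:`BarWaveParams` the nearest bar center is at
    ``c(t) = y0 + v*t + duty*P/2 (mod P)``.
    """
    y = np.asarray(y, dtype=float)
    center = p.offset_um + p.speed_um_per_h * (np.asarray(t, dtype=float) / 3600.0) + p.duty * p.period_um / 2.0
    frac = (y - center) / p.period_um
    phase = np.mod(frac + 0.5, 1.0) - 0.5
    sign = 1.0 if p.speed_um_per_h >= 0 else -1.0
    return sign * phase


# ---------------------------------------------------------------------------
# Voronoi tessellation and the per-cell vortex gradient


def voronoi_assign(
    centroids: list[tuple[int, float, float]],
    fov_shape: tuple[int, int],
) -> np.ndarray:
    """Assign every pixel the label of its nearest centroid.

    ``centroids`` is a list of ``(label, x, y)`` in pixel coordinates
    (pixel-center convention).  Distances are Euclidean; exact ties go
    to the smaller label.  Returns an integer label image covering the
    FOV exactly (no background pixels).
    """
    if not centroids:
        raise LoopscopeError("voronoi_assign requires at least one centroid")
    labels = np.asarray([c[0] for c in centroids], dtype=int)
    if len(set(labels.tolist())) != len(labels):
        raise LoopscopeError("centroid labels must be unique")
    order = np.argsort(labels)
    labels = labels[order]
    pts = np.asarray([(c[1], c[2]) for c in centroids], dtype=float)[order]

    rows, cols = fov_shape
    xx, yy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    query = np.column_stack([xx.ravel(), yy.ravel()])

    tree = cKDTree(pts)
    k = min(len(pts), 4)
    dist, idx = tree.query(query, k=k)
    if k == 1:
        return labels[idx].reshape(fov_shape)
    # resolve near-ties exactly: among neighbours at the minimal squared
    # distance (recomputed in float64), pick the smallest label
    cand = pts[idx]  # (npix, k, 2)
    d2 = ((cand - query[:, None, :]) ** 2).sum(axis=2)
    d2min = d2.min(axis=1, keepdims=True)
    tied = d2 <= d2min + 1e-9
    cand_labels = np.where(tied, labels[idx], np.iinfo(np.int64).max)
    out = cand_labels.min(axis=1)
    return out.reshape(fov_shape)


def _tangent(rx: float, ry: float, chirality: str) -> tuple[float, float]:
    norm = float(np.hypot(rx, ry))
    if norm == 0:
        return 0.0, 0.0
    tx, ty = ry / norm, -rx / norm  # ccw on screen in the row-down frame
    if chirality == "cw":
        tx, ty = -tx, -ty
    return tx, ty


def vortex_gradient_pattern(
    centroids: list[tuple[int, float, float]],
    regions: np.ndarray,
    p: VortexParams,
    valid_from: float = 0.0,
) -> StimulusPattern:
    """Per-cell linear light gradient along each cell's rotational tangent.

    Within each cell's Voronoi region the intensity ramps linearly along
    the tangent direction of the cell centroid about ``p.center``, so the
    brightest edge of the region faces the direction of intended motion.
    A cell exactly at the center receives uniform ``max_intensity / 2``;
    a degenerate (single-pixel or zero-extent) region receives uniform
    ``max_intensity``.
    """
    rows, cols = regions.shape
    cx, cy = p.center if p.center is not None else ((cols - 1) / 2.0, (rows - 1) / 2.0)
    if not (0 <= cx <= cols - 1 and 0 <= cy <= rows - 1):
        raise LoopscopeError("vortex center must lie inside the FOV")

    intensity = np.zeros_like(regions, dtype=float)
    objects = ndimage.find_objects(regions)
    by_label = {int(lab): (float(x), float(y)) for lab, x, y in centroids}
    if p.gradient_scope == "fov":
        fov_diag = float(np.hypot(rows - 1, cols - 1))

    for lab, sl in enumerate(objects, start=1):
        if sl is None or lab not in by_label:
            continue
        x0, y0 = by_label[lab]
        tx, ty = _tangent(x0 - cx, y0 - cy, p.chirality)
        sub = regions[sl] == lab
        if tx == 0.0 and ty == 0.0:  # centroid at the rotation center
            intensity[sl][sub] = p.max_intensity / 2.0
            continue
        rsl, csl = sl
        yy, xx = np.mgrid[rsl.start : rsl.stop, csl.start : csl.stop]
        proj = xx * tx + yy * ty
        vals = proj[sub]
        lo, hi = float(vals.min()), float(vals.max())
        if p.gradient_scope == "fov":
            ramp = 0.5 + (proj - (x0 * tx + y0 * ty)) / fov_diag
            patch = p.max_intensity * np.clip(ramp, 0.0, 1.0)
        elif hi - lo < 1e-12:  # degenerate region
            patch = np.full_like(proj, p.max_intensity, dtype=float)
        else:
            patch = p.max_intensity * (proj - lo) / (hi - lo)
        tgt = intensity[sl]
        tgt[sub] = patch[sub]
        intensity[sl] = tgt
    return StimulusPattern(intensity, valid_from=valid_from, provenance="vortex")


# ---------------------------------------------------------------------------
# bang-bang feedback and constant regions


def bang_bang_pattern(
    observations,
    mask: np.ndarray,
    p: BangBangParams,
    valid_from: float = 0.0,
) -> StimulusPattern:
    """Full-power illumination of every cell below its set point.

    ``observations`` is an iterable of objects with ``label`` and
    ``mean_intensity`` attributes (see ``segmentation.CellObservation``);
    intensities must have been measured on ``p.channel`` from the frame
    that produced ``mask``.
    """
    sp = np.asarray(p.setpoint, dtype=float)
    if sp.ndim == 2 and sp.shape != mask.shape:
        raise LoopscopeError(
            f"set-point image shape {sp.shape} does not match mask shape {mask.shape}"
        )
    intensity = np.zeros(mask.shape, dtype=float)
    for obs in observations:
        region = mask == obs.label
        if sp.ndim == 2:
            target = float(sp[region].mean()) if region.any() else np.inf
        else:
            target = float(sp)
        meas = obs.mean_intensity[p.channel] if isinstance(obs.mean_intensity, dict) else float(obs.mean_intensity)
        if meas < target - p.hysteresis_band:
            intensity[region] = 1.0
    return StimulusPattern(intensity, valid_from=valid_from, provenance="bangbang")


def constant_pattern(
    fov_shape: tuple[int, int],
    intensity: float = 1.0,
    region: tuple[int, int, int, int] | None = None,
    valid_from: float = 0.0,
) -> StimulusPattern:
    """Uniform illumination of a rectangle ``(x0, y0, x1, y1)`` (or the full FOV)."""
    img = np.zeros(fov_shape, dtype=float)
    if region is None:
        img[:] = intensity
    else:
        x0, y0, x1, y1 = region
        if not (0 <= x0 <= x1 <= fov_shape[1] and 0 <= y0 <= y1 <= fov_shape[0]):
            raise LoopscopeError("constant-pattern region outside the FOV")
        img[y0:y1, x0:x1] = intensity
    return StimulusPattern(img, valid_from=valid_from, provenance="constant")


# ---------------------------------------------------------------------------
# pattern manager


@dataclass
class PatternManager:
    """Stores per-position patterns and serves the one valid at time t.

    Time-parametric open-loop modules (bars, constant) may be registered
    as callables ``t -> StimulusPattern`` and are evaluated on demand;
    closed-loop modules submit concrete patterns.  Before any pattern is
    available an all-dark fallback of the position's FOV shape is
    returned, so stimulation cadence is never broken.
    """

    fov_shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    _stored: dict[str, list[StimulusPattern]] = field(default_factory=dict)
    _parametric: dict[str, Callable[[float], StimulusPattern]] = field(default_factory=dict)

    def register_parametric(self, position_name: str, fn: Callable[[float], StimulusPattern]) -> None:
        self._parametric[position_name] = fn

    def submit(self, pattern: StimulusPattern) -> None:
        self._stored.setdefault(pattern.position_name, []).append(pattern)

    def current(self, position_name: str, t: float) -> StimulusPattern:
        if position_name in self._parametric:
            pat = self._parametric[position_name](t)
            pat.position_name = position_name
            return pat
        candidates = [p for p in self._stored.get(position_name, []) if p.valid_from <= t]
        if candidates:
            return max(candidates, key=lambda p: p.valid_from)
        shape = self.fov_shapes.get(position_name)
        if shape is None:
            raise LoopscopeError(f"no FOV shape registered for position {position_name!r}")
        return StimulusPattern(
            np.zeros(shape), valid_from=0.0, position_name=position_name, provenance="fallback-dark"
        )
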