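"""Simulated microscope and biology.

This is the fixture generator that makes the whole closed loop testable
without hardware: agent cells that polarize and migrate along
illumination gradients (a surrogate for light-activated EGF-receptor
signaling), a reversible photochromic fluorophore (a surrogate for
TagRFP, which brightens ~4.5-fold under blue light and relaxes in the
dark), and a renderer producing nuclear-dye-like images.

Motility model
--------------
Each cell carries a polarity vector p that relaxes toward a drive
derived from the illumination field L:

    drive = unit(grad Ls) * min(alpha * |grad Ls|, 1) * gate
    dp/dt = (drive - p) / tau

where Ls is L smoothed over the cell's sensing length.  The adaptation
``gate`` suppresses response to slowly brightening fields: when the
local (Eulerian) intensity rise rate r is positive the gate is a Hill
function r^h / (r^h + r_half^h), while dimming or static fields always
elicit the full response.  This asymmetric, adaptive sensing is what
lets slowly traveling stimulus bars entrain sustained migration in the
wave direction while fast bars merely rock cells back and forth.  When
no gradient signal is present, polarity decays slowly (persistence time
``tau_dark_min``) — cells keep crawling for a while after the light has
moved on.  Velocity is ``v0 * p`` plus isotropic diffusion-like noise;
cells reflect (position and polarity) at the FOV boundary.

Photochromism is two-state first-order kinetics: under illumination the
fluorescence relaxes exponentially toward ``fold_change x baseline``
with time constant ``tau_on_s``; in the dark it relaxes back to the
baseline with ``tau_off_s``.  Fluorescence therefore never leaves
``[baseline, fold_change * baseline]``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .config import ExperimentPlan, StagePosition
from .errors import LoopscopeError
from .orchestrator import Frame, MicroscopeInterface
from .patterns import StimulusPattern

__all__ = [
    "MotilityParams",
    "PhotochromicParams",
    "CameraModel",
    "CellAgent",
    "Population",
    "init_population",
    "photochromic_update",
    "step_dynamics",
    "render_image",
    "IlluminationState",
    "SimulatedMicroscope",
    "simulated_scope",
]


@dataclass(frozen=True)
class MotilityParams:
    """Gradient-following motility with adaptive sensing.

    v0_um_per_h       maximum crawling speed (at |p| = 1)
    alpha_um          gradient sensitivity; drive saturates at |grad| = 1/alpha
    tau_p_min         polarity relaxation time under an active gradient signal
    tau_dark_min      polarity persistence time without a gradient signal
    noise_um_per_sqrt_h  diffusive positional noise amplitude
    sensing_sigma_um  spatial smoothing scale of the sensed field
    adapt_rate_half_per_h, adapt_hill
                      Hill gate on the local intensity rise rate (1/h)
    """

    v0_um_per_h: float = 10.0
    alpha_um: float = 60.0
    tau_p_min: float = 20.0
    tau_dark_min: float = 180.0
    noise_um_per_sqrt_h: float = 1.0
    sensing_sigma_um: float = 15.0
    adapt_rate_half_per_h: float = 0.6
    adapt_hill: float = 8.0
    adapt_memory_s: float = 1800.0
    drive_eps: float = 0.1
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.v0_um_per_h < 0:
            raise LoopscopeError("v0 must be non-negative")
        if self.tau_p_min <= 0 or self.tau_dark_min <= 0:
            raise LoopscopeError("polarity time constants must be positive")


@dataclass(frozen=True)
class PhotochromicParams:
    fold_change: float = 4.5
    tau_on_s: float = 30.0
    tau_off_s: float = 120.0

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise LoopscopeError("photochromic fold change must be >= 1")
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise LoopscopeError("photochromic time constants must be positive")


@dataclass(frozen=True)
class CameraModel:
    pixel_size_um: float = 1.0
    fov_shape: tuple[int, int] = (256, 256)
    background: float = 5.0
    read_noise_sigma: float = 2.0
    psf_sigma_um: float = 1.5
    nuclear_amplitude: float = 150.0
    fluor_amplitude: float = 150.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise LoopscopeError("pixel size and PSF sigma must be positive")

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.fov_shape[1] * self.pixel_size_um, self.fov_shape[0] * self.pixel_size_um)


@dataclass
class CellAgent:
    """One simulated cell (a view into a :class:`Population`)."""

    id: int
    position: tuple[float, float]  # (x, y) um
    polarity: tuple[float, float]
    baseline_fluorescence: float
    current_fluorescence: float
    radius: float


class Population:
    """Structure-of-arrays container for a field of simulated cells."""

    def __init__(self, xy: np.ndarray, baseline: np.ndarray, radius: np.ndarray, ids: np.ndarray | None = None):
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        n = len(self.xy)
        self.polarity = np.zeros((n, 2))
        self.baseline = np.asarray(baseline, dtype=float)
        self.fluor = self.baseline.copy()
        self.radius = np.asarray(radius, dtype=float)
        self.ids = np.arange(n) if ids is None else np.asarray(ids, dtype=int)

    def __len__(self) -> int:
        return len(self.xy)

    def __getitem__(self, i: int) -> CellAgent:
        return CellAgent(
            id=int(self.ids[i]),
            position=tuple(self.xy[i]),
            polarity=tuple(self.polarity[i]),
            baseline_fluorescence=float(self.baseline[i]),
            current_fluorescence=float(self.fluor[i]),
            radius=float(self.radius[i]),
        )

    def copy(self) -> "Population":
        out = Population(self.xy.copy(), self.baseline.copy(), self.radius.copy(), self.ids.copy())
        out.polarity = self.polarity.copy()
        out.fluor = self.fluor.copy()
        return out


def init_population(
    n: int,
    fov_um: tuple[float, float],
    heterogeneity_cv: float = 0.45,
    seed: int | np.random.Generator = 0,
    arrangement: str = "uniform",
    grid_jitter_um: float = 3.0,
    radius_um: float = 3.0,
) -> Population:
    """Create ``n`` cells in a ``(width, height)`` um FOV.

    Baseline fluorescences are lognormal with unit mean and the requested
    coefficient of variation.  ``arrangement="grid"`` places cells on a
    jittered grid (useful for well-separated segmentation fixtures);
    ``"uniform"`` scatters them uniformly.  Deterministic given the seed.
    """
    if n < 0:
        raise LoopscopeError("population size must be non-negative")
    if heterogeneity_cv < 0:
        raise LoopscopeError("heterogeneity CV must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = float(fov_um[0]), float(fov_um[1])
    if n == 0:
        return Population(np.empty((0, 2)), np.empty(0), np.empty(0))
    if arrangement == "grid":
        nx = max(1, int(np.ceil(np.sqrt(n * w / h))))
        ny = int(np.ceil(n / nx))
        gx = (np.arange(nx) + 0.5) * (w / nx)
        gy = (np.arange(ny) + 0.5) * (h / ny)
        xx, yy = np.meshgrid(gx, gy)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        keep = rng.permutation(len(pts))[:n]
        xy = pts[np.sort(keep)] + rng.uniform(-grid_jitter_um, grid_jitter_um, (n, 2))
        xy = np.clip(xy, [radius_um, radius_um], [w - radius_um, h - radius_um])
    elif arrangement == "uniform":
        xy = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))
    else:
        raise LoopscopeError(f"unknown arrangement {arrangement!r}")
    if heterogeneity_cv > 0:
        s2 = np.log1p(heterogeneity_cv**2)
        baseline = np.exp(rng.normal(-s2 / 2, np.sqrt(s2), n))
    else:
        baseline = np.ones(n)
    return Population(xy, baseline, np.full(n, radius_um))


def photochromic_update(
    fluor: np.ndarray | float,
    baseline: np.ndarray | float,
    illuminated: np.ndarray | bool,
    dt_s: float,
    p: PhotochromicParams,
) -> np.ndarray | float:
    """Exact first-order relaxation of fluorescence over ``dt_s`` seconds.

    Illuminated cells relax toward ``fold_change * baseline`` with
    ``tau_on_s``; dark cells relax toward ``baseline`` with ``tau_off_s``.
    Those two values are the fixed points, and the result always stays in
    ``[baseline, fold_change * baseline]``.
    """
    if dt_s < 0:
        raise LoopscopeError("dt must be non-negative")
    fluor = np.asarray(fluor, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    lit = np.asarray(illuminated, dtype=bool)
    target = np.where(lit, p.fold_change * baseline, baseline)
    tau = np.where(lit, p.tau_on_s, p.tau_off_s)
    out = target + (fluor - target) * np.exp(-dt_s / tau)
    return out if out.ndim else float(out)


class IlluminationState:
    """The projected field plus the derived quantities cells sense.

    Holds the raw intensity map, its smoothed version, the smoothed
    spatial gradient (1/um), and an adaptation memory field: an
    exponential moving average of the smoothed intensity with time
    constant ``adapt_memory_s``.  The local rise rate that feeds the
    adaptation gate is ``(smoothed - memory) / adapt_memory``; for a
    steadily advancing stimulus edge this equals the Eulerian rise rate
    even though projected patterns are pixel-rasterized and only change
    in discrete steps.
    """

    def __init__(
        self,
        fov_shape: tuple[int, int],
        pixel_size_um: float,
        sensing_sigma_um: float,
        adapt_memory_s: float = 1800.0,
    ):
        self.pixel_size_um = pixel_size_um
        self.sensing_sigma_px = sensing_sigma_um / pixel_size_um
        self.adapt_memory_s = adapt_memory_s
        self.raw = np.zeros(fov_shape)
        self.smoothed = np.zeros(fov_shape)
        self.memory: np.ndarray | None = None
        self.grad_x = np.zeros(fov_shape)
        self.grad_y = np.zeros(fov_shape)

    def set_field(self, intensity: np.ndarray, t_s: float | None = None) -> None:
        intensity = np.asarray(intensity, dtype=float)
        if intensity.shape != self.raw.shape:
            raise LoopscopeError(
                f"pattern shape {intensity.shape} does not match FOV {self.raw.shape}"
            )
        self.raw = intensity
        self.smoothed = ndimage.gaussian_filter(intensity, self.sensing_sigma_px, mode="nearest")
        if self.memory is None:  # start fully adapted to the first field
            self.memory = self.smoothed.copy()
        gy, gx = np.gradient(self.smoothed, self.pixel_size_um)
        self.grad_x, self.grad_y = gx, gy

    def tick(self, dt_s: float) -> None:
        """Relax the adaptation memory toward the current field."""
        if self.memory is not None:
            self.memory += (self.smoothed - self.memory) * (1.0 - np.exp(-dt_s / self.adapt_memory_s))

    def sample(self, xy_um: np.ndarray) -> dict[str, np.ndarray]:
        coords = np.stack([xy_um[:, 1] / self.pixel_size_um, xy_um[:, 0] / self.pixel_size_um])

        def interp(img, order=1):
            return ndimage.map_coordinates(img, coords, order=order, mode="nearest")

        memory = self.memory if self.memory is not None else self.smoothed
        rate = (self.smoothed - memory) * (3600.0 / self.adapt_memory_s)
        return {
            "raw": interp(self.raw),
            "grad_x": interp(self.grad_x),
            "grad_y": interp(self.grad_y),
            "rate_per_h": interp(rate),
        }


def step_dynamics(
    pop: Population,
    illumination: IlluminationState | np.ndarray,
    dt_s: float,
    m: MotilityParams,
    p: PhotochromicParams,
    rng: np.random.Generator,
    pixel_size_um: float = 1.0,
    fov_um: tuple[float, float] | None = None,
) -> Population:
    """Advance the population in place by ``dt_s`` seconds and return it.

    A bare array may be passed for a static illumination field (its rise
    rate is zero, so the adaptation gate is fully open).
    """
    if dt_s <= 0:
        raise LoopscopeError("dt must be positive")
    if isinstance(illumination, np.ndarray):
        state = IlluminationState(
            illumination.shape, pixel_size_um, m.sensing_sigma_um, m.adapt_memory_s
        )
        state.set_field(illumination, 0.0)
        illumination = state
    if fov_um is None:
        shape = illumination.raw.shape
        fov_um = (shape[1] * illumination.pixel_size_um, shape[0] * illumination.pixel_size_um)
    if len(pop) == 0:
        return pop

    dt_h = dt_s / 3600.0
    s = illumination.sample(pop.xy)
    grad = np.column_stack([s["grad_x"], s["grad_y"]])
    gnorm = np.linalg.norm(grad, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(gnorm[:, None] > 0, grad / np.maximum(gnorm[:, None], 1e-300), 0.0)
    magnitude = np.minimum(m.alpha_um * gnorm, 1.0)
    rise = np.maximum(s["rate_per_h"], 0.0)
    h = m.adapt_hill
    gate = np.where(
        rise > 0, rise**h / (rise**h + m.adapt_rate_half_per_h**h), 1.0
    )
    drive = unit * (magnitude * gate)[:, None]

    # response threshold: gradient signals below drive_eps are not sensed at
    # all — polarity then simply persists (slow decay toward zero)
    active = np.linalg.norm(drive, axis=1) > m.drive_eps
    drive[~active] = 0.0
    tau_h = np.where(active, m.tau_p_min, m.tau_dark_min) / 60.0
    relax = 1.0 - np.exp(-dt_h / tau_h)
    pop.polarity += (drive - pop.polarity) * relax[:, None]
    pnorm = np.linalg.norm(pop.polarity, axis=1)
    over = pnorm > 1.0
    if np.any(over):
        pop.polarity[over] /= pnorm[over, None]

    step = m.v0_um_per_h * pop.polarity * dt_h
    step += m.noise_um_per_sqrt_h * np.sqrt(dt_h) * rng.standard_normal(pop.xy.shape)
    pop.xy += step

    if m.boundary == "periodic":  # the FOV as a window into a larger tissue
        for axis, size in enumerate(fov_um):
            pop.xy[:, axis] %= size
    else:  # reflect: position folds back, polarity flips
        for axis, size in enumerate(fov_um):
            lo = pop.xy[:, axis] < 0
            hi = pop.xy[:, axis] > size
            pop.xy[lo, axis] = -pop.xy[lo, axis]
            pop.xy[hi, axis] = 2 * size - pop.xy[hi, axis]
            pop.polarity[lo | hi, axis] *= -1
            np.clip(pop.xy[:, axis], 0, size, out=pop.xy[:, axis])

    lit = s["raw"] > 1e-9
    # re-sample at updated positions would couple motion and switching within
    # one step; sampling at the pre-step position keeps the update explicit
    pop.fluor = photochromic_update(pop.fluor, pop.baseline, lit, dt_s, p)
    illumination.tick(dt_s)
    return pop


def render_image(
    pop: Population,
    channel: str,
    cam: CameraModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a camera frame: Gaussian spots + background + read noise.

    ``nuclear`` uses a constant per-cell amplitude (a dye image for
    segmentation); ``fluor`` scales each spot by the cell's current
    photochromic fluorescence.  Spot width is the PSF and cell radius
    added in quadrature.  Intensities are clipped at zero.
    """
    if channel not in ("nuclear", "fluor"):
        raise LoopscopeError(f"unknown channel {channel!r}")
    img = np.zeros(cam.fov_shape)
    rows, cols = cam.fov_shape
    for i in range(len(pop)):
        sigma_px = float(np.hypot(cam.psf_sigma_um, pop.radius[i])) / cam.pixel_size_um
        amp = cam.nuclear_amplitude if channel == "nuclear" else cam.fluor_amplitude * pop.fluor[i]
        cx = pop.xy[i, 0] / cam.pixel_size_um
        cy = pop.xy[i, 1] / cam.pixel_size_um
        halfw = int(np.ceil(4 * sigma_px))
        r0, r1 = max(0, int(cy) - halfw), min(rows, int(cy) + halfw + 1)
        c0, c1 = max(0, int(cx) - halfw), min(cols, int(cx) + halfw + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
    img += cam.background
    if rng is not None and cam.read_noise_sigma > 0:
        img += cam.read_noise_sigma * rng.standard_normal(img.shape)
    return np.clip(img, 0, None)


@dataclass
class _PositionSim:
    population: Population
    cam: CameraModel
    motility: MotilityParams
    photochromic: PhotochromicParams
    illum: IlluminationState
    rng: np.random.Generator
    t_s: float = 0.0
    frame_index: int = 0


class SimulatedMicroscope(MicroscopeInterface):
    """Virtual microscope: one independent cell field per stage position.

    ``project`` replaces the position's illumination field, which then
    drives the cell dynamics until the next projection; ``snap`` renders
    the current state; ``advance_to`` integrates all positions' dynamics
    up to the requested experiment time in substeps of at most
    ``max_substep_s``.  Each position draws from its own seed stream
    (derived from the master seed and the position name), so adding or
    removing positions never perturbs the others.
    """

    def __init__(self, seed: int = 0, max_substep_s: float = 60.0):
        self.seed = seed
        self.max_substep_s = max_substep_s
        self._positions: dict[str, _PositionSim] = {}
        self._current: str | None = None

    def _rng_for(self, name: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        )

    def add_position(
        self,
        name: str,
        population: Population,
        cam: CameraModel,
        motility: MotilityParams | None = None,
        photochromic: PhotochromicParams | None = None,
    ) -> None:
        motility = motility or MotilityParams()
        self._positions[name] = _PositionSim(
            population=population,
            cam=cam,
            motility=motility,
            photochromic=photochromic or PhotochromicParams(),
            illum=IlluminationState(
                cam.fov_shape, cam.pixel_size_um, motility.sensing_sigma_um, motility.adapt_memory_s
            ),
            rng=self._rng_for(name),
        )
        if self._current is None:
            self._current = name

    # -- MicroscopeInterface ------------------------------------------------

    def move_to(self, position: StagePosition) -> None:
        if position.name not in self._positions:
            raise LoopscopeError(f"unknown simulated position {position.name!r}")
        self._current = position.name

    def snap(self, channel: str, exposure_ms: float = 50.0) -> Frame:
        sim = self._positions[self._require_current()]
        pixels = render_image(sim.population, channel, sim.cam, sim.rng)
        frame = Frame(pixels=pixels, position_name=self._current, channel=channel, time=sim.t_s,
                      frame_index=sim.frame_index)
        sim.frame_index += 1
        return frame

    def project(self, pattern: StimulusPattern, duration_ms: float = 500.0) -> None:
        name = pattern.position_name or self._require_current()
        sim = self._positions[name]
        sim.illum.set_field(pattern.intensity, sim.t_s)

    def advance_to(self, t_s: float) -> None:
        for sim in self._positions.values():
            while sim.t_s < t_s - 1e-9:
                dt = min(self.max_substep_s, t_s - sim.t_s)
                step_dynamics(
                    sim.population, sim.illum, dt, sim.motility, sim.photochromic, sim.rng
                )
                sim.t_s += dt

    def _require_current(self) -> str:
        if self._current is None:
            raise LoopscopeError("no simulated positions configured")
        return self._current

    def population(self, name: str) -> Population:
        return self._positions[name].population

    def time(self, name: str) -> float:
        return self._positions[name].t_s


def simulated_scope(plan: ExperimentPlan, seed: int | None = None) -> SimulatedMicroscope:
    """Build a simulator for a plan from each position's ``[simulate]`` table.

    Recognized keys (all optional): n_cells, cv, arrangement, v0, tau_p_min,
    alpha, k_fold, tau_on_s, tau_off_s, psf_sigma_um, noise, background.
    """
    scope = SimulatedMicroscope(seed=plan.schedule.seed if seed is None else seed)
    for stage, cfg in plan.positions:
        sim = cfg.simulate
        cam = CameraModel(
            pixel_size_um=cfg.pixel_size_um,
            fov_shape=cfg.fov_shape,
            psf_sigma_um=float(sim.get("psf_sigma_um", 1.5)),
            background=float(sim.get("background", 5.0)),
            read_noise_sigma=float(sim.get("noise", 2.0)),
        )
        defaults = MotilityParams()
        motility = MotilityParams(
            v0_um_per_h=float(sim.get("v0", defaults.v0_um_per_h)),
            tau_p_min=float(sim.get("tau_p_min", defaults.tau_p_min)),
            alpha_um=float(sim.get("alpha", defaults.alpha_um)),
            sensing_sigma_um=float(sim.get("sensing_sigma_um", defaults.sensing_sigma_um)),
            noise_um_per_sqrt_h=float(sim.get("motility_noise", defaults.noise_um_per_sqrt_h)),
            boundary=str(sim.get("boundary", defaults.boundary)),
        )
        photo = PhotochromicParams(
            fold_change=float(sim.get("k_fold", 4.5)),
            tau_on_s=float(sim.get("tau_on_s", 30.0)),
            tau_off_s=float(sim.get("tau_off_s", 120.0)),
        )
        pop = init_population(
            n=int(sim.get("n_cells", 200)),
            fov_um=cam.fov_um,
            heterogeneity_cv=float(sim.get("cv", 0.45)),
            seed=scope._rng_for(stage.name + "/init"),
            arrangement=sim.get("arrangement", "grid"),
        )
        scope.add_position(stage.name, pop, cam, motility, photo)
    return scope
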