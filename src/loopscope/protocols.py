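"""Reference simulation protocols.

Self-contained, seeded experiment recipes that exercise the whole
engine and compute the headline quantities of each experiment class:
traveling-wave entrainment sweeps, per-cell vortex stimulation,
bang-bang feedback control of a heterogeneous photochromic population,
and segmentation-recovery benchmarks.  The acceptance script and the
test suite both run these; they are also convenient starting points for
configuring real experiments.

Problem sizes here are scaled-down study conditions (hundreds of cells,
hours of simulated time) chosen so a full protocol runs in seconds to a
couple of minutes on one CPU; the scientific parameters (cadences,
photochromic kinetics, motility defaults, set points) are the package
defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from . import analysis
from .config import (
    ExperimentPlan,
    PositionConfig,
    ScheduleConfig,
    StagePosition,
    build_experiment_plan,
)
from .orchestrator import run_loop, validate_record
from .patterns import BarWaveParams, bar_wave_pattern
from .registry import PatternModule, default_registry
from .segmentation import measure_cells, segment_nuclei_threshold
from .simulate import (
    CameraModel,
    MotilityParams,
    PhotochromicParams,
    SimulatedMicroscope,
    init_population,
    photochromic_update,
    render_image,
)

__all__ = [
    "wave_speed_sweep",
    "feedback_control_run",
    "setpoint_image_run",
    "vortex_run",
    "multipoint_contract_run",
    "segmentation_recovery",
    "photochromic_checks",
]


# ---------------------------------------------------------------------------
# traveling waves


def wave_speed_sweep(
    seed: int,
    speeds_um_per_h: tuple[float, ...] = (8.0, 12.0, 25.0, 50.0),
    n_cells: int = 300,
    hours: float = 16.0,
    fov_um: tuple[float, float] = (96.0, 768.0),
    period_um: float = 160.0,
    duty: float = 0.5,
    stim_interval_s: float = 60.0,
    imaging_interval_s: float = 300.0,
    n_bins: int = 20,
    warmup_h: float = 4.0,
) -> dict:
    """Sweep bar-wave speeds and quantify tissue entrainment.

    For each wave speed, cells are simulated under a bar pattern
    re-projected at the stimulation cadence; positions are read out at
    the imaging cadence, linked into tracks, differentiated, and binned
    by wave phase.  Returns per-speed mean along-wave velocity and the
    phase-bin table (warm-up excluded).

    The default spatial period keeps the dark gap between bars wider
    than twice the cells' sensing range, so each cell interacts with
    one bar at a time; with narrower gaps, cells midway between bars
    sense both edges at once and the phase structure blurs.  The warm-up
    discards the stimulus-onset transient: cells respond to the freshly
    appearing pattern before their adaptation state has built up, and
    that initial polarization takes a few persistence times to clear.
    """
    results: dict = {"speeds": list(speeds_um_per_h), "mean_velocity": {}, "phase_bins": {}}
    for speed in speeds_um_per_h:
        p = BarWaveParams(period_um=period_um, speed_um_per_h=speed, duty=duty)
        cam = CameraModel(pixel_size_um=1.0, fov_shape=(int(fov_um[1]), int(fov_um[0])))
        scope = SimulatedMicroscope(seed=int(seed) * 1000 + int(speed), max_substep_s=stim_interval_s)
        pop = init_population(
            n_cells, cam.fov_um, heterogeneity_cv=0.45, seed=scope._rng_for("wave/init"),
            arrangement="uniform",
        )
        # periodic boundaries: the FOV is a window into a much larger tissue,
        # so entrained cells do not pile up against a wall during long drifts
        scope.add_position("wave", pop, cam, motility=MotilityParams(boundary="periodic"))
        detections = []
        t, t_end = 0.0, hours * 3600.0
        next_img = 0.0
        while t <= t_end + 1e-9:
            pat = bar_wave_pattern(p, t, cam.pixel_size_um, cam.fov_shape)
            pat.position_name = "wave"
            scope.project(pat, 500.0)
            if t >= next_img - 1e-9:
                detections.append(
                    pd.DataFrame(
                        {
                            "time_s": t,
                            "x_um": pop.xy[:, 0].copy(),
                            "y_um": pop.xy[:, 1].copy(),
                            "true_id": pop.ids.copy(),
                        }
                    )
                )
                next_img += imaging_interval_s
            t += stim_interval_s
            scope.advance_to(min(t, t_end) if t <= t_end else t_end)
        tracks = analysis.link_tracks(detections, max_link_distance_um=10.0)
        samples = analysis.frame_velocities(tracks)
        samples = samples[samples["time_s"] >= warmup_h * 3600.0]
        sign = 1.0 if speed >= 0 else -1.0
        results["mean_velocity"][speed] = float((sign * samples["vy"]).mean())
        results["phase_bins"][speed] = analysis.velocity_vs_phase(samples, p, n_bins=n_bins)
    return results


# ---------------------------------------------------------------------------
# bang-bang feedback control


def _grid_plan(
    name: str,
    pattern: dict,
    n_cells: int,
    fov_px: int,
    length_s: float,
    interval_s: float,
    seed: int,
    cv: float = 0.45,
) -> ExperimentPlan:
    sched = ScheduleConfig(
        experiment_length_s=length_s,
        imaging_interval_s=interval_s,
        stimulation_interval_s=interval_s,
        seed=seed,
    )
    cfg = PositionConfig(
        position_name=name,
        pattern=pattern,
        segmentation={"module": "threshold", "channel": "nuclear", "smooth_sigma": 2.0, "min_area": 9},
        channels=[{"name": "nuclear", "exposure_ms": 50.0}, {"name": "fluor", "exposure_ms": 50.0}],
        pixel_size_um=1.0,
        fov_shape=(fov_px, fov_px),
        simulate={"n_cells": n_cells, "cv": cv},
    )
    return build_experiment_plan(sched, [StagePosition(name, 0.0, 0.0)], [cfg])


def _fresh_scope(plan: ExperimentPlan, seed: int) -> SimulatedMicroscope:
    from .simulate import simulated_scope

    return simulated_scope(plan, seed=seed)


def _measured_baseline(scope: SimulatedMicroscope, name: str, background: float) -> pd.DataFrame:
    """Calibration pre-scan: measure per-cell background-corrected intensity at t=0."""
    pop = scope.population(name)
    sim = scope._positions[name]
    nuclear = render_image(pop, "nuclear", sim.cam, sim.rng)
    fluor = render_image(pop, "fluor", sim.cam, sim.rng)
    mask = segment_nuclei_threshold(nuclear, smooth_sigma=2.0, min_area=9)
    obs = measure_cells({"nuclear": nuclear, "fluor": fluor}, mask)
    return pd.DataFrame(
        {
            "label": [o.label for o in obs],
            "x_px": [o.centroid[0] for o in obs],
            "y_px": [o.centroid[1] for o in obs],
            "fluor": [o.mean_intensity["fluor"] - background for o in obs],
        }
    )


def _match_to_truth(obs_xy: np.ndarray, truth_xy: np.ndarray) -> np.ndarray:
    """Index of the nearest true cell for each observation."""
    return cKDTree(truth_xy).query(obs_xy)[1]


def feedback_control_run(
    seed: int,
    n_cells: int = 1000,
    n_steps: int = 40,
    interval_s: float = 30.0,
    setpoint_factor: float = 2.5,
    cv: float = 0.45,
    fov_px: int = 640,
) -> dict:
    """Bang-bang control of a heterogeneous photochromic population.

    Runs the full closed loop (render -> segment -> measure -> bang-bang
    pattern -> stimulate) at the imaging/control cadence.  The scalar set
    point is ``setpoint_factor`` times the population-mean baseline
    intensity measured in a calibration pre-scan.  Returns the CV time
    course of background-corrected per-cell intensities, the fold
    reduction CV(0)/CV(final), and the per-cell cumulative light dose
    against true baseline fluorescence (with Spearman correlation).
    """
    background = 5.0
    calib_plan = _grid_plan("ctrl", {"module": "bangbang", "setpoint": 1.0, "channel": "fluor"},
                            n_cells, fov_px, n_steps * interval_s, interval_s, seed, cv)
    scope0 = _fresh_scope(calib_plan, seed)
    calib = _measured_baseline(scope0, "ctrl", background)
    setpoint_meas = setpoint_factor * float(calib["fluor"].mean()) + background

    plan = _grid_plan(
        "ctrl",
        {"module": "bangbang", "setpoint": setpoint_meas, "channel": "fluor"},
        n_cells, fov_px, n_steps * interval_s, interval_s, seed, cv,
    )
    scope = _fresh_scope(plan, seed)
    truth_xy = scope.population("ctrl").xy.copy()
    truth_baseline = scope.population("ctrl").baseline.copy()
    record = run_loop(plan, scope)

    cells = record.cells_table()
    cells["corrected"] = cells["mean_intensity"] - background
    cv_rows = []
    for t, frame in cells.groupby("time_s"):
        vals = frame["corrected"].to_numpy(float)
        cv_rows.append({"time_s": t, "cv": vals.std(ddof=1) / vals.mean(), "n": len(vals)})
    cv_tc = pd.DataFrame(cv_rows).sort_values("time_s").reset_index(drop=True)

    dose = np.zeros(len(truth_xy))
    for t, frame in cells.groupby("time_s"):
        idx = _match_to_truth(frame[["x_px", "y_px"]].to_numpy(float), truth_xy)
        np.add.at(dose, idx, frame["stimulated"].to_numpy(float))
    rho = stats.spearmanr(dose, truth_baseline).statistic

    return {
        "plan": plan,
        "record": record,
        "cv_timecourse": cv_tc,
        "cv0": float(cv_tc["cv"].iloc[0]),
        "cv_final": float(cv_tc["cv"].iloc[-1]),
        "fold_reduction": float(cv_tc["cv"].iloc[0] / cv_tc["cv"].iloc[-1]),
        "dose": dose,
        "baseline": truth_baseline,
        "spearman_dose_baseline": float(rho),
        "setpoint": setpoint_meas,
    }


def setpoint_image_run(
    seed: int,
    n_cells: int = 600,
    n_steps: int = 40,
    interval_s: float = 30.0,
    levels: tuple[float, float] = (1.5, 2.25),
    fov_px: int = 512,
) -> dict:
    """Drive a cell field toward a two-level grayscale set-point image.

    The set-point image splits the FOV into a left half at
    ``levels[0]`` and a right half at ``levels[1]`` times the measured
    population-mean baseline intensity.  Levels sit well inside the
    actuator's authority (the sustained-light steady state of a typical
    cell) so the target is achievable for nearly all baselines.
    Reports, per cell, whether it has come within 10% of its local set
    point at any control step ("reached"), and the fraction within the
    band at the final step.
    """
    background = 5.0
    calib_plan = _grid_plan("spi", {"module": "bangbang", "setpoint": 1.0, "channel": "fluor"},
                            n_cells, fov_px, n_steps * interval_s, interval_s, seed)
    scope0 = _fresh_scope(calib_plan, seed)
    calib = _measured_baseline(scope0, "spi", background)
    base_meas = float(calib["fluor"].mean())
    sp_img = np.full((fov_px, fov_px), levels[0] * base_meas + background)
    sp_img[:, fov_px // 2 :] = levels[1] * base_meas + background

    plan = _grid_plan(
        "spi",
        {"module": "bangbang", "setpoint": sp_img, "channel": "fluor"},
        n_cells, fov_px, n_steps * interval_s, interval_s, seed,
    )
    scope = _fresh_scope(plan, seed)
    truth_xy = scope.population("spi").xy.copy()
    record = run_loop(plan, scope)

    cells = record.cells_table()
    cells["corrected"] = cells["mean_intensity"] - background
    cells["local_sp"] = np.where(
        cells["x_px"].to_numpy(float) < fov_px / 2, levels[0] * base_meas, levels[1] * base_meas
    )
    cells["in_band"] = (
        np.abs(cells["corrected"] - cells["local_sp"]) / cells["local_sp"] <= 0.10
    )
    reached = np.zeros(len(truth_xy), dtype=bool)
    final_t = cells["time_s"].max()
    final_in_band = float(cells.loc[cells["time_s"] == final_t, "in_band"].mean())
    for t, frame in cells.groupby("time_s"):
        idx = _match_to_truth(frame[["x_px", "y_px"]].to_numpy(float), truth_xy)
        reached[idx[frame["in_band"].to_numpy(bool)]] = True
    return {
        "record": record,
        "plan": plan,
        "cells": cells,
        "frac_reached": float(reached.mean()),
        "frac_final_in_band": final_in_band,
    }


# ---------------------------------------------------------------------------
# vortex


def vortex_run(
    seed: int,
    n_cells: int = 200,
    hours: float = 2.0,
    fov_px: int = 360,
    imaging_interval_s: float = 300.0,
    stim_interval_s: float = 60.0,
) -> dict:
    """Closed-loop per-cell counter-clockwise gradient stimulation.

    Runs segmentation -> Voronoi -> per-cell tangential gradient ->
    stimulation, then quantifies the resulting flow in polar
    coordinates about the FOV center.
    """
    sched = ScheduleConfig(
        experiment_length_s=hours * 3600.0,
        imaging_interval_s=imaging_interval_s,
        stimulation_interval_s=stim_interval_s,
        seed=seed,
    )
    cfg = PositionConfig(
        position_name="vortex",
        pattern={"module": "vortex", "chirality": "ccw", "max_intensity": 1.0},
        segmentation={"module": "threshold", "channel": "nuclear", "smooth_sigma": 2.0, "min_area": 9},
        channels=[{"name": "nuclear", "exposure_ms": 50.0}],
        pixel_size_um=1.0,
        fov_shape=(fov_px, fov_px),
        # the vortex stimulus is subcellular: cells must sense the gradient
        # across their own body, so the sensing scale is the cell radius
        simulate={"n_cells": n_cells, "sensing_sigma_um": 4.0},
    )
    plan = build_experiment_plan(sched, [StagePosition("vortex", 0.0, 0.0)], [cfg])
    scope = _fresh_scope(plan, seed)
    record = run_loop(plan, scope)

    cells = record.cells_table()
    cells["x_um"] = cells["x_px"]
    cells["y_um"] = cells["y_px"]
    detections = [g for _, g in cells.groupby("time_s")]
    tracks = analysis.link_tracks(detections, max_link_distance_um=10.0)
    samples = analysis.frame_velocities(tracks)
    center = (fov_px / 2.0, fov_px / 2.0)
    samples = analysis.polar_decompose(samples, center)
    profile = analysis.radial_profile(samples, center, n_rings=6, r_max_um=fov_px / 2.0)
    return {
        "record": record,
        "plan": plan,
        "samples": samples,
        "profile": profile,
        "mean_v_tangential": float(samples["v_tangential"].mean()),
        "mean_v_radial": float(samples["v_radial"].mean()),
    }


# ---------------------------------------------------------------------------
# multipoint scheduling, fault isolation


class _BrokenModule(PatternModule):
    """A closed-loop pattern module that always fails (fault injection)."""

    name = "broken"
    needs_masks = True

    def __init__(self, params, pixel_size_um, fov_shape):
        pass

    def compute(self, t, mask, observations):
        raise RuntimeError("injected pattern-module failure")


def multipoint_contract_run(
    seed: int,
    n_positions: int = 15,
    length_s: float = 600.0,
    imaging_interval_s: float = 120.0,
    stim_interval_s: float = 60.0,
    fov_px: int = 160,
    n_cells: int = 40,
    inject_failures: bool = True,
) -> dict:
    """A multipoint run mixing module types, with injected failures.

    Positions cycle through bang-bang, vortex, bars, and constant
    modules; with ``inject_failures`` the last position uses an
    always-raising closed-loop module.  Validates the closed-loop
    ordering contract by replay, and checks per-position isolation by
    re-running without the failing position and comparing the others'
    records.
    """
    registry = default_registry()
    registry.register_pattern(_BrokenModule)

    def build(names: list[str]) -> ExperimentPlan:
        sched = ScheduleConfig(
            experiment_length_s=length_s,
            imaging_interval_s=imaging_interval_s,
            stimulation_interval_s=stim_interval_s,
            seed=seed,
        )
        positions, configs = [], []
        kinds = [
            {"module": "bangbang", "setpoint": 100.0, "channel": "fluor"},
            {"module": "vortex", "chirality": "ccw"},
            {"module": "bars", "period_um": 80.0, "speed_um_per_h": 12.0, "duty": 0.5},
            {"module": "constant", "intensity": 1.0},
        ]
        for i, name in enumerate(names):
            pattern = dict(kinds[i % len(kinds)])
            if inject_failures and name == f"P{n_positions - 1:02d}":
                pattern = {"module": "broken"}
            needs_fluor = pattern["module"] in ("bangbang",)
            channels = [{"name": "nuclear", "exposure_ms": 50.0}]
            if needs_fluor:
                channels.append({"name": "fluor", "exposure_ms": 50.0})
            closed_loop = registry.pattern_needs_masks(pattern["module"])
            configs.append(
                PositionConfig(
                    position_name=name,
                    pattern=pattern,
                    segmentation=(
                        {"module": "threshold", "channel": "nuclear", "smooth_sigma": 2.0, "min_area": 9}
                        if closed_loop
                        else None
                    ),
                    channels=channels,
                    pixel_size_um=1.0,
                    fov_shape=(fov_px, fov_px),
                    simulate={"n_cells": n_cells},
                )
            )
            positions.append(StagePosition(name, x=1000.0 * i, y=0.0))
        return build_experiment_plan(sched, positions, configs, registry)

    names = [f"P{i:02d}" for i in range(n_positions)]
    plan = build(names)
    record = run_loop(plan, _fresh_scope(plan, seed), registry=registry)
    violations = validate_record(record, plan, registry)

    isolation_ok = True
    if inject_failures:
        kept = names[:-1]
        plan2 = build(kept)
        record2 = run_loop(plan2, _fresh_scope(plan2, seed), registry=registry)
        t1, t2 = record.cells_table(), record2.cells_table()
        for name in kept:
            a = t1[t1["position"] == name].reset_index(drop=True)
            b = t2[t2["position"] == name].reset_index(drop=True)
            if not a.equals(b):
                isolation_ok = False
        e1, e2 = record.events_table(), record2.events_table()
        for name in kept:
            a = e1[e1["position"] == name].reset_index(drop=True)
            b = e2[e2["position"] == name].reset_index(drop=True)
            if not a.equals(b):
                isolation_ok = False
    return {
        "plan": plan,
        "record": record,
        "violations": violations,
        "isolation_ok": isolation_ok,
        "n_pattern_errors": sum(record.pattern_errors.values()),
    }


# ---------------------------------------------------------------------------
# segmentation recovery and photochromic checks


def segmentation_recovery(
    seed: int, n_fixtures: int = 100, n_cells: int = 30, fov_px: int = 256
) -> dict:
    """Detection and localization accuracy on well-separated fixtures.

    Renders ``n_fixtures`` random fields of nuclei on a jittered grid
    (spacing well above 6x the effective spot sigma, SNR >= 10),
    segments them, and scores exact-count recovery and worst-case
    centroid error per fixture.
    """
    rng = np.random.default_rng(seed)
    cam = CameraModel(pixel_size_um=1.0, fov_shape=(fov_px, fov_px))
    counts_ok = 0
    max_err = []
    for _ in range(n_fixtures):
        pop = init_population(n_cells, cam.fov_um, heterogeneity_cv=0.45, seed=rng, arrangement="grid")
        img = render_image(pop, "nuclear", cam, rng)
        mask = segment_nuclei_threshold(img, smooth_sigma=2.0, min_area=9)
        obs = measure_cells(img, mask)
        if mask.n_cells == n_cells:
            counts_ok += 1
            obs_xy = np.array([o.centroid for o in obs])
            d, _ = cKDTree(pop.xy / cam.pixel_size_um).query(obs_xy)
            max_err.append(float(d.max()))
    return {
        "count_accuracy": counts_ok / n_fixtures,
        "centroid_max_err_px": float(np.max(max_err)) if max_err else np.inf,
        "centroid_mean_err_px": float(np.mean(max_err)) if max_err else np.inf,
    }


def photochromic_checks(seed: int = 0) -> dict:
    """Closed-form kinetics vs fine-step numerical integration, and reversibility."""
    p = PhotochromicParams()
    rng = np.random.default_rng(seed)
    rel_errors = []
    for _ in range(50):
        baseline = float(rng.uniform(0.5, 2.0))
        F0 = float(rng.uniform(baseline, p.fold_change * baseline))
        lit = bool(rng.integers(2))
        dt = float(rng.uniform(1.0, 600.0))
        closed = photochromic_update(F0, baseline, lit, dt, p)
        # independent fixed-step RK4 integration of the same ODE
        target = p.fold_change * baseline if lit else baseline
        tau = p.tau_on_s if lit else p.tau_off_s
        n = 2000
        h = dt / n
        F = F0
        for _ in range(n):
            k1 = (target - F) / tau
            k2 = (target - (F + h / 2 * k1)) / tau
            k3 = (target - (F + h / 2 * k2)) / tau
            k4 = (target - (F + h * k3)) / tau
            F += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        rel_errors.append(abs(closed - F) / abs(closed))
    # steady-state fold under sustained light, then reversibility in the dark
    F = 1.0
    for _ in range(200):
        F = photochromic_update(F, 1.0, True, 10.0, p)
    fold = float(F)
    for _ in range(int(8 * p.tau_off_s)):  # >= 5 tau_off; 1% needs ~6
        F = photochromic_update(F, 1.0, False, 1.0, p)
    residual = abs(F - 1.0)
    return {
        "max_rel_error_vs_numeric": float(np.max(rel_errors)),
        "steady_state_fold": fold,
        "reversibility_residual": float(residual),
    }
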