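"""Post-hoc quantification of closed-loop runs.

Track linking (greedy mutual nearest neighbour), velocity estimation,
wave-phase binning of velocities, polar decomposition and radial
profiles for rotational flows, and coefficient-of-variation time
courses for feedback-control experiments.  All tabular interfaces are
tidy pandas DataFrames so results can be written straight to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patterns import BarWaveParams, wave_phase

__all__ = [
    "Track",
    "link_tracks",
    "frame_velocities",
    "velocity_vs_phase",
    "phase_aligned_traces",
    "polar_decompose",
    "radial_profile",
    "intensity_cv_timecourse",
]


@dataclass
class Track:
    """One linked cell trajectory: ``samples`` has time_s, x_um, y_um + extras."""

    track_id: int
    samples: pd.DataFrame

    def __len__(self) -> int:
        return len(self.samples)


def link_tracks(detections: list[pd.DataFrame], max_link_distance_um: float) -> list[Track]:
    """Link per-frame detections into tracks.

    ``detections`` is a time-ordered list of DataFrames, one per frame,
    each with at least ``time_s``, ``x_um`` and ``y_um`` columns (extra
    columns are carried along).  Between consecutive frames, mutual
    nearest neighbours within ``max_link_distance_um`` are linked in
    ascending-distance order; no detection is used twice, and unmatched
    detections start new tracks.
    """
    tracks: list[list[pd.Series]] = []
    open_by_det: dict[int, int] = {}  # index in current frame -> track index
    for fi, df in enumerate(detections):
        df = df.reset_index(drop=True)
        if fi == 0 or not open_by_det:
            links: dict[int, int] = {}
        else:
            prev = detections[fi - 1].reset_index(drop=True)
            links = _mutual_links(
                prev[["x_um", "y_um"]].to_numpy(float),
                df[["x_um", "y_um"]].to_numpy(float),
                max_link_distance_um,
            )
        new_open: dict[int, int] = {}
        for j in range(len(df)):
            i = links.get(j)
            if i is not None and i in open_by_det:
                ti = open_by_det[i]
            else:
                tracks.append([])
                ti = len(tracks) - 1
            tracks[ti].append(df.iloc[j])
            new_open[j] = ti
        open_by_det = new_open
    return [
        Track(track_id=ti, samples=pd.DataFrame(rows).reset_index(drop=True))
        for ti, rows in enumerate(tracks)
        if rows
    ]


def _mutual_links(a: np.ndarray, b: np.ndarray, max_dist: float) -> dict[int, int]:
    """Map index-in-b -> index-in-a for mutual nearest neighbours within max_dist."""
    if len(a) == 0 or len(b) == 0:
        return {}
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tb.query(a)  # a_i's nearest b
    _, nn_ba = ta.query(b)  # b_j's nearest a
    pairs = [
        (d_ab[i], i, int(nn_ab[i]))
        for i in range(len(a))
        if d_ab[i] <= max_dist and nn_ba[nn_ab[i]] == i
    ]
    pairs.sort()
    links: dict[int, int] = {}
    used_a: set[int] = set()
    for _d, i, j in pairs:
        if i not in used_a and j not in links:
            links[j] = i
            used_a.add(i)
    return links


def frame_velocities(tracks: list[Track], smoothing_window: int = 1) -> pd.DataFrame:
    """Per-sample velocities (um/h) by finite differences.

    Central differences at interior samples, one-sided at track ends;
    an optional boxcar of ``smoothing_window`` frames smooths the
    velocity series.  Tracks with fewer than two samples are skipped.
    Returns a tidy frame with track_id, time_s, x_um, y_um, vx, vy.
    """
    rows = []
    for tr in tracks:
        s = tr.samples
        if len(s) < 2:
            continue
        t = s["time_s"].to_numpy(float)
        vx = np.gradient(s["x_um"].to_numpy(float), t) * 3600.0
        vy = np.gradient(s["y_um"].to_numpy(float), t) * 3600.0
        if smoothing_window > 1:
            kernel = np.ones(smoothing_window) / smoothing_window
            vx = np.convolve(vx, kernel, mode="same")
            vy = np.convolve(vy, kernel, mode="same")
        out = s.copy()
        out["track_id"] = tr.track_id
        out["vx"] = vx
        out["vy"] = vy
        rows.append(out)
    if not rows:
        return pd.DataFrame(columns=["track_id", "time_s", "x_um", "y_um", "vx", "vy"])
    return pd.concat(rows, ignore_index=True)


def velocity_vs_phase(
    samples: pd.DataFrame,
    p: BarWaveParams,
    n_bins: int = 20,
    replicate_col: str | None = None,
) -> pd.DataFrame:
    """Bin the along-wave velocity component by wave phase.

    The velocity component is signed along the direction of wave travel
    (positive = moving with the outgoing wave).  Bins partition
    [-0.5, 0.5) cycles; empty bins are reported with NaN mean and count
    zero rather than dropped.  With ``replicate_col`` set, bin means are
    computed per replicate first and the reported mean/SD aggregate the
    replicate-level means.
    """
    phase = wave_phase(samples["y_um"].to_numpy(float), samples["time_s"].to_numpy(float), p)
    sign = 1.0 if p.speed_um_per_h >= 0 else -1.0
    v_along = sign * samples["vy"].to_numpy(float)
    edges = np.linspace(-0.5, 0.5, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    df = pd.DataFrame({"bin": idx, "v": v_along})
    if replicate_col is not None:
        df["rep"] = samples[replicate_col].to_numpy()
        per_rep = df.groupby(["bin", "rep"])["v"].mean().reset_index()
        g = per_rep.groupby("bin")["v"]
        stats = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
        counts = df.groupby("bin")["v"].size()
    else:
        g = df.groupby("bin")["v"]
        stats = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
        counts = g.size()
    out = pd.DataFrame(
        {
            "bin_center": (edges[:-1] + edges[1:]) / 2,
            "mean": np.nan,
            "sd": np.nan,
            "count": 0,
        }
    )
    out.loc[stats.index, "mean"] = stats["mean"].to_numpy()
    out.loc[stats.index, "sd"] = stats["sd"].to_numpy()
    out.loc[counts.index, "count"] = counts.to_numpy()
    return out


def phase_aligned_traces(
    tracks: list[Track], p: BarWaveParams
) -> tuple[list[pd.DataFrame], pd.DataFrame, int]:
    """Along-wave displacement vs time since the track's zero-phase crossing.

    t0 is the first time the track's wave phase crosses zero (linearly
    interpolated between frames); displacement is measured along the
    wave axis relative to the interpolated position at t0.  Returns
    (per-track traces, mean trace on the common time grid, number of
    tracks excluded because they never cross phase zero).
    """
    sign = 1.0 if p.speed_um_per_h >= 0 else -1.0
    traces: list[pd.DataFrame] = []
    excluded = 0
    for tr in tracks:
        s = tr.samples
        t = s["time_s"].to_numpy(float)
        y = s["y_um"].to_numpy(float)
        ph = wave_phase(y, t, p)
        t0 = None
        for i in range(len(ph) - 1):
            a, b = ph[i], ph[i + 1]
            if a == 0.0:
                t0, y0 = t[i], y[i]
                break
            if a * b < 0 and abs(b - a) < 0.5:  # genuine crossing, not a wrap
                f = a / (a - b)
                t0 = t[i] + f * (t[i + 1] - t[i])
                y0 = y[i] + f * (y[i + 1] - y[i])
                break
        if t0 is None:
            excluded += 1
            continue
        traces.append(
            pd.DataFrame(
                {"dt_s": t - t0, "disp_um": sign * (y - y0), "track_id": tr.track_id}
            )
        )
    if traces:
        allt = pd.concat(traces, ignore_index=True)
        # bin onto the (shared) frame spacing
        dts = np.diff(np.unique(allt["dt_s"]))
        step = float(np.median(dts)) if len(dts) else 1.0
        allt["dt_bin"] = np.round(allt["dt_s"] / step) * step
        mean_trace = (
            allt.groupby("dt_bin")["disp_um"].agg(["mean", "count"]).reset_index()
        ).rename(columns={"dt_bin": "dt_s"})
    else:
        mean_trace = pd.DataFrame(columns=["dt_s", "mean", "count"])
    return traces, mean_trace, excluded


def polar_decompose(samples: pd.DataFrame, center_um: tuple[float, float]) -> pd.DataFrame:
    """Add v_radial (positive outward) and v_tangential (positive ccw on screen).

    Uses the same chirality convention as the vortex pattern module: in
    the row-down display frame the ccw tangent of offset (rx, ry) is
    (ry, -rx)/|r|.  A sample exactly at the center gets both components
    zero by convention.
    """
    out = samples.copy()
    rx = out["x_um"].to_numpy(float) - center_um[0]
    ry = out["y_um"].to_numpy(float) - center_um[1]
    norm = np.hypot(rx, ry)
    safe = np.maximum(norm, 1e-300)
    rhx, rhy = rx / safe, ry / safe
    thx, thy = rhy, -rhx
    vx, vy = out["vx"].to_numpy(float), out["vy"].to_numpy(float)
    vr = vx * rhx + vy * rhy
    vt = vx * thx + vy * thy
    vr[norm == 0] = 0.0
    vt[norm == 0] = 0.0
    out["r_um"] = norm
    out["v_radial"] = vr
    out["v_tangential"] = vt
    return out


def radial_profile(
    samples: pd.DataFrame, center_um: tuple[float, float], n_rings: int, r_max_um: float
) -> pd.DataFrame:
    """Ring-averaged tangential velocity and angular velocity.

    Rings of equal radial width cover [0, r_max_um] (the FOV inscribed
    circle, typically); samples beyond r_max are ignored.  Angular
    velocity omega = v_tangential / r is averaged per sample (rad/h).
    Empty rings are flagged rather than dropped.
    """
    if not {"v_radial", "v_tangential"} <= set(samples.columns):
        samples = polar_decompose(samples, center_um)
    r = samples["r_um"].to_numpy(float)
    edges = np.linspace(0, r_max_um, n_rings + 1)
    idx = np.digitize(r, edges) - 1
    rows = []
    for ring in range(n_rings):
        sel = idx == ring
        sub = samples.loc[sel]
        with np.errstate(invalid="ignore", divide="ignore"):
            omega = sub["v_tangential"].to_numpy(float) / np.maximum(sub["r_um"].to_numpy(float), 1e-300)
        rows.append(
            {
                "ring": ring,
                "r_mid_um": (edges[ring] + edges[ring + 1]) / 2,
                "v_tangential_mean": sub["v_tangential"].mean() if len(sub) else np.nan,
                "v_radial_mean": sub["v_radial"].mean() if len(sub) else np.nan,
                "omega_mean": float(np.mean(omega)) if len(sub) else np.nan,
                "count": int(sel.sum()),
                "empty": not bool(sel.any()),
            }
        )
    return pd.DataFrame(rows)


def intensity_cv_timecourse(
    cells: pd.DataFrame, condition_col: str | None = None
) -> pd.DataFrame:
    """CV of per-cell mean intensities at each frame time (per condition).

    Requires columns ``time_s`` and ``mean_intensity``.  The CV at a
    time point with zero mean intensity is undefined and flagged.  The
    fold reduction relative to the first time point is included
    (CV(0)/CV(t)).
    """
    df = cells.copy()
    if condition_col is None:
        df["_cond"] = "all"
        condition_col = "_cond"
    rows = []
    for cond, sub in df.groupby(condition_col):
        for t, frame in sub.groupby("time_s"):
            vals = frame["mean_intensity"].to_numpy(float)
            mean = float(vals.mean()) if len(vals) else np.nan
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            cv = sd / mean if mean not in (0.0,) and np.isfinite(mean) and mean != 0 else np.nan
            rows.append(
                {
                    "condition": cond,
                    "time_s": t,
                    "n": len(vals),
                    "mean": mean,
                    "cv": cv,
                    "undefined": not np.isfinite(cv),
                }
            )
    out = pd.DataFrame(rows).sort_values(["condition", "time_s"]).reset_index(drop=True)
    folds = []
    for cond, sub in out.groupby("condition"):
        cv0 = sub["cv"].iloc[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            folds.append(pd.Series(cv0 / sub["cv"].to_numpy(), index=sub.index))
    out["fold_reduction"] = pd.concat(folds).sort_index()
    return out


def intensity_histograms(
    cells: pd.DataFrame, times: list[float], bin_edges: np.ndarray
) -> pd.DataFrame:
    """Per-time histograms of per-cell mean intensities over stated bin edges."""
    rows = []
    for t in times:
        vals = cells.loc[cells["time_s"] == t, "mean_intensity"].to_numpy(float)
        counts, _ = np.histogram(vals, bins=bin_edges)
        for lo, hi, c in zip(bin_edges[:-1], bin_edges[1:], counts):
            rows.append({"time_s": t, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
    return pd.DataFrame(rows)
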