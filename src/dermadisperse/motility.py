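"""Per-track and population motility statistics.

Speed, Euclidean/accumulated displacement, persistence, time-ensemble mean
squared displacement (MSD) and its fitted slope — the latter reported both
raw (the convention of the source imaging analyses, which label the MSD
slope itself the "diffusion coefficient") and physically normalised as
D = slope/4 for planar diffusion.

Dividing lineages are analysed in 180-minute windows anchored to the
division: mothers over the 180 min before it, daughters over 0-180 and
180-360 min after it; non-dividing cells over their whole track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import Track, TrackSet, ValidationError

PHASE_LABELS = ("mother_pre180", "daughter_0_180", "daughter_180_360", "non_dividing")
WINDOW_MIN = 180.0


@dataclass
class PhaseWindow:
    label: str
    t_start: float
    t_end: float


@dataclass
class MSDCurve:
    lags: np.ndarray     # minutes
    msd: np.ndarray      # um^2
    n_pairs: np.ndarray  # (track, start-time) pairs per lag


@dataclass
class DiffusionEstimate:
    slope: float          # um^2/min, MSD slope ("diffusion coefficient" of the imaging convention)
    intercept: float      # um^2
    d_normalised: float   # slope/4, planar diffusion coefficient um^2/min
    fit_window: tuple     # (lag_lo, lag_hi) minutes
    r_squared: float


@dataclass
class DisplacementMetrics:
    euclidean: float
    accumulated: float
    persistence: Optional[float]  # None when accumulated == 0
    n_points: int


def instantaneous_speed(track: Track):
    """Per-step speed series: planar step length over the actual step duration,
    timestamped at the later frame.  Gaps contribute one value over their Δt."""
    if track.n_points < 2:
        warnings.warn(f"track {track.track_id!r} has < 2 points; empty speed series")
        return np.array([]), np.array([])
    dt = np.diff(track.t)
    step = np.hypot(np.diff(track.x), np.diff(track.y))
    return track.t[1:], step / dt


def _window_indices(track: Track, t_start: float, t_end: float) -> np.ndarray:
    return np.nonzero((track.t >= t_start - 1e-9) & (track.t < t_end - 1e-9))[0]


def displacement_metrics(track: Track, window: PhaseWindow) -> Optional[DisplacementMetrics]:
    """Euclidean distance, accumulated path length and persistence
    (euclidean/accumulated, in [0, 1]) over the in-window points.

    Returns None (no-data) when fewer than 2 points fall in the window.
    """
    idx = _window_indices(track, window.t_start, window.t_end)
    if len(idx) < 2:
        return None
    x, y = track.x[idx], track.y[idx]
    euclid = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    accum = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    pers = (euclid / accum) if accum > 0 else None
    return DisplacementMetrics(euclid, accum, pers, len(idx))


def assign_phase_windows(trackset: TrackSet) -> dict:
    """Map each track to its phase windows and the point indices inside each.

    Mother: [division-180, division); daughters: [division, division+180) and
    [division+180, division+360); non-dividing: one window over the whole track.
    """
    out: dict = {}
    for tr in trackset.tracks:
        entries = []
        if tr.role == "non_dividing":
            w = PhaseWindow("non_dividing", float(tr.t[0]), float(tr.t[-1]) + trackset.frame_interval)
            entries.append((w, np.arange(tr.n_points)))
        elif tr.role == "mother":
            if tr.division_time is None:
                raise ValidationError(f"mother track {tr.track_id!r} lacks division_time")
            w = PhaseWindow("mother_pre180", tr.division_time - WINDOW_MIN, tr.division_time)
            idx = _window_indices(tr, w.t_start, w.t_end)
            if len(idx) == 0:
                warnings.warn(f"mother track {tr.track_id!r}: empty pre-division window")
            entries.append((w, idx))
        elif tr.role == "daughter":
            if tr.division_time is None:
                raise ValidationError(f"daughter track {tr.track_id!r} lacks division_time")
            for k, label in enumerate(("daughter_0_180", "daughter_180_360")):
                w = PhaseWindow(label, tr.division_time + k * WINDOW_MIN,
                                tr.division_time + (k + 1) * WINDOW_MIN)
                idx = _window_indices(tr, w.t_start, w.t_end)
                entries.append((w, idx))
        out[tr.track_id] = entries
    return out


def msd_time_ensemble(tracks: Iterable[Track], max_lag: float,
                      frame_interval: float) -> MSDCurve:
    """Time-ensemble MSD: for each lag (multiples of the frame interval up to
    ``max_lag``), the mean squared planar displacement over all tracks and all
    valid start times.  A pair is valid only if both endpoints were observed
    (gaps are never interpolated)."""
    tracks = list(tracks)
    n_lags = int(np.floor(max_lag / frame_interval + 1e-9))
    if n_lags < 1:
        raise ValueError("max_lag must be at least one frame interval")
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for tr in tracks:
        if tr.n_points < 2:
            continue
        fidx = np.round((tr.t - tr.t[0]) / frame_interval).astype(int)
        pos = {int(f): i for i, f in enumerate(fidx)}
        for lag in range(1, n_lags + 1):
            i0, i1 = [], []
            for f, i in pos.items():
                j = pos.get(f + lag)
                if j is not None:
                    i0.append(i)
                    i1.append(j)
            if i0:
                dx = tr.x[i1] - tr.x[i0]
                dy = tr.y[i1] - tr.y[i0]
                sums[lag - 1] += np.sum(dx * dx + dy * dy)
                counts[lag - 1] += len(i0)
    keep = counts >= 1
    if not np.any(keep):
        warnings.warn("no valid displacement pairs at any lag; empty MSD curve")
        return MSDCurve(np.array([]), np.array([]), np.array([], dtype=int))
    lags = (np.arange(1, n_lags + 1) * frame_interval)[keep]
    return MSDCurve(lags, sums[keep] / counts[keep], counts[keep])


def diffusion_coefficient(curve: MSDCurve,
                          fit_window: Optional[tuple] = None) -> DiffusionEstimate:
    """Ordinary least-squares line through the (lag, MSD) points of
    ``fit_window`` (inclusive lag range; default: all lags)."""
    if fit_window is None:
        fit_window = (float(curve.lags[0]), float(curve.lags[-1]))
    lo, hi = fit_window
    sel = (curve.lags >= lo - 1e-9) & (curve.lags <= hi + 1e-9)
    lags, msd = curve.lags[sel], curve.msd[sel]
    if len(lags) < 2:
        raise ValueError("fit window must contain at least 2 lags")
    slope, intercept = np.polyfit(lags, msd, 1)
    pred = slope * lags + intercept
    ss_res = float(np.sum((msd - pred) ** 2))
    ss_tot = float(np.sum((msd - np.mean(msd)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionEstimate(float(slope), float(intercept), float(slope) / 4.0,
                             (float(lo), float(hi)), r2)


def default_fit_window(curve: MSDCurve, tracks: Sequence[Track]) -> tuple:
    """Lags from the first up to a quarter of the shortest contributing track
    duration — a standard guard against noisy large-lag estimates."""
    durations = [tr.duration for tr in tracks if tr.n_points >= 2]
    hi = max(curve.lags[0], min(durations) / 4.0) if durations else curve.lags[-1]
    return (float(curve.lags[0]), float(hi))


def _clip_track(track: Track, t_start: float, t_end: float) -> Optional[Track]:
    idx = _window_indices(track, t_start, t_end)
    if len(idx) < 2:
        return None
    return Track(track.track_id, track.lineage_id, track.role,
                 track.t[idx], track.x[idx], track.y[idx],
                 division_time=track.division_time)


def phase_tracks(trackset: TrackSet, label: str) -> list:
    """Sub-tracks restricted to one phase window (for phase-stratified MSD)."""
    windows = assign_phase_windows(trackset)
    by_id = {tr.track_id: tr for tr in trackset.tracks}
    out = []
    for track_id, entries in windows.items():
        tr = by_id[track_id]
        for w, idx in entries:
            if w.label == label and len(idx) >= 2:
                sub = _clip_track(tr, w.t_start, w.t_end)
                if sub is not None:
                    out.append(sub)
    return out


def phase_metrics_table(trackset: TrackSet) -> pd.DataFrame:
    """Per-track, per-phase-window summary: mean speed, Euclidean and
    accumulated distance, persistence."""
    rows = []
    windows = assign_phase_windows(trackset)
    by_id = {tr.track_id: tr for tr in trackset.tracks}
    for track_id, entries in windows.items():
        tr = by_id[track_id]
        for w, idx in entries:
            dm = displacement_metrics(tr, w)
            if len(idx) >= 2:
                tt = tr.t[idx]
                xx, yy = tr.x[idx], tr.y[idx]
                speeds = np.hypot(np.diff(xx), np.diff(yy)) / np.diff(tt)
                mean_speed = float(np.mean(speeds))
            else:
                mean_speed = np.nan
            rows.append({
                "track_id": track_id,
                "lineage_id": tr.lineage_id,
                "role": tr.role,
                "phase": w.label,
                "t_start_min": w.t_start,
                "t_end_min": w.t_end,
                "n_points": len(idx),
                "mean_speed_um_min": mean_speed,
                "euclidean_um": dm.euclidean if dm else np.nan,
                "accumulated_um": dm.accumulated if dm else np.nan,
                "persistence": dm.persistence if dm and dm.persistence is not None else np.nan,
            })
    return pd.DataFrame(rows)
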