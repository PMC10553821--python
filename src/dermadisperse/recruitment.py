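"""Condensate-entry statistics with absorbing censoring.

A cell "enters" at the first observed frame whose nucleus centroid lies
inside a condensate disc; from that frame on the track is censored (removed
from the at-risk set).  Entry rates of dividing-lineage and non-dividing
cells are compared per 180-minute window with two-sided Fisher exact tests,
and entry-distance distributions are built from each entering cell's
reference starting position (the mother's position at division for dividing
lineages, the first tracked position for non-dividing cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CondensateMap, Track, TrackSet

WINDOW_MIN = 180.0


@dataclass
class EntryEvent:
    track_id: str
    lineage_id: str
    role: str
    entry_time: float                    # absolute minutes
    time_since_reference: float          # minutes since division (dividing) or track start
    condensate_id: str
    start_distance: float                # um, reference start position to entered centre
    started_inside: bool = False         # first observed point already inside a disc


@dataclass
class DistanceDensity:
    """Normalised entry-distance histogram plus a Gaussian-kernel smooth."""
    edges: np.ndarray     # bin edges, um
    density: np.ndarray   # probability density per bin (integrates to 1)
    smooth_x: np.ndarray
    smooth_y: np.ndarray
    n: int


def _reference_positions(trackset: TrackSet) -> dict:
    """Reference starting position per track: for dividing lineages the
    mother's position at the division frame (falling back to the daughter's
    first point when no mother track exists), else the first tracked point."""
    refs = {}
    mothers = {tr.lineage_id: tr for tr in trackset.tracks if tr.role == "mother"}
    for tr in trackset.tracks:
        if tr.role == "daughter" and tr.lineage_id in mothers:
            mo = mothers[tr.lineage_id]
            refs[tr.track_id] = (float(mo.x[-1]), float(mo.y[-1]))
        else:
            refs[tr.track_id] = (float(tr.x[0]), float(tr.y[0]))
    return refs


def detect_entries(trackset: TrackSet, condensates: CondensateMap) -> list:
    """First-entry events for every track, with absorbing censoring.

    Tracks whose first observed point is already inside a disc are flagged
    ``started_inside`` and excluded from rate analyses downstream.
    """
    if len(condensates) == 0:
        raise ValueError("condensate map is empty")
    centres = condensates.centres()
    radii = condensates.radius
    refs = _reference_positions(trackset)
    events = []
    for tr in trackset.tracks:
        pos = tr.positions()
        d = np.linalg.norm(pos[:, None, :] - centres[None, :, :], axis=2)
        inside = d <= radii[None, :]
        hits = np.nonzero(inside.any(axis=1))[0]
        if len(hits) == 0:
            continue
        k = int(hits[0])
        c = int(np.argmin(np.where(inside[k], d[k], np.inf)))
        ref = refs[tr.track_id]
        t_ref = tr.division_time if (tr.role in ("mother", "daughter")
                                     and tr.division_time is not None) else tr.t[0]
        events.append(EntryEvent(
            track_id=tr.track_id,
            lineage_id=tr.lineage_id,
            role=tr.role,
            entry_time=float(tr.t[k]),
            time_since_reference=float(tr.t[k] - t_ref),
            condensate_id=condensates.ids[c],
            start_distance=float(np.hypot(ref[0] - condensates.cx[c],
                                          ref[1] - condensates.cy[c])),
            started_inside=(k == 0),
        ))
    return events


def _group_of(role: str) -> str:
    return "non_dividing" if role == "non_dividing" else "dividing"


def entry_proportions(events: list, trackset: TrackSet,
                      exclude_started_inside: bool = True) -> dict:
    """Fraction of tracked cells entering a condensate, per group.

    Groups: ``dividing`` (mother/daughter roles; both daughters of a lineage
    count separately) and ``non_dividing``.
    """
    excluded = {ev.track_id for ev in events if ev.started_inside} if exclude_started_inside else set()
    entered = {ev.track_id for ev in events if ev.track_id not in excluded}
    out = {}
    for group in ("dividing", "non_dividing"):
        members = [tr for tr in trackset.tracks
                   if _group_of(tr.role) == group and tr.track_id not in excluded]
        n = len(members)
        k = sum(1 for tr in members if tr.track_id in entered)
        out[group] = {
            "n_entered": k,
            "n_tracked": n,
            "fraction": (k / n) if n else float("nan"),
        }
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table, by summing the
    hypergeometric probabilities of tables (at fixed margins) no more likely
    than the observed one.  A zero margin yields p = 1 by convention."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def windowed_entry_rates(events: list, trackset: TrackSet,
                         window: float = WINDOW_MIN) -> pd.DataFrame:
    """Entry counts and at-risk sets per consecutive window, with a Fisher
    exact comparison of the dividing group against the non-dividing reference.

    Windows are anchored per track: to the division for dividing lineages
    (so window 0 is 0-180 min post-mitosis) and to the first tracked frame
    for non-dividing cells.  Entered and lost-to-observation tracks leave the
    risk set at the window in which they go.
    """
    if window < 2 * trackset.frame_interval:
        raise ValueError("window must span at least 2 frames")
    excluded = {ev.track_id for ev in events if ev.started_inside}
    entry_by_track = {ev.track_id: ev for ev in events if not ev.started_inside}

    # per track: window index of entry (or None) and last fully observed window
    info = []
    for tr in trackset.tracks:
        if tr.track_id in excluded:
            continue
        group = _group_of(tr.role)
        if tr.role == "mother":
            continue  # mothers end at division; daughters carry the lineage forward
        t_ref = tr.division_time if (tr.role == "daughter"
                                     and tr.division_time is not None) else tr.t[0]
        ev = entry_by_track.get(tr.track_id)
        w_entry = int((ev.entry_time - t_ref) // window) if ev is not None else None
        w_last = int(max(tr.t[-1] - t_ref, 0.0) // window)
        info.append((group, w_entry, w_last))

    n_windows = max((i[2] for i in info), default=-1) + 1
    rows = []
    for w in range(n_windows):
        counts = {}
        for group in ("dividing", "non_dividing"):
            at_risk = sum(1 for g, we, wl in info
                          if g == group and (we is None or we >= w) and wl >= w)
            entered = sum(1 for g, we, wl in info if g == group and we == w)
            counts[group] = (entered, at_risk)
        k1, n1 = counts["dividing"]
        k0, n0 = counts["non_dividing"]
        p = fisher_exact_2x2([[k1, max(n1 - k1, 0)], [k0, max(n0 - k0, 0)]])
        rows.append({
            "window": w,
            "t_lo_min": w * window,
            "t_hi_min": (w + 1) * window,
            "dividing_entered": k1,
            "dividing_at_risk": n1,
            "non_dividing_entered": k0,
            "non_dividing_at_risk": n0,
            "fisher_p": p,
        })
    return pd.DataFrame(rows)


def cumulative_entry_curve(events: list, trackset: TrackSet, group: str) -> pd.DataFrame:
    """Cumulative fraction of the group's tracked cells entered, vs time
    since each track's reference (division or start)."""
    excluded = {ev.track_id for ev in events if ev.started_inside}
    members = [tr for tr in trackset.tracks
               if _group_of(tr.role) == group and tr.role != "mother"
               and tr.track_id not in excluded]
    n = len(members)
    ids = {tr.track_id for tr in members}
    times = sorted(ev.time_since_reference for ev in events
                   if ev.track_id in ids and not ev.started_inside)
    rows = [{"t_min": 0.0, "cumulative_fraction": 0.0}]
    for i, t in enumerate(times, start=1):
        rows.append({"t_min": t, "cumulative_fraction": i / n if n else float("nan")})
    return pd.DataFrame(rows)


def distance_density(distances, bin_width: float = 10.0,
                     smooth: bool = True) -> DistanceDensity:
    """Normalised histogram (and Gaussian KDE smooth) of scalar distances."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    hi = max(np.max(d), bin_width)
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    hist, edges = np.histogram(d, bins=edges, density=True)
    if smooth and d.size > 1 and np.std(d) > 0:
        kde = stats.gaussian_kde(d)
        bw = kde.factor * np.std(d)
        xs = np.linspace(0.0, edges[-1] + 4 * bw, 256)
        ys = kde(xs) + kde(-xs)  # reflect at zero: distances are non-negative
    else:
        xs = 0.5 * (edges[:-1] + edges[1:])
        ys = hist.copy()
    return DistanceDensity(edges, hist, xs, ys, int(d.size))


def entry_distance_density(events: list, group: Optional[str] = None,
                           bin_width: float = 10.0) -> DistanceDensity:
    """Probability density of entry over starting distance, per group."""
    sel = [ev for ev in events if not ev.started_inside
           and (group is None or _group_of(ev.role) == group)]
    if not sel:
        raise ValueError(f"no entry events in group {group!r}")
    return distance_density([ev.start_distance for ev in sel], bin_width=bin_width)
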