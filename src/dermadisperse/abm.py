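"""Agent-based model of mesenchymal dispersal with absorbing condensates.

Cells perform an off-lattice diffusive random walk on a periodic square
domain.  A cell selected to divide is replaced by two daughters displaced
half the mitotic jump each in diametrically opposite directions at axial
angle theta; each daughter then executes a persistent random walk (steps
d_pers, turning angles Phi_i about the previous heading, first heading along
its mitotic-jump direction) for the fast phase, after which it reverts to
the interphase walk.  Any cell whose end-of-step position falls inside a
condensate disc is absorbed and removed.

Per step the draw order is fixed (movement, then division, then
absorption) and all randomness flows from one seeded generator per
replicate, so runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ._angles import wrap_axial
from ._kinematics import _RAYLEIGH_MEAN
from .datamodel import CondensateMap, DivisionEvent, Track, TrackSet, extent_of
from .recruitment import distance_density


@dataclass
class SimConfig:
    """Parameters of one simulation run (lengths um, times minutes)."""

    domain_size: float = 300.0
    frame_dt: float = 10.0
    duration: float = 1500.0
    n_cells: int = 150
    D: float = 0.00127                 # interphase diffusion coefficient, um^2/min
    division_rate: float = 0.002      # per-cell per-step division probability
                                      # (~half the population divides over 25 h)
    n_divisions_target: Optional[int] = None  # fixed schedule overriding the rate
    jump_length: float = 10.0          # mitotic separation distance, um
    theta_kappa: float = 0.0           # concentration of theta about theta_axis (0 = uniform axial)
    theta_axis: float = 0.0            # preferred mitosis axis, degrees
    persist_steps: int = 18            # fast-phase length (180 min at 10-min steps)
    d_pers_mean: float = 0.6           # mean fast-phase step distance, um
    phi_kappa: float = 6.0             # turning-angle concentration in the fast phase
                                       # (matches the high persistence of tracked daughters)
    pause_steps: int = 0               # optional post-cytokinesis pause
    condensates: Optional[CondensateMap] = None
    origin_offset: tuple = (0.0, 0.0)  # translation (mod domain) of the seeding field
    seed: int = 0

    def validate(self) -> None:
        if self.domain_size <= 0 or self.frame_dt <= 0:
            raise ValueError("domain_size and frame_dt must be positive")
        if self.D < 0 or self.persist_steps < 0 or self.n_cells < 1:
            raise ValueError("invalid D, persist_steps or n_cells")
        if not (0.0 <= self.division_rate <= 1.0):
            raise ValueError("division_rate must be a probability")
        if self.condensates is not None and len(self.condensates):
            L = self.domain_size
            if np.any(self.condensates.cx < 0) or np.any(self.condensates.cx > L) or \
               np.any(self.condensates.cy < 0) or np.any(self.condensates.cy > L):
                raise ValueError("condensate centres must lie within the domain")


@dataclass
class Absorption:
    cell_id: str
    role: str
    time: float
    condensate_id: str
    start_position: tuple  # birth position (daughters) or initial position
    birth_time: float = 0.0

    @property
    def on_arrival(self) -> bool:
        """Absorbed at the frame the cell appeared (born/seeded inside a
        disc): excluded from entry-rate analyses, as in the tracking data."""
        return self.time <= self.birth_time + 1e-9


@dataclass
class SimResult:
    trackset: TrackSet            # unwrapped trajectories with roles/division times
    absorptions: list
    divisions: list
    config: SimConfig
    replicate: int = 0
    conservation_ok: bool = True


def torus_distance(p, q, L: float) -> np.ndarray:
    """Minimal-image planar distance on a periodic square of side L."""
    d = np.abs(np.asarray(p, float) - np.asarray(q, float))
    d = np.minimum(d, L - d)
    return np.sqrt(np.sum(d * d, axis=-1))


class _Cell:
    __slots__ = ("cid", "role", "lineage", "pos", "upos", "heading",
                 "fast_left", "pause_left", "t", "x", "y", "birth_pos",
                 "division_time")

    def __init__(self, cid, role, lineage, pos, t0, division_time=None):
        self.cid = cid
        self.role = role
        self.lineage = lineage
        self.pos = np.array(pos, dtype=float)    # wrapped
        self.upos = np.array(pos, dtype=float)   # unwrapped
        self.heading = 0.0
        self.fast_left = 0
        self.pause_left = 0
        self.t = [t0]
        self.x = [pos[0]]
        self.y = [pos[1]]
        self.birth_pos = (float(pos[0]), float(pos[1]))
        self.division_time = division_time


def simulate(config: SimConfig, seed: Optional[int] = None,
             replicate: int = 0) -> SimResult:
    """Run the agent-based model once; fully seeded and replicable."""
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + replicate)
    L = config.domain_size
    dt = config.frame_dt
    n_steps = int(round(config.duration / dt))
    sigma = np.sqrt(2.0 * config.D * dt)
    pers_scale = config.d_pers_mean / _RAYLEIGH_MEAN

    cmap = config.condensates
    has_cond = cmap is not None and len(cmap) > 0
    if has_cond:
        centres = cmap.centres()
        radii = cmap.radius

    cells = []
    offset = np.asarray(config.origin_offset, dtype=float)
    for i in range(config.n_cells):
        pos = np.mod(rng.uniform(0.0, L, size=2) + offset, L)
        cells.append(_Cell(f"c{i:04d}", "non_dividing", f"c{i:04d}", pos, 0.0))
    next_id = config.n_cells

    absorptions: list = []
    divisions: list = []
    done_tracks: list = []
    n_divisions = 0
    conservation_ok = True

    division_schedule: dict = {}
    if config.n_divisions_target is not None:
        # fixed schedule: target count spread uniformly over the run
        steps = rng.integers(1, max(n_steps - config.persist_steps, 2),
                             size=config.n_divisions_target)
        for s in steps:
            division_schedule[int(s)] = division_schedule.get(int(s), 0) + 1

    def absorb_check(t_now: float) -> None:
        nonlocal cells
        if not has_cond:
            return
        keep = []
        for c in cells:
            d = torus_distance(c.pos[None, :], centres, L)
            hit = np.nonzero(d <= radii)[0]
            if len(hit):
                j = int(hit[np.argmin(d[hit])])
                absorptions.append(Absorption(c.cid, c.role, t_now,
                                              cmap.ids[j], c.birth_pos,
                                              birth_time=c.t[0]))
                done_tracks.append(c)
            else:
                keep.append(c)
        cells = keep

    # cells placed inside a condensate are absorbed at t = 0 (degenerate runs valid)
    absorb_check(0.0)
    if not cells:
        warnings.warn("all cells absorbed at t = 0 (condensates cover the seeding area)")

    for step in range(1, n_steps + 1):
        t_now = step * dt
        # 1. movement
        for c in cells:
            if c.pause_left > 0:
                c.pause_left -= 1
                move = np.zeros(2)
            elif c.fast_left > 0:
                if config.phi_kappa > 0:
                    turn = rng.vonmises(0.0, config.phi_kappa)
                else:
                    turn = rng.uniform(-np.pi, np.pi)
                if c.fast_left < config.persist_steps:  # first fast step keeps the jump heading
                    c.heading += turn
                length = rng.rayleigh(pers_scale)
                move = length * np.array([np.cos(c.heading), np.sin(c.heading)])
                c.fast_left -= 1
            else:
                move = rng.normal(0.0, sigma, size=2)
            c.upos = c.upos + move
            c.pos = np.mod(c.pos + move, L)
            c.t.append(t_now)
            c.x.append(c.upos[0])
            c.y.append(c.upos[1])
        # 2. division
        eligible = [c for c in cells if c.fast_left == 0 and c.pause_left == 0]
        if config.n_divisions_target is not None:
            k = min(division_schedule.get(step, 0), len(eligible))
            chosen = list(rng.choice(len(eligible), size=k, replace=False)) if k else []
            dividing = [eligible[i] for i in chosen]
        else:
            flips = rng.random(len(eligible)) < config.division_rate
            dividing = [c for c, f in zip(eligible, flips) if f]
        for mo in dividing:
            theta = _draw_theta(rng, config)
            u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
            mo.role = "mother"
            mo.division_time = t_now
            cells.remove(mo)
            done_tracks.append(mo)
            kids = []
            for sgn in (+1.0, -1.0):
                d = _Cell(f"c{next_id:04d}", "daughter", mo.lineage,
                          np.mod(mo.pos + sgn * u * config.jump_length / 2.0, L),
                          t_now, division_time=t_now)
                d.upos = mo.upos + sgn * u * config.jump_length / 2.0
                d.x[0], d.y[0] = d.upos[0], d.upos[1]
                d.heading = np.arctan2(sgn * u[1], sgn * u[0])
                d.fast_left = config.persist_steps
                d.pause_left = config.pause_steps
                kids.append(d)
                next_id += 1
            cells.extend(kids)
            divisions.append(DivisionEvent(
                lineage_id=mo.lineage, time=t_now,
                position=(float(mo.upos[0]), float(mo.upos[1])),
                daughter_ids=(kids[0].cid, kids[1].cid),
                mitosis_angle=float(wrap_axial(theta)),
            ))
            n_divisions += 1
        # 3. absorption
        absorb_check(t_now)
        # conservation: alive + absorbed = initial + divisions
        if len(cells) + len(absorptions) != config.n_cells + n_divisions:
            conservation_ok = False

    done_tracks.extend(cells)
    tracks = [
        Track(track_id=c.cid, lineage_id=c.lineage, role=c.role,
              t=np.asarray(c.t), x=np.asarray(c.x), y=np.asarray(c.y),
              division_time=c.division_time)
        for c in done_tracks
    ]
    extent = extent_of([tr.x for tr in tracks], [tr.y for tr in tracks],
                       base=(0.0, 0.0, L, L))
    ts = TrackSet(tracks=tracks, frame_interval=dt, field_extent=extent)
    return SimResult(ts, absorptions, divisions, config, replicate,
                     conservation_ok=conservation_ok)


def _draw_theta(rng: np.random.Generator, config: SimConfig) -> float:
    if np.isinf(config.theta_kappa):
        return float(config.theta_axis)
    if config.theta_kappa > 0:
        psi = rng.vonmises(0.0, config.theta_kappa)
        return float(config.theta_axis + np.degrees(psi) / 2.0)
    return float(rng.uniform(0.0, 180.0))


def run_replicates(config: SimConfig, n_replicates: int = 8,
                   seed: Optional[int] = None) -> list:
    base = config.seed if seed is None else seed
    return [simulate(config, seed=base, replicate=r) for r in range(n_replicates)]


@dataclass
class EntrySummary:
    per_replicate: list          # dicts {group: fraction}
    mean: dict                   # group -> mean fraction
    sem: dict                    # group -> standard error over replicates
    densities: dict              # group -> DistanceDensity or None
    start_positions: dict        # group -> (n, 2) initial locations of enterers
    wilcoxon_p: Optional[float]  # one-sided dividing > non_dividing, paired


def entry_statistics(results: list, bin_width: float = 10.0) -> EntrySummary:
    """Per-replicate condensate-entry fractions by group, with a paired
    one-sided Wilcoxon comparison and entry-distance densities.

    ``dividing`` = daughter agents (cells that arose from a division);
    initial cells that later divided leave the non-dividing denominator,
    since they can no longer be absorbed.  Starting distances use the
    minimal-image convention on the periodic domain.
    """
    if not results:
        raise ValueError("no replicates")
    per_rep = []
    distances = {"dividing": [], "non_dividing": []}
    starts = {"dividing": [], "non_dividing": []}
    for res in results:
        L = res.config.domain_size
        cmap = res.config.condensates
        ts = res.trackset
        # cells born or seeded inside a disc never migrated in: excluded
        excluded = {a.cell_id for a in res.absorptions if a.on_arrival}
        n_daughters = sum(1 for tr in ts.tracks
                          if tr.role == "daughter" and tr.track_id not in excluded)
        # initial cells that divided can no longer be absorbed
        n_initial_mothers = sum(1 for tr in ts.tracks
                                if tr.role == "mother" and int(tr.track_id[1:]) < res.config.n_cells)
        n_nondiv = (res.config.n_cells - n_initial_mothers
                    - sum(1 for a in res.absorptions
                          if a.on_arrival and a.role == "non_dividing"))
        abs_div = [a for a in res.absorptions
                   if a.role == "daughter" and not a.on_arrival]
        abs_non = [a for a in res.absorptions
                   if a.role == "non_dividing" and not a.on_arrival]
        frac = {
            "dividing": len(abs_div) / n_daughters if n_daughters else float("nan"),
            "non_dividing": len(abs_non) / n_nondiv if n_nondiv else float("nan"),
        }
        per_rep.append(frac)
        if cmap is not None and len(cmap):
            by_id = {cid: k for k, cid in enumerate(cmap.ids)}
            for group, pool in (("dividing", abs_div), ("non_dividing", abs_non)):
                for a in pool:
                    k = by_id[a.condensate_id]
                    d = torus_distance(np.asarray(a.start_position),
                                       np.array([cmap.cx[k], cmap.cy[k]]), L)
                    distances[group].append(float(d))
                    starts[group].append(a.start_position)
    mean = {g: float(np.nanmean([r[g] for r in per_rep])) for g in ("dividing", "non_dividing")}
    sem = {g: float(np.nanstd([r[g] for r in per_rep], ddof=1) / np.sqrt(len(per_rep)))
           if len(per_rep) > 1 else float("nan")
           for g in ("dividing", "non_dividing")}
    densities = {g: (distance_density(distances[g], bin_width=bin_width)
                     if distances[g] else None)
                 for g in ("dividing", "non_dividing")}
    wp = None
    if len(per_rep) >= 5:
        d = np.array([r["dividing"] for r in per_rep])
        n = np.array([r["non_dividing"] for r in per_rep])
        ok = np.isfinite(d) & np.isfinite(n)
        if ok.sum() >= 5 and np.any(d[ok] != n[ok]):
            wp = float(stats.wilcoxon(d[ok], n[ok], alternative="greater").pvalue)
    return EntrySummary(per_rep, mean, sem, densities,
                        {g: np.asarray(v, dtype=float).reshape(-1, 2) if v else np.zeros((0, 2))
                         for g, v in starts.items()},
                        wp)
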