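"""Seeded generators of synthetic inputs with known ground truth.

Three generators mirror the statistical structure the analyses assume:

* tracking tables — diffusive non-dividing cells at a target mean speed
  (default 0.02 um/min at 10-min frames) and dividing lineages with a
  diametric mitotic separation followed by a 180-min fast persistent phase
  at a multiple of the interphase speed;
* mitosis-angle fields — tangential organisation around a condensate whose
  concentration decays exponentially with distance, or globally/patch-wise
  aligned fields;
* fibre images — anti-aliased line segments with axial orientations drawn
  about a target orientation, coloured like the stained collagen channel.

Every generator is deterministic given its seed and returns a ground-truth
record alongside the data, so parameter-recovery tests close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._angles import sample_axial, wrap_axial
from ._kinematics import (
    diffusion_for_mean_speed,
    diffusive_steps,
    persistent_steps,
    sigma_for_mean_speed,
)
from .datamodel import CondensateMap, Track, TrackSet, extent_of
from .spatial import MitosisAngleField


@dataclass
class TrackGenParams:
    n_nondividing: int = 50
    n_lineages: int = 45
    frame_dt: float = 10.0
    duration: float = 1500.0           # 25 h of imaging
    interphase_speed: float = 0.02     # um/min mean step speed
    fast_multiplier: float = 3.0
    fast_duration: float = 180.0
    pause_frames: int = 0
    persistence_concentration: float = 4.0
    jump_length_um: float = 10.0
    condensates: Optional[CondensateMap] = None
    field: tuple = (0.0, 0.0, 400.0, 400.0)
    seed: int = 0


def gen_trackset(params: TrackGenParams):
    """Generate a TrackSet of diffusive non-dividing cells and dividing
    lineages with the stereotyped post-mitotic fast phase.

    Returns (TrackSet, ground_truth dict).
    """
    if params.duration < params.fast_duration:
        raise ValueError("duration must cover at least one fast phase")
    rng = np.random.default_rng(params.seed)
    dt = params.frame_dt
    n_steps = int(round(params.duration / dt))
    sigma = sigma_for_mean_speed(params.interphase_speed, dt)
    fast_step = params.fast_multiplier * params.interphase_speed * dt
    nf = int(round(params.fast_duration / dt))
    x0, y0, x1, y1 = params.field

    tracks = []
    for i in range(params.n_nondividing):
        start = rng.uniform([x0, y0], [x1, y1])
        steps = diffusive_steps(rng, n_steps, sigma)
        pos = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        t = np.arange(n_steps + 1) * dt
        tracks.append(Track(f"nd{i:03d}", f"nd{i:03d}", "non_dividing",
                            t, pos[:, 0], pos[:, 1]))

    # division times leave room for both daughter windows and some mother history
    lo = max(2 * dt, 0.1 * params.duration)
    hi = max(lo + dt, params.duration - 2 * params.fast_duration)
    for i in range(params.n_lineages):
        lid = f"lin{i:03d}"
        t_div = float(np.round(rng.uniform(lo, hi) / dt) * dt)
        start = rng.uniform([x0, y0], [x1, y1])
        n_mo = int(round(t_div / dt))
        steps = diffusive_steps(rng, n_mo, sigma)
        mo_pos = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        mo_t = np.arange(n_mo + 1) * dt
        tracks.append(Track(f"mo{i:03d}", lid, "mother", mo_t,
                            mo_pos[:, 0], mo_pos[:, 1], division_time=t_div))
        theta = rng.uniform(0.0, 180.0)
        u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
        n_rest = n_steps - n_mo
        for k, sgn in enumerate((+1.0, -1.0)):
            birth = mo_pos[-1] + sgn * u * params.jump_length_um / 2.0
            heading = np.arctan2(sgn * u[1], sgn * u[0])
            n_pause = min(params.pause_frames, n_rest)
            n_fast = min(nf, n_rest - n_pause)
            n_diff = n_rest - n_pause - n_fast
            incr = np.vstack([
                np.zeros((n_pause, 2)),
                persistent_steps(rng, n_fast, heading, fast_step,
                                 params.persistence_concentration),
                diffusive_steps(rng, n_diff, sigma),
            ])
            pos = birth + np.vstack([np.zeros(2), np.cumsum(incr, axis=0)])
            t = t_div + np.arange(n_rest + 1) * dt
            tracks.append(Track(f"da{i:03d}{'ab'[k]}", lid, "daughter", t,
                                pos[:, 0], pos[:, 1], division_time=t_div))

    extent = extent_of([tr.x for tr in tracks], [tr.y for tr in tracks],
                       base=params.field)
    ts = TrackSet(tracks=tracks, frame_interval=dt, field_extent=extent)
    truth = {
        "interphase_speed_um_min": params.interphase_speed,
        "interphase_sigma_um": sigma,
        "interphase_D_um2_min": diffusion_for_mean_speed(params.interphase_speed, dt),
        "msd_slope_um2_min": 4.0 * diffusion_for_mean_speed(params.interphase_speed, dt),
        "fast_multiplier": params.fast_multiplier,
        "fast_duration_min": params.fast_duration,
        "jump_length_um": params.jump_length_um,
        "seed": params.seed,
    }
    return ts, truth


@dataclass
class AngleFieldParams:
    n_samples: int = 600
    extent: tuple = (0.0, 0.0, 400.0, 400.0)
    condensate_centre: Optional[tuple] = (200.0, 200.0)
    condensate_radius: float = 40.0
    tangential_concentration_near: float = 4.0   # doubled-angle von Mises kappa at d = 0
    decay_range: float = 60.0                    # um; kappa(d) = kappa0 * exp(-d/decay_range)
    global_alignment: Optional[tuple] = None     # (axis_deg, kappa) for condensate-free fields
    patches: Optional[list] = None               # [(x0, y0, x1, y1, axis_deg, kappa), ...]
    seed: int = 0


def gen_mitosis_field(params: AngleFieldParams):
    """Generate a mitosis-angle field.

    Condensate mode (default): absolute axial angles tangential to the
    condensate (relative angle about 90 degrees) with concentration
    kappa(d) = kappa0 * exp(-d / decay_range), uniform axial far away.
    Global/patch modes produce aligned fields for randomness-map tests.
    Returns (MitosisAngleField, ground_truth dict).
    """
    if params.n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(params.seed)
    x0, y0, x1, y1 = params.extent
    xs = rng.uniform(x0, x1, params.n_samples)
    ys = rng.uniform(y0, y1, params.n_samples)

    if params.patches is not None:
        ang = sample_axial(rng, 0.0, 0.0, size=params.n_samples)
        for (px0, py0, px1, py1, axis_deg, kappa) in params.patches:
            sel = (xs >= px0) & (xs < px1) & (ys >= py0) & (ys < py1)
            ang[sel] = sample_axial(rng, axis_deg, kappa, size=int(sel.sum()))
        truth = {"mode": "patches", "patches": params.patches, "seed": params.seed}
    elif params.global_alignment is not None:
        axis_deg, kappa = params.global_alignment
        ang = sample_axial(rng, axis_deg, kappa, size=params.n_samples)
        truth = {"mode": "global", "axis_deg": axis_deg, "kappa": kappa,
                 "seed": params.seed}
    else:
        cx, cy = params.condensate_centre
        d = np.hypot(xs - cx, ys - cy)
        kappa = params.tangential_concentration_near * np.exp(-d / params.decay_range)
        bearing = np.degrees(np.arctan2(cy - ys, cx - xs))
        tangent = bearing + 90.0
        ang = np.array([
            sample_axial(rng, tangent[i], kappa[i]) for i in range(params.n_samples)
        ], dtype=float)
        truth = {"mode": "condensate", "centre": (cx, cy),
                 "radius": params.condensate_radius,
                 "kappa0": params.tangential_concentration_near,
                 "decay_range_um": params.decay_range, "seed": params.seed}
    field = MitosisAngleField(xs, ys, wrap_axial(ang), extent=params.extent)
    return field, truth


def gen_fibre_image(orientation: float, concentration: float,
                    size: tuple = (256, 256), n_fibres: int = 150,
                    noise: float = 0.05, seed: int = 0) -> np.ndarray:
    """Render an RGB fibre image with known ground-truth orientation.

    ``concentration`` is the doubled-angle von Mises kappa of the fibre
    orientations about ``orientation`` (0 = isotropic, inf = parallel
    stripes); fibres are drawn in a magenta-like stain colour (positive a,
    negative b in L*a*b) on a dark noisy background.  Angles follow the
    image convention (y down, counter-clockwise from +x). Returns uint8 RGB.
    """
    from skimage.draw import line_aa

    ny, nx = size
    if ny < 64 or nx < 64:
        raise ValueError("image must be at least 64x64")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((ny, nx), dtype=float)
    half = 0.35 * min(ny, nx)
    if np.isinf(concentration):
        angles = np.full(n_fibres, orientation, dtype=float)
        # parallel stripes: evenly spaced perpendicular offsets
        centres_t = (np.arange(n_fibres) + 0.5) / n_fibres
        u = np.array([np.cos(np.deg2rad(orientation)), np.sin(np.deg2rad(orientation))])
        nvec = np.array([-u[1], u[0]])
        mid = np.array([nx / 2.0, ny / 2.0])
        span = 0.9 * min(nx, ny)
        centres = mid + (centres_t[:, None] - 0.5) * span * nvec
    else:
        angles = sample_axial(rng, orientation, concentration, size=n_fibres)
        centres = np.column_stack([rng.uniform(0, nx, n_fibres),
                                   rng.uniform(0, ny, n_fibres)])
    for (cxp, cyp), a in zip(centres, angles):
        # image frame: x = column, y = row (downward); angle from +x toward +y.
        # fibres are ~3 px wide so they survive the pipeline's median filter
        ux, uy = np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))
        nxv, nyv = -uy, ux
        for off in (-1.0, 0.0, 1.0):
            ox, oy = off * nxv, off * nyv
            r0, c0 = int(round(cyp + oy - half * uy)), int(round(cxp + ox - half * ux))
            r1, c1 = int(round(cyp + oy + half * uy)), int(round(cxp + ox + half * ux))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
            canvas[rr[keep], cc[keep]] = np.maximum(canvas[rr[keep], cc[keep]], val[keep])
    canvas = np.clip(canvas, 0.0, 1.0)
    bg = np.clip(rng.normal(0.06, noise, size=(ny, nx)), 0.0, 1.0)
    fibre_rgb = np.array([0.75, 0.15, 0.85])     # magenta-violet: +a, -b
    bg_rgb = np.array([0.05, 0.08, 0.05])
    img = bg[..., None] * bg_rgb[None, None, :] + canvas[..., None] * fibre_rgb[None, None, :]
    return (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
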