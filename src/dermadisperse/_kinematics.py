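"""Shared kinematic primitives for the simulator and the data generator.

Interphase motion is an off-lattice diffusive walk (isotropic Gaussian
steps); the post-mitotic fast phase is a persistent random walk whose
per-step distance is Rayleigh-distributed about a target mean and whose
heading turns by a wrapped (von Mises) angle about the previous heading,
the first step headed along the mitotic-jump direction.
"""

from __future__ import annotations

import numpy as np

#: Mean of a Rayleigh variate with unit scale.
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)


def sigma_for_mean_speed(mean_speed: float, dt: float) -> float:
    """Per-axis Gaussian step scale giving the target mean step speed.

    Step length is Rayleigh(sigma) with mean sigma*sqrt(pi/2), so
    sigma = mean_speed*dt / sqrt(pi/2).  The equivalent planar diffusion
    coefficient is D = sigma^2 / (2 dt).
    """
    return mean_speed * dt / _RAYLEIGH_MEAN


def diffusion_for_mean_speed(mean_speed: float, dt: float) -> float:
    s = sigma_for_mean_speed(mean_speed, dt)
    return s * s / (2.0 * dt)


def diffusive_steps(rng: np.random.Generator, n_steps: int, sigma: float) -> np.ndarray:
    """(n_steps, 2) Gaussian displacement increments with per-axis std sigma."""
    return rng.normal(0.0, sigma, size=(n_steps, 2))


def persistent_steps(rng: np.random.Generator, n_steps: int,
                     start_heading_rad: float, mean_step: float,
                     kappa: float) -> np.ndarray:
    """(n_steps, 2) persistent-walk increments.

    Per-step distance ~ Rayleigh with mean ``mean_step``; heading turns by a
    von Mises angle (concentration ``kappa``; 0 = uniform) about the previous
    heading, starting from ``start_heading_rad``.
    """
    if n_steps == 0:
        return np.zeros((0, 2))
    if kappa > 0:
        turns = rng.vonmises(0.0, kappa, size=n_steps)
    else:
        turns = rng.uniform(-np.pi, np.pi, size=n_steps)
    turns[0] = 0.0
    headings = start_heading_rad + np.cumsum(turns)
    scale = mean_step / _RAYLEIGH_MEAN
    lengths = rng.rayleigh(scale, size=n_steps)
    return np.column_stack([lengths * np.cos(headings), lengths * np.sin(headings)])
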