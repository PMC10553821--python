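"""Axial (undirected, mod-180) angle arithmetic shared across the package.

Mitosis axes, nucleus orientations and fibre directions are orientations,
not directions: theta and theta+180 are the same object.  All comparisons
therefore go through the acute axial difference, and all averaging through
doubled-angle unit vectors, where the axial circle maps one-to-one onto the
full circle.
"""

from __future__ import annotations

import numpy as np

#: Semivariance plateau of i.i.d. uniform axial angles, in deg^2.
#: The acute difference of two independent uniform orientations is uniform
#: on [0, 90], so E[d^2]/2 = (90^2/3)/2 = 1350.
UNIFORM_AXIAL_SILL = 1350.0


def wrap_axial(angle_deg):
    """Reduce angles to the axial fundamental domain [0, 180)."""
    return np.mod(angle_deg, 180.0)


def axial_difference(a_deg, b_deg):
    """Acute difference between two axial angles, in [0, 90] degrees."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def axial_to_vec(angle_deg):
    """Map axial angles to doubled-angle unit-vector components (cos, sin)."""
    phi = np.deg2rad(2.0 * np.asarray(angle_deg, dtype=float))
    return np.cos(phi), np.sin(phi)


def vec_to_axial(c, s):
    """Back-transform doubled-angle vector components to [0, 180) degrees."""
    return np.mod(np.degrees(np.arctan2(s, c)) / 2.0, 180.0)


def axial_mean(angles_deg, weights=None):
    """Circular mean orientation of axial angles via the doubled-angle map."""
    c, s = axial_to_vec(angles_deg)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        return vec_to_axial(np.sum(w * c), np.sum(w * s))
    return vec_to_axial(np.mean(c), np.mean(s))


def sample_axial(rng, center_deg, kappa, size=None):
    """Draw axial angles about ``center_deg`` with von Mises concentration
    ``kappa`` on the doubled-angle circle; ``kappa = 0`` gives uniform axial.
    """
    if np.isinf(kappa):
        out = np.broadcast_to(np.asarray(center_deg, dtype=float), np.shape(size) or (() if size is None else (size,)))
        return wrap_axial(np.array(out, dtype=float, copy=True))
    if kappa > 0:
        psi = rng.vonmises(0.0, kappa, size=size)
    else:
        psi = rng.uniform(-np.pi, np.pi, size=size)
    return wrap_axial(np.asarray(center_deg, dtype=float) + np.degrees(psi) / 2.0)
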