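"""In-memory containers for tracked nuclei, lineages and condensate geometry.

The coordinate convention follows drift-corrected maximum-intensity
projections: x increases rightward, y increases downward, the origin at the
field's top-left corner, positions in micrometres, times in minutes.  Angles
are measured counter-clockwise from +x in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ROLES = ("mother", "daughter", "non_dividing")


class SchemaError(ValueError):
    """An input table is missing or mislabelling a required column."""


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


@dataclass
class Track:
    """One nucleus trajectory: time-ordered planar positions plus a lineage role.

    ``division_time`` is present iff the track belongs to a dividing lineage:
    a mother's last point is at or before it, a daughter's first point at or
    after it.  Missed frames are retained as time gaps, never interpolated.
    """

    track_id: str
    lineage_id: str
    role: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    division_time: Optional[float] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_points else 0.0

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def gap_frames(self, frame_interval: float) -> int:
        """Number of missed frames implied by time gaps larger than one interval."""
        if self.n_points < 2:
            return 0
        dt = np.diff(self.t)
        return int(np.round(np.sum(dt / frame_interval) - len(dt)))

    def validate(self, frame_interval: Optional[float] = None) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"track {self.track_id!r}: unknown role {self.role!r}")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError(f"track {self.track_id!r}: ragged coordinate arrays")
        if self.n_points == 0:
            raise ValidationError(f"track {self.track_id!r}: empty track")
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise ValidationError(f"track {self.track_id!r}: non-finite or negative times")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"track {self.track_id!r}: non-finite coordinates")
        if self.n_points > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError(f"track {self.track_id!r}: times not strictly increasing")
        if frame_interval is not None and self.n_points > 1:
            # every step must be a whole number of frame intervals (gaps allowed)
            steps = np.diff(self.t) / frame_interval
            if not np.allclose(steps, np.round(steps), atol=1e-6):
                raise ValidationError(
                    f"track {self.track_id!r}: time steps are not multiples of the frame interval"
                )
        if self.role == "daughter":
            if self.division_time is None:
                raise ValidationError(f"daughter track {self.track_id!r} lacks division_time")
            if self.t[0] < self.division_time - 1e-9:
                raise ValidationError(
                    f"daughter track {self.track_id!r} starts before its division"
                )
        if self.role == "mother":
            if self.division_time is None:
                raise ValidationError(f"mother track {self.track_id!r} lacks division_time")
            if self.t[-1] > self.division_time + 1e-9:
                raise ValidationError(f"mother track {self.track_id!r} outlives its division")


@dataclass
class TrackSet:
    """A collection of tracks acquired at one frame interval over one field."""

    tracks: list
    frame_interval: float
    field_extent: tuple  # (x0, y0, x1, y1) in um

    def __len__(self) -> int:
        return len(self.tracks)

    def by_role(self, *roles: str) -> list:
        return [tr for tr in self.tracks if tr.role in roles]

    def lineages(self) -> dict:
        out: dict = {}
        for tr in self.tracks:
            if tr.role in ("mother", "daughter"):
                out.setdefault(tr.lineage_id, []).append(tr)
        return out

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        x0, y0, x1, y1 = self.field_extent
        for tr in self.tracks:
            tr.validate(frame_interval=self.frame_interval)
            if np.any(tr.x < x0 - 1e-6) or np.any(tr.x > x1 + 1e-6) or np.any(
                tr.y < y0 - 1e-6
            ) or np.any(tr.y > y1 + 1e-6):
                raise ValidationError(
                    f"track {tr.track_id!r} leaves the declared field extent"
                )


@dataclass
class CondensateMap:
    """Static absorbing discs representing dermal condensates."""

    ids: list
    cx: np.ndarray
    cy: np.ndarray
    radius: np.ndarray

    def __post_init__(self):
        self.cx = np.atleast_1d(np.asarray(self.cx, dtype=float))
        self.cy = np.atleast_1d(np.asarray(self.cy, dtype=float))
        self.radius = np.atleast_1d(np.asarray(self.radius, dtype=float))
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate condensate ids")
        if np.any(self.radius <= 0):
            raise ValidationError("condensate radius must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    def centres(self) -> np.ndarray:
        return np.column_stack([self.cx, self.cy])


@dataclass
class DivisionEvent:
    """A mitosis: time, midpoint of the daughter pair at the first
    post-cytokinesis frame, and the axial mitosis angle in [0, 180)."""

    lineage_id: str
    time: float
    position: tuple
    daughter_ids: tuple
    mitosis_angle: float

    def __post_init__(self):
        if not (0.0 <= self.mitosis_angle < 180.0):
            raise ValidationError("mitosis_angle must lie in [0, 180)")
        if self.daughter_ids[0] == self.daughter_ids[1]:
            raise ValidationError("daughter ids must be distinct")


def extent_of(points_x: Sequence[np.ndarray], points_y: Sequence[np.ndarray],
              base: Optional[tuple] = None) -> tuple:
    """Bounding rectangle of coordinate arrays, optionally grown from ``base``."""
    xs = np.concatenate([np.atleast_1d(p) for p in points_x]) if points_x else np.array([0.0])
    ys = np.concatenate([np.atleast_1d(p) for p in points_y]) if points_y else np.array([0.0])
    x0, y0, x1, y1 = xs.min(), ys.min(), xs.max(), ys.max()
    if base is not None:
        x0, y0 = min(x0, base[0]), min(y0, base[1])
        x1, y1 = max(x1, base[2]), max(y1, base[3])
    return (float(x0), float(y0), float(x1), float(y1))
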