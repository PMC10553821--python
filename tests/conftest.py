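import numpy as np
import pytest

from dermadisperse.datamodel import CondensateMap, Track, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(track_id="t0", role="non_dividing", points=None, dt=10.0,
               division_time=None, lineage=None):
    """Small helper to build a Track from a list of (x, y) positions."""
    pts = np.asarray(points if points is not None else [(0.0, 0.0), (1.0, 0.0)], float)
    t0 = division_time if (role == "daughter" and division_time is not None) else 0.0
    t = t0 + np.arange(len(pts)) * dt
    return Track(track_id=track_id, lineage_id=lineage or track_id, role=role,
                 t=t, x=pts[:, 0], y=pts[:, 1], division_time=division_time)


@pytest.fixture
def single_disc():
    return CondensateMap(ids=["c1"], cx=[100.0], cy=[100.0], radius=[40.0])


@pytest.fixture
def simple_trackset():
    tracks = [
        make_track("a", points=[(0, 0), (1, 0), (2, 0)]),
        make_track("b", points=[(10, 10), (10, 11), (10, 12)]),
    ]
    return TrackSet(tracks=tracks, frame_interval=10.0, field_extent=(0, 0, 20, 20))
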