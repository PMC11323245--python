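import numpy as np
import pytest

from tunnelwater.geometry import TunnelSnapshot, TransportEvent


@pytest.fixture
def straight_snapshot():
    """Five spheres along z, radii 2.0/1.5/1.0/1.5/2.0 (bottleneck at 2)."""
    centers = np.array([[0.0, 0.0, z] for z in range(5)])
    radii = np.array([2.0, 1.5, 1.0, 1.5, 2.0])
    return TunnelSnapshot(0, "T1", centers, radii)


@pytest.fixture
def snapshot_series(straight_snapshot):
    """Same geometry over frames 0..4."""
    return {
        f: TunnelSnapshot(f, "T1", straight_snapshot.centers,
                          straight_snapshot.radii)
        for f in range(5)
    }


def make_event(frames, oxygen, tunnel="T1", matched=None, **kw):
    frames = np.asarray(frames)
    if matched is None:
        matched = [frozenset({tunnel})] * len(frames)
    return TransportEvent(event_id=kw.pop("event_id", "E1"),
                          water_id=kw.pop("water_id", "W1"),
                          frames=frames, oxygen=oxygen,
                          matched_tunnels=matched, **kw)


@pytest.fixture
def clean_bundle_small():
    from tunnelwater.synthetic import scenario_clean
    return scenario_clean(seed=7, n_events=60, n_sims=5)
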