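import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_events(values, window=100, threshold_ratio=0.5):
    """Independent frame-by-frame oracle for the event detector.

    Computes each frame's windowed minimum by direct scan, thresholds frame
    by frame, then merges consecutive supra-threshold frames into events.
    Deliberately naive: shares no code with capnet.events.
    """
    values = list(map(float, values))
    n = len(values)
    supra = []
    for t in range(n):
        w0 = (t // window) * window
        w1 = min(w0 + window, n)
        ref = min(values[w0:w1])
        supra.append(values[t] > (1.0 + threshold_ratio) * ref)
    events = []
    t = 0
    while t < n:
        if supra[t]:
            s = t
            while t + 1 < n and supra[t + 1]:
                t += 1
            events.append((s, t))
        t += 1
    return events


def flood_fill_clusters(active, connectivity=8):
    """Brute-force spatiotemporal flood fill oracle for cluster linking.

    ``active`` is a dict/set of (row, col, frame) entries on an implicit
    grid.  Returns a set of frozensets of entries (the components).
    """
    active = set(active)
    if connectivity == 8:
        offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    else:
        offs = [(0, 0), (0, 1), (1, 0), (0, -1), (-1, 0)]
    seen = set()
    comps = []
    for start in active:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            r, c, t = stack.pop()
            if (r, c, t) in comp:
                continue
            comp.add((r, c, t))
            for dr, dc in offs:
                for dt in (-1, 0, 1):
                    q = (r + dr, c + dc, t + dt)
                    if q in active and q not in comp:
                        stack.append(q)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
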