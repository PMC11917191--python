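import numpy as np
import pytest

from dyadnirs.types import Event, EventStream, GazeEpisodes


def make_events(actor, specs):
    """specs: list of (code, modality, onset_ms, offset_ms)."""
    evs = [Event(c, m, on, off) for c, m, on, off in sorted(specs, key=lambda s: s[2])]
    return EventStream(actor, evs)


@pytest.fixture
def full_gaze():
    return GazeEpisodes([(0, 1_000_000)])


def random_session(rng, n_max=50, duration_ms=120_000):
    """A random small coded session for oracle-equivalence checks."""
    def stream(actor):
        n = int(rng.integers(0, n_max + 1))
        onsets = np.sort(rng.integers(0, duration_ms, n))
        evs = []
        for on in onsets:
            vocal = rng.random() < 0.4
            dur = int(rng.integers(1, 3000))
            evs.append(
                Event("vocal" if vocal else "smile",
                      "vocal" if vocal else "facial",
                      int(on), int(on) + dur)
            )
        return EventStream(actor, evs)

    n_ep = int(rng.integers(1, 5))
    bounds = np.sort(rng.integers(0, duration_ms, 2 * n_ep))
    intervals = []
    for k in range(n_ep):
        s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
        if e > s:
            intervals.append((s, e))
    gaze = GazeEpisodes(intervals) if intervals else GazeEpisodes([(0, duration_ms)])
    return stream("mother"), stream("infant"), gaze
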