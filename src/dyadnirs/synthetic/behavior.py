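"""Generative model of one mother-infant interaction session.

Mutual gaze covers a configurable fraction of the session, split into a
handful of episodes.  Within mutual gaze the infant emits behaviors as a
homogeneous Poisson process; each infant behavior independently triggers a
maternal response with probability ``response_prob`` at a latency drawn
uniformly from ``response_latency_ms``; the mother additionally emits
spontaneous behaviors as an independent Poisson process.  Each behavior is
facial (a smile, eyebrow movement or tongue protrusion) or vocal with a
configurable Bernoulli probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import (
    FACIAL_CODES,
    NO_TOUCH,
    TOUCH_PRIORITY,
    VOCAL_CODE,
    Event,
    EventStream,
    GazeEpisodes,
    TouchRecord,
)

__all__ = ["DyadSimConfig", "simulate_dyad", "simulate_touch"]


@dataclass
class DyadSimConfig:
    """Parameters of the dyadic interaction generator.

    duration_ms defaults to the 4 coded minutes; rates are per second.
    """

    duration_ms: int = 240_000
    infant_rate: float = 0.1
    maternal_base_rate: float = 0.1
    response_prob: float = 0.5
    response_latency_ms: tuple[float, float] = (100.0, 900.0)
    gaze_coverage: float = 0.8
    n_gaze_episodes: int = 8
    p_vocal: float = 0.4
    mean_duration_ms: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.infant_rate < 0 or self.maternal_base_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must lie in [0, 1]")
        if not 0 <= self.gaze_coverage <= 1:
            raise ValueError("gaze_coverage must lie in [0, 1]")
        lo, hi = self.response_latency_ms
        if lo < 0 or hi < lo:
            raise ValueError("response_latency_ms must satisfy 0 <= low <= high")


def _gaze_episodes(cfg: DyadSimConfig, rng: np.random.Generator) -> GazeEpisodes:
    if cfg.gaze_coverage == 0:
        return GazeEpisodes([])
    if cfg.gaze_coverage == 1:
        return GazeEpisodes([(0, cfg.duration_ms)])
    k = cfg.n_gaze_episodes
    gaze_total = cfg.gaze_coverage * cfg.duration_ms
    gap_total = cfg.duration_ms - gaze_total
    gaze_lens = rng.dirichlet(np.full(k, 2.0)) * gaze_total
    gap_lens = rng.dirichlet(np.full(k, 2.0)) * gap_total
    intervals = []
    t = 0.0
    for gap, ep in zip(gap_lens, gaze_lens):
        start = t + gap
        end = start + ep
        s, e = int(round(start)), int(round(end))
        if e > s:  # rounding can collapse a tiny episode; drop it
            intervals.append((s, e))
        t = end
    return GazeEpisodes(intervals)


def _poisson_onsets(
    rate_per_s: float, gaze: GazeEpisodes, rng: np.random.Generator
) -> np.ndarray:
    onsets = []
    for start, end in gaze.intervals:
        n = rng.poisson(rate_per_s * (end - start) / 1000.0)
        onsets.extend(rng.uniform(start, end, size=n))
    return np.sort(np.array(onsets))


def _make_event(onset_ms: float, cfg: DyadSimConfig, rng: np.random.Generator) -> Event:
    vocal = rng.random() < cfg.p_vocal
    dur = rng.exponential(cfg.mean_duration_ms)
    onset = int(round(onset_ms))
    return Event(
        code=VOCAL_CODE if vocal else str(rng.choice(FACIAL_CODES)),
        modality="vocal" if vocal else "facial",
        onset_ms=onset,
        offset_ms=onset + max(1, int(round(dur))),
    )


def simulate_dyad(cfg: DyadSimConfig) -> tuple[EventStream, EventStream, GazeEpisodes]:
    """Generate (mother_stream, infant_stream, gaze_episodes), reproducible
    from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    gaze = _gaze_episodes(cfg, rng)

    infant_events = [
        _make_event(t, cfg, rng) for t in _poisson_onsets(cfg.infant_rate, gaze, rng)
    ]

    mother_events = []
    lo, hi = cfg.response_latency_ms
    for ev in infant_events:
        if rng.random() < cfg.response_prob:
            latency = lo if hi == lo else rng.uniform(lo, hi)
            mother_events.append(_make_event(ev.onset_ms + latency, cfg, rng))
    for t in _poisson_onsets(cfg.maternal_base_rate, gaze, rng):
        mother_events.append(_make_event(t, cfg, rng))
    mother_events.sort(key=lambda e: e.onset_ms)

    return (
        EventStream("mother", mother_events),
        EventStream("infant", infant_events),
        gaze,
    )


def simulate_touch(
    seed: int,
    n_segments: int,
    category_probs: dict[str, float],
    segment_s: float = 2.0,
) -> TouchRecord:
    """Independent per-segment draws from ``category_probs``.

    ``category_probs`` maps the seven touch categories plus "none" to
    probabilities summing to 1 (missing categories default to 0).
    """
    all_codes = TOUCH_PRIORITY + (NO_TOUCH,)
    unknown = set(category_probs) - set(all_codes)
    if unknown:
        raise ValueError(f"unknown touch categories: {sorted(unknown)}")
    probs = np.array([category_probs.get(c, 0.0) for c in all_codes])
    if (probs < 0).any():
        raise ValueError("negative touch probabilities")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"touch probabilities sum to {probs.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    codes = list(rng.choice(all_codes, size=n_segments, p=probs))
    return TouchRecord(codes=codes, video_duration_s=segment_s * n_segments,
                       segment_s=segment_s)
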