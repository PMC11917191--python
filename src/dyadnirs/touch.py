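"""Maternal touch coding: per-segment priority resolution and aggregation.

The free-play video is divided into 2-s segments.  Each segment receives at
most one of seven hand-touch categories; when several are present the
highest-priority one is coded, priority following the fixed enumeration
(affective > harsh > playful > attention-getting > instrumental > static >
incidental), which orders categories by intentionality and affective value.
A segment without touch is coded "none".

Aggregation treats every coded segment as touched for its whole duration,
sums durations per category, and normalises by the video duration so dyads
with slightly different interaction lengths are comparable.  "All touch" is
the summed proportion over the seven categories; affective touch is also
reported separately (the two touch predictors used downstream).
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .types import NO_TOUCH, TOUCH_PRIORITY, TouchRecord

__all__ = ["resolve_segment", "aggregate_touch", "TOUCH_PRIORITY"]

_PRIORITY_RANK = {code: i for i, code in enumerate(TOUCH_PRIORITY)}


def resolve_segment(present_categories: Iterable[str]) -> str:
    """Single code for a segment: the highest-priority category present.

    An empty set yields "none".
    """
    cats = set(present_categories)
    unknown = cats - set(TOUCH_PRIORITY)
    if unknown:
        raise ValueError(f"unknown touch categories: {sorted(unknown)}")
    if not cats:
        return NO_TOUCH
    return min(cats, key=_PRIORITY_RANK.__getitem__)


def segment_durations(record: TouchRecord) -> list[float]:
    """Actual length of each segment; the final one may be partial."""
    n = len(record.codes)
    if n == 0:
        raise ValueError("touch record has no coded segments")
    full = record.segment_s
    durs = [full] * n
    tail = record.video_duration_s - full * (n - 1)
    if tail <= 0:
        raise ValueError(
            "video duration inconsistent with segment count "
            f"({record.video_duration_s} s for {n} segments)"
        )
    durs[-1] = min(full, tail)
    return durs


def aggregate_touch(record: TouchRecord) -> Mapping[str, float]:
    """Duration proportions per category plus the summed "all_touch".

    Returns a dict with one entry per touch category, "none", and
    "all_touch", each a fraction of the video duration in [0, 1].
    """
    durs = segment_durations(record)
    totals = {code: 0.0 for code in TOUCH_PRIORITY}
    totals[NO_TOUCH] = 0.0
    for code, dur in zip(record.codes, durs):
        totals[code] += dur
    out = {code: t / record.video_duration_s for code, t in totals.items()}
    out["all_touch"] = sum(out[code] for code in TOUCH_PRIORITY)
    return out
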