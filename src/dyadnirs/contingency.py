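"""Maternal contingency detection and the chance-corrected responsiveness index.

A maternal behavior is *contingent* on an infant behavior when it starts
within a fixed latency window W (default 1000 ms) after the infant
behavior's onset; for infant vocalisations the window extends to W after
the vocalisation's offset, so that a mother who waits for her infant to
finish is still credited.  A maternal behavior starting at exactly the same
time as the infant behavior is not contingent (it cannot be a response).
When several maternal behaviors fall inside one window, only the first
counts.  When the infant produces several behaviors simultaneously, a
maternal behavior is contingent on each of them separately.

Raw response rates confound responsiveness with maternal activity level: a
very active mother lands in latency windows by chance.  The responsiveness
index subtracts the Poisson probability of at least one maternal behavior
in a W-length window given the mother's overall rate M/D during mutual
gaze::

    index = C/I - (1 - exp(-M * W / D))

with C contingent maternal behaviors, I infant behaviors, M maternal
behaviors, D the mutual-gaze duration (same time unit as W).  An index of
0 means responding at chance level, positive means above chance.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .types import (
    ContingencySummary,
    EventStream,
    GazeEpisodes,
    UndefinedIndexError,
)

__all__ = [
    "detect_contingent",
    "responsiveness_index",
    "contingency_pipeline",
]


def _window_end(event, w_ms: int) -> int:
    # Facial expressions: response window anchored at onset; vocalisations:
    # extended to offset (mother may wait for the utterance to finish).
    if event.modality == "vocal":
        return event.offset_ms + w_ms
    return event.onset_ms + w_ms


def detect_contingent(
    mother: EventStream,
    infant: EventStream,
    gaze: GazeEpisodes,
    w_ms: int = 1000,
    inclusive_end: bool = True,
    reuse_maternal: bool = True,
) -> list[tuple[int, int]]:
    """Pair infant behaviors with the maternal behavior contingent on them.

    Only events whose onset falls inside a mutual-gaze episode are
    considered (coding inspects mutual-gaze episodes only).  Returns a list
    of ``(infant_index, mother_index)`` pairs into the gaze-restricted,
    onset-sorted event lists of each stream.

    Parameters
    ----------
    w_ms:
        Latency window in ms.
    inclusive_end:
        Whether a maternal onset exactly at the window end still counts.
        The boundary convention is not fixed by the coding rules; the
        default includes it.
    reuse_maternal:
        If False, a maternal behavior already paired with an earlier
        (non-simultaneous) infant behavior cannot be paired again.  Within a
        group of simultaneous infant behaviors a maternal behavior pairs
        with each member regardless.
    """
    infant_events = [e for e in infant.events if gaze.contains(e.onset_ms)]
    mother_events = [e for e in mother.events if gaze.contains(e.onset_ms)]

    pairs: list[tuple[int, int]] = []
    used: set[int] = set()

    # Group simultaneous infant behaviors (identical onset) so that one
    # maternal behavior may answer each member of the group.
    i = 0
    while i < len(infant_events):
        j = i
        while j < len(infant_events) and infant_events[j].onset_ms == infant_events[i].onset_ms:
            j += 1
        group = range(i, j)
        newly_used = []
        for gi in group:
            ev = infant_events[gi]
            end = _window_end(ev, w_ms)
            best = None
            for mi, mev in enumerate(mother_events):
                if mev.onset_ms <= ev.onset_ms:
                    continue  # simultaneity exclusion + causality
                if mev.onset_ms > end or (not inclusive_end and mev.onset_ms == end):
                    continue
                if not reuse_maternal and mi in used:
                    continue
                if best is None or mev.onset_ms < mother_events[best].onset_ms:
                    best = mi
            if best is not None:
                pairs.append((gi, best))
                newly_used.append(best)
        used.update(newly_used)
        i = j
    return pairs


def responsiveness_index(summary: ContingencySummary) -> float:
    """Chance-corrected responsiveness: C/I minus the Poisson chance term.

    Raises :class:`UndefinedIndexError` when I = 0 or D = 0 (no infant
    behavior or no mutual gaze: the dyad is unanalyzable).
    """
    if summary.I <= 0:
        raise UndefinedIndexError("no infant behaviors in window: index undefined")
    if summary.D_ms <= 0:
        raise UndefinedIndexError("no mutual gaze in window: index undefined")
    chance = 1.0 - math.exp(-summary.M * summary.W_ms / summary.D_ms)
    return summary.C / summary.I - chance


def contingency_pipeline(
    mother: EventStream,
    infant: EventStream,
    gaze: GazeEpisodes,
    w_ms: int = 1000,
    warmup_ms: int = 60_000,
    coded_ms: int = 240_000,
    inclusive_end: bool = True,
    reuse_maternal: bool = True,
) -> ContingencySummary:
    """Score one dyad: clip to the coded window, detect, compute the index.

    The first ``warmup_ms`` of the interaction are a warm-up phase and are
    discarded; the following ``coded_ms`` are analyzed.  All counts (C, I,
    M) and the gaze duration D refer to the clipped window only.
    """
    start, stop = warmup_ms, warmup_ms + coded_ms
    mother_c = mother.clipped(start, stop)
    infant_c = infant.clipped(start, stop)
    gaze_c = gaze.clipped(start, stop)

    pairs = detect_contingent(
        mother_c, infant_c, gaze_c, w_ms=w_ms,
        inclusive_end=inclusive_end, reuse_maternal=reuse_maternal,
    )
    n_infant = sum(1 for e in infant_c.events if gaze_c.contains(e.onset_ms))
    n_mother = sum(1 for e in mother_c.events if gaze_c.contains(e.onset_ms))
    summary = ContingencySummary(
        C=len(pairs), I=n_infant, M=n_mother, D_ms=gaze_c.total_ms(), W_ms=w_ms,
    )
    return replace(summary, index=responsiveness_index(summary))
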