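"""Shared domain containers for dyadic-interaction and infant fNIRS analysis.

The behavioral side deals in millisecond-resolution coded event streams
(facial expressions and vocalisations of mother and infant, mutual-gaze
episodes, per-2-s touch codes).  The optical side deals in dual-wavelength
intensity recordings with a block trial structure and per-trial looking
annotations.  Everything here is a plain dataclass over numpy/pandas
containers; behaviour lives in the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FACIAL_CODES = ("smile", "eyebrow", "tongue")
VOCAL_CODE = "vocal"

CONDITIONS = ("contingent", "noncontingent")

#: Channels forming the posterior-STS regions of interest, by hemisphere.
ROI_CHANNELS = {"right": (8, 9, 13, 14), "left": (23, 24, 28, 29)}


class UndefinedIndexError(ValueError):
    """A summary statistic is undefined for this input (e.g. no infant
    behaviors or no mutual gaze in the analysis window)."""


class UndefinedStatisticError(ValueError):
    """A reliability statistic is undefined (degenerate marginals, constant
    ratings)."""


@dataclass(frozen=True)
class Event:
    """One coded behavior: a facial expression or vocal utterance."""

    code: str
    modality: str  # "facial" | "vocal"
    onset_ms: int
    offset_ms: int

    def __post_init__(self) -> None:
        if self.offset_ms < self.onset_ms:
            raise ValueError(f"event offset {self.offset_ms} before onset {self.onset_ms}")
        if self.onset_ms < 0:
            raise ValueError("event times must be non-negative")
        if self.modality not in ("facial", "vocal"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class EventStream:
    """All coded behaviors of one interaction partner, sorted by onset."""

    actor: str  # "mother" | "infant"
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset_ms for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError(f"{self.actor} events must be sorted by onset")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events], dtype=np.int64)

    def clipped(self, start_ms: int, stop_ms: int) -> "EventStream":
        """Events whose onset falls within [start_ms, stop_ms)."""
        kept = [e for e in self.events if start_ms <= e.onset_ms < stop_ms]
        return EventStream(self.actor, kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.actor, e.modality, e.code, e.onset_ms, e.offset_ms) for e in self.events],
            columns=["actor", "modality", "code", "onset_ms", "offset_ms"],
        )


@dataclass
class GazeEpisodes:
    """Non-overlapping, sorted intervals of mutual gaze, in ms."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"zero/negative-duration gaze episode ({start}, {end})")
            if start < prev_end:
                raise ValueError("gaze episodes must be sorted and non-overlapping")
            prev_end = end

    def total_ms(self) -> int:
        return sum(end - start for start, end in self.intervals)

    def contains(self, t_ms: int) -> bool:
        return any(start <= t_ms < end for start, end in self.intervals)

    def clipped(self, start_ms: int, stop_ms: int) -> "GazeEpisodes":
        out = []
        for s, e in self.intervals:
            s2, e2 = max(s, start_ms), min(e, stop_ms)
            if e2 > s2:
                out.append((s2, e2))
        return GazeEpisodes(out)


@dataclass
class ContingencySummary:
    """Counts feeding the chance-corrected responsiveness index.

    C: maternal contingent behaviors, I: infant behaviors, M: maternal
    behaviors, D_ms: total mutual-gaze duration, W_ms: latency window.
    """

    C: int
    I: int
    M: int
    D_ms: int
    W_ms: int = 1000
    index: Optional[float] = None


TOUCH_PRIORITY = (
    "affective",
    "harsh",
    "playful",
    "attention_getting",
    "instrumental",
    "static",
    "incidental",
)
NO_TOUCH = "none"
TOUCH_CODES = TOUCH_PRIORITY + (NO_TOUCH,)


@dataclass
class TouchRecord:
    """Per-2-s-segment touch codes for one free-play session.

    ``codes[i]`` is the single category coded for segment i after priority
    resolution.  The final segment may be shorter than ``segment_s`` when the
    video length is not a multiple of it; its actual length is used when
    aggregating.
    """

    codes: list[str]
    video_duration_s: float
    segment_s: float = 2.0

    def __post_init__(self) -> None:
        unknown = set(self.codes) - set(TOUCH_CODES)
        if unknown:
            raise ValueError(f"unknown touch codes: {sorted(unknown)}")
        if self.video_duration_s <= 0:
            raise ValueError("video duration must be positive")


@dataclass
class Montage:
    """Channel geometry: source/detector pairing, separation, hemisphere."""

    table: pd.DataFrame  # columns: channel, source, detector, distance_mm, hemisphere

    def __post_init__(self) -> None:
        d = self.table["distance_mm"]
        if (d < 20).any() or (d > 25).any():
            raise ValueError("source-detector separation must lie in [20, 25] mm")

    @property
    def channels(self) -> np.ndarray:
        return self.table["channel"].to_numpy()

    def distance_mm(self, channel: int) -> float:
        row = self.table.loc[self.table["channel"] == channel]
        if row.empty:
            raise KeyError(f"channel {channel} not in montage")
        return float(row["distance_mm"].iloc[0])


@dataclass
class NirsRecording:
    """Raw dual-wavelength intensity with trial structure and annotations.

    intensity: (n_channels, 2, n_times) volts, wavelength axis ordered as
    ``wavelengths``.  markers: one row per trial (trial, condition,
    baseline_onset_s, onset_s).  looking: one row per trial
    (trial, frac_trial_looking, frac_brush_looking).
    """

    intensity: np.ndarray
    fs: float
    montage: Montage
    markers: pd.DataFrame
    looking: pd.DataFrame
    wavelengths: tuple[float, float] = (760.0, 850.0)
    brush_intervals: Optional[list[list[tuple[float, float]]]] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must have shape (n_channels, 2, n_times)")
        if self.intensity.shape[0] != len(self.montage.table):
            raise ValueError("intensity channel count does not match montage")
        bad = set(self.markers["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs


@dataclass
class EpochSet:
    """Baseline-corrected HbO/HbR condition epochs per ROI for one subject.

    ``epochs[(roi, condition)]`` is a dict with "hbo" and "hbr" arrays of
    shape (n_valid_trials, n_samples) in µMol, time-locked to trial onset.
    """

    epochs: dict[tuple[str, str], dict[str, np.ndarray]]
    times: np.ndarray
    valid_trial_counts: dict[str, int]
    rois: Sequence[str] = ("left", "right")

    def condition_average(self, roi: str, condition: str, chromophore: str = "hbo") -> np.ndarray:
        """Trial-averaged epoch; raises KeyError if the ROI/condition is absent."""
        return self.epochs[(roi, condition)][chromophore].mean(axis=0)

    def available_rois(self) -> list[str]:
        return sorted({roi for roi, _ in self.epochs})
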