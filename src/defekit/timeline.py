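"""Event-timeline extraction from raw frame and pressure streams.

A defecation event is summarised by five anchor times:

==========  =========================================================
``t0``      sit-down: first seated pressure sample
``t1``      first stool drop: first dropping-filter detection that is
            double-confirmed by the state stream showing ``stool``
``tf``      last stool drop: first dropping detection of the final
            drop episode
``tt``      cleansing start: first ``stool -> toilet_paper`` state
            transition after ``tf``
``te``      event end: last transition into the ``clean`` state after
            ``tt``
==========  =========================================================

with ``t0 <= t1 <= tf <= tt <= te``.  Derived durations:

* active defecation duration  ``ADD = tf - t1``
* total defecation duration   ``TDD = te - t0``
* eu-tenesmus duration        ``ETD = tt - tf`` (last drop to cleansing)

Cleansing posture is inferred from the order of the final pressure
release and the first toilet-paper frame: release first means the
participant stood up to wipe (standing, 1); toilet paper first means
they wiped while seated (0).

Drop-episode segmentation: consecutive dropping-filter detections less
than ``episode_gap_s`` apart belong to one episode; a new episode starts
after a longer gap or once a dropped-filter detection has confirmed the
previous stool reached the water.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    NoCleansingError,
    NoDefecationError,
    StreamOrderError,
    TruncatedStreamError,
)
from .records import DROPPED, DROPPING, FrameRecord, PressureRecord, StoolDetection

__all__ = [
    "EventTimeline",
    "DropEpisode",
    "extract_timeline",
    "extract_event",
    "derive_durations",
    "classify_cleansing",
]

#: Gap (s) beyond which successive dropping detections start a new episode.
DEFAULT_EPISODE_GAP_S = 1.0
#: Frames of slack allowed between a dropping detection and the stool state.
DEFAULT_CONFIRM_WINDOW = 2


@dataclass(frozen=True)
class EventTimeline:
    """The five anchor times plus behavioural flags of one event."""

    t0: float
    t1: float
    tf: float
    tt: float
    te: float
    stool_count: int
    urination_first: bool
    cleansing_seated: bool
    urination_observed: bool = True

    def __post_init__(self) -> None:
        if not (self.t0 <= self.t1 <= self.tf <= self.tt <= self.te):
            raise StreamOrderError(
                "anchor times must satisfy t0 <= t1 <= tf <= tt <= te, got "
                f"({self.t0}, {self.t1}, {self.tf}, {self.tt}, {self.te})"
            )
        if self.stool_count < 1:
            raise ValueError("stool_count must be >= 1")


@dataclass(frozen=True)
class DropEpisode:
    """One segmented drop: its above-water and below-water detections."""

    t_dropping: float          # first dropping-filter detection time
    t_dropped: float | None    # first dropped-filter confirmation (None if missing)
    pixel_row: int | None      # row of the first dropped detection
    pixel_width: int | None    # pixel width of the first dropped detection

    @property
    def sdd(self) -> float | None:
        """Stool-dropping duration of this episode, if confirmed."""
        if self.t_dropped is None:
            return None
        return self.t_dropped - self.t_dropping


def _segment_episodes(
    frames: list[FrameRecord],
    waterline_row: int,
    episode_gap_s: float,
) -> list[DropEpisode]:
    episodes: list[dict] = []
    current: dict | None = None
    for frame in frames:
        for det in frame.detections:
            tag = det.filter_tag
            if tag == DROPPING:
                new_episode = (
                    current is None
                    or current["t_dropped"] is not None
                    or frame.time_s - current["t_last_dropping"] >= episode_gap_s
                )
                if new_episode:
                    current = {
                        "t_dropping": frame.time_s,
                        "t_last_dropping": frame.time_s,
                        "t_dropped": None,
                        "row": None,
                        "width": None,
                    }
                    episodes.append(current)
                else:
                    current["t_last_dropping"] = frame.time_s
            elif tag == DROPPED and current is not None and current["t_dropped"] is None:
                current["t_dropped"] = frame.time_s
                current["row"] = det.pixel_row
                current["width"] = det.pixel_width
    return [
        DropEpisode(e["t_dropping"], e["t_dropped"], e["row"], e["width"])
        for e in episodes
    ]


def extract_event(
    frames: list[FrameRecord],
    pressures: list[PressureRecord],
    waterline_row: int = 1300,
    episode_gap_s: float = DEFAULT_EPISODE_GAP_S,
    confirm_window: int = DEFAULT_CONFIRM_WINDOW,
) -> tuple[EventTimeline, list[DropEpisode]]:
    """Extract the timeline and the segmented drop episodes of one event.

    Raises :class:`NoDefecationError` when the stream never shows stool,
    :class:`NoCleansingError` when it never shows toilet paper, and
    :class:`TruncatedStreamError` when it never returns to clean.
    """
    if not pressures or not any(p.seated for p in pressures):
        raise ValueError("pressure stream must contain at least one seated sample")
    t0 = next(p.time_s for p in pressures if p.seated)

    states = [f.state for f in frames]
    stool_idx = [i for i, s in enumerate(states) if s == "stool"]
    if not stool_idx:
        raise NoDefecationError("state stream never enters the stool state")

    episodes = _segment_episodes(frames, waterline_row, episode_gap_s)
    if not episodes:
        raise NoDefecationError("no dropping-filter detections in the stream")

    # t1: the first dropping detection double-confirmed by the state model —
    # a stool-state frame must occur at or before (detection index +
    # confirm_window).
    frame_index_at = {}
    for i, f in enumerate(frames):
        if f.detections:
            frame_index_at.setdefault(f.time_s, i)
    first_stool = stool_idx[0]
    t1 = None
    for ep in episodes:
        idx = frame_index_at.get(ep.t_dropping)
        if idx is not None and first_stool <= idx + confirm_window:
            t1 = ep.t_dropping
            break
    if t1 is None:
        raise NoDefecationError("no stool-state-confirmed dropping detection")

    confirmed = [ep for ep in episodes if ep.t_dropping >= t1]
    tf = confirmed[-1].t_dropping

    # tt: first stool -> toilet_paper state transition after tf.
    tt = None
    for prev, cur in zip(frames, frames[1:]):
        if prev.state == "stool" and cur.state == "toilet_paper" and cur.time_s >= tf:
            tt = cur.time_s
            break
    if tt is None:
        if not any(s == "toilet_paper" for s in states):
            raise NoCleansingError("state stream never shows toilet paper")
        raise NoCleansingError("no stool -> toilet_paper transition after last drop")

    # te: last transition into the clean state after tt.
    te = None
    for prev, cur in zip(frames, frames[1:]):
        if cur.state == "clean" and prev.state != "clean" and cur.time_s >= tt:
            te = cur.time_s
    if te is None:
        raise TruncatedStreamError("stream ends before returning to the clean state")

    urine_times = [f.time_s for f in frames if f.state == "urine"]
    urination_observed = bool(urine_times)
    urination_first = bool(urine_times) and min(urine_times) < t1

    seated = classify_cleansing(pressures, frames) == 0

    timeline = EventTimeline(
        t0=t0,
        t1=t1,
        tf=tf,
        tt=tt,
        te=te,
        stool_count=len(confirmed),
        urination_first=urination_first,
        cleansing_seated=seated,
        urination_observed=urination_observed,
    )
    return timeline, confirmed


def extract_timeline(
    frames: list[FrameRecord],
    pressures: list[PressureRecord],
    waterline_row: int = 1300,
    **kwargs,
) -> EventTimeline:
    """Timeline-only convenience wrapper around :func:`extract_event`."""
    timeline, _ = extract_event(frames, pressures, waterline_row, **kwargs)
    return timeline


def derive_durations(tl: EventTimeline) -> tuple[float, float, float]:
    """Exact-arithmetic durations ``(ADD, TDD, ETD)`` from the anchors."""
    return tl.tf - tl.t1, tl.te - tl.t0, tl.tt - tl.tf


def classify_cleansing(
    pressures: list[PressureRecord],
    frames: list[FrameRecord],
) -> int:
    """Cleansing posture: 0 = seated, 1 = standing.

    Standing when the final seated->unseated pressure transition precedes
    the first toilet-paper frame; seated otherwise (including when the
    pressure never releases within the stream).
    """
    tp_times = [f.time_s for f in frames if f.state == "toilet_paper"]
    if not tp_times:
        raise NoCleansingError("state stream never shows toilet paper")
    first_tp = min(tp_times)

    release = None
    for prev, cur in zip(pressures, pressures[1:]):
        if prev.seated and not cur.seated:
            release = cur.time_s
    if release is not None and release < first_tp:
        return 1
    return 0
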