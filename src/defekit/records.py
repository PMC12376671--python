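"""Raw sensor-stream record types shared by the generator and the extractors.

A monitored defecation event is observed through two synchronized streams:

* an optical stream of frames, each carrying a toilet-state label
  (``clean`` / ``urine`` / ``stool`` / ``toilet_paper``) and zero or more
  stool detections (pixel row + pixel width of the detected object), and
* a pressure stream from the seat sensor (time, seated flag).

Detections are split at the waterline row into the *dropping* region
(above the water, row < waterline) and the *dropped* region (at or below
the waterline); the time gap between the first detection in each region
is the stool-dropping duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STATES = ("clean", "urine", "stool", "toilet_paper")

DROPPING = "dropping"
DROPPED = "dropped"


def tag_for_row(pixel_row: int, waterline_row: int) -> str:
    """Region tag for a detection: above the waterline it is *dropping*,
    at or below the waterline it is *dropped*."""
    return DROPPING if pixel_row < waterline_row else DROPPED


@dataclass(frozen=True)
class StoolDetection:
    """One detected stool object in a single frame.

    ``pixel_row`` is counted from the image top; ``filter_tag`` records
    which region filter produced the detection and must be consistent
    with the waterline split.
    """

    pixel_row: int
    pixel_width: int
    filter_tag: str

    def __post_init__(self) -> None:
        if self.pixel_row < 0:
            raise ValueError(f"pixel_row must be >= 0, got {self.pixel_row}")
        if self.pixel_width < 1:
            raise ValueError(f"pixel_width must be >= 1, got {self.pixel_width}")
        if self.filter_tag not in (DROPPING, DROPPED):
            raise ValueError(f"unknown filter_tag {self.filter_tag!r}")


@dataclass(frozen=True)
class FrameRecord:
    """One optical frame: capture time, toilet-state label, detections."""

    time_s: float
    state: str
    detections: tuple[StoolDetection, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_s < 86400.0:
            raise ValueError(f"time_s must lie in [0, 86400), got {self.time_s}")
        if self.state not in STATES:
            raise ValueError(f"unknown toilet state {self.state!r}")


@dataclass(frozen=True)
class PressureRecord:
    """One seat-pressure sample."""

    time_s: float
    seated: bool
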