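"""Odor-visual association task paradigm.

The task presents a lavender odorant for 6 s once every 36 s, paired with a
visual cue, at four intensities in ascending blocks (three repetitions per
intensity, weakest first).  Visual-only trials with the same cue are
interleaved midway between odor cycles.  A run is 234 volumes at TR 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

ODOR_VISUAL = "odor_visual"
VISUAL_ONLY = "visual_only"
N_INTENSITIES = 4


@dataclass(frozen=True)
class Event:
    """One trial: stimulus onset/duration in seconds from the first volume."""

    onset: float
    duration: float
    condition: str
    intensity: Optional[int] = None

    def __post_init__(self):
        if self.condition not in (ODOR_VISUAL, VISUAL_ONLY):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == ODOR_VISUAL:
            if self.intensity not in (1, 2, 3, 4):
                raise ValueError(
                    f"odor_visual event at {self.onset}s needs intensity in 1..4"
                )
        elif self.intensity is not None:
            raise ValueError("visual_only events carry no intensity")


@dataclass(frozen=True)
class ParadigmDesign:
    """Scan timing plus the ordered trial table of the odor-visual task."""

    tr: float
    n_volumes: int
    events: Tuple[Event, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.tr <= 0 or self.n_volumes <= 0:
            raise ValueError("tr and n_volumes must be positive")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        end = self.duration
        for e in self.events:
            if e.onset + e.duration > end:
                raise ValueError(
                    f"event at onset {e.onset:g}s (+{e.duration:g}s) exceeds "
                    f"scan duration {end:g}s"
                )

    @property
    def duration(self) -> float:
        """Scan length in seconds."""
        return self.tr * self.n_volumes

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def events_of(self, condition: str) -> Tuple[Event, ...]:
        return tuple(e for e in self.events if e.condition == condition)

    def onset_volumes(self, condition: str) -> np.ndarray:
        """Onset indices on the volume grid (nearest volume)."""
        return np.array(
            [int(round(e.onset / self.tr)) for e in self.events_of(condition)],
            dtype=int,
        )


def build_paradigm(
    tr: float = 2.0,
    n_volumes: int = 234,
    n_odor_trials: int = 12,
    n_visual_trials: int = 12,
    cycle: float = 36.0,
    odor_duration: float = 6.0,
    start: float = 10.0,
) -> ParadigmDesign:
    """Lay out the default odor-visual paradigm.

    Odor trials occur once per ``cycle`` starting at ``start`` seconds, with
    intensities assigned in ascending blocks (all intensity-1 trials before
    intensity-2, and so on).  Visual-only trials sit midway between
    consecutive odor cycles.  Each odor trial's full cycle must fit inside
    the scan.

    Raises
    ------
    ValueError
        If any trial's cycle extends past the end of the scan; the message
        names the first offending onset.
    """
    if n_odor_trials < 0 or n_visual_trials < 0:
        raise ValueError("trial counts must be non-negative")
    if n_odor_trials % N_INTENSITIES != 0:
        raise ValueError(
            f"n_odor_trials={n_odor_trials} must be divisible by "
            f"{N_INTENSITIES} to form ascending intensity blocks"
        )
    scan_end = tr * n_volumes
    per_intensity = n_odor_trials // N_INTENSITIES
    events = []
    for i in range(n_odor_trials):
        onset = start + i * cycle
        if onset + cycle > scan_end:
            raise ValueError(
                f"odor trial onset {onset:g}s: cycle ends at "
                f"{onset + cycle:g}s, beyond scan duration {scan_end:g}s"
            )
        intensity = 1 + i // per_intensity
        events.append(Event(onset, odor_duration, ODOR_VISUAL, intensity))
    for i in range(n_visual_trials):
        onset = start + cycle / 2.0 + i * cycle
        if onset + odor_duration > scan_end:
            raise ValueError(
                f"visual trial onset {onset:g}s (+{odor_duration:g}s) exceeds "
                f"scan duration {scan_end:g}s"
            )
        events.append(Event(onset, odor_duration, VISUAL_ONLY))
    events.sort(key=lambda e: e.onset)
    return ParadigmDesign(tr=tr, n_volumes=n_volumes, events=tuple(events))
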