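"""Core domain containers: recording metadata and in-memory EEG signals."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2}):(\d{2})$")


class Group(str, Enum):
    """Binary diagnostic class of a subject."""

    INSOMNIA = "insomnia"
    HEALTHY = "healthy"


def parse_clock(t: str) -> float:
    """Parse ``hh:mm:ss`` into seconds since midnight.

    Hours are taken modulo 24 so both ``8:22:38`` and ``08:22:38`` work.
    """
    m = _CLOCK_RE.match(t.strip())
    if not m:
        raise ValueError(f"malformed clock time: {t!r} (expected hh:mm:ss)")
    h, mi, s = (int(g) for g in m.groups())
    if h >= 24 or mi >= 60 or s >= 60:
        raise ValueError(f"clock fields out of range: {t!r}")
    return h * 3600.0 + mi * 60.0 + s


@dataclass
class RecordingMeta:
    """Per-recording metadata: identity, class, rate and in-bed clock times.

    ``waso_min`` (wake after sleep onset) is an annotation pass-through; the
    sleep summaries never compute it.
    """

    subject_id: str
    group: Group
    fs: float = 512.0
    channel: str = "C4-A1"
    sleep_start: str = "22:00:00"
    sleep_onset: str = "22:10:00"
    sleep_end: str = "06:00:00"
    waso_min: float = 0.0

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for t in (self.sleep_start, self.sleep_onset, self.sleep_end):
            parse_clock(t)


@dataclass
class EEGSignal:
    """A single-channel EEG trace in microvolts with its metadata."""

    samples: np.ndarray
    fs: float
    meta: RecordingMeta | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs
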