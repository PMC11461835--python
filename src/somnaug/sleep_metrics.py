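"""Sleep-architecture summaries from in-bed clock times.

Conventions
-----------
Three quantities are derived from the three clock times (lights-off /
in-bed start, sleep onset SO, in-bed end):

* time in bed      TIB = end − start
* sleep latency    SL  = onset − start
* total sleep time TST = TIB − SL

``TST = TIB − SL`` is the identity used throughout: wake after sleep onset
(WASO) is carried as an annotation input and deliberately *not* subtracted
from TST.  Clock arithmetic is at one-second resolution with a single
midnight wrap (if the later time is smaller, 24 h is added), and minutes
are rounded to two decimals on output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .meta import RecordingMeta, parse_clock

#: sleep latency at or above this many minutes is flagged prolonged
PROLONGED_SL_MIN = 20.0


def minutes_between(t1: str, t2: str) -> float:
    """Minutes from clock time ``t1`` to ``t2``, wrapping once at midnight.

    Returns ``(t2 - t1)`` in minutes rounded to 2 decimals; if ``t2`` is
    earlier than ``t1`` the interval is assumed to span midnight.
    """
    s1, s2 = parse_clock(t1), parse_clock(t2)
    delta = s2 - s1
    if delta < 0:
        delta += 86400.0
    return round(delta / 60.0, 2)


@dataclass(frozen=True)
class SleepSummary:
    """Derived sleep-architecture quantities for one recording (minutes)."""

    subject_id: str
    time_in_bed_min: float
    sleep_latency_min: float
    tst_min: float
    waso_min: float
    latency_flag: str  # "normal" | "prolonged"


def summarize(meta: RecordingMeta) -> SleepSummary:
    """Compute TIB, SL and TST from a recording's clock times.

    Raises ``ValueError`` if the onset does not lie within the in-bed
    interval (after midnight wrap).
    """
    tib = minutes_between(meta.sleep_start, meta.sleep_end)
    sl = minutes_between(meta.sleep_start, meta.sleep_onset)
    if sl > tib:
        raise ValueError(
            f"{meta.subject_id}: sleep onset {meta.sleep_onset} outside the "
            f"in-bed interval {meta.sleep_start}..{meta.sleep_end}"
        )
    # TST from the already-rounded TIB and SL keeps TIB = SL + TST exact.
    tst = round(tib - sl, 2)
    flag = "prolonged" if sl >= PROLONGED_SL_MIN else "normal"
    return SleepSummary(
        subject_id=meta.subject_id,
        time_in_bed_min=tib,
        sleep_latency_min=sl,
        tst_min=tst,
        waso_min=meta.waso_min,
        latency_flag=flag,
    )


def summaries_frame(metas: list[RecordingMeta]):
    """Summarize a cohort into a DataFrame mirroring the usual PSG table."""
    import pandas as pd

    rows = []
    for m in metas:
        s = summarize(m)
        rows.append(
            {
                "subject": s.subject_id,
                "group": m.group.value,
                "sleep_start": m.sleep_start,
                "sleep_onset": m.sleep_onset,
                "sleep_end": m.sleep_end,
                "time_in_bed_min": s.time_in_bed_min,
                "sleep_latency_min": s.sleep_latency_min,
                "tst_min": s.tst_min,
                "waso_min": s.waso_min,
                "latency_flag": s.latency_flag,
            }
        )
    return pd.DataFrame(rows)
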