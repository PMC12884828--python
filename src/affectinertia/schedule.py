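"""Semi-random beep schedules anchored to wake time.

People are assigned to one of a small number of schedules based on their
habitual wake time. The first beep of each day fires at least 55 min after
waking; subsequent beeps follow at semi-random 2-3 h gaps, with the last
beep capped ~13 h after wake (23:55 for the latest schedule).
"""

from __future__ import annotations

import numpy as np

from .design import StudyDesign


class ScheduleError(ValueError):
    """Raised when a wake time is incompatible with the study design."""


def schedule_wake_times(design: StudyDesign) -> np.ndarray:
    """Wake-time anchors (clock hours) of the design's schedules.

    Schedules quantise the wake-time range to whole hours (7 schedules
    over 5-11 AM by default).
    """
    lo, hi = design.wake_time_range
    return np.linspace(lo, hi, design.n_schedules)


def build_beep_schedule(
    design: StudyDesign,
    person_wake_time: float,
    rng: np.random.Generator,
    n_days: int | None = None,
) -> np.ndarray:
    """Draw beep times-of-day for ``n_days`` days of one burst.

    Returns an array of shape ``(n_days, beeps_per_day)`` of clock hours.
    The first beep of a day is ``wake + min_first_beep_offset`` plus a
    uniform jitter; consecutive same-day gaps are uniform draws from the
    design's gap window; a whole day is redrawn if its last beep would
    exceed the latest allowed beep for that schedule.
    """
    lo, hi = design.wake_time_range
    if not (lo <= person_wake_time <= hi):
        raise ScheduleError(
            f"wake time {person_wake_time} outside wake_time_range {design.wake_time_range}"
        )
    if n_days is None:
        n_days = design.n_days_per_wave
    g_lo, g_hi = design.gap_window
    cap = person_wake_time + design.latest_beep_after_wake
    first_lo = person_wake_time + design.min_first_beep_offset
    k = design.beeps_per_day
    out = np.empty((n_days, k))
    for d in range(n_days):
        for _ in range(1000):
            first = first_lo + rng.uniform(0.0, design.first_beep_jitter)
            gaps = rng.uniform(g_lo, g_hi, size=k - 1)
            times = first + np.concatenate([[0.0], np.cumsum(gaps)])
            if times[-1] <= cap:
                out[d] = times
                break
        else:  # pragma: no cover - cap unattainable for this design
            raise ScheduleError("could not place beeps under the latest-beep cap")
    return out
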