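"""Photoperiod schedules and clock-time helpers.

Metabolic phenotyping of nocturnal animals hinges on the light/dark cycle:
the active phase of a nocturnal primate is the dark ("night") period and the
resting phase the lit ("day") period.  All circadian bookkeeping in this
package works in minutes since midnight (0..1439), with "hh:mm" strings at
the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

MINUTES_PER_DAY = 1440


def parse_clock(text: str) -> int:
    """Parse an "hh:mm" clock string into minutes since midnight."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"not an hh:mm clock time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return 60 * h + m


def format_clock(minutes: float) -> str:
    """Render minutes-since-midnight as "hh:mm" (rounded to the minute)."""
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """A 24 h light schedule given by the two switching times.

    The default emulates a long-day (summer-like) photoperiod with 14 h of
    light: lights off at 17:00 and on again at 03:00, so the dark phase runs
    17:00-03:00 across midnight.

    Parameters
    ----------
    lights_off, lights_on:
        "hh:mm" clock times of the light-to-dark and dark-to-light switches.
    """

    lights_off: str = "17:00"
    lights_on: str = "03:00"

    def __post_init__(self) -> None:
        off, on = self.off_minutes, self.on_minutes
        if off == on:
            raise ValueError("lights_off and lights_on must differ")

    @property
    def off_minutes(self) -> int:
        return parse_clock(self.lights_off)

    @property
    def on_minutes(self) -> int:
        return parse_clock(self.lights_on)

    @property
    def night_length_min(self) -> int:
        return (self.on_minutes - self.off_minutes) % MINUTES_PER_DAY

    @property
    def day_length_h(self) -> float:
        """Hours of light per 24 h cycle."""
        return (MINUTES_PER_DAY - self.night_length_min) / 60.0

    def is_night(self, minutes_of_day):
        """Vectorized dark-phase predicate on minutes since midnight."""
        import numpy as np

        m = np.asarray(minutes_of_day)
        since_off = (m - self.off_minutes) % MINUTES_PER_DAY
        return since_off < self.night_length_min

    def phase_of(self, minutes_of_day):
        """Phase labels ("day"/"night") for minutes since midnight."""
        import numpy as np

        night = self.is_night(minutes_of_day)
        return np.where(night, "night", "day")
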