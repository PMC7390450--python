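"""Zeitgeber time and experimental light/stimulus schedules.

Zeitgeber time (ZT) is measured in minutes relative to the entraining light
cycle of the incubator: ZT 0 is lights-on (local clock 08:00) and ZT 720
(= ZT 12 h) is lights-off (local clock 20:00) in the standard 12:12 cycle.
A ZT axis accumulates across days, so minute 1500 is ZT 60 of day 1.

Four built-in schedules are provided:

``LD``
    plain 12:12 light-dark control, no stimuli.
``DMS``
    discontinuous mechanical stimulation: LD photoperiod plus a 5-second
    shake every 30 min throughout the night (ZT 720-1440), i.e. 24 shakes
    per night.
``DLS``
    discontinuous light stimulation: LD photoperiod plus a 10-min light
    pulse (roughly 490-590 lux) every 60 min throughout the night, i.e. 12
    pulses per night.
``DD``
    constant darkness — the lights never come on, modelling a jet-lag-like
    loss of the daytime light cue.  There are no stimuli; the *absence* of
    expected light is the manipulation.

Sleep latency is referenced to nominal lights-off (ZT 720) in every
schedule, including DD where the incubator is never lit; using the same
reference keeps latency comparable across conditions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import yaml

from .errors import ConfigurationError

MINUTES_PER_DAY = 1440
LIGHTS_ON_CLOCK_MIN = 8 * 60    # 08:00 local == ZT 0
NOMINAL_LIGHTS_OFF_ZT = 720.0   # ZT 12

#: default per-day analysis windows: subjective day and night, in ZT minutes
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 720.0), (720.0, 1440.0))

SHAKE_DURATION_MIN = 5.0 / 60.0  # a 5-second shake


def zt_from_clock(clock: _dt.time | str | float) -> float:
    """Map a local 24-h clock time to ZT minutes in [0, 1440).

    Accepts a :class:`datetime.time`, an ``"HH:MM"`` / ``"HH:MM:SS"`` string,
    or minutes past midnight.  08:00 maps to ZT 0 and 20:00 to ZT 720.
    """
    if isinstance(clock, _dt.time):
        minutes = clock.hour * 60 + clock.minute + clock.second / 60.0
    elif isinstance(clock, str):
        parts = [int(p) for p in clock.split(":")]
        while len(parts) < 3:
            parts.append(0)
        minutes = parts[0] * 60 + parts[1] + parts[2] / 60.0
    else:
        minutes = float(clock)
    return (minutes - LIGHTS_ON_CLOCK_MIN) % MINUTES_PER_DAY


def clock_from_zt(zt: float) -> _dt.time:
    """Inverse of :func:`zt_from_clock` (ZT minutes -> local clock time)."""
    minutes = (float(zt) + LIGHTS_ON_CLOCK_MIN) % MINUTES_PER_DAY
    hours, rem = divmod(minutes, 60)
    secs = round((rem - int(rem)) * 60)
    minute = int(rem)
    if secs == 60:
        secs = 0
        minute += 1
        if minute == 60:
            minute = 0
            hours += 1
    return _dt.time(int(hours) % 24, minute, secs)


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered stimulus: a shake or a light pulse at a ZT onset."""

    kind: str            # "mechanical" | "light"
    onset_zt: float      # minutes, within [0, 1440)
    duration: float      # minutes
    intensity: str | None = None


@dataclass(frozen=True)
class StimulusTrain:
    """A periodic stimulus train over one ZT span of the day.

    ``events()`` expands the train into its individual onsets; the built-in
    DMS train yields 24 shakes per night and the DLS train 12 light pulses.
    """

    kind: str
    onset_zt: float      # first onset, minutes
    duration: float      # minutes per delivery
    period: float        # minutes between onsets
    span: tuple[float, float]
    intensity: str | None = None

    def __post_init__(self) -> None:
        if not self.duration < self.period:
            raise ConfigurationError(
                f"stimulus duration {self.duration} must be shorter than period {self.period}"
            )
        lo, hi = self.span
        if not (0 <= lo < hi <= MINUTES_PER_DAY):
            raise ConfigurationError(f"stimulus span {self.span} outside one ZT day")

    def events(self) -> list[StimulusEvent]:
        """Expand into the per-day onset list (half-open span)."""
        out = []
        onset = self.onset_zt
        while onset < self.span[1]:
            if onset >= self.span[0]:
                out.append(StimulusEvent(self.kind, onset, self.duration, self.intensity))
            onset += self.period
        return out

    def onsets_between(self, start_zt: float, end_zt: float) -> Iterator[float]:
        """Absolute ZT onsets in [start_zt, end_zt) across as many days as needed."""
        day = int(start_zt // MINUTES_PER_DAY)
        while day * MINUTES_PER_DAY < end_zt:
            for ev in self.events():
                t = day * MINUTES_PER_DAY + ev.onset_zt
                if start_zt <= t < end_zt:
                    yield t
            day += 1


@dataclass
class ProtocolSchedule:
    """Photoperiod plus stimulus trains defining one experimental condition.

    The photoperiod is stored as half-open lit intervals within one ZT day and
    repeats with period 1440 min.  ``analysis_windows`` are the per-day ZT
    windows over which sleep parameters are summarised (default day ZT 0-12
    and night ZT 12-24).
    """

    name: str
    lit_intervals: tuple[tuple[float, float], ...]
    stimuli: tuple[StimulusTrain, ...] = ()
    analysis_windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS

    def is_light(self, zt: float) -> bool:
        """Photoperiod light status at an absolute ZT minute (periodic)."""
        t = zt % MINUTES_PER_DAY
        return any(lo <= t < hi for lo, hi in self.lit_intervals)

    def light_with_stimuli(self, zt: float) -> bool:
        """Light status including ongoing light-pulse stimuli (what a sensor reads)."""
        if self.is_light(zt):
            return True
        t = zt % MINUTES_PER_DAY
        for train in self.stimuli:
            if train.kind != "light":
                continue
            for ev in train.events():
                if ev.onset_zt <= t < ev.onset_zt + ev.duration:
                    return True
        return False

    def stimulus_events(self) -> list[StimulusEvent]:
        """All per-day stimulus onsets, expanded and sorted by ZT."""
        evs = [e for train in self.stimuli for e in train.events()]
        return sorted(evs, key=lambda e: e.onset_zt)

    def stimulus_onsets_between(self, start_zt: float, end_zt: float) -> list[float]:
        out: list[float] = []
        for train in self.stimuli:
            out.extend(train.onsets_between(start_zt, end_zt))
        return sorted(out)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lit_intervals": [list(iv) for iv in self.lit_intervals],
            "stimuli": [
                {
                    "kind": t.kind,
                    "onset_zt": t.onset_zt,
                    "duration": t.duration,
                    "period": t.period,
                    "span": list(t.span),
                    "intensity": t.intensity,
                }
                for t in self.stimuli
            ],
            "analysis_windows": [list(w) for w in self.analysis_windows],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSchedule":
        return cls(
            name=d["name"],
            lit_intervals=tuple(tuple(iv) for iv in d.get("lit_intervals", [])),
            stimuli=tuple(
                StimulusTrain(
                    kind=s["kind"],
                    onset_zt=float(s["onset_zt"]),
                    duration=float(s["duration"]),
                    period=float(s["period"]),
                    span=tuple(s["span"]),
                    intensity=s.get("intensity"),
                )
                for s in d.get("stimuli", [])
            ),
            analysis_windows=tuple(tuple(w) for w in d.get("analysis_windows", DEFAULT_WINDOWS)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_schedule(name: str) -> ProtocolSchedule:
    """Build one of the four built-in schedules: LD, DMS, DLS or DD."""
    key = name.upper()
    ld_photoperiod = ((0.0, 720.0),)
    if key == "LD":
        return ProtocolSchedule("LD", ld_photoperiod)
    if key == "DMS":
        shakes = StimulusTrain(
            kind="mechanical",
            onset_zt=720.0,
            duration=SHAKE_DURATION_MIN,
            period=30.0,
            span=(720.0, 1440.0),
            intensity="~2 cm shift at 240 rpm",
        )
        return ProtocolSchedule("DMS", ld_photoperiod, (shakes,))
    if key == "DLS":
        pulses = StimulusTrain(
            kind="light",
            onset_zt=720.0,
            duration=10.0,
            period=60.0,
            span=(720.0, 1440.0),
            intensity="490-590 lux",
        )
        return ProtocolSchedule("DLS", ld_photoperiod, (pulses,))
    if key == "DD":
        return ProtocolSchedule("DD", ())
    raise ConfigurationError(f"unknown protocol {name!r}; expected LD, DMS, DLS or DD")


def lights_off_zt(schedule: ProtocolSchedule) -> float:
    """Nominal lights-off (ZT 720) — the sleep-latency reference in every condition.

    DD is never lit, but latency is still referenced to ZT 720 so it stays
    comparable with the lit conditions.
    """
    return NOMINAL_LIGHTS_OFF_ZT


def light_vector(schedule: ProtocolSchedule, t0_zt: float, n_bins: int,
                 bin_width: int = 1, include_stimuli: bool = True) -> "list[bool]":
    """Per-bin light status along a ZT axis (status at each bin's start)."""
    fn = schedule.light_with_stimuli if include_stimuli else schedule.is_light
    return [fn(t0_zt + i * bin_width) for i in range(n_bins)]
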