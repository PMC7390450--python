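"""Sleep-bout calling and per-window sleep parameters.

Fly sleep is defined behaviourally: five or more consecutive minutes with
zero beam-break counts constitute one sleep bout.  From the called bouts,
six parameters summarise each analysis window (by default the 12-h day
ZT 0-12 and night ZT 12-24):

total_sleep
    summed sleep minutes in the window.
sleep_latency
    minutes from nominal lights-off (ZT 12) to the onset of the first sleep
    bout starting at or after lights-off; censored at the window length when
    the fly never sleeps after lights-off within the window.
activity_index
    beam-break counts per waking minute — locomotor intensity while awake;
    undefined (NaN, flagged) when the fly sleeps the entire window.
mean_sleep
    mean duration of the window's sleep episodes (0 when there are none).
max_sleep
    duration of the longest episode in the window.
sleep_frequency
    number of sleep episodes in the window.

Bouts are clipped at window borders: a bout spanning lights-off contributes
one segment to each window, each counted as an episode there, so total
sleep is conserved across windows.  A clipped segment keeps sleep status
even when the clipped piece is shorter than 5 min — the parent bout
qualified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import ActivityTrace
from .errors import CoverageError, EmptyInputError
from .protocol import MINUTES_PER_DAY, NOMINAL_LIGHTS_OFF_ZT, ProtocolSchedule

MIN_SLEEP_MIN = 5  # consolidated-inactivity threshold, minutes

PARAMETER_NAMES = ("total_sleep", "sleep_latency", "activity_index",
                   "mean_sleep", "max_sleep", "sleep_frequency")


@dataclass(frozen=True)
class SleepBout:
    """One maximal run of consolidated inactivity, as a half-open ZT interval."""

    start_zt: float
    end_zt: float

    @property
    def duration(self) -> float:
        return self.end_zt - self.start_zt


@dataclass
class SleepParameters:
    """The six per-window sleep statistics for one fly."""

    window: tuple[float, float]
    total_sleep: float
    sleep_latency: float
    activity_index: float
    mean_sleep: float
    max_sleep: float
    sleep_frequency: int
    latency_censored: bool = False
    activity_index_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "window_start_zt": self.window[0],
            "window_end_zt": self.window[1],
            "total_sleep": self.total_sleep,
            "sleep_latency": self.sleep_latency,
            "activity_index": self.activity_index,
            "mean_sleep": self.mean_sleep,
            "max_sleep": self.max_sleep,
            "sleep_frequency": self.sleep_frequency,
            "latency_censored": self.latency_censored,
            "activity_index_undefined": self.activity_index_undefined,
        }


def detect_sleep_bouts(trace: ActivityTrace, min_duration: float = MIN_SLEEP_MIN
                       ) -> list[SleepBout]:
    """Call sleep bouts: maximal zero-count runs of at least ``min_duration`` minutes.

    Runs shorter than the threshold are wake (brief pauses, not sleep).
    Returned bouts are disjoint, maximal and ordered by onset.
    """
    if trace.n_bins == 0:
        raise EmptyInputError("empty trace")
    if min_duration % trace.bin_width != 0:
        raise ValueError("trace bin_width must divide min_duration")
    zero = trace.counts == 0
    # run boundaries via edges of the zero-mask
    padded = np.diff(np.concatenate(([0], zero.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    bw = trace.bin_width
    bouts = []
    for s, e in zip(starts, ends):
        if (e - s) * bw >= min_duration:
            bouts.append(SleepBout(trace.t0_zt + s * bw, trace.t0_zt + e * bw))
    return bouts


def clip_bouts(bouts: list[SleepBout], window: tuple[float, float]) -> list[SleepBout]:
    """Intersect bouts with a window; empty intersections are dropped.

    Clipped segments keep sleep status regardless of clipped length.
    """
    lo, hi = window
    out = []
    for b in bouts:
        s, e = max(b.start_zt, lo), min(b.end_zt, hi)
        if e > s:
            out.append(SleepBout(s, e))
    return out


def sleep_mask(trace: ActivityTrace, bouts: list[SleepBout]) -> np.ndarray:
    """Boolean per-bin mask: True where the bin lies inside a sleep bout."""
    mask = np.zeros(trace.n_bins, dtype=bool)
    bw = trace.bin_width
    for b in bouts:
        i0 = int(round((b.start_zt - trace.t0_zt) / bw))
        i1 = int(round((b.end_zt - trace.t0_zt) / bw))
        mask[max(i0, 0): min(i1, trace.n_bins)] = True
    return mask


def _latency_reference(window: tuple[float, float]) -> float:
    """Nominal lights-off of the day containing the window start."""
    day = int(window[0] // MINUTES_PER_DAY)
    return day * MINUTES_PER_DAY + NOMINAL_LIGHTS_OFF_ZT


def compute_sleep_parameters(trace: ActivityTrace, bouts: list[SleepBout],
                             window: tuple[float, float],
                             schedule: ProtocolSchedule | None = None) -> SleepParameters:
    """Compute the six sleep parameters for one fly over one ZT window.

    ``bouts`` must come from :func:`detect_sleep_bouts` on the same trace.
    Latency is referenced to nominal lights-off (ZT 720 of the window's day)
    in every condition; for a window that ends before lights-off the fly
    cannot sleep "after lights-off", so latency is censored at the window
    length.
    """
    lo, hi = window
    if lo < trace.t0_zt - 1e-9 or hi > trace.end_zt + 1e-9:
        raise CoverageError(f"window {window} not covered by trace "
                            f"[{trace.t0_zt}, {trace.end_zt})")
    wlen = hi - lo
    clipped = clip_bouts(bouts, window)
    total = sum(b.duration for b in clipped)
    freq = len(clipped)
    mean = total / freq if freq else 0.0
    longest = max((b.duration for b in clipped), default=0.0)

    # nominal lights-off (ZT 720 of the window's day) in every condition,
    # including DD, so latency stays comparable across schedules
    loff = _latency_reference(window)
    post = [b for b in clipped if b.start_zt >= loff]
    if post:
        latency = post[0].start_zt - loff
        censored = False
    else:
        latency = wlen
        censored = True

    sl = trace.window_slice(window)
    mask = sleep_mask(trace, clipped)[sl]
    wake_minutes = wlen - total
    if wake_minutes <= 0:
        activity = float("nan")
        undefined = True
    else:
        wake_counts = int(trace.counts[sl][~mask].sum())
        activity = wake_counts / wake_minutes
        undefined = False

    return SleepParameters(
        window=window,
        total_sleep=float(total),
        sleep_latency=float(latency),
        activity_index=float(activity),
        mean_sleep=float(mean),
        max_sleep=float(longest),
        sleep_frequency=freq,
        latency_censored=censored,
        activity_index_undefined=undefined,
    )


def day_windows(trace: ActivityTrace, schedule: ProtocolSchedule
                ) -> list[tuple[int, tuple[float, float]]]:
    """Per-day analysis windows fully covered by the trace, as (day, window)."""
    out = []
    first_day = int(np.ceil(trace.t0_zt / MINUTES_PER_DAY - 1e-9))
    last_day = int(trace.end_zt // MINUTES_PER_DAY)
    for day in range(max(first_day, int(trace.t0_zt // MINUTES_PER_DAY)), last_day + 1):
        for w0, w1 in schedule.analysis_windows:
            win = (day * MINUTES_PER_DAY + w0, day * MINUTES_PER_DAY + w1)
            if win[0] >= trace.t0_zt - 1e-9 and win[1] <= trace.end_zt + 1e-9:
                out.append((day, win))
    return out


def sleep_parameter_table(traces: list[ActivityTrace], schedule: ProtocolSchedule,
                          min_duration: float = MIN_SLEEP_MIN) -> pd.DataFrame:
    """Per-fly parameter table: one row per (fly, day, analysis window).

    Carries the fly metadata columns (sex, genotype, treatment, protocol)
    alongside the six parameters and the censoring/undefined flags.
    ``window`` labels use within-day ZT hours, e.g. ``"ZT0-12"``.
    """
    if not traces:
        raise EmptyInputError("no traces")
    rows = []
    for tr in traces:
        bouts = detect_sleep_bouts(tr, min_duration)
        for day, win in day_windows(tr, schedule):
            params = compute_sleep_parameters(tr, bouts, win, schedule)
            w0 = (win[0] - day * MINUTES_PER_DAY) / 60
            w1 = (win[1] - day * MINUTES_PER_DAY) / 60
            row = {"fly_id": tr.fly_id, "day": day,
                   "window": f"ZT{w0:g}-{w1:g}", **params.as_dict()}
            row.update({k: tr.meta.get(k) for k in ("sex", "genotype", "treatment", "protocol")})
            rows.append(row)
    return pd.DataFrame(rows)


def sleep_profile(traces: list[ActivityTrace], profile_bin: int = 30,
                  min_duration: float = MIN_SLEEP_MIN) -> pd.DataFrame:
    """Population sleep profile: mean +/- SEM fraction of time asleep per ZT bin.

    All traces must share one time axis.  Returns a frame with columns
    (zt_bin, mean, sem, n), ordered by ZT; ``zt_bin`` is the left edge in
    minutes.  SEM uses the sample standard deviation (ddof=1) and is 0 for
    a single fly.
    """
    if not traces:
        raise EmptyInputError("no traces")
    ref = traces[0]
    for tr in traces[1:]:
        if tr.t0_zt != ref.t0_zt or tr.n_bins != ref.n_bins or tr.bin_width != ref.bin_width:
            raise ValueError("all traces must share one time axis")
    if profile_bin % ref.bin_width != 0:
        raise ValueError("profile_bin must be a multiple of the trace bin width")
    per = profile_bin // ref.bin_width
    n_profile = ref.n_bins // per
    if n_profile == 0:
        raise EmptyInputError("trace shorter than one profile bin")
    fracs = np.empty((len(traces), n_profile))
    for i, tr in enumerate(traces):
        mask = sleep_mask(tr, detect_sleep_bouts(tr, min_duration))
        fracs[i] = mask[: n_profile * per].reshape(n_profile, per).mean(axis=1)
    mean = fracs.mean(axis=0)
    if len(traces) > 1:
        sem = fracs.std(axis=0, ddof=1) / np.sqrt(len(traces))
    else:
        sem = np.zeros(n_profile)
    return pd.DataFrame({
        "zt_bin": ref.t0_zt + np.arange(n_profile) * float(profile_bin),
        "mean": mean,
        "sem": sem,
        "n": len(traces),
    })


def exclude_dead_flies(traces: list[ActivityTrace], min_active_window: float = 24.0,
                       enabled: bool = False) -> tuple[list[ActivityTrace], pd.DataFrame]:
    """Drop flies with zero counts over the final ``min_active_window`` hours.

    A fly that never breaks the beam for a full day at the end of the
    recording is most likely dead and would otherwise score as continuously
    asleep.  Exclusion is off by default; the report lists every fly with
    its exclusion status either way.
    """
    window_bins = int(min_active_window * 60)
    rows, kept = [], []
    for tr in traces:
        nb = min(window_bins // tr.bin_width, tr.n_bins)
        dead = bool(tr.counts[tr.n_bins - nb:].sum() == 0) if nb > 0 else False
        excluded = dead and enabled
        rows.append({"fly_id": tr.fly_id, "dead_final_window": dead, "excluded": excluded})
        if not excluded:
            kept.append(tr)
    return kept, pd.DataFrame(rows)
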