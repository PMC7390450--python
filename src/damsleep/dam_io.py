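"""Reading and writing DAM-style activity-monitor files.

A Drosophila Activity Monitor (DAM) records, per 32-channel monitor, one
tab-delimited row per acquisition interval:

    index  date  time  status  <6 device fields>  light  c1 ... c32

where ``c1..c32`` are beam-break counts for the flies in channels 1-32 and
``light`` is the on-board light sensor (>0 means lit).  The acquisition
interval may be finer than one minute (devices commonly log every 6 s); the
reader sums finer rows into the requested analysis bin width, conserving
total counts.  All sleep definitions downstream operate on 1-minute bins.

Timestamp hygiene is strict: rows must be in ascending time order and
contiguous.  A gap is an error, never silently zero-filled — fabricated
zero-count minutes would be indistinguishable from sleep.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    ChannelLookupError,
    ConfigurationError,
    DamGapError,
    DamOrderingError,
    DamParseError,
    EmptyInputError,
)
from .protocol import MINUTES_PER_DAY, zt_from_clock

N_CHANNELS = 32
_N_META_COLS = 11  # index, date, time, status, 6 device fields, light sensor
_N_COLS = _N_META_COLS + N_CHANNELS

#: wall-clock datetime corresponding to ZT 0 of day 0 in files this package writes
ZT0_EPOCH = _dt.datetime(2020, 1, 1, 8, 0, 0)

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"

DESIGN_COLUMNS = ("monitor_file", "channel", "fly_id", "sex", "genotype",
                  "treatment", "protocol")
KNOWN_PROTOCOLS = ("LD", "DMS", "DLS", "DD")


@dataclass
class ActivityTrace:
    """One fly's uniformly binned beam-break counts on a ZT time axis.

    ``t0_zt`` is the ZT minute of the first bin's left edge; bin ``i`` covers
    ``[t0_zt + i*bin_width, t0_zt + (i+1)*bin_width)``.  ``counts`` and
    ``light`` have one entry per bin.
    """

    fly_id: str
    monitor_channel: int
    t0_zt: float
    bin_width: int
    counts: np.ndarray
    light: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.light = np.asarray(self.light, dtype=bool)
        if self.counts.ndim != 1 or self.light.ndim != 1:
            raise ValueError("counts and light must be 1-D")
        if len(self.counts) != len(self.light):
            raise ValueError("counts and light must have equal length")
        if not (1 <= self.monitor_channel <= N_CHANNELS):
            raise ValueError(f"monitor_channel {self.monitor_channel} outside 1..{N_CHANNELS}")
        if not float(self.bin_width).is_integer() or self.bin_width <= 0:
            raise ValueError("bin_width must be a positive integer number of minutes")
        self.bin_width = int(self.bin_width)
        if self.t0_zt < 0:
            raise ValueError("t0_zt must be >= 0")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                np.mod(self.counts, 1) == 0
            ) and np.all(self.counts >= 0):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValueError("counts must be non-negative integers")
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def end_zt(self) -> float:
        return self.t0_zt + self.n_bins * self.bin_width

    def bin_starts(self) -> np.ndarray:
        return self.t0_zt + np.arange(self.n_bins) * float(self.bin_width)

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Indices of bins whose span lies inside ``window`` (half-open ZT minutes)."""
        lo, hi = window
        i0 = int(np.ceil((lo - self.t0_zt) / self.bin_width))
        i1 = int(np.floor((hi - self.t0_zt) / self.bin_width))
        return slice(max(i0, 0), min(max(i1, 0), self.n_bins))


@dataclass
class MonitorData:
    """Parsed contents of one monitor file, resampled to ``bin_width`` minutes."""

    start_datetime: _dt.datetime
    t0_zt: float                 # ZT of the first bin, in [0, 1440)
    bin_width: int
    light: np.ndarray            # bool, per bin
    counts: np.ndarray           # int, shape (n_bins, 32)
    source: str = ""

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def end_datetime(self) -> _dt.datetime:
        return self.start_datetime + _dt.timedelta(minutes=self.n_bins * self.bin_width)

    def series(self, channel: int) -> np.ndarray:
        """Count series for one channel (1-based, 1..32)."""
        if not (1 <= channel <= N_CHANNELS):
            raise ChannelLookupError(f"channel {channel} outside 1..{N_CHANNELS}")
        return self.counts[:, channel - 1]

    def channel_map(self) -> dict[int, np.ndarray]:
        return {c: self.counts[:, c - 1] for c in range(1, N_CHANNELS + 1)}


def _parse_row(line: str, lineno: int) -> tuple[_dt.datetime, int, int, np.ndarray]:
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) < _N_COLS:
        raise DamParseError(
            f"line {lineno}: expected >= {_N_COLS} tab-separated columns, got {len(fields)}"
        )
    try:
        stamp = _dt.datetime.strptime(f"{fields[1]} {fields[2]}", f"{_DATE_FMT} {_TIME_FMT}")
    except ValueError as exc:
        raise DamParseError(f"line {lineno}: bad date/time {fields[1]!r} {fields[2]!r}") from exc
    status = fields[3]
    if status not in ("1", "MT"):
        warnings.warn(f"line {lineno}: unknown machine status {status!r}; row kept",
                      stacklevel=3)
    try:
        light = int(fields[_N_META_COLS - 1])
        counts = np.array([int(v) for v in fields[_N_META_COLS:_N_COLS]], dtype=np.int64)
    except ValueError as exc:
        raise DamParseError(f"line {lineno}: non-integer count field") from exc
    if np.any(counts < 0):
        raise DamParseError(f"line {lineno}: negative count")
    return stamp, int(status == "1" or status == "MT"), light, counts


def read_dam_file(path, bin_width: int = 1) -> MonitorData:
    """Parse a DAM monitor file and resample counts to ``bin_width``-minute bins.

    Rows at a finer acquisition interval (e.g. every 6 s) are summed into
    bins; the per-bin light status is on when more than half the
    contributing rows read light.  Trailing rows that do not fill a complete
    bin are dropped with a warning.
    """
    if bin_width <= 0 or not float(bin_width).is_integer():
        raise ConfigurationError("bin_width must be a positive integer number of minutes")
    bin_width = int(bin_width)
    path = Path(path)
    stamps: list[_dt.datetime] = []
    lights: list[int] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            stamp, _ok, light, counts = _parse_row(line, lineno)
            stamps.append(stamp)
            lights.append(light)
            rows.append(counts)
    if not rows:
        raise EmptyInputError(f"{path}: no data rows")

    interval: float  # seconds between rows
    if len(stamps) > 1:
        diffs = [(b - a).total_seconds() for a, b in zip(stamps, stamps[1:])]
        interval = diffs[0]
        if interval <= 0:
            raise DamOrderingError(f"{path}: timestamps not strictly increasing at row 2")
        for i, d in enumerate(diffs, start=2):
            if d <= 0:
                raise DamOrderingError(f"{path}: timestamps not strictly increasing at row {i}")
            if abs(d - interval) > 1e-9:
                missing_from = stamps[i - 2] + _dt.timedelta(seconds=interval)
                raise DamGapError(
                    f"{path}: gap before row {i}: missing span "
                    f"[{missing_from:%Y-%m-%d %H:%M:%S}, {stamps[i - 1]:%Y-%m-%d %H:%M:%S})"
                )
    else:
        interval = bin_width * 60.0

    spb = bin_width * 60.0  # seconds per analysis bin
    if interval > spb + 1e-9:
        raise ConfigurationError(
            f"{path}: acquisition interval {interval:.0f}s coarser than bin width {spb:.0f}s"
        )
    if abs(spb / interval - round(spb / interval)) > 1e-9:
        raise ConfigurationError(
            f"{path}: bin width {spb:.0f}s is not a multiple of the acquisition interval "
            f"{interval:.0f}s"
        )
    rows_per_bin = int(round(spb / interval))
    n_bins = len(rows) // rows_per_bin
    if n_bins == 0:
        raise EmptyInputError(f"{path}: fewer rows than one {bin_width}-min bin")
    used = n_bins * rows_per_bin
    if used < len(rows):
        warnings.warn(f"{path}: dropped {len(rows) - used} trailing rows "
                      f"(incomplete final bin)", stacklevel=2)
    mat = np.vstack(rows[:used]).reshape(n_bins, rows_per_bin, N_CHANNELS)
    light_mat = (np.asarray(lights[:used]) > 0).reshape(n_bins, rows_per_bin)
    return MonitorData(
        start_datetime=stamps[0],
        t0_zt=zt_from_clock(stamps[0].time()),
        bin_width=bin_width,
        light=light_mat.mean(axis=1) > 0.5,
        counts=mat.sum(axis=1),
        source=str(path),
    )


def write_raw_dam(path, start: _dt.datetime, interval_seconds: float,
                  light_rows: Sequence[int], count_rows: np.ndarray) -> None:
    """Write rows at an arbitrary acquisition interval (e.g. 6 s).

    ``count_rows`` has one row per acquisition interval and up to 32 columns;
    missing channels are padded with zeros.  Used to emulate raw device
    output finer than the 1-minute analysis grid.
    """
    count_rows = np.asarray(count_rows, dtype=np.int64)
    if count_rows.ndim != 2:
        raise ValueError("count_rows must be 2-D (rows x channels)")
    if count_rows.shape[1] > N_CHANNELS:
        raise CapacityError(f"{count_rows.shape[1]} channels exceed monitor capacity "
                            f"of {N_CHANNELS}")
    if count_rows.shape[0] == 0:
        raise EmptyInputError("no rows to write")
    if len(light_rows) != count_rows.shape[0]:
        raise ValueError("light_rows length must match count_rows")
    full = np.zeros((count_rows.shape[0], N_CHANNELS), dtype=np.int64)
    full[:, : count_rows.shape[1]] = count_rows
    with open(path, "w") as fh:
        for i in range(full.shape[0]):
            stamp = start + _dt.timedelta(seconds=i * interval_seconds)
            meta = [str(i + 1), stamp.strftime(_DATE_FMT), stamp.strftime(_TIME_FMT),
                    "1", "0", "0", "0", "0", "0", "0", str(int(light_rows[i]))]
            fh.write("\t".join(meta + [str(v) for v in full[i]]) + "\n")


def write_dam_file(data, path, t0_zt: float | None = None, bin_width: int = 1,
                   light: np.ndarray | None = None) -> None:
    """Write traces or a channel map as a DAM monitor file (one row per bin).

    ``data`` is either a list of :class:`ActivityTrace` sharing one time axis
    (channel taken from each trace) or a mapping ``channel -> count series``
    (then ``t0_zt`` and ``light`` must be given).  Wall-clock timestamps are
    anchored so that ZT 0 of day 0 falls on 2020-01-01 08:00; reading the
    file back reproduces counts, light and minute-resolution timestamps.
    """
    if isinstance(data, Mapping):
        if not data:
            raise EmptyInputError("empty channel map")
        if len(data) > N_CHANNELS:
            raise CapacityError(f"{len(data)} channels exceed monitor capacity of {N_CHANNELS}")
        for c in data:
            if not (1 <= int(c) <= N_CHANNELS):
                raise ChannelLookupError(f"channel {c} outside 1..{N_CHANNELS}")
        lengths = {len(v) for v in data.values()}
        if len(lengths) != 1:
            raise ConfigurationError("all channel series must share one time axis")
        n = lengths.pop()
        if n == 0:
            raise EmptyInputError("empty count series")
        if t0_zt is None:
            raise ConfigurationError("t0_zt required when writing a channel map")
        if light is None:
            light = np.zeros(n, dtype=bool)
        mat = np.zeros((n, N_CHANNELS), dtype=np.int64)
        for c, series in data.items():
            mat[:, int(c) - 1] = np.asarray(series, dtype=np.int64)
    else:
        traces = list(data)
        if not traces:
            raise EmptyInputError("no traces to write")
        if len(traces) > N_CHANNELS:
            raise CapacityError(f"{len(traces)} traces exceed monitor capacity of {N_CHANNELS}")
        ref = traces[0]
        for tr in traces[1:]:
            if tr.t0_zt != ref.t0_zt or tr.n_bins != ref.n_bins or tr.bin_width != ref.bin_width:
                raise ConfigurationError("all traces must share one time axis")
        channels = [tr.monitor_channel for tr in traces]
        if len(set(channels)) != len(channels):
            raise ConfigurationError("duplicate monitor channels among traces")
        if ref.n_bins == 0:
            raise EmptyInputError("empty count series")
        t0_zt = ref.t0_zt
        bin_width = ref.bin_width
        light = ref.light
        mat = np.zeros((ref.n_bins, N_CHANNELS), dtype=np.int64)
        for tr in traces:
            mat[:, tr.monitor_channel - 1] = tr.counts

    n = mat.shape[0]
    start = ZT0_EPOCH + _dt.timedelta(minutes=float(t0_zt))
    light_rows = np.asarray(light).astype(int)
    with open(path, "w") as fh:
        for i in range(n):
            stamp = start + _dt.timedelta(minutes=i * bin_width)
            meta = [str(i + 1), stamp.strftime(_DATE_FMT), stamp.strftime(_TIME_FMT),
                    "1", "0", "0", "0", "0", "0", "0", str(int(light_rows[i]))]
            fh.write("\t".join(meta + [str(v) for v in mat[i]]) + "\n")


# ---------------------------------------------------------------------------
# design tables


def read_design_table(path) -> pd.DataFrame:
    """Read and validate a design CSV mapping (monitor_file, channel) to fly metadata."""
    df = pd.read_csv(path, dtype={"channel": int, "fly_id": str})
    return validate_design(df)


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"design table missing columns: {missing}")
    dup = df.duplicated(subset=["monitor_file", "channel"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["monitor_file", "channel"]].tolist()
        raise ConfigurationError(f"duplicate (monitor_file, channel) pair {pair} in design")
    bad = set(df["protocol"].unique()) - set(KNOWN_PROTOCOLS)
    if bad:
        raise ConfigurationError(
            f"unknown protocol(s) {sorted(bad)} in design; known: {KNOWN_PROTOCOLS}"
        )
    return df


def assemble_traces(files: Mapping[str, "MonitorData | str | Path"],
                    design: pd.DataFrame, bin_width: int = 1) -> list[ActivityTrace]:
    """Build one :class:`ActivityTrace` per design row, trimmed to the common interval.

    ``files`` maps the monitor_file names used in the design to parsed
    :class:`MonitorData` or on-disk paths.  When several monitors were
    started at different wall-clock times, all traces are trimmed to the
    intersection of their recording intervals so every fly shares one axis.
    """
    design = validate_design(design)
    parsed: dict[str, MonitorData] = {}
    for name, item in files.items():
        parsed[name] = item if isinstance(item, MonitorData) else read_dam_file(item, bin_width)
    if not parsed:
        raise EmptyInputError("no monitor files")
    for md in parsed.values():
        if md.bin_width != bin_width:
            raise ConfigurationError("all monitor data must share the requested bin width")

    start = max(md.start_datetime for md in parsed.values())
    end = min(md.end_datetime for md in parsed.values())
    if end <= start:
        raise ConfigurationError("monitor files have no overlapping recording interval")

    traces = []
    for row in design.itertuples(index=False):
        if row.monitor_file not in parsed:
            raise ChannelLookupError(f"design references unknown monitor file "
                                     f"{row.monitor_file!r}")
        md = parsed[row.monitor_file]
        series = md.series(int(row.channel))  # raises ChannelLookupError outside 1..32
        offset_bins = int((start - md.start_datetime).total_seconds() // 60) // bin_width
        n_bins = int((end - start).total_seconds() // 60) // bin_width
        traces.append(ActivityTrace(
            fly_id=str(row.fly_id),
            monitor_channel=int(row.channel),
            t0_zt=md.t0_zt + offset_bins * bin_width,
            bin_width=bin_width,
            counts=series[offset_bins: offset_bins + n_bins],
            light=md.light[offset_bins: offset_bins + n_bins],
            meta={"sex": row.sex, "genotype": row.genotype,
                  "treatment": row.treatment, "protocol": row.protocol},
        ))
    return traces
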