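"""Trikinetics DAM monitor file I/O, binning and the survivor filter.

The reader/writer speak the DAMSystem3 single-beam dialect: one line per
minute, 42 tab-separated fields — reading index, date (``dd Mmm yy``), time
(``HH:MM:SS``), a status code (1 = valid reading) and six auxiliary fields,
followed by 32 beam-crossing counts for channels 1–32.

Minutes with an invalid status code, and any gaps in the timestamp sequence,
are represented as missing (NaN) — never as silent zeros — because a zero is
a meaningful behavioral observation while a dropped reading is not.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schedule import MINUTES_PER_DAY, LightSchedule

__all__ = [
    "MonitorData",
    "SurvivalReport",
    "DamParseError",
    "parse_dam_text",
    "write_dam_text",
    "read_dam_file",
    "write_dam_file",
    "read_activity_csv",
    "bin_series",
    "filter_survivors",
]

N_CHANNELS = 32
VALID_STATUS = 1

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_MONTH_INDEX = {m.lower(): i + 1 for i, m in enumerate(_MONTHS)}


class DamParseError(ValueError):
    """Malformed DAM monitor file."""


@dataclass
class SurvivalReport:
    """Per-fly alive/dead verdicts and the death rule that produced them."""

    table: pd.DataFrame  # fly_id, genotype, status, death_minute
    death_run_hours: float
    window_days: tuple[int, int]

    @property
    def n_dead(self) -> int:
        return int((self.table["status"] == "dead").sum())

    @property
    def n_alive(self) -> int:
        return int((self.table["status"] == "alive").sum())


class MonitorData:
    """Per-fly, per-minute activity counts plus metadata.

    Attributes
    ----------
    counts : float array, shape (n_flies, n_minutes); NaN marks missing.
    timestamps : one entry per recorded minute, strictly increasing, gap-free.
    flies : DataFrame indexed by fly_id with columns ``monitor``, ``channel``,
        ``genotype``, ``sex`` (simulated data adds ground-truth columns).
    schedule : optional :class:`LightSchedule` anchoring ZT/CT.
    status : per-minute DAM status codes (1 = valid).
    """

    def __init__(
        self,
        counts: np.ndarray,
        timestamps: pd.DatetimeIndex,
        flies: pd.DataFrame,
        schedule: LightSchedule | None = None,
        status: np.ndarray | None = None,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (flies x minutes)")
        if counts.shape[1] != len(timestamps):
            raise ValueError("counts columns must match timestamps")
        if counts.shape[0] != len(flies):
            raise ValueError("counts rows must match fly metadata")
        with np.errstate(invalid="ignore"):
            if np.nanmin(counts, initial=0) < 0:
                raise ValueError("counts must be non-negative")
        dup = flies.duplicated(subset=["monitor", "channel"])
        if dup.any():
            raise ValueError("duplicate monitor/channel in fly metadata")
        if (flies["genotype"].astype(str) == "").any():
            raise ValueError("genotype labels must be non-empty")
        self.counts = counts
        self.timestamps = pd.DatetimeIndex(timestamps)
        self.flies = flies
        self.schedule = schedule
        self.status = (
            np.full(counts.shape[1], VALID_STATUS, dtype=int)
            if status is None
            else np.asarray(status, dtype=int)
        )

    # -- dimensions ------------------------------------------------------
    @property
    def n_flies(self) -> int:
        return self.counts.shape[0]

    @property
    def n_minutes(self) -> int:
        return self.counts.shape[1]

    @property
    def fly_ids(self) -> list[str]:
        return list(self.flies.index)

    # -- time alignment --------------------------------------------------
    @property
    def anchor(self) -> pd.Timestamp:
        """The ZT0 instant at or before the first timestamp."""
        if self.schedule is None:
            raise ValueError("no schedule attached")
        t0 = self.timestamps[0]
        cand = t0.normalize() + pd.Timedelta(hours=self.schedule.reference_lights_on)
        if cand > t0:
            cand -= pd.Timedelta(days=1)
        return cand

    def experiment_minutes(self) -> np.ndarray:
        """Minute index since ZT0 of day 0 for every recorded column."""
        delta = (self.timestamps - self.anchor) / pd.Timedelta(minutes=1)
        return np.round(np.asarray(delta)).astype(int)

    def zt_hours(self) -> np.ndarray:
        return (self.experiment_minutes() / 60.0) % 24.0

    def day_index(self) -> np.ndarray:
        return self.experiment_minutes() // MINUTES_PER_DAY

    def aligned_counts(self, fly: str | int) -> np.ndarray:
        """Fly's counts on the full experiment-minute grid (NaN-padded)."""
        if self.schedule is None:
            raise ValueError("no schedule attached")
        row = self.counts[self._fly_row(fly)]
        out = np.full(self.schedule.n_days * MINUTES_PER_DAY, np.nan)
        m = self.experiment_minutes()
        ok = (m >= 0) & (m < out.size)
        out[m[ok]] = row[ok]
        return out

    def _fly_row(self, fly: str | int) -> int:
        if isinstance(fly, str):
            return int(self.flies.index.get_loc(fly))
        return int(fly)

    # -- subsetting ------------------------------------------------------
    def select_flies(self, fly_ids: Sequence[str]) -> "MonitorData":
        rows = [self._fly_row(f) for f in fly_ids]
        return MonitorData(
            self.counts[rows],
            self.timestamps,
            self.flies.iloc[rows],
            self.schedule,
            self.status,
        )

    # -- export ----------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Canonical long format: fly_id, genotype, timestamp, zt, phase, count."""
        zt = self.zt_hours() if self.schedule is not None else np.full(self.n_minutes, np.nan)
        if self.schedule is not None:
            days = np.clip(self.day_index(), 0, self.schedule.n_days - 1)
            phase = np.array([self.schedule.regime_of_day(int(d)) for d in days])
        else:
            phase = np.array([""] * self.n_minutes)
        frames = []
        for i, fid in enumerate(self.fly_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "fly_id": fid,
                        "genotype": self.flies["genotype"].iloc[i],
                        "timestamp": self.timestamps,
                        "zt": np.round(zt, 6),
                        "phase": phase,
                        "count": self.counts[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonitorData):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts, equal_nan=True)
            and self.timestamps.equals(other.timestamps)
            and self.flies.index.equals(other.flies.index)
            and np.array_equal(self.status, other.status)
        )


def _default_flies(monitor: int) -> pd.DataFrame:
    ids = [f"M{monitor:02d}C{c:02d}" for c in range(1, N_CHANNELS + 1)]
    return pd.DataFrame(
        {
            "monitor": monitor,
            "channel": range(1, N_CHANNELS + 1),
            "genotype": "unknown",
            "sex": "male",
        },
        index=pd.Index(ids, name="fly_id"),
    )


def _parse_datetime(date_s: str, time_s: str, lineno: int) -> pd.Timestamp:
    try:
        day_s, mon_s, yr_s = date_s.strip().split()
        month = _MONTH_INDEX[mon_s.lower()]
        hh, mm, ss = (int(v) for v in time_s.strip().split(":"))
        return pd.Timestamp(
            year=2000 + int(yr_s), month=month, day=int(day_s),
            hour=hh, minute=mm, second=ss,
        )
    except (KeyError, ValueError) as exc:
        raise DamParseError(f"line {lineno}: bad date/time {date_s!r} {time_s!r}") from exc


def parse_dam_text(
    lines: Iterable[str],
    channel_map: Mapping[int, Mapping[str, str]] | pd.DataFrame | None = None,
    schedule: LightSchedule | None = None,
    monitor: int = 1,
) -> MonitorData:
    """Parse DAMSystem3 monitor lines into a :class:`MonitorData`.

    ``channel_map`` maps channel number (1–32) to ``{"genotype": ..., "sex": ...}``;
    unmapped channels get genotype ``"unknown"``.  Rows whose status code is
    not 1 become missing minutes for all channels.  Malformed lines,
    duplicate timestamps and non-monotonic timestamps raise
    :class:`DamParseError` naming the line.
    """
    times: list[pd.Timestamp] = []
    rows: list[np.ndarray] = []
    statuses: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 10 + N_CHANNELS:
            raise DamParseError(
                f"line {lineno}: expected {10 + N_CHANNELS} fields, got {len(fields)}"
            )
        ts = _parse_datetime(fields[1], fields[2], lineno)
        try:
            status = int(fields[3])
            counts = np.array([int(v) for v in fields[10:10 + N_CHANNELS]], dtype=float)
        except ValueError as exc:
            raise DamParseError(f"line {lineno}: non-integer field") from exc
        if times:
            if ts == times[-1]:
                raise DamParseError(f"line {lineno}: duplicate timestamp {ts}")
            if ts < times[-1]:
                raise DamParseError(f"line {lineno}: non-monotonic timestamp {ts}")
        if status != VALID_STATUS:
            counts[:] = np.nan
        times.append(ts)
        rows.append(counts)
        statuses.append(status)
    if not times:
        return MonitorData(
            np.empty((N_CHANNELS, 0)),
            pd.DatetimeIndex([]),
            _apply_channel_map(_default_flies(monitor), channel_map),
            schedule,
            np.empty(0, dtype=int),
        )
    # fill timestamp gaps with missing minutes
    full_index = pd.date_range(times[0], times[-1], freq="min")
    counts = np.full((len(full_index), N_CHANNELS), np.nan)
    status_arr = np.zeros(len(full_index), dtype=int)
    pos = full_index.get_indexer(pd.DatetimeIndex(times))
    if (pos < 0).any():
        raise DamParseError("timestamps are not on a whole-minute grid")
    counts[pos] = np.vstack(rows)
    status_arr[pos] = statuses
    flies = _apply_channel_map(_default_flies(monitor), channel_map)
    return MonitorData(counts.T, full_index, flies, schedule, status_arr)


def _apply_channel_map(flies: pd.DataFrame, channel_map) -> pd.DataFrame:
    if channel_map is None:
        return flies
    flies = flies.copy()
    if isinstance(channel_map, pd.DataFrame):
        it = ((int(r["channel"]), r) for _, r in channel_map.iterrows())
    else:
        it = channel_map.items()
    for ch, meta in it:
        if not 1 <= int(ch) <= N_CHANNELS:
            raise ValueError(f"channel {ch} outside 1..{N_CHANNELS}")
        sel = flies["channel"] == int(ch)
        flies.loc[sel, "genotype"] = str(meta["genotype"])
        if "sex" in meta:
            flies.loc[sel, "sex"] = str(meta["sex"])
    return flies


def write_dam_text(data: MonitorData) -> list[str]:
    """Serialize to DAMSystem3 lines; inverse of :func:`parse_dam_text`.

    Minutes whose counts are missing for *all* flies are written with an
    invalid status code (and zero counts); partial per-fly missingness has no
    representation in the monitor dialect and raises.
    """
    if data.n_flies > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} flies per monitor file")
    channels = data.flies["channel"].to_numpy() if data.n_flies else np.array([], dtype=int)
    lines = []
    for j in range(data.n_minutes):
        col = data.counts[:, j]
        missing = np.isnan(col)
        status = int(data.status[j])
        if missing.all() and data.n_flies:
            if status == VALID_STATUS:
                status = 51  # generic invalid-reading code
            row_counts = np.zeros(N_CHANNELS, dtype=int)
        elif missing.any():
            raise ValueError(
                f"minute {j}: per-fly missingness is not representable in DAM text"
            )
        else:
            row_counts = np.zeros(N_CHANNELS, dtype=int)
            row_counts[channels - 1] = col.astype(int)
        ts = data.timestamps[j]
        date_s = f"{ts.day:02d} {_MONTHS[ts.month - 1]} {ts.year % 100:02d}"
        time_s = f"{ts.hour:02d}:{ts.minute:02d}:{ts.second:02d}"
        fields = [str(j + 1), date_s, time_s, str(status)] + ["0"] * 6
        fields += [str(v) for v in row_counts]
        lines.append("\t".join(fields))
    return lines


def read_dam_file(path, **kwargs) -> MonitorData:
    with open(path) as fh:
        return parse_dam_text(fh, **kwargs)


def write_dam_file(data: MonitorData, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(write_dam_text(data)))
        fh.write("\n")


def read_activity_csv(path_or_buf, schedule: LightSchedule | None = None) -> MonitorData:
    """Plain-CSV interchange reader: columns fly_id, timestamp, count
    (optional genotype, sex).  Wide-format alternative to the DAM dialect."""
    df = pd.read_csv(path_or_buf, parse_dates=["timestamp"])
    wide = df.pivot(index="fly_id", columns="timestamp", values="count")
    wide = wide.sort_index(axis=1)
    ts = pd.DatetimeIndex(wide.columns)
    meta = pd.DataFrame(
        {
            "monitor": 1,
            "channel": range(1, len(wide.index) + 1),
            "genotype": "unknown",
            "sex": "male",
        },
        index=pd.Index(wide.index, name="fly_id"),
    )
    for colname in ("genotype", "sex"):
        if colname in df.columns:
            meta[colname] = df.groupby("fly_id")[colname].first().reindex(wide.index)
    return MonitorData(wide.to_numpy(dtype=float), ts, meta, schedule)


def bin_series(counts: Sequence[float] | np.ndarray, minutes_per_bin: int) -> np.ndarray:
    """Sum per-minute counts into fixed-width bins.

    A bin containing any missing minute is missing; a trailing partial bin is
    dropped.  Conserves total counts over complete bins.
    """
    w = int(minutes_per_bin)
    if w < 1:
        raise ValueError("minutes_per_bin must be >= 1")
    x = np.asarray(counts, dtype=float)
    nb = x.size // w
    return x[: nb * w].reshape(nb, w).sum(axis=1)


def filter_survivors(
    data: MonitorData,
    window_days: tuple[int, int],
    death_run_hours: float = 24.0,
) -> tuple[MonitorData, SurvivalReport]:
    """Apply the dead-fly filter over an analysis window of experiment days.

    A fly is dead iff its counts are all zero from some minute through the
    end of the half-open window ``[d0, d1)`` and that terminal zero run lasts
    at least ``death_run_hours``.  Missing minutes neither start nor break a
    zero run.  Dead flies are removed from the returned subset.
    """
    d0, d1 = window_days
    if d1 <= d0:
        raise ValueError("empty analysis window")
    if data.schedule is None:
        raise ValueError("schedule required to resolve day windows")
    if d0 < 0 or d1 > data.schedule.n_days:
        raise ValueError("analysis window outside recording")
    run_min = float(death_run_hours) * 60.0
    statuses, death_minutes = [], []
    lo, hi = d0 * MINUTES_PER_DAY, d1 * MINUTES_PER_DAY
    for fid in data.fly_ids:
        w = data.aligned_counts(fid)[lo:hi]
        active = np.flatnonzero(w > 0)
        last_active = active[-1] if active.size else -1
        terminal_zero = len(w) - (last_active + 1)
        if terminal_zero >= run_min:
            statuses.append("dead")
            death_minutes.append(lo + last_active + 1)
        else:
            statuses.append("alive")
            death_minutes.append(-1)
    table = pd.DataFrame(
        {
            "genotype": data.flies["genotype"].to_numpy(),
            "status": statuses,
            "death_minute": death_minutes,
        },
        index=data.flies.index.copy(),
    )
    report = SurvivalReport(table, float(death_run_hours), (d0, d1))
    alive_ids = [f for f, s in zip(data.fly_ids, statuses) if s == "alive"]
    return data.select_flies(alive_ids), report
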