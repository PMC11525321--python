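"""Reading, writing, resampling and gap-flagging of continuous annotation traces.

Raw traces arrive as *event logs*: ordered ``(timestamp, value)`` pairs produced
by a changes-only logger (a PAGAN-style web annotator or anything similar), with
values on a bounded interval scale (default -100..100).  Downstream stages work
on :class:`Annotation` objects: uniform-rate sample grids with NaN marking the
spans where the logger was silent while the value changed — i.e. where linear
interpolation would invent data.

Two plain-text dialects are supported:

``simple_csv``
    header ``time_s,value``; one event per row.
``pagan_csv``
    header ``participant,stimulus,timestamp_ms,value``; timestamps in
    milliseconds are converted to seconds on load.

Grid conventions used package-wide: the sample grid starts at the first event
time, is 0-based and endpoint-inclusive, and region windows elsewhere are
half-open ``[start, end)`` in samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ParseError, RangeError

__all__ = [
    "RawEventLog",
    "Annotation",
    "load_event_log",
    "write_event_log",
    "resample",
    "read_annotation_csv",
    "write_annotation_csv",
]

DIALECTS = ("simple_csv", "pagan_csv")


@dataclass
class RawEventLog:
    """A changes-only event log from one annotator watching one stimulus.

    ``events`` is an ordered sequence of ``(timestamp_s, value)`` pairs with
    strictly increasing timestamps and values within ``[v_min, v_max]``.
    """

    annotator_id: str
    stimulus_id: str
    events: list[tuple[float, float]]
    v_min: float = -100.0
    v_max: float = 100.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParseError("event timestamps must be strictly increasing")
        for t, v in self.events:
            if t < 0:
                raise ParseError(f"negative timestamp {t}")
            if not (self.v_min <= v <= self.v_max):
                raise RangeError(
                    f"value {v} outside scale bounds [{self.v_min}, {self.v_max}]"
                )


@dataclass
class Annotation:
    """One rater's construct trace on a uniform time grid.

    ``values`` holds one float per grid sample with ``NaN`` marking missing
    data (the gap rule below).  ``delta`` is the sampling period used as the
    finite-difference step by the trend-agreement machinery.
    """

    annotator_id: str
    stimulus_id: str
    rate_hz: float
    values: np.ndarray
    t0: float = 0.0
    v_min: float = -100.0
    v_max: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DegenerateInputError("an annotation needs at least 2 samples")
        if self.rate_hz <= 0:
            raise DegenerateInputError("rate_hz must be positive")

    @property
    def delta(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.delta

    def __len__(self) -> int:
        return int(self.values.size)


def load_event_log(
    path: str | Path,
    dialect: str = "simple_csv",
    annotator_id: str = "",
    stimulus_id: str = "",
    v_min: float = -100.0,
    v_max: float = 100.0,
) -> RawEventLog:
    """Read a changes-only event log in one of the plain-text dialects.

    ``annotator_id``/``stimulus_id`` override the ids for ``simple_csv``
    (which does not carry them); ``pagan_csv`` takes them from its columns.
    Raises :class:`ParseError` naming the offending line on malformed rows and
    :class:`RangeError` on out-of-bounds values.
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    events: list[tuple[float, float]] = []
    ids = (annotator_id, stimulus_id)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        expected = (
            ["time_s", "value"]
            if dialect == "simple_csv"
            else ["participant", "stimulus", "timestamp_ms", "value"]
        )
        if header is None or [h.strip() for h in header] != expected:
            raise ParseError(f"{path}: line 1: expected header {','.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                if dialect == "simple_csv":
                    t, v = float(row[0]), float(row[1])
                else:
                    ids = (row[0].strip(), row[1].strip())
                    t, v = float(row[2]) / 1000.0, float(row[3])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row {row!r}") from exc
            events.append((t, v))
    return RawEventLog(ids[0], ids[1], events, v_min=v_min, v_max=v_max)


def write_event_log(log: RawEventLog, path: str | Path, dialect: str = "simple_csv") -> None:
    """Write an event log in the named dialect (inverse of :func:`load_event_log`)."""
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "simple_csv":
            writer.writerow(["time_s", "value"])
            for t, v in log.events:
                writer.writerow([repr(float(t)), repr(float(v))])
        else:
            writer.writerow(["participant", "stimulus", "timestamp_ms", "value"])
            for t, v in log.events:
                writer.writerow(
                    [log.annotator_id, log.stimulus_id, repr(float(t) * 1000.0), repr(float(v))]
                )


def resample(
    log: RawEventLog,
    rate_hz: float = 1.0,
    max_const_hold: float | None = None,
    gap_tol_s: float | None = None,
) -> Annotation:
    """Resample an event log onto a uniform grid with linear interpolation.

    The grid starts at the first event time and ends at (the grid point at or
    before) the last event time.  Changes-only logging makes two cases of
    logger silence fundamentally different:

    * equal values on both ends of a silent span — a valid constant hold
      (nothing was logged because nothing changed);
    * different values with nothing logged in between — lost data, so grid
      points strictly inside any such span longer than ``gap_tol_s`` are
      marked NaN instead of being invented by interpolation.

    ``gap_tol_s`` defaults to two grid periods: silent spans shorter than that
    are ordinary logger cadence and are interpolated.  ``max_const_hold``, when
    set, additionally flags the interior of equal-valued holds longer than the
    given number of seconds (a guard against annotator inattention; ``None``
    trusts holds of any length).
    """
    if len(log.events) < 2:
        raise DegenerateInputError("resample needs at least 2 events")
    if rate_hz <= 0:
        raise DegenerateInputError("rate_hz must be positive")
    delta = 1.0 / rate_hz
    if gap_tol_s is None:
        gap_tol_s = 2.0 * delta

    times = np.array([t for t, _ in log.events])
    vals = np.array([v for _, v in log.events])
    t0, t_end = times[0], times[-1]
    n = int(np.floor((t_end - t0) * rate_hz + 1e-9)) + 1
    n = max(n, 2)
    grid = t0 + np.arange(n) * delta

    out = np.interp(grid, times, vals, right=vals[-1])
    # Gap rule: applied to the raw event stream, before trusting interpolation.
    for (ta, va), (tb, vb) in zip(log.events, log.events[1:]):
        span = tb - ta
        flag = (va != vb and span > gap_tol_s + 1e-12) or (
            va == vb and max_const_hold is not None and span > max_const_hold + 1e-12
        )
        if flag:
            inside = (grid > ta + 1e-12) & (grid < tb - 1e-12)
            out[inside] = np.nan
    return Annotation(
        log.annotator_id,
        log.stimulus_id,
        rate_hz,
        out,
        t0=float(t0),
        v_min=log.v_min,
        v_max=log.v_max,
    )


def write_annotation_csv(ann: Annotation, path: str | Path) -> None:
    """Write a resampled annotation as ``time_s,value`` (empty field = missing)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(ann.times, ann.values):
            writer.writerow([repr(float(t)), "" if np.isnan(v) else repr(float(v))])


def read_annotation_csv(
    path: str | Path,
    annotator_id: str = "",
    stimulus_id: str = "",
    v_min: float = -100.0,
    v_max: float = 100.0,
) -> Annotation:
    """Read a ``time_s,value`` annotation CSV written by :func:`write_annotation_csv`.

    The grid must be uniform; the rate is inferred from the time column.
    """
    path = Path(path)
    ts: list[float] = []
    vs: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["time_s", "value"]:
            raise ParseError(f"{path}: line 1: expected header time_s,value")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                ts.append(float(row[0]))
                vs.append(float(row[1]) if row[1].strip() else np.nan)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row {row!r}") from exc
    if len(ts) < 2:
        raise DegenerateInputError(f"{path}: needs at least 2 samples")
    steps = np.diff(ts)
    if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ParseError(f"{path}: time grid is not uniform")
    return Annotation(
        annotator_id,
        stimulus_id,
        1.0 / steps[0],
        np.array(vs),
        t0=ts[0],
        v_min=v_min,
        v_max=v_max,
    )
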