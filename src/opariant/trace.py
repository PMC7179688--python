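"""Per-fly trace files and the fly-attribute table.

The canonical trace dialect is a UTF-8 CSV with header
``time_s,position_mm,laser_on,session``: uniformly sampled, 0-based time,
position in millimetres along the chamber axis, a binary laser flag and one
of the five session labels per sample.  Each session occupies one contiguous
block and the five blocks appear in protocol order.  Attributes (group,
triplet, genotype, sex, eclosion date, procedure-error flag) live in a
separate CSV keyed by ``fly_id``.

Reading validates structure and reports the offending row and field; writing
emits a canonical form such that ``write(read(f))`` is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import GROUPS, SESSION_ORDER

TRACE_COLUMNS = ("time_s", "position_mm", "laser_on", "session")
ATTR_COLUMNS = ("fly_id", "group", "triplet_id", "genotype", "sex",
                "eclosion_date", "procedure_error")
#: Attribute fields that must be non-empty for a record to count as complete.
REQUIRED_ATTRS = ("fly_id", "group", "triplet_id", "genotype", "sex",
                  "eclosion_date")


class TraceFormatError(ValueError):
    """Structural problem in a trace or attribute file."""


@dataclass(frozen=True)
class SessionWindow:
    """Half-open sample-index window ``[start, stop)`` of one session."""

    label: str
    start: int
    stop: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    def duration(self, dt: float) -> float:
        return self.n_samples * dt


@dataclass
class PositionTrace:
    """One fly's uniformly sampled position + laser time-series.

    Sample ``i`` covers the half-open time interval ``[i*dt, (i+1)*dt)``.
    """

    fly_id: str
    dt: float
    position: np.ndarray
    laser_on: np.ndarray
    sessions: List[SessionWindow]

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.laser_on = np.asarray(self.laser_on, dtype=np.uint8)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.position)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def window(self, label: str) -> SessionWindow:
        for w in self.sessions:
            if w.label == label:
                return w
        raise KeyError(f"trace {self.fly_id} has no session {label!r}")

    def session_labels(self) -> np.ndarray:
        out = np.empty(self.n_samples, dtype=object)
        for w in self.sessions:
            out[w.start:w.stop] = w.label
        return out

    def validate(self, chamber_length: Optional[float] = None) -> None:
        if self.dt <= 0:
            raise TraceFormatError(f"{self.fly_id}: dt must be positive")
        if len(self.laser_on) != len(self.position):
            raise TraceFormatError(
                f"{self.fly_id}: position and laser length mismatch")
        bad = ~np.isin(self.laser_on, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TraceFormatError(
                f"{self.fly_id}: laser_on must be 0/1 (row {row})")
        if (self.position < 0).any():
            row = int(np.flatnonzero(self.position < 0)[0])
            raise TraceFormatError(
                f"{self.fly_id}: negative position (row {row})")
        if chamber_length is not None and (self.position > chamber_length).any():
            row = int(np.flatnonzero(self.position > chamber_length)[0])
            raise TraceFormatError(
                f"{self.fly_id}: position beyond chamber (row {row})")
        labels = [w.label for w in self.sessions]
        if labels != list(SESSION_ORDER):
            raise TraceFormatError(
                f"{self.fly_id}: sessions {labels} != {list(SESSION_ORDER)}")
        cursor = 0
        for w in self.sessions:
            if w.start != cursor or w.stop <= w.start:
                raise TraceFormatError(
                    f"{self.fly_id}: session windows must be contiguous, "
                    f"non-empty and ordered ({w.label})")
            cursor = w.stop
        if cursor != self.n_samples:
            raise TraceFormatError(
                f"{self.fly_id}: session windows do not cover the trace")


@dataclass(frozen=True)
class FlyRecord:
    """One row of the attribute table, with validation flags."""

    fly_id: str
    group: str
    triplet_id: str
    genotype: str = ""
    sex: str = ""
    eclosion_date: str = ""
    procedure_error: bool = False
    attribute_complete: bool = True
    triplet_complete: bool = True


def write_trace(trace: PositionTrace, path) -> None:
    """Write a trace in the canonical CSV form."""
    n = trace.n_samples
    df = pd.DataFrame({
        "time_s": np.arange(n) * trace.dt,
        "position_mm": trace.position,
        "laser_on": trace.laser_on.astype(int),
        "session": trace.session_labels(),
    })
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")


def read_trace(path, fly_id: Optional[str] = None) -> PositionTrace:
    """Read and validate a canonical trace CSV.

    ``fly_id`` defaults to the file stem.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
    if len(df) < 2:
        raise TraceFormatError(f"{path}: trace needs at least 2 samples")

    times = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(times)
    if (steps <= 0).any():
        row = int(np.flatnonzero(steps <= 0)[0]) + 1
        raise TraceFormatError(
            f"{path}: time_s not strictly increasing at row {row}")
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=0, atol=dt * 1e-3):
        row = int(np.flatnonzero(np.abs(steps - dt) > dt * 1e-3)[0]) + 1
        raise TraceFormatError(f"{path}: non-uniform sampling at row {row}")

    laser = df["laser_on"].to_numpy()
    bad = ~np.isin(laser, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise TraceFormatError(
            f"{path}: laser_on must be 0 or 1 (row {row}, "
            f"value {laser[bad][0]!r})")

    labels = df["session"].to_numpy(dtype=object)
    unknown = ~np.isin(labels, SESSION_ORDER)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise TraceFormatError(
            f"{path}: unknown session label {labels[row]!r} (row {row})")
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(labels)]))
    windows = [SessionWindow(str(labels[a]), int(a), int(b))
               for a, b in zip(starts, stops)]
    block_labels = [w.label for w in windows]
    if block_labels != list(SESSION_ORDER):
        raise TraceFormatError(
            f"{path}: session blocks {block_labels} are not the five "
            f"sessions in protocol order")

    return PositionTrace(
        fly_id=fly_id if fly_id is not None else path.stem,
        dt=dt,
        position=df["position_mm"].to_numpy(dtype=float),
        laser_on=laser.astype(np.uint8),
        sessions=windows,
    )


def write_attributes(records, path) -> None:
    """Write the attribute table (one row per fly)."""
    rows = [{
        "fly_id": r.fly_id, "group": r.group, "triplet_id": r.triplet_id,
        "genotype": r.genotype, "sex": r.sex,
        "eclosion_date": r.eclosion_date,
        "procedure_error": int(bool(r.procedure_error)),
    } for r in records]
    pd.DataFrame(rows, columns=list(ATTR_COLUMNS)).to_csv(
        path, index=False, lineterminator="\n")


def read_attributes(path) -> List[FlyRecord]:
    """Read the attribute table; flag rather than drop incomplete rows.

    Errors on duplicate ``fly_id``; a triplet missing one of the three group
    members gets ``triplet_complete=False`` on all its records (curation
    decides what to do with flags — reading never drops data).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("fly_id", "group", "triplet_id"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
    dup = df["fly_id"][df["fly_id"].duplicated()]
    if not dup.empty:
        raise TraceFormatError(
            f"{path}: duplicate fly_id {dup.iloc[0]!r}")

    bad_group = ~df["group"].isin(GROUPS) & (df["group"] != "")
    if bad_group.any():
        row = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise TraceFormatError(
            f"{path}: unknown group {df['group'].iloc[row]!r} (row {row})")

    complete_by_triplet = df[df["group"].isin(GROUPS)].groupby(
        "triplet_id")["group"].nunique()

    records = []
    for _, row in df.iterrows():
        missing = [c for c in REQUIRED_ATTRS
                   if c not in df.columns or str(row.get(c, "")).strip() == ""]
        triplet = str(row["triplet_id"])
        records.append(FlyRecord(
            fly_id=str(row["fly_id"]),
            group=str(row["group"]),
            triplet_id=triplet,
            genotype=str(row.get("genotype", "")),
            sex=str(row.get("sex", "")),
            eclosion_date=str(row.get("eclosion_date", "")),
            procedure_error=str(row.get("procedure_error", "0")).strip()
            in ("1", "True", "true"),
            attribute_complete=not missing,
            triplet_complete=bool(
                complete_by_triplet.get(triplet, 0) == len(GROUPS)),
        ))
    return records


def records_frame(records) -> pd.DataFrame:
    """Attribute records as a DataFrame (validation flags included)."""
    return pd.DataFrame([r.__dict__ for r in records])
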