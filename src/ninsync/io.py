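"""Session file I/O and stream alignment.

All on-disk artifacts are comma-separated text with a mandatory header row
and "." decimal separator. Times are in seconds with session start at 0;
intervals are half-open [t0, t1).

Schemas
-------
traces.csv   : t, <cell_id_1>, <cell_id_2>, ...
accel.csv    : t, x, y, z            (acceleration in g)
events.csv   : cell_id, region, onset_s, amplitude
stim.csv     : onset_s, duration_s, site[, current_ma]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: LSM6DS3 accelerometer scale at the +/-2 g range: 0.061 mg per count.
G_PER_COUNT = 0.061e-3

#: Sensor range with a small tolerance for rail values after conversion.
ACCEL_RANGE_G = 2.05


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence with timestamps and per-cell region labels.

    Attributes
    ----------
    cell_ids : list of str
        Opaque cell identifiers, one per row of ``values``.
    region : list of str
        Per-cell region label (e.g. ``"CBL"``, ``"CTX"``).
    t : ndarray
        Per-frame timestamps in seconds, strictly increasing.
    values : ndarray, shape (n_cells, n_frames)
        Fluorescence in arbitrary units. No NaNs permitted.
    frame_rate_hz : float
        Nominal acquisition rate (30 frames/s for this scope).
    constant_cells : list of str
        Cells whose signal is all-constant; retained but flagged.
    """

    cell_ids: list[str]
    region: list[str]
    t: np.ndarray
    values: np.ndarray
    frame_rate_hz: float = 30.0
    constant_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("row count must equal number of cell ids")
        if len(self.region) != len(self.cell_ids):
            raise ValueError("one region label required per cell")
        if self.values.shape[1] != self.t.size:
            raise ValueError("column count must equal number of timestamps")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("non-monotone timestamps")
        if np.isnan(self.values).any():
            raise ValueError("missing values in trace matrix (gaps are an error)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        """Session length assuming one trailing frame interval."""
        if self.t.size < 2:
            return 0.0
        return float(self.t[-1] - self.t[0] + np.median(np.diff(self.t)))


@dataclass
class AccelRecord:
    """Three-axis accelerometer time series in g (nominal 104 Hz)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    nominal_rate_hz: float = 104.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise ValueError("t, x, y, z must have equal lengths")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("non-monotone timestamps")
        for name, ch in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(np.abs(ch) > ACCEL_RANGE_G):
                raise ValueError(
                    f"|{name}| exceeds sensor range {ACCEL_RANGE_G} g after conversion"
                )


@dataclass
class StimLog:
    """Optogenetic stimulation schedule."""

    onsets: np.ndarray
    duration_s: np.ndarray
    site: list[str]
    current_ma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        if self.duration_s.size == 1 and self.onsets.size > 1:
            self.duration_s = np.full(self.onsets.size, float(self.duration_s))
        if not np.all(np.diff(self.onsets) >= 0):
            raise ValueError("stimulus onsets must be sorted")
        if np.any(self.duration_s <= 0):
            raise ValueError("stimulus durations must be positive")
        if isinstance(self.site, str):
            self.site = [self.site] * self.onsets.size

    @property
    def n_stimuli(self) -> int:
        return self.onsets.size


@dataclass
class AlignmentMap:
    """Frame-to-accelerometer-sample correspondence.

    ``accel_index[i]`` is the accelerometer sample nearest in time to frame
    ``frame_index[i]``; ``offset_s`` is signed (frame time - accel time).
    Frames whose nearest sample lies farther than the tolerance are dropped
    and counted in ``n_dropped``.
    """

    frame_index: np.ndarray
    accel_index: np.ndarray
    offset_s: np.ndarray
    tolerance_s: float
    n_dropped: int


def imu_counts_to_g(counts) -> np.ndarray:
    """Convert raw signed accelerometer counts to g (0.061 mg per bit)."""
    return np.asarray(counts, dtype=float) * G_PER_COUNT


def read_trace_table(path, region_map: dict[str, str]) -> TraceMatrix:
    """Read a traces CSV (one ``t`` column + one column per cell).

    Parameters
    ----------
    path : str or pathlib.Path
    region_map : dict
        Maps every cell-id column to its region label. An unmapped cell id
        is a hard error naming the id.
    """
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError("traces table must have a 't' column")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("non-monotone timestamps")
    cell_ids = [c for c in df.columns if c != "t"]
    for cid in cell_ids:
        if cid not in region_map:
            raise KeyError(f"cell id {cid!r} missing from region_map")
    values = df[cell_ids].to_numpy(dtype=float).T
    if np.isnan(values).any():
        raise ValueError("missing values in trace table")
    frame_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 30.0
    constant = [cid for cid, row in zip(cell_ids, values) if np.ptp(row) == 0.0]
    return TraceMatrix(
        cell_ids=cell_ids,
        region=[region_map[c] for c in cell_ids],
        t=t,
        values=values,
        frame_rate_hz=frame_rate,
        constant_cells=constant,
    )


def write_trace_table(tm: TraceMatrix, path) -> None:
    df = pd.DataFrame({"t": tm.t})
    for cid, row in zip(tm.cell_ids, tm.values):
        df[cid] = row
    df.to_csv(path, index=False, float_format="%.17g")


def read_accel_table(path, nominal_rate_hz: float = 104.0) -> AccelRecord:
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"accel table must have a {col!r} column")
    return AccelRecord(
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
        nominal_rate_hz=nominal_rate_hz,
    )


def write_accel_table(rec: AccelRecord, path) -> None:
    pd.DataFrame({"t": rec.t, "x": rec.x, "y": rec.y, "z": rec.z}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_stim_table(path) -> StimLog:
    df = pd.read_csv(path)
    current = df["current_ma"].to_numpy(float) if "current_ma" in df.columns else None
    return StimLog(
        onsets=df["onset_s"].to_numpy(float),
        duration_s=df["duration_s"].to_numpy(float),
        site=df["site"].astype(str).tolist(),
        current_ma=current,
    )


def write_stim_table(log: StimLog, path) -> None:
    d = {"onset_s": log.onsets, "duration_s": log.duration_s, "site": log.site}
    if log.current_ma is not None:
        d["current_ma"] = log.current_ma
    pd.DataFrame(d).to_csv(path, index=False, float_format="%.17g")


def align_streams(frame_ts, accel_ts, tolerance_s: float = 0.015) -> AlignmentMap:
    """Map each imaging frame to the nearest accelerometer sample.

    Frames whose nearest sample is farther than ``tolerance_s`` are dropped
    and counted. Both series must be strictly increasing and non-empty.
    """
    frame_ts = np.asarray(frame_ts, dtype=float)
    accel_ts = np.asarray(accel_ts, dtype=float)
    if frame_ts.size == 0 or accel_ts.size == 0:
        raise ValueError("empty timestamp series")
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be positive")
    # nearest neighbour via searchsorted on the sorted accel series
    pos = np.searchsorted(accel_ts, frame_ts)
    left = np.clip(pos - 1, 0, accel_ts.size - 1)
    right = np.clip(pos, 0, accel_ts.size - 1)
    choose_right = np.abs(accel_ts[right] - frame_ts) < np.abs(
        accel_ts[left] - frame_ts
    )
    nearest = np.where(choose_right, right, left)
    offsets = frame_ts - accel_ts[nearest]
    keep = np.abs(offsets) <= tolerance_s
    return AlignmentMap(
        frame_index=np.nonzero(keep)[0],
        accel_index=nearest[keep],
        offset_s=offsets[keep],
        tolerance_s=tolerance_s,
        n_dropped=int((~keep).sum()),
    )
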