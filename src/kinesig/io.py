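"""Kinematic trial file I/O and the shared data model.

Trials are exchanged in two plain-text dialects common in motion capture:

* TRC — tab-separated marker trajectories (``DataRate``/``NumFrames``/``Units``
  header, X/Y/Z column triplets per marker), units mm or m.
* MOT/STO — joint-angle time series (free-form header terminated by
  ``endheader``, first column ``time``, angles in degrees unless the header
  says ``inDegrees=no``).

Internally everything is SI-ish: positions in meters, angles in degrees,
time in seconds, 0-based frames, vertical axis index 1 (Y-up) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConflictError, DataError, FormatError, SchemaError, UnitError

ACTIVITIES = (
    "walk",
    "run",
    "timed_up_and_go",
    "sit_to_stand",
    "calf_raise",
    "jump",
    "shoulder_abduction",
    "elbow_flexion",
    "arm_rom",
)

GROUPS = ("FSHD", "DM", "CTL")

#: Gaps (NaN runs) up to this many seconds are linearly interpolated at read
#: time; anything longer rejects the trial.
MAX_GAP_S = 0.1


@dataclass
class KinematicsRecording:
    """One trial of one activity: marker positions and joint angles.

    markers maps name -> (n_frames, 3) array in meters (ground-fixed frame);
    joint_angles maps name -> (n_frames,) array in degrees.
    """

    participant_id: str
    activity: str
    time: np.ndarray
    sampling_rate: float
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    joint_angles: dict[str, np.ndarray] = field(default_factory=dict)
    participant_height: float = float("nan")
    vertical_axis: int = 1
    session: int = 1

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_frames else 0.0

    def validate(self) -> "KinematicsRecording":
        if self.activity not in ACTIVITIES:
            raise SchemaError(f"unknown activity {self.activity!r}")
        if self.sampling_rate < 60:
            raise DataError(
                f"sampling rate {self.sampling_rate} Hz below the 60 Hz minimum"
            )
        if self.n_frames >= 2 and not np.all(np.diff(self.time) > 0):
            raise DataError("time vector is not strictly increasing")
        n = self.n_frames
        for name, arr in self.markers.items():
            if arr.shape != (n, 3):
                raise DataError(f"marker {name!r} has shape {arr.shape}, expected ({n}, 3)")
            if np.isnan(arr).any():
                raise DataError(f"marker {name!r} contains NaN after ingestion")
        for name, arr in self.joint_angles.items():
            if arr.shape != (n,):
                raise DataError(f"angle {name!r} has length {arr.shape}, expected {n}")
            if np.isnan(arr).any():
                raise DataError(f"angle {name!r} contains NaN after ingestion")
        return self


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    sex: str
    age: float
    height: float
    bmi: float
    session: int = 1

    def __post_init__(self):
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group label {self.group!r}")
        if not self.height > 0:
            raise DataError(f"participant {self.participant_id}: height must be > 0")


@dataclass(frozen=True)
class TFTRecord:
    """Human-measured timed-function-test times (s) and Brooke score."""

    participant_id: str
    walk10m_s: float | None = None
    run10m_s: float | None = None
    tug_s: float | None = None
    sts5x_s: float | None = None
    brooke: int | None = None

    def __post_init__(self):
        for name in ("walk10m_s", "run10m_s", "tug_s", "sts5x_s"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DataError(f"{self.participant_id}: {name} must be > 0, got {v}")
        if self.brooke is not None and self.brooke not in range(1, 7):
            raise DataError(f"{self.participant_id}: brooke must be in 1..6")


# ---------------------------------------------------------------------------
# gap handling


def _fill_gaps(arr: np.ndarray, rate: float, what: str) -> np.ndarray:
    """Linearly interpolate NaN runs <= MAX_GAP_S; reject longer gaps."""
    arr = np.asarray(arr, dtype=float)
    bad = np.isnan(arr)
    if not bad.any():
        return arr
    max_gap_frames = int(math.floor(MAX_GAP_S * rate))
    # find run lengths of consecutive NaNs
    idx = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    starts, ends = idx[0::2], idx[1::2]
    if bad[0] or bad[-1]:
        raise DataError(f"{what}: gap at trial boundary cannot be interpolated")
    for s, e in zip(starts, ends):
        if e - s > max_gap_frames:
            raise DataError(
                f"{what}: gap of {(e - s) / rate:.3f} s exceeds {MAX_GAP_S} s limit"
            )
    good = ~bad
    x = np.arange(len(arr))
    return np.interp(x, x[good], arr[good])


# ---------------------------------------------------------------------------
# TRC


def read_trc(
    path: str | Path,
    participant_id: str = "",
    activity: str = "walk",
    participant_height: float = float("nan"),
    vertical_axis: int = 1,
    session: int = 1,
) -> KinematicsRecording:
    """Read a TRC marker file into a KinematicsRecording (markers populated)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        units = header["Units"].strip()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header: {exc}") from None
    if units == "mm":
        scale = 1e-3
    elif units == "m":
        scale = 1.0
    else:
        raise UnitError(f"{path}: unsupported TRC units {units!r}")
    marker_row = lines[3].rstrip("\n").split("\t")
    marker_names = [m for m in marker_row[2:] if m.strip()]
    if len(set(marker_names)) != len(marker_names):
        dupes = sorted({m for m in marker_names if marker_names.count(m) > 1})
        raise SchemaError(f"{path}: duplicate marker names {dupes}")

    data_rows = [ln for ln in lines[5:] if ln.strip()]
    table = []
    for ln in data_rows:
        cells = ln.split("\t")
        table.append([float(c) if c.strip() else np.nan for c in cells])
    width = 2 + 3 * len(marker_names)
    data = np.full((len(table), width), np.nan)
    for i, row in enumerate(table):
        data[i, : min(len(row), width)] = row[:width]
    frames = data[:, 0]
    # time reconstructed from frame numbers and DataRate (header convention)
    time = (frames - frames[0]) / rate
    markers: dict[str, np.ndarray] = {}
    for j, name in enumerate(marker_names):
        xyz = data[:, 2 + 3 * j : 5 + 3 * j] * scale
        for ax in range(3):
            xyz[:, ax] = _fill_gaps(xyz[:, ax], rate, f"{path}:{name}")
        markers[name] = xyz
    return KinematicsRecording(
        participant_id=participant_id,
        activity=activity,
        time=time,
        sampling_rate=rate,
        markers=markers,
        participant_height=participant_height,
        vertical_axis=vertical_axis,
        session=session,
    ).validate()


def write_trc(rec: KinematicsRecording, path: str | Path, units: str = "m") -> None:
    """Write markers to a TRC file (inverse of read_trc)."""
    if units == "m":
        scale = 1.0
    elif units == "mm":
        scale = 1e3
    else:
        raise UnitError(f"unsupported TRC units {units!r}")
    path = Path(path)
    names = list(rec.markers)
    n = rec.n_frames
    rate = rec.sampling_rate
    out = []
    out.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    out.append(
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames"
    )
    out.append(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\t{units}\t{rate:g}\t1\t{n}")
    out.append("Frame#\tTime\t" + "\t\t\t".join(names) + ("\t\t" if names else ""))
    sub = ["", ""]
    for j in range(len(names)):
        sub += [f"X{j + 1}", f"Y{j + 1}", f"Z{j + 1}"]
    out.append("\t".join(sub))
    out.append("")
    for i in range(n):
        cells = [str(i + 1), f"{rec.time[i]:.10f}"]
        for name in names:
            cells += [f"{v * scale:.10f}" for v in rec.markers[name][i]]
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# MOT / STO


def read_mot(
    path: str | Path,
    participant_id: str = "",
    activity: str = "walk",
    participant_height: float = float("nan"),
    session: int = 1,
) -> KinematicsRecording:
    """Read a MOT/STO joint-angle file (joint_angles populated, degrees)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    in_degrees = True
    body_start = None
    for i, ln in enumerate(lines):
        low = ln.strip().lower()
        if low.startswith("indegrees"):
            in_degrees = low.split("=", 1)[1].strip() == "yes"
        if low == "endheader":
            body_start = i + 1
            break
    if body_start is None:
        raise FormatError(f"{path}: missing 'endheader' sentinel")
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if not body:
        raise FormatError(f"{path}: no data after endheader")
    cols = body[0].split()
    if not cols or cols[0] != "time":
        raise FormatError(f"{path}: first column must be 'time', got {cols[:1]}")
    if len(set(cols)) != len(cols):
        raise SchemaError(f"{path}: duplicate column names")
    try:
        data = np.array([[float(c) for c in ln.split()] for ln in body[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data row: {exc}") from None
    if data.ndim != 2 or data.shape[1] != len(cols):
        raise FormatError(f"{path}: ragged data table")
    time = data[:, 0]
    if len(time) >= 2 and not np.all(np.diff(time) > 0):
        raise DataError(f"{path}: time column not strictly increasing")
    rate = (len(time) - 1) / (time[-1] - time[0]) if len(time) > 1 else 60.0
    rate = float(np.round(rate, 3))
    angles: dict[str, np.ndarray] = {}
    for j, name in enumerate(cols[1:], start=1):
        col = _fill_gaps(data[:, j], rate, f"{path}:{name}")
        angles[name] = col if in_degrees else np.degrees(col)
    return KinematicsRecording(
        participant_id=participant_id,
        activity=activity,
        time=time,
        sampling_rate=rate,
        joint_angles=angles,
        participant_height=participant_height,
        session=session,
    ).validate()


def write_mot(rec: KinematicsRecording, path: str | Path) -> None:
    path = Path(path)
    names = list(rec.joint_angles)
    out = [
        path.stem,
        "version=1",
        f"nRows={rec.n_frames}",
        f"nColumns={len(names) + 1}",
        "inDegrees=yes",
        "endheader",
        "\t".join(["time"] + names),
    ]
    for i in range(rec.n_frames):
        cells = [f"{rec.time[i]:.10f}"] + [
            f"{rec.joint_angles[n][i]:.10f}" for n in names
        ]
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# cohort manifest


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[list[Participant], list[TFTRecord], pd.DataFrame]:
    """Read a cohort directory (manifest.csv, trials.csv, optional tfts.csv).

    manifest.csv: participant_id, session, group, sex, age, height_m, bmi
    trials.csv:   participant_id, session, activity, trc_file, mot_file
                  (file columns may be empty; paths relative to the directory)
    tfts.csv:     participant_id, walk10m_s, run10m_s, tug_s, sts5x_s, brooke
    """
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path} not found")
    manifest = pd.read_csv(manifest_path)
    participants: list[Participant] = []
    seen: set[tuple[str, int]] = set()
    for i, row in manifest.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise SchemaError(
                f"{manifest_path} row {i}: unknown group label {group!r} "
                f"(participant {row['participant_id']})"
            )
        key = (str(row["participant_id"]), int(row.get("session", 1)))
        if key in seen:
            raise ConflictError(f"{manifest_path} row {i}: duplicate participant-session {key}")
        seen.add(key)
        participants.append(
            Participant(
                participant_id=str(row["participant_id"]),
                group=group,
                sex=str(row["sex"]),
                age=float(row["age"]),
                height=float(row["height_m"]),
                bmi=float(row["bmi"]),
                session=int(row.get("session", 1)),
            )
        )

    tfts: list[TFTRecord] = []
    tft_path = cohort_dir / "tfts.csv"
    if tft_path.exists():
        tdf = pd.read_csv(tft_path)

        def _opt(row, col, cast=float):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)

        for _, row in tdf.iterrows():
            tfts.append(
                TFTRecord(
                    participant_id=str(row["participant_id"]),
                    walk10m_s=_opt(row, "walk10m_s"),
                    run10m_s=_opt(row, "run10m_s"),
                    tug_s=_opt(row, "tug_s"),
                    sts5x_s=_opt(row, "sts5x_s"),
                    brooke=_opt(row, "brooke", int),
                )
            )

    trials_path = cohort_dir / "trials.csv"
    if trials_path.exists():
        trials = pd.read_csv(trials_path).fillna("")
        dup = trials.duplicated(subset=["participant_id", "session", "activity"])
        if dup.any():
            bad = trials[dup].iloc[0]
            raise ConflictError(
                f"duplicate trial for ({bad['participant_id']}, "
                f"{bad['activity']}, session {bad['session']})"
            )
        for col in ("trc_file", "mot_file"):
            for i, fname in enumerate(trials[col]):
                if fname and not (cohort_dir / fname).exists():
                    raise SchemaError(
                        f"{trials_path} row {i}: dangling file reference {fname!r}"
                    )
        if (~trials["activity"].isin(ACTIVITIES)).any():
            bad = trials.loc[~trials["activity"].isin(ACTIVITIES), "activity"].iloc[0]
            raise SchemaError(f"{trials_path}: unknown activity {bad!r}")
    else:
        trials = pd.DataFrame(
            columns=["participant_id", "session", "activity", "trc_file", "mot_file"]
        )
    return participants, tfts, trials


def summarize_cohort(participants: Iterable[Participant]) -> dict:
    """Group sizes and percent-female arithmetic for a cohort table."""
    parts = [p for p in participants if p.session == 1]
    out: dict = {"n_total": len(parts)}
    for g in GROUPS:
        sub = [p for p in parts if p.group == g]
        out[f"n_{g}"] = len(sub)
        n_f = sum(1 for p in sub if p.sex == "F")
        out[f"n_female_{g}"] = n_f
        out[f"pct_female_{g}"] = 100.0 * n_f / len(sub) if sub else float("nan")
    n_f = sum(1 for p in parts if p.sex == "F")
    out["n_female"] = n_f
    out["pct_female"] = 100.0 * n_f / len(parts) if parts else float("nan")
    return out
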