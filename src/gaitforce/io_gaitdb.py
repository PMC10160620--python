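"""Read and write in-shoe force records and the cohort demographics table.

Force records follow the public Physionet gait-database dialect: plain
whitespace-delimited text, no header, one row per sample at a nominal
100 Hz, 19 numeric columns::

    time [s], 8 left-shoe sensors [N], 8 right-shoe sensors [N],
    left total [N], right total [N]

The two trailing per-foot totals are parsed and kept for cross-checking,
but every downstream computation recomputes totals as the row-wise sum of
the eight sensors of each shoe.

Demographics are a delimited table (comma or tab, sniffed) with a header
naming at least the subject id, group, body mass and walking speed; other
clinical columns are optional and preserved as ``None`` when absent.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, SchemaError

N_COLUMNS = 19
N_SENSORS = 8
#: mismatch between a parsed per-foot total column and the recomputed
#: sensor sum beyond this many newtons triggers a warning
TOTAL_TOLERANCE_N = 0.5

_GROUP_ALIASES = {
    "pd": "PD",
    "parkinson": "PD",
    "parkinsons": "PD",
    "patient": "PD",
    "control": "control",
    "co": "control",
    "ct": "control",
    "healthy": "control",
    "hc": "control",
}

_SEX_ALIASES = {"m": "M", "male": "M", "f": "F", "female": "F"}

#: accepted header spellings -> canonical SubjectMeta field
DEFAULT_COLUMN_MAP = {
    "subject_id": "subject_id",
    "id": "subject_id",
    "subject": "subject_id",
    "group": "group",
    "sex": "sex",
    "gender": "sex",
    "age": "age",
    "height": "height_cm",
    "height_cm": "height_cm",
    "body_mass": "body_mass_kg",
    "mass": "body_mass_kg",
    "weight": "body_mass_kg",
    "body_mass_kg": "body_mass_kg",
    "walking_speed": "walking_speed_mps",
    "speed": "walking_speed_mps",
    "ssws": "walking_speed_mps",
    "walking_speed_mps": "walking_speed_mps",
    "hoehn_yahr": "hoehn_yahr",
    "hy": "hoehn_yahr",
    "updrs": "updrs",
    "tug": "tug_s",
    "tug_s": "tug_s",
    "timed_up_and_go": "tug_s",
}

_MANDATORY = ("subject_id", "group", "body_mass_kg", "walking_speed_mps")


@dataclass
class SensorTrace:
    """Raw multichannel shoe-sensor recording for one subject.

    ``left_sensors`` and ``right_sensors`` are ``(n_samples, 8)`` arrays in
    newtons; ``sample_times`` is strictly increasing and nominally uniform.
    """

    subject_id: str
    sample_times: np.ndarray
    left_sensors: np.ndarray
    right_sensors: np.ndarray
    sampling_rate: float
    body_mass_kg: float | None = None
    #: per-foot total columns as parsed from file (None if synthesized)
    parsed_left_total: np.ndarray | None = None
    parsed_right_total: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.left_sensors = np.asarray(self.left_sensors, dtype=float)
        self.right_sensors = np.asarray(self.right_sensors, dtype=float)
        n = self.sample_times.shape[0]
        for name, arr in (("left_sensors", self.left_sensors),
                          ("right_sensors", self.right_sensors)):
            if arr.shape != (n, N_SENSORS):
                raise FormatError(
                    f"{name} has shape {arr.shape}, expected ({n}, {N_SENSORS})")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.sample_times.shape[0]

    def with_body_mass(self, body_mass_kg: float) -> "SensorTrace":
        return replace(self, body_mass_kg=body_mass_kg)


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and clinical scores for one subject.

    Clinical instruments (Hoehn–Yahr, UPDRS, timed-up-and-go) are consumed
    as given; ``None`` marks a value absent from the source table.
    """

    subject_id: str
    group: str                      # "PD" or "control"
    body_mass_kg: float
    walking_speed_mps: float | None
    sex: str = "unknown"            # "M", "F", "unknown"
    age: float | None = None
    height_cm: float | None = None
    hoehn_yahr: float | None = None
    updrs: float | None = None
    tug_s: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "control"):
            raise SchemaError(f"unknown group label {self.group!r}")
        if self.body_mass_kg is None or self.body_mass_kg <= 0:
            raise SchemaError(
                f"subject {self.subject_id}: body mass must be positive")


def _as_lines(source) -> tuple[list[str], str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        return path.read_text().splitlines(), str(path)
    text = source.read()
    if isinstance(text, bytes):
        text = text.decode()
    return text.splitlines(), "<stream>"


def read_force_record(source, subject_id: str,
                      body_mass_kg: float | None = None) -> SensorTrace:
    """Parse a 19-column force record from a path or open text stream.

    Raises :class:`FormatError` naming the offending line on malformed
    rows, and on a non-increasing time column. Negative force readings are
    clamped to zero (sensor baseline noise below true zero).
    """
    lines, origin = _as_lines(source)
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != N_COLUMNS:
            raise FormatError(
                f"{origin}, line {lineno}: expected {N_COLUMNS} columns, "
                f"got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(
                f"{origin}, line {lineno}: non-numeric value ({exc})") from None
    arr = np.array(rows, dtype=float).reshape(-1, N_COLUMNS)
    times = arr[:, 0]
    if len(times) > 1:
        dts = np.diff(times)
        if np.any(dts <= 0):
            bad = int(np.argmax(dts <= 0)) + 2
            raise FormatError(
                f"{origin}, line {bad}: time column is not strictly increasing")
        sampling_rate = 1.0 / float(np.median(dts))
    else:
        sampling_rate = 100.0
    left = np.maximum(arr[:, 1:9], 0.0)
    right = np.maximum(arr[:, 9:17], 0.0)
    left_total = arr[:, 17]
    right_total = arr[:, 18]
    for foot, sensors, total in (("left", left, left_total),
                                 ("right", right, right_total)):
        if len(times) and np.max(np.abs(sensors.sum(axis=1) - total)) > TOTAL_TOLERANCE_N:
            warnings.warn(
                f"{origin}: parsed {foot} total disagrees with sensor sum by "
                f"more than {TOTAL_TOLERANCE_N} N; recomputed sums are used",
                stacklevel=2)
    return SensorTrace(
        subject_id=subject_id,
        sample_times=times,
        left_sensors=left,
        right_sensors=right,
        sampling_rate=sampling_rate,
        body_mass_kg=body_mass_kg,
        parsed_left_total=left_total,
        parsed_right_total=right_total,
    )


def write_force_record(trace: SensorTrace, dest) -> None:
    """Emit the 19-column dialect; totals are recomputed sensor sums.

    Times and forces are written with 2 decimals (10 ms / 0.01 N grid),
    matching the nominal 100 Hz resolution of the source instrumentation.
    """
    left_total = trace.left_sensors.sum(axis=1)
    right_total = trace.right_sensors.sum(axis=1)
    block = np.column_stack([
        trace.sample_times, trace.left_sensors, trace.right_sensors,
        left_total, right_total,
    ]) if len(trace) else np.empty((0, N_COLUMNS))
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            np.savetxt(fh, block, fmt="%.2f", delimiter="\t")
    else:
        np.savetxt(dest, block, fmt="%.2f", delimiter="\t")


def _canonical_value(fieldname: str, value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    if fieldname == "group":
        key = str(value).strip().lower()
        if key not in _GROUP_ALIASES:
            raise SchemaError(f"unknown group label {value!r}")
        return _GROUP_ALIASES[key]
    if fieldname == "sex":
        return _SEX_ALIASES.get(str(value).strip().lower(), "unknown")
    if fieldname == "subject_id":
        return str(value).strip()
    return float(value)


def read_demographics(source, column_map: dict[str, str] | None = None,
                      height_unit: str = "cm") -> list[SubjectMeta]:
    """Read a demographics table into a list of :class:`SubjectMeta`.

    Parameters
    ----------
    column_map
        Optional mapping from nonstandard header names (lower-cased) to
        canonical field names, merged over the built-in aliases.
    height_unit
        ``"cm"`` (default) or ``"m"``; the source table's height unit.
    """
    if height_unit not in ("cm", "m"):
        raise SchemaError(f"height_unit must be 'cm' or 'm', got {height_unit!r}")
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=None, engine="python")
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    mapping = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update({k.lower(): v for k, v in column_map.items()})
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in mapping:
            renames[col] = mapping[key]
    df = df.rename(columns=renames)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"demographics table missing mandatory column(s): "
                          f"{', '.join(missing)}")
    metas: list[SubjectMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        kwargs = {}
        for fieldname in ("subject_id", "group", "sex", "age", "height_cm",
                          "body_mass_kg", "walking_speed_mps", "hoehn_yahr",
                          "updrs", "tug_s"):
            if fieldname in df.columns:
                kwargs[fieldname] = _canonical_value(fieldname, row[fieldname])
        if kwargs.get("height_cm") is not None and height_unit == "m":
            kwargs["height_cm"] = kwargs["height_cm"] * 100.0
        meta = SubjectMeta(**kwargs)
        if meta.subject_id in seen:
            raise SchemaError(f"duplicate subject_id {meta.subject_id!r}")
        seen.add(meta.subject_id)
        metas.append(meta)
    return metas


def write_demographics(metas: Sequence[SubjectMeta], dest) -> None:
    """Write a tab-delimited demographics table readable by read_demographics."""
    cols = ["subject_id", "group", "sex", "age", "height_cm", "body_mass_kg",
            "walking_speed_mps", "hoehn_yahr", "updrs", "tug_s"]
    df = pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metas])
    df.to_csv(dest, sep="\t", index=False)


def subject_id_from_filename(path, pattern: str = r"^(?P<id>[^.]+)") -> str:
    """Extract a subject id from a file name via a configurable regex.

    The regex must contain a named group ``id``; default takes everything
    before the first dot.
    """
    name = Path(path).name
    m = re.match(pattern, name)
    if not m or "id" not in m.groupdict():
        raise SchemaError(f"cannot extract subject id from {name!r} "
                          f"with pattern {pattern!r}")
    return m.group("id")
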