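"""Reading and writing trial log files.

One trial per file. The dialect is plain text: header lines prefixed by
``%`` carrying ``key: value`` metadata (subject traits, movement type,
per-device sampling rates), followed by CSV data rows

    timestamp_ms,device_id,sensor_tag,x,y,z

with one sample per line, devices interleaved by timestamp. Only rows
tagged ``ACC`` are acceleration samples; gyroscope/magnetometer rows
(``GYR``, ``MAG``) are tolerated and ignored. Real UMAFall-style files
with a different column layout can be adapted via ``column_map``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from fallban.types import (
    DEFAULT_FS,
    DeviceKind,
    Position,
    SensorTrace,
    Subject,
    TrialRecord,
)

_ACC_TAG = "ACC"

#: Default 0-based column indices of the data rows.
DEFAULT_COLUMNS = {"timestamp": 0, "device": 1, "tag": 2, "x": 3, "y": 4, "z": 5}


class LogFormatError(ValueError):
    """Raised on malformed log files."""


def _format_float(x: float) -> str:
    s = format(x, ".17g")
    return s


def write_log_file(trial: TrialRecord, path: str | Path) -> Path:
    """Serialize a trial to a log file; inverse of :func:`parse_log_file`.

    Device identifiers are derived from positions (``dev-<position>``).
    Samples from all devices are interleaved globally by timestamp
    (stable within a device).
    """
    path = Path(path)
    buf = io.StringIO()
    s = trial.subject
    buf.write(f"% trial_id: {trial.trial_id}\n")
    buf.write(f"% movement_type: {trial.movement_type}\n")
    buf.write(f"% duration_s: {_format_float(trial.duration)}\n")
    buf.write(f"% subject_id: {s.id}\n")
    buf.write(f"% gender: {s.gender}\n")
    buf.write(f"% age: {_format_float(s.age)}\n")
    buf.write(f"% height_cm: {_format_float(s.height_cm)}\n")
    buf.write(f"% weight_kg: {_format_float(s.weight_kg)}\n")
    for pos, tr in trial.traces.items():
        buf.write(
            f"% device: dev-{pos.value},{tr.device_kind.value},"
            f"{_format_float(tr.fs)}\n"
        )
    rows: list[tuple[float, int, str]] = []
    for k, (pos, tr) in enumerate(trial.traces.items()):
        dev = f"dev-{pos.value}"
        for i in range(len(tr)):
            ms = tr.t[i] * 1000.0
            line = (
                f"{_format_float(ms)},{dev},{_ACC_TAG},"
                f"{_format_float(tr.a[i, 0])},{_format_float(tr.a[i, 1])},"
                f"{_format_float(tr.a[i, 2])}"
            )
            rows.append((ms, k, line))
    rows.sort(key=lambda r: r[0])  # stable: ties keep per-device file order
    for _, _, line in rows:
        buf.write(line + "\n")
    path.write_text(buf.getvalue())
    return path


def default_device_map(positions=None) -> dict[str, Position]:
    """Device-id → position map matching :func:`write_log_file` naming."""
    positions = list(positions) if positions is not None else list(Position)
    return {f"dev-{p.value}": p for p in positions}


def parse_log_file(
    path: str | Path,
    device_map: dict[str, Position] | None = None,
    column_map: dict[str, int] | None = None,
) -> TrialRecord:
    """Parse one trial log file into a :class:`TrialRecord`.

    Parameters
    ----------
    path : path
        Log file to read.
    device_map : dict, optional
        Maps device identifiers found in the file to body positions.
        Defaults to the identifiers emitted by :func:`write_log_file`.
    column_map : dict, optional
        0-based column indices for ``timestamp``, ``device``, ``tag``,
        ``x``, ``y``, ``z``; override to ingest foreign CSV layouts.
        A ``tag`` index of ``None`` treats every row as acceleration.

    Raises
    ------
    LogFormatError
        On malformed numeric fields (with line number), device ids
        absent from ``device_map``, or a file with fewer than two
        samples for every device.
    """
    path = Path(path)
    device_map = device_map if device_map is not None else default_device_map()
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    header: dict[str, str] = {}
    device_meta: dict[str, tuple[DeviceKind, float | None]] = {}
    per_device: dict[str, list[tuple[float, float, float, float]]] = {}

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("%"):
                body = line[1:].strip()
                if ":" not in body:
                    continue
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "device":
                    parts = [p.strip() for p in value.split(",")]
                    dev_id = parts[0]
                    kind = DeviceKind(parts[1]) if len(parts) > 1 else DeviceKind.MOTE
                    fs = float(parts[2]) if len(parts) > 2 else None
                    device_meta[dev_id] = (kind, fs)
                else:
                    header[key] = value
                continue
            fields = line.split(",")
            tag_idx = cols.get("tag")
            if tag_idx is not None:
                if len(fields) <= tag_idx:
                    raise LogFormatError(f"{path}:{lineno}: too few columns")
                if fields[tag_idx].strip() != _ACC_TAG:
                    continue
            dev_id = fields[cols["device"]].strip()
            if dev_id not in device_map:
                raise LogFormatError(
                    f"{path}:{lineno}: device identifier {dev_id!r} "
                    "not present in device_map"
                )
            try:
                ts_ms = float(fields[cols["timestamp"]])
                x = float(fields[cols["x"]])
                y = float(fields[cols["y"]])
                z = float(fields[cols["z"]])
            except (ValueError, IndexError) as exc:
                raise LogFormatError(
                    f"{path}:{lineno}: malformed numeric field ({exc})"
                ) from None
            per_device.setdefault(dev_id, []).append((ts_ms / 1000.0, x, y, z))

    if not any(len(v) >= 2 for v in per_device.values()):
        raise LogFormatError(f"{path}: empty trial (no device has 2 samples)")

    traces: dict[Position, SensorTrace] = {}
    for dev_id, samples in per_device.items():
        pos = device_map[dev_id]
        arr = np.array(samples, dtype=float)
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        kind, fs = device_meta.get(dev_id, (DeviceKind.MOTE, None))
        if fs is None:
            gaps = np.diff(arr[:, 0])
            gaps = gaps[gaps > 0]
            fs = 1.0 / float(np.median(gaps)) if gaps.size else DEFAULT_FS[kind]
        traces[pos] = SensorTrace(
            position=pos, device_kind=kind, fs=fs, t=arr[:, 0], a=arr[:, 1:]
        )

    subject = Subject(
        id=header.get("subject_id", "unknown"),
        gender=header.get("gender", "unknown"),
        age=float(header.get("age", "nan")),
        height_cm=float(header.get("height_cm", "nan")),
        weight_kg=float(header.get("weight_kg", "nan")),
    )
    return TrialRecord(
        trial_id=header.get("trial_id", path.stem),
        movement_type=header["movement_type"],
        traces=traces,
        subject=subject,
        duration=float(header.get("duration_s", "15")),
    )


def write_dataset(trials, directory: str | Path) -> list[Path]:
    """Write one log file per trial into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trial in enumerate(trials):
        paths.append(write_log_file(trial, directory / f"trial_{i:04d}.csv"))
    return paths


def read_dataset(directory: str | Path, device_map=None) -> list[TrialRecord]:
    """Parse every ``*.csv`` log file in a directory (sorted by name)."""
    directory = Path(directory)
    return [
        parse_log_file(p, device_map=device_map)
        for p in sorted(directory.glob("*.csv"))
    ]
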