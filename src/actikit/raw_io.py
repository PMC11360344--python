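"""Reading and writing the ActiLife-style file formats.

Raw input is the "RAW CSV" export: a short metadata header block, an optional
column-name row, then one row per sample with the three acceleration axes in
g. The exact export dialect varies between software versions, so it is
described explicitly by :class:`RawCsvDialect` rather than hard-coded.

Outputs are plain CSV/JSON: an epoch table (one row per 60 s epoch with the
ActiLife axis ordering axis1=Y, axis2=X, axis3=Z plus the wear flag) and a
summary table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ParseError
from .types import EpochCounts, RawRecording, WearMask

__all__ = [
    "RawCsvDialect",
    "read_raw_csv",
    "write_raw_csv",
    "write_epoch_csv",
    "read_epoch_csv",
    "write_summary",
]

_RATE_RE = re.compile(r"at\s+(\d+(?:\.\d+)?)\s*Hz", re.IGNORECASE)
_START_TIME_RE = re.compile(r"Start Time[\s,]+(\d{1,2}:\d{2}:\d{2})")
_START_DATE_RE = re.compile(r"Start Date[\s,]+(\d{1,2}/\d{1,2}/\d{4})")

_DEFAULT_START = datetime(2021, 6, 1, 0, 0, 0)


@dataclass(frozen=True)
class RawCsvDialect:
    """Shape of a RAW CSV export.

    ``header_line_count`` metadata lines are skipped before data; an optional
    column-name row after them is detected automatically. ``column_order``
    maps file columns to internal axes; ``timestamp_column_present`` marks a
    leading timestamp column; ``decimal_precision`` controls writing only.
    """

    header_line_count: int = 10
    column_order: tuple[str, str, str] = ("x", "y", "z")
    timestamp_column_present: bool = False
    decimal_precision: int = 3

    def __post_init__(self) -> None:
        if self.header_line_count < 0:
            raise ContractError("header_line_count must be >= 0")
        if sorted(self.column_order) != ["x", "y", "z"]:
            raise ContractError(
                f"column_order must be a permutation of x,y,z, got {self.column_order}"
            )


DEFAULT_DIALECT = RawCsvDialect()

_NAME_AXIS_RE = re.compile(r"accelerometer\s*([xyz])", re.IGNORECASE)


def _parse_header(lines: list[str]) -> tuple[float | None, datetime | None]:
    """Extract the sampling rate and start timestamp from the metadata block."""
    text = "\n".join(lines)
    rate = None
    m = _RATE_RE.search(text)
    if m:
        rate = float(m.group(1))
    start = None
    mt = _START_TIME_RE.search(text)
    md = _START_DATE_RE.search(text)
    if mt and md:
        month, day, year = (int(p) for p in md.group(1).split("/"))
        hh, mm, ss = (int(p) for p in mt.group(1).split(":"))
        start = datetime(year, month, day, hh, mm, ss)
    return rate, start


def read_raw_csv(
    path: str | Path,
    dialect: RawCsvDialect = DEFAULT_DIALECT,
    sample_rate_hz: float | None = None,
    start_time: datetime | None = None,
) -> RawRecording:
    """Read a RAW CSV export into a validated :class:`RawRecording`.

    The sampling rate is taken from the header ("... at 60 Hz ...") unless
    supplied explicitly; an explicit value wins. Samples keep file order.

    Raises
    ------
    FormatError
        Missing file, undeclared sampling rate, or inconsistent column count
        (message names the offending line).
    ParseError
        A non-numeric cell (message carries the 1-based file line number).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raw CSV not found: {path}")

    with open(path, "r", newline="") as fh:
        header_lines = []
        for i in range(dialect.header_line_count):
            line = fh.readline()
            if line == "":
                raise FormatError(
                    f"{path}: header truncated — expected {dialect.header_line_count} "
                    f"header lines, file ended at line {i + 1}"
                )
            header_lines.append(line.rstrip("\n"))

        declared_rate, declared_start = _parse_header(header_lines)
        rate = sample_rate_hz if sample_rate_hz is not None else declared_rate
        if rate is None:
            raise FormatError(
                f"{path}: no sampling rate in the {dialect.header_line_count}-line "
                "header and none supplied explicitly"
            )
        start = start_time or declared_start or _DEFAULT_START

        # Optional column-name row directly after the metadata block.
        data_start_line = dialect.header_line_count + 1
        pos = fh.tell()
        first = fh.readline()
        column_order = dialect.column_order
        if first and any(c.isalpha() for c in first):
            names = _NAME_AXIS_RE.findall(first)
            if len(names) == 3:
                column_order = tuple(n.lower() for n in names)  # type: ignore[assignment]
            data_start_line += 1
        else:
            fh.seek(pos)

        try:
            frame = pd.read_csv(fh, header=None, dtype=str, skip_blank_lines=False)
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: no sample rows after the header") from None
        except pd.errors.ParserError as exc:
            raise FormatError(f"{path}: inconsistent column count — {exc}") from None

    expected_cols = 3 + int(dialect.timestamp_column_present)
    if frame.shape[1] != expected_cols:
        raise FormatError(
            f"{path}: expected {expected_cols} columns, found {frame.shape[1]} "
            f"starting at line {data_start_line}"
        )

    axis_cols = frame.iloc[:, 1:] if dialect.timestamp_column_present else frame
    missing = axis_cols.isna().any(axis=1)
    if missing.any():
        bad = int(np.flatnonzero(missing.to_numpy())[0])
        raise FormatError(
            f"{path}: row with too few columns at line {data_start_line + bad}"
        )

    values = {}
    for j, axis_name in enumerate(column_order):
        col = axis_cols.iloc[:, j]
        try:
            values[axis_name] = pd.to_numeric(col, errors="raise").to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(col, errors="coerce")
            bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {col.iloc[bad]!r} in column {j + 1} "
                f"at line {data_start_line + bad}"
            ) from None

    return RawRecording(
        sample_rate_hz=float(rate), start_time=start,
        x=values["x"], y=values["y"], z=values["z"],
    )


def write_raw_csv(
    recording: RawRecording,
    path: str | Path,
    dialect: RawCsvDialect = DEFAULT_DIALECT,
) -> None:
    """Write a recording as an ActiLife-style RAW CSV (readable back by
    :func:`read_raw_csv`)."""
    path = Path(path)
    rate = recording.sample_rate_hz
    rate_txt = f"{rate:g}"
    start = recording.start_time
    header = [
        f"------------ Data File Created By actikit date format M/d/yyyy "
        f"at {rate_txt} Hz  Filter Normal -----------",
        "Serial Number: SYNTH000",
        f"Start Time {start:%H:%M:%S}",
        f"Start Date {start.month}/{start.day}/{start.year}",
        "Epoch Period (hh:mm:ss) 00:00:00",
        "Download Time 00:00:00",
        "Download Date 1/1/2099",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.07     Mode = 12",
        "--------------------------------------------------",
    ]
    n_header = dialect.header_line_count
    if n_header <= len(header):
        lines = header[: n_header]
    else:  # pad with comment lines to honour an unusual dialect
        lines = header + ["-" * 10] * (n_header - len(header))

    prec = dialect.decimal_precision
    cols = [recording.axis(name) for name in dialect.column_order]
    name_row = ",".join(f"Accelerometer {n.upper()}" for n in dialect.column_order)

    with open(path, "w", newline="") as fh:
        for line in lines:
            fh.write(line + "\n")
        if dialect.timestamp_column_present:
            fh.write("Timestamp," + name_row + "\n")
            dt = timedelta(seconds=1.0 / rate)
            for i in range(len(recording)):
                ts = (start + i * dt).isoformat()
                fh.write(ts + "," + ",".join(f"{c[i]:.{prec}f}" for c in cols) + "\n")
        else:
            fh.write(name_row + "\n")
            fmt = ",".join(["%." + str(prec) + "f"] * 3)
            np.savetxt(fh, np.column_stack(cols), fmt=fmt, delimiter=",")


def write_epoch_csv(
    epochs: EpochCounts,
    path: str | Path,
    mask: WearMask | None = None,
) -> None:
    """Write the per-epoch table: ``timestamp,axis1,axis2,axis3,wear``.

    ActiLife axis ordering is used (axis1 = vertical Y, axis2 = X, axis3 = Z).
    With no mask every epoch is written as worn. Values round-trip bit-exactly
    through :func:`read_epoch_csv`.
    """
    if mask is not None and len(mask) != len(epochs):
        raise ContractError(
            f"mask length {len(mask)} != epoch count {len(epochs)}"
        )
    flags = mask.flags if mask is not None else np.ones(len(epochs), dtype=np.int8)
    frame = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in epochs.epoch_timestamps()],
            "axis1": epochs.counts_y,
            "axis2": epochs.counts_x,
            "axis3": epochs.counts_z,
            "wear": flags.astype(int),
        }
    )
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write epoch CSV to {path}: {exc}") from exc


def read_epoch_csv(path: str | Path) -> tuple[EpochCounts, WearMask]:
    """Read an epoch CSV written by :func:`write_epoch_csv`."""
    frame = pd.read_csv(path)
    required = {"timestamp", "axis1", "axis2", "axis3", "wear"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: epoch CSV missing columns {sorted(required - set(frame.columns))}"
        )
    stamps = pd.to_datetime(frame["timestamp"])
    if len(stamps) >= 2:
        epoch_length = float((stamps.iloc[1] - stamps.iloc[0]).total_seconds())
    else:
        epoch_length = 60.0
    start = stamps.iloc[0].to_pydatetime() if len(stamps) else _DEFAULT_START
    epochs = EpochCounts(
        epoch_length_s=epoch_length,
        start_time=start,
        counts_x=frame["axis2"].to_numpy(np.int64),
        counts_y=frame["axis1"].to_numpy(np.int64),
        counts_z=frame["axis3"].to_numpy(np.int64),
    )
    return epochs, WearMask(frame["wear"].to_numpy(np.int8))


def write_summary(summary: Mapping, path: str | Path) -> None:
    """Write a summary mapping as JSON (.json) or a two-column CSV (.csv)."""
    path = Path(path)
    flat = dict(summary)
    if path.suffix.lower() == ".csv":
        rows = []
        for key, value in flat.items():
            if isinstance(value, Mapping):
                rows.extend((f"{key}.{k}", v) for k, v in value.items())
            else:
                rows.append((key, value))
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(flat, fh, indent=2, default=str)
            fh.write("\n")
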