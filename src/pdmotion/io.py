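"""Recording data model and file I/O.

A motor-task session is one :class:`AccelerometerRecording`: a uniformly
sampled tri-axial translational-acceleration series (m/s^2), optionally a
tri-axial angular-rate series (degree/s), plus the five metadata fields the
acquisition app attaches to every test (sampling rate, duration, date, test
type, user id).

Two plaintext serializations are supported:

* an XML dialect — root ``<recording>`` carrying the metadata as attributes,
  with a ``<samples>`` child holding one ``t,x,y,z[,pitch,roll,yaw]`` line per
  sample;
* a CSV dialect with the same columns and a header row, the metadata passed
  separately (convenient for fixtures and spreadsheets).

Numeric values are serialized with ``repr`` (shortest exact decimal), so a
write→read round trip is bit-faithful.
"""

from __future__ import annotations

import enum
import io as _stdio
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import SchemaError

__all__ = [
    "TestType",
    "TestMetadata",
    "AccelerometerRecording",
    "read_recording_xml",
    "write_recording_xml",
    "read_recording_csv",
    "write_recording_csv",
    "validate_recording",
]


class TestType(str, enum.Enum):
    """The three motor performance tasks."""

    HAND_TREMOR = "hand_tremor"
    WALKING = "walking"
    TURNING = "turning"


@dataclass(frozen=True)
class TestMetadata:
    """Session metadata: sampling rate (Hz), duration (s), ISO date, task, user."""

    sampling_rate: float
    duration: float
    date: str
    test_type: TestType
    user_id: str


@dataclass
class AccelerometerRecording:
    """One motor-task session.

    Attributes
    ----------
    metadata
        Session metadata.
    trans_acc
        ``(n, 3)`` translational acceleration in m/s^2 (x, y, z).
    angular_rate
        Optional ``(n, 3)`` angular rate in degree/s (pitch, roll, yaw).
    """

    metadata: TestMetadata
    trans_acc: np.ndarray
    angular_rate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.trans_acc = np.asarray(self.trans_acc, dtype=float)
        if self.angular_rate is not None:
            self.angular_rate = np.asarray(self.angular_rate, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.trans_acc.shape[0]

    @property
    def fs(self) -> float:
        return self.metadata.sampling_rate

    def times(self) -> np.ndarray:
        """Implicit uniform time base in seconds."""
        return np.arange(self.n_samples) / self.fs


_REQUIRED_ATTRS = ("sampling_rate", "duration", "date", "test_type", "user_id")


def validate_recording(rec: AccelerometerRecording) -> list[str]:
    """Check all type invariants; return a list of violation descriptions.

    Returns an empty list iff the recording is valid. Never raises.
    """
    violations: list[str] = []
    md = rec.metadata
    if not (np.isfinite(md.sampling_rate) and md.sampling_rate > 0):
        violations.append("sampling_rate: must be a positive finite number")
    if not (np.isfinite(md.duration) and md.duration > 0):
        violations.append("duration: must be a positive finite number")
    if not isinstance(md.test_type, TestType):
        violations.append("test_type: must be one of hand_tremor/walking/turning")
    acc = rec.trans_acc
    if acc.ndim != 2 or acc.shape[1] != 3:
        violations.append("trans_acc: must be an (n, 3) array")
        return violations
    n = acc.shape[0]
    if n < 2:
        violations.append("trans_acc: need at least 2 samples")
    if not np.all(np.isfinite(acc)):
        violations.append("trans_acc: contains non-finite samples")
    if rec.angular_rate is not None:
        ang = rec.angular_rate
        if ang.ndim != 2 or ang.shape[1] != 3:
            violations.append("angular_rate: must be an (n, 3) array")
        else:
            if ang.shape[0] != n:
                violations.append(
                    "angular_rate: length differs from trans_acc "
                    f"({ang.shape[0]} vs {n})"
                )
            if not np.all(np.isfinite(ang)):
                violations.append("angular_rate: contains non-finite samples")
    if (
        np.isfinite(md.sampling_rate)
        and md.sampling_rate > 0
        and np.isfinite(md.duration)
        and abs(n - md.sampling_rate * md.duration) > 1.0
    ):
        violations.append(
            "duration: sample count inconsistent with sampling_rate x duration "
            f"(|{n} - {md.sampling_rate}*{md.duration}| > 1)"
        )
    return violations


def _format_rows(rec: AccelerometerRecording) -> str:
    t = rec.times()
    lines = []
    for i in range(rec.n_samples):
        parts = [repr(float(t[i]))] + [repr(float(v)) for v in rec.trans_acc[i]]
        if rec.angular_rate is not None:
            parts += [repr(float(v)) for v in rec.angular_rate[i]]
        lines.append(",".join(parts))
    return "\n".join(lines)


def _parse_rows(text: str, where: str) -> tuple[np.ndarray, Optional[np.ndarray]]:
    rows = []
    width = None
    for lineno, raw in enumerate(text.strip().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split(",")
        if width is None:
            width = len(parts)
            if width not in (4, 7):
                raise SchemaError(
                    f"{where}: sample rows must have 4 or 7 columns, got {width}"
                )
        elif len(parts) != width:
            raise SchemaError(
                f"{where}: row {lineno} has {len(parts)} columns, expected {width}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise SchemaError(f"{where}: non-numeric sample on row {lineno}") from None
    if not rows:
        raise SchemaError(f"{where}: no samples found")
    arr = np.asarray(rows, dtype=float)
    trans = arr[:, 1:4]
    angular = arr[:, 4:7] if arr.shape[1] == 7 else None
    return trans, angular


def write_recording_xml(rec: AccelerometerRecording, path: str | Path) -> None:
    """Serialize a recording to the XML dialect (inverse of the reader)."""
    md = rec.metadata
    root = ET.Element(
        "recording",
        attrib={
            "sampling_rate": repr(float(md.sampling_rate)),
            "duration": repr(float(md.duration)),
            "date": md.date,
            "test_type": md.test_type.value,
            "user_id": md.user_id,
        },
    )
    samples = ET.SubElement(root, "samples")
    samples.text = "\n" + _format_rows(rec) + "\n"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_recording_xml(path: str | Path) -> AccelerometerRecording:
    """Parse an XML recording file, verifying schema and invariants.

    Raises :class:`SchemaError` naming the offending field on any violation
    (missing metadata, unknown test type, non-numeric samples, length or
    duration inconsistencies).
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SchemaError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    if root.tag != "recording":
        raise SchemaError(f"{path}: root element must be <recording>, got <{root.tag}>")
    for attr in _REQUIRED_ATTRS:
        if attr not in root.attrib:
            raise SchemaError(f"{path}: missing required attribute '{attr}'")
    try:
        fs = float(root.attrib["sampling_rate"])
        duration = float(root.attrib["duration"])
    except ValueError:
        raise SchemaError(f"{path}: sampling_rate/duration must be numeric") from None
    try:
        test_type = TestType(root.attrib["test_type"])
    except ValueError:
        raise SchemaError(
            f"{path}: unknown test_type '{root.attrib['test_type']}'"
        ) from None
    samples = root.find("samples")
    if samples is None or samples.text is None:
        raise SchemaError(f"{path}: missing <samples> element")
    trans, angular = _parse_rows(samples.text, str(path))
    rec = AccelerometerRecording(
        metadata=TestMetadata(
            sampling_rate=fs,
            duration=duration,
            date=root.attrib["date"],
            test_type=test_type,
            user_id=root.attrib["user_id"],
        ),
        trans_acc=trans,
        angular_rate=angular,
    )
    violations = validate_recording(rec)
    if violations:
        raise SchemaError(f"{path}: " + "; ".join(violations))
    return rec


_CSV_HEADER_4 = "t,x,y,z"
_CSV_HEADER_7 = "t,x,y,z,pitch,roll,yaw"


def write_recording_csv(rec: AccelerometerRecording, path: str | Path) -> None:
    """Write the sample table as CSV with header; metadata is *not* stored."""
    header = _CSV_HEADER_7 if rec.angular_rate is not None else _CSV_HEADER_4
    Path(path).write_text(header + "\n" + _format_rows(rec) + "\n")


def read_recording_csv(
    path: str | Path,
    sampling_rate: float,
    test_type: TestType,
    user_id: str = "",
    date: str = "1970-01-01T00:00:00",
) -> AccelerometerRecording:
    """Read the CSV dialect; sampling rate and task are supplied by the caller."""
    text = Path(path).read_text()
    lines = text.strip().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file")
    header = lines[0].strip()
    if header not in (_CSV_HEADER_4, _CSV_HEADER_7):
        raise SchemaError(
            f"{path}: header must be '{_CSV_HEADER_4}' or '{_CSV_HEADER_7}'"
        )
    trans, angular = _parse_rows("\n".join(lines[1:]), str(path))
    rec = AccelerometerRecording(
        metadata=TestMetadata(
            sampling_rate=sampling_rate,
            duration=trans.shape[0] / sampling_rate,
            date=date,
            test_type=test_type,
            user_id=user_id,
        ),
        trans_acc=trans,
        angular_rate=angular,
    )
    violations = validate_recording(rec)
    if violations:
        raise SchemaError(f"{path}: " + "; ".join(violations))
    return rec
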