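"""Raw sensor text formats and count-to-physical-unit conversions.

The instrumented brace streams two 6-axis MPU6050 IMUs (one above, one
below the knee) as integer counts.  The accelerometer runs at a full-scale
range of +/-2 g with a sensitivity of 16,384 LSB/g and the gyroscope at
+/-250 deg/s with 131 LSB/(deg/s); conversion to physical units is a pure
division by these sensitivities.

Two plain-text dialects are defined here:

* Brace TXT — one CSV line per sample, ``sensor_id,t_ms,ax,ay,az,gx,gy,gz``
  (integer counts, timestamps in integer milliseconds from device boot),
  preceded by ``#activity=<name>`` and ``#rate_hz=<r>`` header lines.
* Criterion TSV — ``time_s<TAB>theta_deg`` rows with a ``#rate_hz=<r>``
  header, holding the motion-capture sagittal knee angle in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, RangeError, StructuralError

ACCEL_SENSITIVITY_LSB_PER_G = 16384.0
GYRO_SENSITIVITY_LSB_PER_DPS = 131.0
ACCEL_FULLSCALE_COUNTS = 32768
GYRO_FULLSCALE_COUNTS = 32750  # 250 deg/s * 131 LSB/(deg/s)
COUNT_LIMIT = 32768

SENSOR_IDS = ("above_knee", "below_knee")
#: Anatomical segment carried by each sensor position.
SENSOR_SEGMENT = {"above_knee": "thigh", "below_knee": "shank"}


@dataclass
class RawImuSample:
    """One time-stamped 6-axis reading in integer counts."""

    t: float  # seconds
    ax: int
    ay: int
    az: int
    gx: int
    gy: int
    gz: int
    sensor_id: str


@dataclass
class BraceRecording:
    """All samples of one brace trial, keyed by sensor position.

    ``samples[sensor_id]`` holds 2-D integer count arrays and a seconds
    time base; both sensors must be present.
    """

    t: dict[str, np.ndarray] = field(default_factory=dict)  # seconds
    accel: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 3) counts
    gyro: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 3) counts
    nominal_rate_hz: float = 20.0
    activity_name: str = ""
    n_bad_lines: int = 0

    def validate(self) -> None:
        for sid in SENSOR_IDS:
            if sid not in self.t or self.t[sid].size == 0:
                raise StructuralError(f"sensor block missing or empty: {sid}")
            if np.any(np.diff(self.t[sid]) < 0):
                raise FormatError(f"timestamps not non-decreasing for {sid}")


@dataclass
class MocapRecording:
    """Criterion sagittal knee angle on a uniform time grid."""

    t: np.ndarray  # seconds
    theta_deg: np.ndarray
    rate_hz: float

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise FormatError("rate_hz must be positive")
        if not np.all(np.isfinite(self.theta_deg)):
            raise FormatError("non-finite angle values")
        dt = np.diff(self.t)
        if dt.size and (np.max(np.abs(dt - 1.0 / self.rate_hz)) > 0.1 / self.rate_hz):
            raise FormatError("time grid not uniform at declared rate")


def convert_accel_counts(counts):
    """Convert accelerometer counts to g (16,384 LSB/g)."""
    counts = np.asarray(counts)
    if np.any(np.abs(counts) > COUNT_LIMIT):
        raise RangeError("accelerometer counts outside +/-32768")
    return counts / ACCEL_SENSITIVITY_LSB_PER_G


def convert_gyro_counts(counts):
    """Convert gyroscope counts to deg/s (131 LSB per deg/s)."""
    counts = np.asarray(counts)
    if np.any(np.abs(counts) > COUNT_LIMIT):
        raise RangeError("gyroscope counts outside +/-32768")
    return counts / GYRO_SENSITIVITY_LSB_PER_DPS


def write_brace_txt(recording: BraceRecording, path) -> None:
    recording.validate()
    lines = [
        f"#activity={recording.activity_name}",
        f"#rate_hz={recording.nominal_rate_hz:g}",
    ]
    for sid in SENSOR_IDS:
        t_ms = np.rint(recording.t[sid] * 1000.0).astype(np.int64)
        acc = recording.accel[sid].astype(np.int64)
        gyr = recording.gyro[sid].astype(np.int64)
        for i in range(t_ms.size):
            lines.append(
                f"{sid},{t_ms[i]},{acc[i, 0]},{acc[i, 1]},{acc[i, 2]},"
                f"{gyr[i, 0]},{gyr[i, 1]},{gyr[i, 2]}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_brace_txt(path, lenient: bool = True) -> BraceRecording:
    """Parse a brace TXT file.

    In lenient mode malformed data lines are dropped, counted in
    ``n_bad_lines`` and reported through a warning; otherwise the first bad
    line raises :class:`FormatError` with its line number.
    """
    text = Path(path).read_text()
    rec = BraceRecording()
    rows: dict[str, list[tuple[int, list[int]]]] = {sid: [] for sid in SENSOR_IDS}
    n_bad = 0
    any_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key == "activity":
                rec.activity_name = val
            elif key == "rate_hz":
                rec.nominal_rate_hz = float(val)
            continue
        parts = line.split(",")
        try:
            if len(parts) != 8 or parts[0] not in SENSOR_IDS:
                raise ValueError
            sid = parts[0]
            vals = [int(p) for p in parts[1:]]
        except ValueError:
            if lenient:
                n_bad += 1
                continue
            raise FormatError(f"{path}: malformed line {lineno}: {raw!r}") from None
        any_data = True
        rows[sid].append((vals[0], vals[1:]))
    if not any_data:
        raise StructuralError(f"{path}: no data lines")
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} malformed line(s)", stacklevel=2)
    for sid in SENSOR_IDS:
        if not rows[sid]:
            raise StructuralError(f"{path}: sensor block missing: {sid}")
        t_ms = np.array([r[0] for r in rows[sid]], dtype=np.int64)
        counts = np.array([r[1] for r in rows[sid]], dtype=np.int64)
        rec.t[sid] = t_ms / 1000.0
        rec.accel[sid] = counts[:, :3]
        rec.gyro[sid] = counts[:, 3:]
    rec.n_bad_lines = n_bad
    rec.validate()
    return rec


def write_mocap_tsv(recording: MocapRecording, path) -> None:
    recording.validate()
    lines = [f"#rate_hz={recording.rate_hz:g}", "time_s\ttheta_deg"]
    for ti, th in zip(recording.t, recording.theta_deg):
        lines.append(f"{ti:.6f}\t{th:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mocap_tsv(path, columns: dict[str, int] | None = None) -> MocapRecording:
    """Parse a criterion TSV export.

    ``columns`` maps ``{"time": i, "theta": j}`` to zero-based column
    indices for exports with a different layout; default is the package's
    own two-column dialect.
    """
    cols = {"time": 0, "theta": 1}
    if columns:
        cols.update(columns)
    rate = None
    t_list: list[float] = []
    th_list: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key == "rate_hz":
                rate = float(val)
            continue
        parts = line.split("\t")
        if parts[cols["time"]] in ("time_s", "time"):  # header row
            continue
        try:
            t_list.append(float(parts[cols["time"]]))
            th_list.append(float(parts[cols["theta"]]))
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed line {lineno}: {raw!r}") from None
    if rate is None:
        raise FormatError(f"{path}: missing #rate_hz header")
    rec = MocapRecording(
        t=np.asarray(t_list), theta_deg=np.asarray(th_list), rate_hz=rate
    )
    rec.validate()
    return rec
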