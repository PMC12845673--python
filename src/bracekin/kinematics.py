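"""Sagittal knee kinematics from dual-IMU raw counts.

The chain implements the brace's estimation model: each segment's tilt is
the four-quadrant arctangent of its in-plane accelerometer axes,
``tilt = atan2(Ax, Ay)`` (0 deg when gravity lies on +Y, i.e. upright
standing, increasing with forward tilt); the knee angle is the thigh minus
the shank tilt (flexion positive) and the knee angular velocity the
difference of the gyroscope-measured segment rates.  Segment tilts are
unwrapped over time before subtraction so the estimate stays correct
across quadrants, and a static standing window at the start of each
recording provides the reference orientation that zeroes the standing
angle.

Also here: the criterion-signal zero-lag Butterworth filter, trial-level
outlier screening on peak values, temporal normalisation onto the
101-point movement-cycle grid, ensemble averaging, cross-correlation
alignment of the unsynchronised brace and criterion streams, and peak
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import io as sio
from .curves import CYCLE_GRID, N_CYCLE_POINTS, JointCurve, NormalizedCurve, SegmentAngleSeries
from .errors import (
    AlignmentError,
    CalibrationError,
    OrientationError,
    PairingError,
    ParameterError,
    QuantityMismatchError,
)


def estimate_tilt(ax_g, ay_g):
    """Segment tilt in degrees from in-plane accelerometer axes (in g).

    Four-quadrant convention ``atan2(Ax, Ay)``: (0, 1) -> 0 deg,
    (1, 0) -> 90 deg, (-1, 0) -> -90 deg; range (-180, 180].
    """
    ax_g = np.asarray(ax_g, dtype=float)
    ay_g = np.asarray(ay_g, dtype=float)
    if np.any((ax_g == 0) & (ay_g == 0)):
        raise OrientationError("zero in-plane acceleration: tilt undefined")
    return np.degrees(np.arctan2(ax_g, ay_g))


def tilt_series(recording: sio.BraceRecording, sensor_id: str) -> SegmentAngleSeries:
    """Unwrapped tilt trajectory of one sensor, in degrees."""
    acc = recording.accel[sensor_id]
    ax = sio.convert_accel_counts(acc[:, 0])
    ay = sio.convert_accel_counts(acc[:, 1])
    tilt = estimate_tilt(ax, ay)
    tilt = np.unwrap(tilt, period=360.0)
    return SegmentAngleSeries(
        t=recording.t[sensor_id], tilt_deg=tilt, segment=sio.SENSOR_SEGMENT[sensor_id]
    )


def segment_rate_series(recording: sio.BraceRecording, sensor_id: str) -> JointCurve:
    """Gyroscope sagittal rate (z axis) of one sensor in deg/s."""
    rate = sio.convert_gyro_counts(recording.gyro[sensor_id][:, 2])
    return JointCurve(
        t=recording.t[sensor_id], value=rate, quantity="velocity",
        rate_hz=recording.nominal_rate_hz,
    )


def static_reference(
    recording: sio.BraceRecording,
    window_s: float = 1.0,
    gyro_quiet_dps: float = 10.0,
) -> dict[str, float]:
    """Mean tilt per segment over the initial static standing window.

    The window is accepted only if the gyroscope magnitude stays below
    ``gyro_quiet_dps`` throughout it; otherwise no quiescent reference
    posture exists and a :class:`CalibrationError` is raised.  Subtracting
    these offsets makes quiet standing read ~0 deg on each segment.
    """
    offsets: dict[str, float] = {}
    for sid in sio.SENSOR_IDS:
        t = recording.t[sid]
        mask = t <= t[0] + window_s
        if mask.sum() < 2:
            raise CalibrationError("static window too short")
        gyro_dps = sio.convert_gyro_counts(recording.gyro[sid][mask])
        mag = np.linalg.norm(gyro_dps, axis=1)
        if np.any(mag > gyro_quiet_dps):
            raise CalibrationError(
                f"{sid}: gyro activity {mag.max():.1f} deg/s in the static window"
            )
        series = tilt_series(recording, sid)
        offsets[sio.SENSOR_SEGMENT[sid]] = float(np.mean(series.tilt_deg[mask]))
    return offsets


def _check_overlap(a_t: np.ndarray, b_t: np.ndarray) -> None:
    if a_t[-1] < b_t[0] or b_t[-1] < a_t[0]:
        raise AlignmentError("series time ranges do not overlap")


def joint_angle(thigh: SegmentAngleSeries, shank: SegmentAngleSeries) -> JointCurve:
    """Knee angle theta = thigh tilt - shank tilt, flexion positive.

    The shank series is linearly interpolated onto the thigh time base
    when the grids differ.
    """
    _check_overlap(thigh.t, shank.t)
    shank_on_thigh = np.interp(thigh.t, shank.t, shank.tilt_deg)
    dt = np.median(np.diff(thigh.t)) if thigh.t.size > 1 else 1.0
    return JointCurve(
        t=thigh.t, value=thigh.tilt_deg - shank_on_thigh,
        quantity="angle", rate_hz=1.0 / dt,
    )


def joint_velocity(thigh_rate: JointCurve, shank_rate: JointCurve) -> JointCurve:
    """Knee angular velocity omega = thigh rate - shank rate (deg/s)."""
    _check_overlap(thigh_rate.t, shank_rate.t)
    shank_on_thigh = np.interp(thigh_rate.t, shank_rate.t, shank_rate.value)
    return JointCurve(
        t=thigh_rate.t, value=thigh_rate.value - shank_on_thigh,
        quantity="velocity", rate_hz=thigh_rate.rate_hz,
    )


def butterworth_zero_lag(curve: JointCurve, cutoff_hz: float, order: int = 4) -> JointCurve:
    """Zero-lag (forward-backward) low-pass Butterworth filter.

    Applied to the criterion signal; order refers to the underlying
    one-pass filter, doubled in effect by filtfilt. DC gain is 1.
    """
    if cutoff_hz <= 0 or cutoff_hz >= curve.rate_hz / 2.0:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={curve.rate_hz / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=curve.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, curve.value)
    return JointCurve(t=curve.t, value=filtered, quantity=curve.quantity, rate_hz=curve.rate_hz)


@dataclass
class OutlierLog:
    removed: list[tuple[int, float, str]]  # (index, peak, reason)
    flagged: bool = False  # rule would have removed > 40 %; all kept


def remove_outlier_trials(
    trials: list, mad_factor: float = 3.0, min_deviation: float = 5.0
) -> tuple[list, OutlierLog]:
    """Screen repeat trials whose peak value is inconsistent with the set.

    A trial is an outlier when its peak deviates from the median peak by
    more than ``mad_factor`` times the scaled median absolute deviation
    (1.4826 * MAD) *and* by at least ``min_deviation`` (the MAD of 3-5
    repeats is too noisy to act on sub-clinical differences alone).  If
    the rule would discard more than 40 % of trials the whole set is kept
    and flagged instead.  Accepts JointCurve or NormalizedCurve items.
    """
    if len(trials) < 3:
        raise PairingError("outlier screening needs at least 3 trials")
    peaks = np.array([float(np.max(tr.value)) for tr in trials])
    med = np.median(peaks)
    mad = 1.4826 * np.median(np.abs(peaks - med))
    log = OutlierLog(removed=[])
    if mad == 0.0:
        return list(trials), log
    dev = np.abs(peaks - med)
    out = (dev > mad_factor * mad) & (dev >= min_deviation)
    if out.sum() > 0.4 * len(trials):
        log.flagged = True
        return list(trials), log
    kept = []
    for i, (tr, is_out) in enumerate(zip(trials, out)):
        if is_out:
            log.removed.append(
                (i, peaks[i], f"peak {peaks[i]:.1f} deviates > {mad_factor}x scaled MAD from median {med:.1f}")
            )
        else:
            kept.append(tr)
    return kept, log


def time_normalize(curve: JointCurve, start_idx: int, end_idx: int) -> NormalizedCurve:
    """Resample a movement cycle onto the 0-100 % grid (101 points)."""
    n = curve.t.size
    if not (0 <= start_idx < n and 0 <= end_idx < n):
        raise IndexError("event indices out of range")
    if end_idx <= start_idx + 1:
        raise ParameterError("end_idx must exceed start_idx by more than 1")
    t0, t1 = curve.t[start_idx], curve.t[end_idx]
    grid_t = t0 + (t1 - t0) * CYCLE_GRID / 100.0
    vals = np.interp(grid_t, curve.t, curve.value)
    return NormalizedCurve(
        value=vals, quantity=curve.quantity, n_source_samples=end_idx - start_idx + 1
    )


def ensemble_average(curves: list[NormalizedCurve]) -> tuple[NormalizedCurve, np.ndarray]:
    """Pointwise mean curve and sample SD across curves on the cycle grid."""
    if not curves:
        raise PairingError("ensemble of zero curves")
    q = curves[0].quantity
    if any(c.quantity != q for c in curves):
        raise QuantityMismatchError("cannot average angle and velocity curves together")
    stack = np.stack([c.value for c in curves])
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sd = stack.std(axis=0, ddof=1)
        sd[np.all(stack == stack[0], axis=0)] = 0.0  # identical copies: exactly zero
    else:
        sd = np.zeros(N_CYCLE_POINTS)
    return NormalizedCurve(value=mean, quantity=q, n_source_samples=len(curves)), sd


def align_streams(
    brace: JointCurve,
    mocap: JointCurve,
    max_lag_s: float = 2.0,
    min_corr: float = 0.5,
) -> tuple[float, JointCurve, JointCurve]:
    """Recover the clock offset between the brace and criterion streams.

    Searches integer brace-sample lags for the maximum normalised
    cross-correlation between the two angle curves (criterion interpolated
    onto the 20 Hz brace grid), then returns the lag (criterion clock lead
    in seconds), the trimmed brace curve, and the criterion resampled onto
    the same grid.
    """
    dt = 1.0 / brace.rate_hz
    lags = np.arange(-int(round(max_lag_s / dt)), int(round(max_lag_s / dt)) + 1)
    b = brace.value
    best_corr, best_lag = -np.inf, 0
    for lag in lags:
        t_shift = brace.t + lag * dt
        inside = (t_shift >= mocap.t[0]) & (t_shift <= mocap.t[-1])
        if inside.sum() < brace.rate_hz:  # need >= 1 s of overlap
            continue
        m = np.interp(t_shift[inside], mocap.t, mocap.value)
        bb = b[inside]
        sb, sm = bb.std(), m.std()
        if sb == 0 or sm == 0:
            continue
        corr = float(np.mean((bb - bb.mean()) * (m - m.mean())) / (sb * sm))
        if corr > best_corr:
            best_corr, best_lag = corr, lag
    if not np.isfinite(best_corr) or best_corr < min_corr:
        raise AlignmentError(f"peak correlation {best_corr:.2f} below {min_corr}")
    lag_s = best_lag * dt
    t_shift = brace.t + lag_s
    inside = (t_shift >= mocap.t[0]) & (t_shift <= mocap.t[-1])
    brace_trim = JointCurve(
        t=brace.t[inside], value=brace.value[inside],
        quantity=brace.quantity, rate_hz=brace.rate_hz,
    )
    mocap_on_brace = JointCurve(
        t=brace.t[inside], value=np.interp(t_shift[inside], mocap.t, mocap.value),
        quantity=mocap.quantity, rate_hz=brace.rate_hz,
    )
    return lag_s, brace_trim, mocap_on_brace


def extract_peak(curve: NormalizedCurve) -> tuple[float, float]:
    """Peak value and its position in % of the movement cycle.

    Ties broken by the earliest grid position.
    """
    idx = int(np.argmax(curve.value))
    return float(curve.value[idx]), float(curve.grid[idx])
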