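"""Forward simulation of brace and motion-capture recordings.

The simulator plays a ground-truth ADL bout through a planar sensor model:
each 6-axis IMU sees gravity projected onto its in-plane axes at the
segment's sagittal tilt (Ax = g sin(phi), Ay = g cos(phi)) plus band-limited
motion-artifact/sensor noise, and its gyroscope sees the segment angular
rate plus a constant bias and white noise.  Signals are quantised at the
MPU6050 settings used by the brace (+/-2 g at 16,384 LSB/g, +/-250 deg/s at
131 LSB/(deg/s)), clamped at full scale, and sampled at 20 Hz.  The
criterion system samples the true knee angle at 200 Hz with small
independent noise and an unsynchronised clock offset.

Every recording starts with a static standing lead-in (used downstream for
reference-orientation calibration) and ends with a short standing tail.
Low-frequency sinusoidal "slippage" of each sensor's mounting emulates
soft-tissue/strap artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d

from . import io as sio
from .curves import JointCurve
from .errors import ConfigError
from .profiles import TASKS, TASK_PEAK_DEG, AdlProfile, generate_adl_profile


@dataclass
class SimulationConfig:
    """Study-level settings of the synthetic validation experiment.

    Defaults mirror the validation study's design: 13 participants, five
    trials per task, a 20 Hz brace against a 200 Hz optical criterion,
    and realistically imperfect sensors.
    """

    n_participants: int = 13
    n_trials_per_task: int = 5
    brace_rate_hz: float = 20.0
    mocap_rate_hz: float = 200.0
    accel_noise_g: float = 0.05  # band-limited motion artefact + sensor noise, per axis
    gyro_noise_dps: float = 0.5
    gyro_bias_dps: float = 1.0  # constant per-sensor offset magnitude
    start_offset_s: tuple[float, float] = (0.0, 1.0)  # uniform desync range
    soft_tissue_amp_deg: float = 3.0  # strap-slippage artefact amplitude
    mocap_noise_deg: float = 0.25
    mount_offset_sd_deg: float = 3.0  # per-trial sensor mounting misalignment
    static_lead_s: float = 2.0
    tail_s: float = 1.0
    between_subject_peak_sd_deg: float = 10.0
    within_subject_peak_sd_deg: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.brace_rate_hz <= 0 or self.mocap_rate_hz <= 0:
            raise ConfigError("sampling rates must be positive")
        for name in ("accel_noise_g", "gyro_noise_dps", "soft_tissue_amp_deg",
                     "mocap_noise_deg", "mount_offset_sd_deg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_trials_per_task < 1 or self.n_participants < 1:
            raise ConfigError("counts must be >= 1")
        lo, hi = self.start_offset_s
        if lo < 0 or hi < lo:
            raise ConfigError("start_offset_s must be a non-negative (lo, hi) range")

    def noise_free(self) -> "SimulationConfig":
        """Copy with every noise, bias, slippage and offset source zeroed
        (quantisation and sampling remain)."""
        return replace(
            self,
            accel_noise_g=0.0,
            gyro_noise_dps=0.0,
            gyro_bias_dps=0.0,
            start_offset_s=(0.0, 0.0),
            soft_tissue_amp_deg=0.0,
            mocap_noise_deg=0.0,
            mount_offset_sd_deg=0.0,
        )


@dataclass
class SimulatedTrial:
    """One simulated brace + criterion trial pair with its ground truth."""

    participant_id: int
    task: str
    trial_index: int
    brace_recording: sio.BraceRecording
    mocap_recording: sio.MocapRecording
    truth_joint_angle: JointCurve
    truth_joint_velocity: JointCurve
    event_start_s: float  # movement onset on the brace clock
    event_end_s: float
    offset_s: float  # criterion clock lead over the brace clock
    peak_flexion_deg: float = float("nan")


def _event_angle(profile: AdlProfile, tau, lead_s: float) -> np.ndarray:
    """Knee/segment-independent helper: truth on the full recording
    timeline (standing outside the movement window)."""
    tau = np.asarray(tau, dtype=float)
    return profile.joint_angle(np.clip(tau - lead_s, 0.0, profile.duration_s))


def _band_limited_noise(rng, n: int, sd: float) -> np.ndarray:
    """Zero-mean low-pass noise with the requested per-sample SD."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    w = gaussian_filter1d(rng.standard_normal(n), sigma=1.0, mode="nearest")
    s = w.std()
    return w * (sd / s) if s > 0 else np.zeros(n)


def quantize(values, sensitivity: float, fullscale_counts: int) -> np.ndarray:
    """Round physical values to integer counts and clamp at full scale."""
    counts = np.rint(np.asarray(values, dtype=float) * sensitivity)
    return np.clip(counts, -fullscale_counts, fullscale_counts).astype(np.int64)


def simulate_imu(
    profile: AdlProfile,
    segment: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mount_offset_deg: float = 0.0,
    slip_phase: float | None = None,
    gyro_bias_dps: float | None = None,
):
    """Simulate one sensor's raw count streams for a whole trial.

    Returns ``(t, accel_counts, gyro_counts)`` with counts of shape (n, 3);
    the time base covers static lead-in + movement + tail at the brace rate.
    """
    if segment not in ("thigh", "shank"):
        raise ConfigError(f"segment must be 'thigh' or 'shank', got {segment!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lead, tail = config.static_lead_s, config.tail_s
    total = lead + profile.duration_s + tail
    n = int(round(total * config.brace_rate_hz)) + 1
    t = np.arange(n) / config.brace_rate_hz

    seg_fn = profile.thigh_angle_fn if segment == "thigh" else profile.shank_angle_fn

    def seg_angle(tau):
        tau = np.asarray(tau, dtype=float)
        return seg_fn(np.clip(tau - lead, 0.0, profile.duration_s))

    phase = rng.uniform(0, 2 * np.pi) if slip_phase is None else slip_phase
    slip_f = 0.1  # Hz, slow strap creep
    phi = mount_offset_deg + seg_angle(t)
    phi = phi + config.soft_tissue_amp_deg * np.sin(2 * np.pi * slip_f * t + phase)

    # segment rate: central difference of the continuous tilt + slip term
    h = 1e-4
    rate = (seg_angle(t + h) - seg_angle(t - h)) / (2 * h)
    rate = rate + config.soft_tissue_amp_deg * 2 * np.pi * slip_f * np.cos(
        2 * np.pi * slip_f * t + phase
    )

    phi_rad = np.deg2rad(phi)
    ax = np.sin(phi_rad) + _band_limited_noise(rng, n, config.accel_noise_g)
    ay = np.cos(phi_rad) + _band_limited_noise(rng, n, config.accel_noise_g)
    az = _band_limited_noise(rng, n, 0.5 * config.accel_noise_g)  # off-plane

    bias = config.gyro_bias_dps if gyro_bias_dps is None else gyro_bias_dps
    gz = rate + bias + rng.normal(0.0, config.gyro_noise_dps, n) if config.gyro_noise_dps else rate + bias
    gx = rng.normal(0.0, 0.5 * config.gyro_noise_dps, n) if config.gyro_noise_dps else np.zeros(n)
    gy = rng.normal(0.0, 0.5 * config.gyro_noise_dps, n) if config.gyro_noise_dps else np.zeros(n)

    accel = np.stack(
        [quantize(a, sio.ACCEL_SENSITIVITY_LSB_PER_G, sio.ACCEL_FULLSCALE_COUNTS) for a in (ax, ay, az)],
        axis=1,
    )
    gyro = np.stack(
        [quantize(g, sio.GYRO_SENSITIVITY_LSB_PER_DPS, sio.GYRO_FULLSCALE_COUNTS) for g in (gx, gy, gz)],
        axis=1,
    )
    return t, accel, gyro


def simulate_mocap(
    profile: AdlProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    offset_s: float = 0.0,
) -> sio.MocapRecording:
    """Criterion knee-angle recording at the mocap rate.

    The criterion clock starts ``offset_s`` seconds before the brace clock,
    so features appear ``offset_s`` later on the criterion time axis.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total = config.static_lead_s + profile.duration_s + config.tail_s + offset_s
    n = int(round(total * config.mocap_rate_hz)) + 1
    t = np.arange(n) / config.mocap_rate_hz
    theta = _event_angle(profile, t - offset_s, config.static_lead_s)
    if config.mocap_noise_deg > 0:
        theta = theta + rng.normal(0.0, config.mocap_noise_deg, n)
    return sio.MocapRecording(t=t, theta_deg=theta, rate_hz=config.mocap_rate_hz)


def simulate_trial(
    profile: AdlProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_id: int = 0,
    trial_index: int = 0,
) -> SimulatedTrial:
    """Simulate one matched brace/criterion trial with ground truth."""
    lead = config.static_lead_s
    lo, hi = config.start_offset_s
    offset = rng.uniform(lo, hi) if hi > lo else lo

    brace = sio.BraceRecording(
        nominal_rate_hz=config.brace_rate_hz, activity_name=profile.task
    )
    for sid in sio.SENSOR_IDS:
        seg = sio.SENSOR_SEGMENT[sid]
        mount = rng.normal(0.0, config.mount_offset_sd_deg) if config.mount_offset_sd_deg else 0.0
        bias = rng.normal(0.0, config.gyro_bias_dps) if config.gyro_bias_dps else 0.0
        t, acc, gyr = simulate_imu(
            profile, seg, config, rng=rng, mount_offset_deg=mount, gyro_bias_dps=bias
        )
        brace.t[sid], brace.accel[sid], brace.gyro[sid] = t, acc, gyr

    mocap = simulate_mocap(profile, config, rng=rng, offset_s=offset)

    n_truth = int(round(profile.duration_s * config.brace_rate_hz)) + 1
    t_truth = np.arange(n_truth) / config.brace_rate_hz
    truth_theta = JointCurve(
        t=t_truth + lead, value=profile.joint_angle(t_truth),
        quantity="angle", rate_hz=config.brace_rate_hz,
    )
    truth_omega = JointCurve(
        t=t_truth + lead, value=profile.joint_velocity(t_truth),
        quantity="velocity", rate_hz=config.brace_rate_hz,
    )
    return SimulatedTrial(
        participant_id=participant_id,
        task=profile.task,
        trial_index=trial_index,
        brace_recording=brace,
        mocap_recording=mocap,
        truth_joint_angle=truth_theta,
        truth_joint_velocity=truth_omega,
        event_start_s=lead,
        event_end_s=lead + profile.duration_s,
        offset_s=offset,
        peak_flexion_deg=profile.peak_flexion_deg,
    )


def make_dataset(config: SimulationConfig, tasks=TASKS) -> list[SimulatedTrial]:
    """Simulate the full study: participants x tasks x trials.

    Per-participant task peaks are drawn around the task's conventional
    value with the configured between-subject SD, and jittered per trial
    with the within-subject SD, so ensemble variability is non-degenerate.
    Identical configs produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[SimulatedTrial] = []
    for pid in range(1, config.n_participants + 1):
        for task in tasks:
            base = TASK_PEAK_DEG[task]
            p_peak = base + (
                rng.normal(0.0, config.between_subject_peak_sd_deg)
                if config.between_subject_peak_sd_deg else 0.0
            )
            for k in range(config.n_trials_per_task):
                peak = p_peak + (
                    rng.normal(0.0, config.within_subject_peak_sd_deg)
                    if config.within_subject_peak_sd_deg else 0.0
                )
                peak = float(np.clip(peak, 10.0, 160.0))
                profile = generate_adl_profile(task, peak_flexion_deg=peak)
                trials.append(
                    simulate_trial(profile, config, rng, participant_id=pid, trial_index=k)
                )
    return trials


# ---------------------------------------------------------------------------
# On-disk dataset layout: brace TXT + criterion TSV + truth TSV + manifest
# ---------------------------------------------------------------------------

def _write_truth_tsv(trial: SimulatedTrial, path: Path) -> None:
    lines = [f"#rate_hz={trial.truth_joint_angle.rate_hz:g}",
             "time_s\ttheta_deg\tomega_dps"]
    for t, th, om in zip(trial.truth_joint_angle.t, trial.truth_joint_angle.value,
                         trial.truth_joint_velocity.value):
        lines.append(f"{t:.6f}\t{th:.6f}\t{om:.6f}")
    path.write_text("\n".join(lines) + "\n")


def write_dataset(trials: list[SimulatedTrial], outdir) -> Path:
    """Write every trial's files plus a YAML manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in trials:
        stem = f"p{tr.participant_id:02d}_{tr.task}_t{tr.trial_index}"
        brace_p = outdir / f"{stem}.brace.txt"
        mocap_p = outdir / f"{stem}.mocap.tsv"
        truth_p = outdir / f"{stem}.truth.tsv"
        sio.write_brace_txt(tr.brace_recording, brace_p)
        sio.write_mocap_tsv(tr.mocap_recording, mocap_p)
        _write_truth_tsv(tr, truth_p)
        entries.append(
            dict(
                participant=tr.participant_id, task=tr.task, trial=tr.trial_index,
                brace=brace_p.name, mocap=mocap_p.name, truth=truth_p.name,
                event_start_s=round(tr.event_start_s, 6),
                event_end_s=round(tr.event_end_s, 6),
                offset_s=round(tr.offset_s, 6),
            )
        )
    manifest = outdir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"trials": entries}, sort_keys=False))
    return manifest


def read_dataset(manifest_path) -> list[SimulatedTrial]:
    """Load a written dataset back into :class:`SimulatedTrial` objects."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    meta = yaml.safe_load(manifest_path.read_text())
    trials = []
    for e in meta["trials"]:
        brace = sio.read_brace_txt(root / e["brace"])
        mocap = sio.read_mocap_tsv(root / e["mocap"])
        rate = None
        rows = []
        for line in (root / e["truth"]).read_text().splitlines():
            if line.startswith("#rate_hz="):
                rate = float(line.split("=", 1)[1])
            elif line and not line.startswith(("#", "time_s")):
                rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        theta = JointCurve(t=arr[:, 0], value=arr[:, 1], quantity="angle", rate_hz=rate)
        omega = JointCurve(t=arr[:, 0], value=arr[:, 2], quantity="velocity", rate_hz=rate)
        trials.append(
            SimulatedTrial(
                participant_id=e["participant"], task=e["task"], trial_index=e["trial"],
                brace_recording=brace, mocap_recording=mocap,
                truth_joint_angle=theta, truth_joint_velocity=omega,
                event_start_s=e["event_start_s"], event_end_s=e["event_end_s"],
                offset_s=e["offset_s"],
            )
        )
    return trials
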