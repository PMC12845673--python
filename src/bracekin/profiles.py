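"""Ground-truth thigh/shank angle trajectories for five daily-living tasks.

Each activity-of-daily-living (ADL) profile is built from smooth bump
functions (squared sine or normalised Bernstein-type bumps), giving
C1-continuous segment trajectories whose difference — the sagittal knee
angle, flexion positive — starts and ends near the static standing value
and reaches the requested peak flexion exactly once per movement
repetition.  Level and slope walking are periodic (one flexion bump per
stride, three strides by default); stair, sit-to-stand and shoelace
profiles are single bouts with task-specific timing of the flexion peak.

The split of the knee angle into thigh and shank motion uses a fixed
per-task thigh share: during sitting most of the flexion comes from the
thigh segment pitching back, during swing-phase walking mostly from the
shank swinging forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import UnknownTaskError

TASKS = ("walk", "slope", "stair", "sit", "shoelace")

#: Conventional defaults: peak sagittal knee flexion (deg) and bout
#: duration (s) per task.  Walking swing-phase flexion ~60 deg, chair
#: sit-to-stand ~90 deg, deep stair/shoelace flexion ~90-110 deg.
TASK_PEAK_DEG = {"walk": 60.0, "slope": 65.0, "stair": 95.0, "sit": 90.0, "shoelace": 110.0}
TASK_DURATION_S = {"walk": 3.0, "slope": 4.0, "stair": 5.0, "sit": 4.0, "shoelace": 6.0}
#: Number of movement repetitions (strides for gait tasks, bouts otherwise).
TASK_REPS = {"walk": 3, "slope": 3, "stair": 1, "sit": 1, "shoelace": 1}
#: Fraction of the knee angle carried by the thigh segment.
TASK_THIGH_SHARE = {"walk": 0.30, "slope": 0.35, "stair": 0.45, "sit": 0.55, "shoelace": 0.30}
#: (a, b) exponents of the u^a (1-u)^b bout bump; peak sits at a/(a+b).
TASK_BUMP_SHAPE = {"stair": (2, 3), "sit": (2, 2), "shoelace": (3, 3)}


@dataclass
class AdlProfile:
    """Parametric thigh and shank sagittal tilt trajectories for one task.

    ``thigh_angle_fn`` / ``shank_angle_fn`` map time in seconds (vectorised)
    to segment tilt in degrees; the implied knee angle is their difference.
    """

    task: str
    duration_s: float
    thigh_angle_fn: Callable[[np.ndarray], np.ndarray]
    shank_angle_fn: Callable[[np.ndarray], np.ndarray]
    peak_flexion_deg: float
    n_reps: int = 1

    def joint_angle(self, t) -> np.ndarray:
        return self.thigh_angle_fn(t) - self.shank_angle_fn(t)

    def joint_velocity(self, t, h: float = 1e-4) -> np.ndarray:
        """Knee angular velocity (deg/s) by central difference on the
        continuous trajectory."""
        t = np.asarray(t, dtype=float)
        return (self.joint_angle(t + h) - self.joint_angle(t - h)) / (2.0 * h)


def _periodic_bump(u: np.ndarray, n_reps: int) -> np.ndarray:
    """sin^2 flexion bump repeated once per stride; C-infinity, in [0, 1]."""
    return np.sin(np.pi * np.mod(u * n_reps, 1.0)) ** 2


def _bout_bump(u: np.ndarray, a: int, b: int) -> np.ndarray:
    """Normalised u^a (1-u)^b bump on [0, 1]; C1 at both ends, single
    interior maximum at u = a/(a+b)."""
    u = np.clip(u, 0.0, 1.0)
    peak = (a / (a + b)) ** a * (b / (a + b)) ** b
    return u**a * (1.0 - u) ** b / peak


def generate_adl_profile(
    task: str, peak_flexion_deg: float | None = None, duration_s: float | None = None
) -> AdlProfile:
    """Build the ground-truth segment trajectories for one ADL bout.

    Parameters
    ----------
    task:
        One of ``walk``, ``slope``, ``stair``, ``sit``, ``shoelace``.
    peak_flexion_deg:
        Maximum knee flexion reached (degrees, within [10, 160]); default
        is the task's conventional value.
    duration_s:
        Total bout duration in seconds (> 0).
    """
    if task not in TASKS:
        raise UnknownTaskError(f"unknown ADL task: {task!r}; expected one of {TASKS}")
    peak = TASK_PEAK_DEG[task] if peak_flexion_deg is None else float(peak_flexion_deg)
    dur = TASK_DURATION_S[task] if duration_s is None else float(duration_s)
    if not (10.0 <= peak <= 160.0):
        raise ValueError(f"peak_flexion_deg must lie in [10, 160], got {peak}")
    if dur <= 0:
        raise ValueError("duration_s must be positive")
    n_reps = TASK_REPS[task]
    share = TASK_THIGH_SHARE[task]

    if task in ("walk", "slope"):
        def joint(t, peak=peak, dur=dur, n=n_reps):
            u = np.clip(np.asarray(t, dtype=float) / dur, 0.0, 1.0)
            return peak * _periodic_bump(u, n)
    else:
        a, b = TASK_BUMP_SHAPE[task]
        def joint(t, peak=peak, dur=dur, a=a, b=b):
            u = np.asarray(t, dtype=float) / dur
            return peak * _bout_bump(u, a, b)

    def thigh(t, joint=joint, share=share):
        return share * joint(t)

    def shank(t, joint=joint, share=share):
        return (share - 1.0) * joint(t)

    return AdlProfile(
        task=task,
        duration_s=dur,
        thigh_angle_fn=thigh,
        shank_angle_fn=shank,
        peak_flexion_deg=peak,
        n_reps=n_reps,
    )
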