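"""Core time-series containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CYCLE_POINTS = 101  # 0..100 % of movement cycle in 1 % steps
CYCLE_GRID = np.arange(N_CYCLE_POINTS, dtype=float)


@dataclass
class SegmentAngleSeries:
    """Sagittal tilt of one body segment over time, degrees."""

    t: np.ndarray
    tilt_deg: np.ndarray
    segment: str  # "thigh" | "shank"


@dataclass
class JointCurve:
    """Uniformly sampled knee angle (deg) or angular velocity (deg/s)."""

    t: np.ndarray
    value: np.ndarray
    quantity: str  # "angle" | "velocity"
    rate_hz: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same shape")


@dataclass
class NormalizedCurve:
    """A curve resampled onto the fixed 0-100 % movement-cycle grid."""

    value: np.ndarray
    quantity: str
    n_source_samples: int = 0
    grid: np.ndarray = field(default_factory=lambda: CYCLE_GRID.copy())

    def __post_init__(self):
        self.value = np.asarray(self.value, dtype=float)
        if self.value.size != N_CYCLE_POINTS:
            raise ValueError(f"normalized curves have exactly {N_CYCLE_POINTS} points")
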