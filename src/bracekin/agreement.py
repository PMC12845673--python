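"""Method-agreement and validity statistics for brace vs criterion.

Covers the device-validation suite: full-curve RMSE with its qualitative
bands (< 5 deg excellent, 5-10 deg good, > 10 deg poor), the
RMSE-to-observed-SD ratio (RSR; <= 0.50 very good, 0.51-0.60 good,
0.61-0.70 satisfactory, > 0.70 unsatisfactory), Bland-Altman bias and 95 %
limits of agreement on per-participant peak values with a 5 % acceptability
criterion, and the standard error of measurement SEM = SD(d)/sqrt(2) with
its minimal detectable change MDC95 = 1.96 sqrt(2) SEM.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .curves import NormalizedCurve
from .errors import PairingError


@dataclass
class AgreementReport:
    """All validity metrics for one task x one quantity."""

    task: str
    quantity: str  # "angle" | "velocity"
    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    rmse: float
    rsr: float
    sem: float
    mdc: float
    rmse_label: str
    rsr_label: str
    within_5pct: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias_ci_low"], d["bias_ci_high"] = d.pop("bias_ci")
        return d


def rmse_curve(reference: NormalizedCurve | np.ndarray, criterion: NormalizedCurve | np.ndarray) -> float:
    """Root mean square difference between two cycle-normalised curves."""
    a = reference.value if isinstance(reference, NormalizedCurve) else np.asarray(reference, float)
    b = criterion.value if isinstance(criterion, NormalizedCurve) else np.asarray(criterion, float)
    if a.shape != b.shape:
        raise PairingError("curves must share the 101-point grid")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_label(rmse_deg: float) -> str:
    """Qualitative band for a joint-angle RMSE: < 5 deg excellent,
    5-10 deg (inclusive) good, above poor."""
    if rmse_deg < 5.0:
        return "excellent"
    if rmse_deg <= 10.0:
        return "good"
    return "poor"


def rsr(rmse: float, sd_observed: float) -> float:
    """RMSE-observed-standard-deviation ratio."""
    if sd_observed <= 0:
        raise ZeroDivisionError("observed SD must be positive for RSR")
    return float(rmse / sd_observed)


def rsr_label(value: float) -> str:
    """Qualitative RSR band: <= 0.50 very good, 0.51-0.60 good,
    0.61-0.70 satisfactory, > 0.70 unsatisfactory."""
    if value <= 0.50:
        return "very_good"
    if value <= 0.60:
        return "good"
    if value <= 0.70:
        return "satisfactory"
    return "unsatisfactory"


def bland_altman(ref_peaks, crit_peaks):
    """Bland-Altman agreement of paired per-participant peak values.

    Differences are reference minus criterion.  Returns
    ``(bias, (loa_low, loa_high), (ci_low, ci_high), within_5pct)`` where
    the limits of agreement are bias +/- 1.96 SD(d), the CI is the
    t-based 95 % interval of the bias, and ``within_5pct`` flags |bias|
    within 5 % of the grand mean of the pairwise averages.
    """
    ref = np.asarray(ref_peaks, dtype=float)
    crit = np.asarray(crit_peaks, dtype=float)
    if ref.shape != crit.shape or ref.ndim != 1:
        raise PairingError("peak vectors must be paired 1-D arrays")
    n = ref.size
    if n < 3:
        raise PairingError("Bland-Altman needs >= 3 pairs")
    d = ref - crit
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    ci = (bias - half, bias + half)
    grand_mean = float(np.mean((ref + crit) / 2.0))
    within = bool(abs(bias) <= 0.05 * abs(grand_mean))
    return bias, loa, ci, within


def sem_mdc(ref_peaks, crit_peaks) -> tuple[float, float]:
    """Standard error of measurement and 95 % minimal detectable change
    from paired difference scores: SEM = SD(d)/sqrt(2),
    MDC = 1.96 sqrt(2) SEM."""
    ref = np.asarray(ref_peaks, dtype=float)
    crit = np.asarray(crit_peaks, dtype=float)
    if ref.shape != crit.shape or ref.size < 3:
        raise PairingError("SEM needs >= 3 paired values")
    sd = float((ref - crit).std(ddof=1))
    sem = sd / np.sqrt(2.0)
    mdc = 1.96 * np.sqrt(2.0) * sem
    return float(sem), float(mdc)


def validity_report(
    task: str,
    quantity: str,
    rmse: float,
    sd_observed: float,
    ref_peaks,
    crit_peaks,
) -> AgreementReport:
    """Compose the full agreement report for one task x quantity."""
    bias, loa, ci, within = bland_altman(ref_peaks, crit_peaks)
    sem, mdc = sem_mdc(ref_peaks, crit_peaks)
    ratio = rsr(rmse, sd_observed)
    return AgreementReport(
        task=task,
        quantity=quantity,
        bias=bias,
        loa_low=loa[0],
        loa_high=loa[1],
        bias_ci=ci,
        rmse=float(rmse),
        rsr=ratio,
        sem=sem,
        mdc=mdc,
        rmse_label=rmse_label(rmse),
        rsr_label=rsr_label(ratio),
        within_5pct=within,
    )
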