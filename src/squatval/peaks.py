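"""Peak-knee-flexion extraction.

All outcome variables are read at the instant of peak knee flexion of a
trial, which suppresses velocity effects on the comparison.  Each modality
locates the peak on its own knee sagittal curve (the two systems' summary
values were produced independently); the extraction mode can be switched to
a shared instant through configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .optical import JointAngleSeries

__all__ = ["PeakExtract", "detect_peak_knee_flexion", "extract_at_peak", "peaks_to_frame"]

#: PeakExtract field -> (joint, plane) in a JointAngleSeries bundle
VARIABLE_MAP = {
    "knee_flexion": ("knee", "sagittal"),
    "hip_flexion": ("hip", "sagittal"),
    "hip_sway": ("hip", "frontal"),
    "spine_flexion": ("spine", "sagittal"),
    "spine_sway": ("spine", "frontal"),
}


@dataclass(frozen=True)
class PeakExtract:
    """All five outcome variables of one trial at peak knee flexion (deg)."""

    subject: int
    trial: int
    modality: str
    peak_time_s: float
    knee_flexion: float
    hip_flexion: float
    hip_sway: float
    spine_flexion: float
    spine_sway: float


def detect_peak_knee_flexion(
    time: np.ndarray, knee_sagittal: np.ndarray, min_peak_deg: float = 1.0
) -> tuple[float, float]:
    """Global maximum of the knee sagittal curve; ties go to the earlier time.

    A flat-at-zero or all-missing curve raises (no squat detected); a
    maximum on the first or last sample triggers a warning (no interior
    maximum — e.g. a monotone ramp).
    """
    time = np.asarray(time, dtype=float)
    x = np.asarray(knee_sagittal, dtype=float)
    if len(x) == 0 or np.all(np.isnan(x)):
        raise ValueError("no knee flexion data: cannot detect a squat")
    finite = np.where(np.isnan(x), -np.inf, x)
    i = int(np.argmax(finite))  # argmax returns the first (earliest) maximum
    if finite[i] < min_peak_deg:
        raise ValueError(
            f"knee sagittal curve never exceeds {min_peak_deg} deg: no squat detected"
        )
    if i in (0, len(x) - 1):
        warnings.warn("peak knee flexion on a series endpoint (no interior maximum)",
                      stacklevel=2)
    return float(time[i]), float(x[i])


def extract_at_peak(
    series: dict[str, JointAngleSeries],
    subject: int = 0,
    trial: int = 0,
    peak_time: float | None = None,
) -> PeakExtract:
    """Sample every outcome variable at the peak-knee-flexion frame.

    With *peak_time* None the peak is located on this bundle's own knee
    curve (per-modality instant); passing a time pins the extraction to a
    shared instant instead.  All series must share one timeline.
    """
    knee = series["knee"]
    for s in series.values():
        if len(s.time) != len(knee.time) or not np.allclose(s.time, knee.time):
            raise ValueError("all joint series of a trial must share one timeline")
    if peak_time is None:
        peak_time, _ = detect_peak_knee_flexion(knee.time, knee.sagittal)
    i = int(np.argmin(np.abs(knee.time - peak_time)))
    values = {}
    for var, (joint, plane) in VARIABLE_MAP.items():
        x = getattr(series[joint], plane)
        if np.isnan(x[i]):
            raise ValueError(f"{var} missing at the peak frame (t={peak_time:.3f} s)")
        values[var] = float(x[i])
    return PeakExtract(
        subject=subject,
        trial=trial,
        modality=knee.modality,
        peak_time_s=float(knee.time[i]),
        **values,
    )


def peaks_to_frame(extracts: list[PeakExtract]) -> pd.DataFrame:
    """Peaks table: subject, trial, modality, peak time and the five variables."""
    rows = [
        {
            "subject": e.subject,
            "trial": e.trial,
            "modality": e.modality,
            "peak_time_s": round(e.peak_time_s, 4),
            **{v: round(getattr(e, v), 1) for v in VARIABLE_MAP},
        }
        for e in extracts
    ]
    return pd.DataFrame(rows)
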