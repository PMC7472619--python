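"""Sensor (IMU) pipeline: quaternion CSV -> tilt/sway/twist joint angles.

The new-tool path starts from per-segment orientation quaternions at 50 Hz
(the fusion to orientation happens inside the sensors).  Each stream is
validated (unit norm, hemisphere continuity), calibrated per segment against
its averaged upright reading — which cancels constant sensor-to-segment
mounting misalignment exactly and zeroes all joint angles at the upright
pose — and converted per joint into tilt (sagittal), sway (frontal) and
twist (transverse) angles.  For comparison against the 120 Hz optical
reference, *orientations* (never finished angle curves) are resampled onto
the reference timeline by spherical linear interpolation and the angles are
recomputed afterwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import (
    SignConvention,
    chordal_mean,
    quat_conjugate,
    quat_multiply,
    quat_normalize,
    relative_orientation,
    sign_convention,
    slerp,
    tilt_sway_twist,
)
from .optical import JointAngleSeries
from .simulate import JOINTS

__all__ = [
    "QuaternionFrameSeries",
    "read_quaternion_csv",
    "segment_calibration",
    "sensor_joint_angles",
    "resample_to_reference",
]

log = logging.getLogger(__name__)


@dataclass
class QuaternionFrameSeries:
    """Per-segment unit quaternion streams on a common timestamp grid.

    ``quats`` maps segment name -> (n, 4) scalar-first unit quaternions,
    renormalized and hemisphere-aligned (consecutive samples have a
    non-negative 4-vector dot product).
    """

    time: np.ndarray
    quats: dict[str, np.ndarray]
    fs: float = 50.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("quaternion timestamps must be strictly increasing")
            self.fs = 1.0 / float(np.mean(dt))
        self.time = t

    @property
    def segments(self) -> list[str]:
        return list(self.quats)


def _fix_hemisphere(q: np.ndarray) -> np.ndarray:
    """Flip sample signs so consecutive quaternions share a hemisphere."""
    dots = np.sum(q[1:] * q[:-1], axis=1)
    flips = np.concatenate(([1.0], np.cumprod(np.where(dots < 0, -1.0, 1.0))))
    return q * flips[:, np.newaxis]


def read_quaternion_csv(
    path: str | Path, norm_warn: float = 1e-6, norm_fail: float = 1e-2
) -> QuaternionFrameSeries:
    """Load the IMU CSV dialect (time_s + <segment>_w/_x/_y/_z).

    Every sample is checked for unit norm: deviations beyond *norm_fail*
    abort with the offending line numbers (corrupt stream); deviations
    beyond *norm_warn* are renormalized and logged.  Hemisphere continuity
    is enforced after loading.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    segs = sorted({c[:-2] for c in df.columns if c.endswith("_w")})
    if not segs:
        raise ValueError(f"{path}: no <segment>_w/_x/_y/_z quaternion columns found")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    quats: dict[str, np.ndarray] = {}
    warns: list[str] = []
    for seg in segs:
        cols = [f"{seg}_{c}" for c in "wxyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: segment {seg} lacks columns {missing}")
        q = df[cols].to_numpy(dtype=float)
        bad_rows = np.flatnonzero(~np.isfinite(q).all(axis=1))
        if len(bad_rows):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: malformed rows (lines {[int(i) + 2 for i in bad_rows[:5]]})")
        norms = np.linalg.norm(q, axis=1)
        off = np.abs(norms - 1.0)
        fail = np.flatnonzero(off > norm_fail)
        if len(fail):
            raise ValueError(
                f"{path}: segment {seg} quaternion norm off by > {norm_fail} "
                f"(lines {[int(i) + 2 for i in fail[:5]]}) — corrupt stream"
            )
        n_renorm = int(np.sum(off > norm_warn))
        if n_renorm:
            msg = f"{seg}: renormalized {n_renorm} sample(s) with |norm-1| > {norm_warn}"
            warns.append(msg)
            log.warning("%s: %s", path, msg)
        q = q / norms[:, np.newaxis]
        quats[seg] = _fix_hemisphere(q)
    return QuaternionFrameSeries(time=t, quats=quats, warnings=warns)


def segment_calibration(cal: QuaternionFrameSeries) -> dict[str, np.ndarray]:
    """Averaged upright reading per segment over the static window."""
    return {seg: chordal_mean(q) for seg, q in cal.quats.items()}


def apply_segment_calibration(
    series: QuaternionFrameSeries, reference: dict[str, np.ndarray]
) -> QuaternionFrameSeries:
    """Right-multiply each stream by the inverse of its upright reading.

    The sensor reading is (segment world orientation) ⊗ (constant mounting
    rotation); right-multiplying by the inverse upright reading cancels the
    mount exactly and leaves the segment's rotation relative to upright.
    """
    out = {
        seg: quat_normalize(quat_multiply(q, quat_conjugate(reference[seg])[np.newaxis, :]))
        for seg, q in series.quats.items()
    }
    return QuaternionFrameSeries(
        time=series.time, quats=out, warnings=list(series.warnings)
    )


def resample_to_reference(
    series: QuaternionFrameSeries, ref_time: np.ndarray
) -> QuaternionFrameSeries:
    """SLERP every segment stream onto *ref_time*.

    Reference times outside the sensor window are truncated (logged); an
    empty overlap is an error.  A reference time equal to a sample time
    returns that sample exactly.
    """
    ref_time = np.asarray(ref_time, dtype=float)
    t = series.time
    keep = (ref_time >= t[0] - 1e-9) & (ref_time <= t[-1] + 1e-9)
    if not keep.any():
        raise ValueError("reference timeline does not overlap the sensor window")
    if not keep.all():
        log.warning(
            "reference timeline truncated to sensor window: %d of %d samples kept",
            int(keep.sum()), len(ref_time),
        )
    rt = np.clip(ref_time[keep], t[0], t[-1])
    idx = np.clip(np.searchsorted(t, rt, side="right") - 1, 0, len(t) - 2)
    frac = (rt - t[idx]) / (t[idx + 1] - t[idx])
    out = {}
    for seg, q in series.quats.items():
        out[seg] = slerp(q[idx], q[idx + 1], frac)
    return QuaternionFrameSeries(time=rt, quats=out, warnings=list(series.warnings))


def sensor_joint_angles(
    series: QuaternionFrameSeries,
    calibration: QuaternionFrameSeries,
    signs: dict[str, SignConvention] | None = None,
    side: str = "right",
    ref_time: np.ndarray | None = None,
) -> dict[str, JointAngleSeries]:
    """Quaternion streams -> calibrated tilt/sway/twist joint angles.

    Per joint: per-segment upright calibration, relative orientation of the
    secondary segment in the primary's frame, then tilt/sway/twist — the
    sagittal, frontal and transverse outputs respectively.  When *ref_time*
    is given, orientations are SLERP-resampled onto it first and the angles
    recomputed on that grid.  Singular frames (longitudinal axis flipped by
    ~180 deg) are flagged in the series warnings.
    """
    signs = signs or {j: sign_convention(j, side) for j in JOINTS}
    reference = segment_calibration(calibration)
    cal_series = apply_segment_calibration(series, reference)
    if ref_time is not None:
        cal_series = resample_to_reference(cal_series, ref_time)
    out: dict[str, JointAngleSeries] = {}
    for joint, (primary, secondary) in JOINTS.items():
        for seg in (primary, secondary):
            if seg not in cal_series.quats:
                raise ValueError(f"sensor series lacks segment '{seg}' for joint '{joint}'")
        q_rel = relative_orientation(cal_series.quats[primary], cal_series.quats[secondary])
        tst = tilt_sway_twist(q_rel, signs=signs[joint])
        w = list(series.warnings)
        nsing = int(np.sum(tst.singular))
        if nsing:
            w.append(f"singular swing-twist frames: {nsing}")
        out[joint] = JointAngleSeries(
            joint=joint,
            time=cal_series.time,
            sagittal=np.asarray(tst.tilt, dtype=float),
            frontal=np.asarray(tst.sway, dtype=float),
            transverse=np.asarray(tst.twist, dtype=float),
            modality="sensor",
            warnings=w,
        )
    return out


def quaternion_series_from_frame(df: pd.DataFrame) -> QuaternionFrameSeries:
    """Build a validated series from an in-memory IMU table (same dialect)."""
    segs = sorted({c[:-2] for c in df.columns if c.endswith("_w")})
    t = df["time_s"].to_numpy(dtype=float)
    quats = {}
    for seg in segs:
        q = df[[f"{seg}_{c}" for c in "wxyz"]].to_numpy(dtype=float)
        n = np.linalg.norm(q, axis=1)
        quats[seg] = _fix_hemisphere(q / n[:, np.newaxis])
    return QuaternionFrameSeries(time=t, quats=quats)
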