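"""Optical (reference-system) pipeline: marker CSV -> Euler joint angles.

The gold-standard path mirrors conventional laboratory processing: labelled
120 Hz marker trajectories are gap-filled, low-pass filtered with a
zero-phase 4th-order Butterworth at 3 Hz, turned into per-segment
orientations by a least-squares rigid (Procrustes) fit of each four-marker
cluster against its upright-calibration template, and finally converted to
calibrated sagittal / frontal / transverse Euler joint angles for the spine,
hip and knee.

The filter runs forward and backward so peak timing carries no phase lag;
the effective magnitude response is therefore the squared single-pass
response.  Filtering is applied to marker coordinates, not to angles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .kinematics import (
    SignConvention,
    calibrate,
    chordal_mean,
    euler_sagittal_frontal_transverse,
    quat_from_matrix,
    relative_orientation,
    sign_convention,
)
from .simulate import JOINTS, SEGMENTS

__all__ = [
    "MarkerFrameSeries",
    "JointAngleSeries",
    "GapError",
    "read_marker_csv",
    "fill_gaps",
    "butterworth_zero_phase",
    "cluster_pose",
    "optical_joint_angles",
]


class GapError(ValueError):
    """A marker cluster is unusable for longer than the allowed gap."""


@dataclass
class MarkerFrameSeries:
    """Uniformly sampled, labelled 3D marker trajectories (mm).

    ``data`` holds one ``<marker>_x/_y/_z`` column triple per marker plus
    ``time_s``; missing samples are NaN.
    """

    data: pd.DataFrame
    fs: float = 120.0

    def __post_init__(self) -> None:
        if "time_s" not in self.data.columns:
            raise ValueError("marker table must contain a time_s column")
        t = self.data["time_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError("marker timestamps must be uniform")
            self.fs = 1.0 / float(np.mean(dt))

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def markers(self) -> list[str]:
        names = []
        for c in self.data.columns:
            m = re.fullmatch(r"(.+)_x", c)
            if m and f"{m.group(1)}_y" in self.data.columns:
                names.append(m.group(1))
        return names

    def xyz(self, marker: str) -> np.ndarray:
        return self.data[[f"{marker}_{a}" for a in "xyz"]].to_numpy()


@dataclass
class JointAngleSeries:
    """Per-joint sagittal/frontal/transverse angle curves in degrees."""

    joint: str
    time: np.ndarray
    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray
    modality: str  # "optical" or "sensor"
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                f"{self.joint}_sagittal_deg": self.sagittal,
                f"{self.joint}_frontal_deg": self.frontal,
                f"{self.joint}_transverse_deg": self.transverse,
            }
        )


def read_marker_csv(path: str | Path, fs: float = 120.0) -> MarkerFrameSeries:
    """Load the marker CSV dialect (time_s + <marker>_x/_y/_z in mm)."""
    df = pd.read_csv(path)
    return MarkerFrameSeries(df, fs=fs)


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps(series: MarkerFrameSeries, max_gap_s: float = 0.1) -> MarkerFrameSeries:
    """Linearly interpolate marker dropouts up to *max_gap_s* per coordinate.

    Longer gaps are left missing and reported as warnings; if any cluster
    retains fewer than 3 valid markers over a stretch longer than
    *max_gap_s*, a :class:`GapError` names the cluster and interval.
    """
    df = series.data.copy()
    t = df["time_s"].to_numpy()
    max_run = max(int(round(max_gap_s * series.fs)), 1)
    long_gaps: list[str] = []
    for col in df.columns:
        if col == "time_s":
            continue
        x = df[col].to_numpy(dtype=float)
        isnan = np.isnan(x)
        if not isnan.any():
            continue
        runs = _nan_runs(isnan)
        fillable = np.zeros_like(isnan)
        for a, b in runs:  # [a, b) half-open
            interior = a > 0 and b < len(x)
            if interior and (b - a) <= max_run:
                fillable[a:b] = True
            else:
                long_gaps.append(f"{col}: t=[{t[a]:.3f}, {t[min(b, len(t) - 1)]:.3f}] s")
        if fillable.any():
            good = ~isnan
            x[fillable] = np.interp(t[fillable], t[good], x[good])
            df[col] = x
    out = MarkerFrameSeries(df, fs=series.fs)

    # cluster usability: >= 3 fully valid markers per frame
    for seg in _clusters(out):
        valid = np.zeros(len(df), dtype=int)
        for mk in _clusters(out)[seg]:
            valid += (~np.isnan(out.xyz(mk)).any(axis=1)).astype(int)
        bad = valid < 3
        for a, b in _nan_runs(bad):
            if (b - a) > max_run:
                raise GapError(
                    f"cluster '{seg}' has <3 valid markers for "
                    f"t=[{t[a]:.3f}, {t[b - 1]:.3f}] s (> {max_gap_s} s)"
                )
    if long_gaps:
        warnings.warn(f"unfilled marker gaps: {'; '.join(long_gaps)}", stacklevel=2)
    return out


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def _clusters(series: MarkerFrameSeries) -> dict[str, list[str]]:
    """Group marker names into clusters by their '<segment>_m<i>' prefix."""
    groups: dict[str, list[str]] = {}
    for mk in series.markers:
        m = re.fullmatch(r"(.+)_m(\d+)", mk)
        key = m.group(1) if m else mk
        groups.setdefault(key, []).append(mk)
    return groups


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def butterworth_zero_phase(
    x: np.ndarray,
    order: int = 4,
    cutoff_hz: float = 3.0,
    fs: float = 120.0,
    pad_s: float = 1.0,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along axis 0.

    Forward-backward application of an ``order``-th order Butterworth at
    ``cutoff_hz`` with reflective (even) padding of up to *pad_s* seconds per
    end, trimmed afterwards.  Requires the series to outlast three dominant
    filter time constants (3 / cutoff seconds); raises ``ValueError``
    otherwise.  NaNs are rejected — fill gaps first.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= int(3.0 * fs / cutoff_hz):
        raise ValueError(
            f"series of {n} samples is too short to filter at "
            f"{cutoff_hz} Hz (need > {int(3 * fs / cutoff_hz)} samples)"
        )
    if np.isnan(x).any():
        raise ValueError("cannot filter a series with missing samples; fill gaps first")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = min(int(round(pad_s * fs)), n - 1)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_series(series: MarkerFrameSeries, order: int = 4, cutoff_hz: float = 3.0) -> MarkerFrameSeries:
    """Apply the zero-phase Butterworth to every coordinate column."""
    df = series.data.copy()
    cols = [c for c in df.columns if c != "time_s"]
    df[cols] = butterworth_zero_phase(df[cols].to_numpy(), order, cutoff_hz, fs=series.fs)
    return MarkerFrameSeries(df, fs=series.fs)


# ---------------------------------------------------------------------------
# cluster pose fit
# ---------------------------------------------------------------------------

def cluster_pose(
    frames: np.ndarray,
    template: np.ndarray,
    residual_warn_mm: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Least-squares rigid rotation from *template* to each frame.

    Orthogonal Procrustes via SVD with a reflection guard, on
    centroid-aligned marker sets.  ``frames`` is ``(n, k, 3)`` and
    ``template`` ``(k, 3)`` with k >= 3 non-collinear markers.  Returns
    ``(quaternions (n, 4), residual RMS per frame (n,), warnings)``.
    """
    frames = np.asarray(frames, dtype=float)
    template = np.asarray(template, dtype=float)
    if frames.ndim != 3 or frames.shape[1] < 3 or template.shape != frames.shape[1:]:
        raise ValueError("frames must be (n, k>=3, 3) matching the template")
    t0 = template - template.mean(axis=0)
    s = np.linalg.svd(t0, compute_uv=False)
    if s[1] < 1e-9:
        raise ValueError("cluster template is collinear/degenerate")
    f0 = frames - frames.mean(axis=1, keepdims=True)
    # R maps template -> frame: maximise trace(R H^T), H = f0^T t0 per frame
    h = np.einsum("nki,kj->nij", f0, t0)
    u, sv, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    d = np.repeat(np.eye(3)[np.newaxis], len(frames), axis=0)
    d[:, 2, 2] = np.sign(det)
    r = u @ d @ vt
    quats = quat_from_matrix(r)
    fit = np.einsum("nij,kj->nki", r, t0)
    resid = np.sqrt(((f0 - fit) ** 2).sum(axis=(1, 2)) / frames.shape[1])
    warns: list[str] = []
    if np.any(resid > residual_warn_mm):
        nbad = int(np.sum(resid > residual_warn_mm))
        warns.append(
            f"cluster pose residual above {residual_warn_mm} mm in {nbad} frame(s) "
            f"(max {resid.max():.1f} mm)"
        )
    return quats, resid, warns


# ---------------------------------------------------------------------------
# end-to-end: markers -> joint angles
# ---------------------------------------------------------------------------

def _segment_orientations(
    series: MarkerFrameSeries,
    templates: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], list[str]]:
    groups = _clusters(series)
    quats: dict[str, np.ndarray] = {}
    warns: list[str] = []
    for seg, templ in templates.items():
        if seg not in groups:
            raise ValueError(f"marker series lacks cluster '{seg}'")
        frames = np.stack([series.xyz(mk) for mk in sorted(groups[seg])], axis=1)
        q, _, w = cluster_pose(frames, templ)
        quats[seg] = q
        warns += [f"{seg}: {msg}" for msg in w]
    return quats, warns


def _calibration_templates(cal: MarkerFrameSeries) -> dict[str, np.ndarray]:
    """Centred mean cluster shapes over the static upright capture.

    Using the upright capture as the template makes the fitted orientation
    of every segment the rotation *relative to upright*, which is exactly
    the zeroing both systems apply at calibration.
    """
    groups = _clusters(cal)
    templates = {}
    for seg, mks in groups.items():
        pts = np.stack([cal.xyz(mk).mean(axis=0) for mk in sorted(mks)])
        templates[seg] = pts - pts.mean(axis=0)
    return templates


def optical_joint_angles(
    series: MarkerFrameSeries,
    calibration: MarkerFrameSeries,
    signs: dict[str, SignConvention] | None = None,
    side: str = "right",
    order: int = 4,
    cutoff_hz: float = 3.0,
    max_gap_s: float = 0.1,
) -> dict[str, JointAngleSeries]:
    """Marker trajectories -> calibrated Euler joint angles at the marker rate.

    The calibration capture is processed identically (gap fill, zero-phase
    Butterworth, cluster pose); per joint the secondary segment's orientation
    in the primary's frame is zeroed against the averaged upright relative
    orientation and decomposed with the sagittal→frontal→transverse Euler
    sequence.  Gimbal-lock warnings are carried on the series.
    """
    signs = signs or {j: sign_convention(j, side) for j in JOINTS}
    cal = filter_series(fill_gaps(calibration, max_gap_s), order, cutoff_hz)
    mov = filter_series(fill_gaps(series, max_gap_s), order, cutoff_hz)
    templates = _calibration_templates(cal)
    q_cal_seg, warns_cal = _segment_orientations(cal, templates)
    q_mov_seg, warns_mov = _segment_orientations(mov, templates)

    out: dict[str, JointAngleSeries] = {}
    for joint, (primary, secondary) in JOINTS.items():
        q_rel_cal = relative_orientation(q_cal_seg[primary], q_cal_seg[secondary])
        q_rel = relative_orientation(q_mov_seg[primary], q_mov_seg[secondary])
        q0 = chordal_mean(q_rel_cal)
        q = calibrate(q_rel, q0)
        e = euler_sagittal_frontal_transverse(q, signs=signs[joint])
        w = list(warns_cal) + list(warns_mov)
        ngim = int(np.sum(e.gimbal_warning))
        if ngim:
            w.append(f"gimbal lock proximity in {ngim} frame(s)")
        out[joint] = JointAngleSeries(
            joint=joint,
            time=mov.time,
            sagittal=np.asarray(e.sagittal, dtype=float),
            frontal=np.asarray(e.frontal, dtype=float),
            transverse=np.asarray(e.transverse, dtype=float),
            modality="optical",
            warnings=w,
        )
    return out


def write_joint_angles_csv(series: dict[str, JointAngleSeries], path: str | Path) -> None:
    """Write the shared JointAngleSeries CSV dialect (modality-blind)."""
    frames = [s.to_frame().set_index("time_s") for s in series.values()]
    df = pd.concat(frames, axis=1).reset_index()
    df["warnings"] = ";".join(sorted({w for s in series.values() for w in s.warnings}))
    df.to_csv(path, index=False, float_format="%.6f")
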