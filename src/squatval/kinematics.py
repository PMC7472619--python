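"""Quaternion and rotation machinery for joint-angle computation.

All rotations are unit quaternions in scalar-first order ``(w, x, y, z)``.
The composition convention is fixed once, package-wide:

    ``quat_multiply(q1, q2)`` means "apply q2 first, then q1", i.e. the
    rotation matrices satisfy ``R(q1 ⊗ q2) = R(q1) @ R(q2)``.

A quaternion ``q`` maps vectors expressed in a segment's local frame into
the world frame: ``v_world = R(q) @ v_local``.  Every body segment carries
the same right-handed local frame:

* first axis  (x): anterior,
* second axis (y): superior / longitudinal (points proximally),
* third axis  (z): to the subject's right (mediolateral).

Joint angles are produced in two flavours from the same calibrated relative
orientation: an intrinsic Euler sequence resolving the sagittal, frontal and
transverse planes in that order (the conventional optical route), and the
tilt / sway / twist system of the sensor route, built on a swing–twist
decomposition about the longitudinal axis.  Anatomical positive directions
(flexion, adduction, internal rotation, homolateral lateral flexion) are
applied through :class:`SignConvention` so that left- and right-side stance
report the same signs.

All functions broadcast over a leading sample axis: a quaternion argument
may be shape ``(4,)`` or ``(n, 4)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ANTERIOR",
    "LONGITUDINAL",
    "LATERAL",
    "IDENTITY",
    "SegmentAxes",
    "SignConvention",
    "TiltSwayTwist",
    "EulerAngles",
    "sign_convention",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_from_axis_angle",
    "quat_to_matrix",
    "quat_from_matrix",
    "quat_rotate",
    "quat_angle_deg",
    "quat_canonical",
    "relative_orientation",
    "calibrate",
    "swing_twist_decompose",
    "tilt_sway_twist",
    "euler_sagittal_frontal_transverse",
    "slerp",
    "chordal_mean",
    "GIMBAL_LOCK_MARGIN_DEG",
]

# Local segment frame (identical for every segment).
ANTERIOR = np.array([1.0, 0.0, 0.0])
LONGITUDINAL = np.array([0.0, 1.0, 0.0])
LATERAL = np.array([0.0, 0.0, 1.0])  # to the subject's right

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

#: Euler output is flagged when the frontal angle comes within this margin of 90 deg.
GIMBAL_LOCK_MARGIN_DEG = 1.0

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SegmentAxes:
    """Orthonormal, right-handed local frame of a body segment.

    The default is the package-wide convention: x anterior, y longitudinal
    (superior), z to the subject's right.
    """

    anterior: np.ndarray = field(default_factory=lambda: ANTERIOR.copy())
    longitudinal: np.ndarray = field(default_factory=lambda: LONGITUDINAL.copy())
    lateral: np.ndarray = field(default_factory=lambda: LATERAL.copy())

    def __post_init__(self) -> None:
        m = np.column_stack([self.anterior, self.longitudinal, self.lateral])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("segment axes must be orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("segment axes must be right-handed (det +1)")


@dataclass(frozen=True)
class SignConvention:
    """Per-joint sign multipliers mapping raw angles to anatomical positives.

    Raw angles are defined in the shared local frame (see module docstring):
    raw sagittal is positive when the longitudinal axis tips anteriorly
    (flexion), raw frontal positive when it tips to the subject's right,
    raw transverse positive when the anterior axis turns to the subject's
    left (internal rotation of a right-side segment).  The multipliers turn
    these into flexion-positive, adduction-positive (hip/knee) or
    homolateral-lateral-flexion-positive (spine), internal-rotation-positive
    angles for the given stance side.
    """

    joint: str
    side: str
    sagittal: int = 1
    frontal: int = 1
    transverse: int = 1

    def __post_init__(self) -> None:
        for m in (self.sagittal, self.frontal, self.transverse):
            if m not in (-1, 1):
                raise ValueError("sign multipliers must be -1 or +1")


def sign_convention(joint: str, side: str = "right") -> SignConvention:
    """Return the sign convention for *joint* (``knee``/``hip``/``spine``).

    With right-side stance, raw frontal lean to the right is abduction for
    the hip/knee (so adduction-positive needs a flip) but homolateral
    lateral flexion for the spine (no flip); both flip when the stance side
    is the left.  Transverse follows internal-rotation-positive the same way.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if joint not in ("knee", "hip", "spine"):
        raise ValueError(f"unknown joint {joint!r}")
    mirror = 1 if side == "right" else -1
    if joint == "spine":
        return SignConvention(joint, side, sagittal=1, frontal=mirror, transverse=mirror)
    return SignConvention(joint, side, sagittal=1, frontal=-mirror, transverse=mirror)


@dataclass(frozen=True)
class TiltSwayTwist:
    """Tilt / sway / twist angles (degrees) plus the total swing angle.

    tilt: sagittal-plane deviation of the secondary segment's longitudinal
    axis; sway: frontal-plane deviation; twist: rotation about the secondary
    longitudinal axis; swing: total (unsigned) deviation of the longitudinal
    axis.  Scalars or arrays, degrees.
    """

    tilt: np.ndarray
    sway: np.ndarray
    twist: np.ndarray
    swing: np.ndarray
    singular: np.ndarray  # True where swing ~ 180 deg (tilt/sway undefined)


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic sagittal→frontal→transverse Euler angles in degrees."""

    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray
    gimbal_warning: np.ndarray  # True where |frontal| is within 1 deg of 90


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------

def _as_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion array must have last dimension 4, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("quaternion contains non-finite components")
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return q scaled to unit norm; reject (near-)zero quaternions."""
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2 (apply q2, then q1)."""
    q1 = _as_quat(q1)
    q2 = _as_quat(q2)
    w1, v1 = q1[..., :1], q1[..., 1:]
    w2, v2 = q2[..., :1], q2[..., 1:]
    w = w1 * w2 - np.sum(v1 * v2, axis=-1, keepdims=True)
    v = w1 * v2 + w2 * v1 + np.cross(v1, v2)
    return np.concatenate([w, v], axis=-1)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate (= inverse for unit quaternions)."""
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_from_axis_angle(axis: Iterable[float], angle_rad: float | np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of *angle_rad* about *axis*."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    angle = np.asarray(angle_rad, dtype=float)
    half = angle[..., np.newaxis] / 2.0 if angle.ndim else np.array([angle / 2.0])
    w = np.cos(half)
    v = np.sin(half) * axis
    out = np.concatenate([w, v], axis=-1)
    return out if angle.ndim else out.reshape(4)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with v_world = R @ v_local (batched)."""
    q = quat_normalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    """Unit quaternion (scalar-first, w >= 0) from rotation matrices.

    Shepperd's method, vectorized over a leading batch axis.
    """
    m = np.asarray(m, dtype=float)
    single = m.ndim == 2
    if single:
        m = m[np.newaxis]
    t = np.einsum("...ii", m)
    q = np.empty(m.shape[:-2] + (4,))
    # four candidate pivots; pick the numerically largest per matrix
    cand = np.stack(
        [t, m[..., 0, 0], m[..., 1, 1], m[..., 2, 2]], axis=-1
    )
    choice = np.argmax(cand, axis=-1)

    # pivot on trace
    s = np.sqrt(np.maximum(t + 1.0, 0.0)) * 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        q0 = np.stack(
            [
                0.25 * s,
                (m[..., 2, 1] - m[..., 1, 2]) / s,
                (m[..., 0, 2] - m[..., 2, 0]) / s,
                (m[..., 1, 0] - m[..., 0, 1]) / s,
            ],
            axis=-1,
        )
        qs = [q0]
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            si = np.sqrt(np.maximum(1.0 + m[..., i, i] - m[..., j, j] - m[..., k, k], 0.0)) * 2.0
            qi = np.empty_like(q0)
            qi[..., 0] = (m[..., k, j] - m[..., j, k]) / si
            qi[..., 1 + i] = 0.25 * si
            qi[..., 1 + j] = (m[..., j, i] + m[..., i, j]) / si
            qi[..., 1 + k] = (m[..., k, i] + m[..., i, k]) / si
            qs.append(qi)
    q = np.choose(choice[..., np.newaxis], qs)
    q = quat_normalize(q)
    q = quat_canonical(q)
    return q[0] if single else q


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q."""
    q = _as_quat(q)
    w, u = q[..., :1], q[..., 1:]
    v = np.asarray(v, dtype=float)
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_angle_deg(q: np.ndarray) -> np.ndarray:
    """Total rotation angle in degrees, in [0, 180]."""
    q = quat_normalize(q)
    w = np.abs(q[..., 0])
    vec = np.linalg.norm(q[..., 1:], axis=-1)
    return np.degrees(2.0 * np.arctan2(vec, w))


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Fix the q/-q sign ambiguity: make the scalar part non-negative."""
    q = _as_quat(q)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


# ---------------------------------------------------------------------------
# relative orientation and calibration
# ---------------------------------------------------------------------------

def relative_orientation(q_primary: np.ndarray, q_secondary: np.ndarray) -> np.ndarray:
    """Secondary segment's orientation expressed in the primary's frame.

    Both inputs must be world-frame unit quaternions; the result is
    ``conj(q_primary) ⊗ q_secondary`` and is invariant under any common
    world-frame rotation of both segments.
    """
    return quat_multiply(quat_conjugate(quat_normalize(q_primary)),
                         quat_normalize(q_secondary))


def calibrate(q_rel: np.ndarray, q_rel_upright: np.ndarray) -> np.ndarray:
    """Zero a relative orientation against its upright-pose reference.

    Returns ``conj(q_rel_upright) ⊗ q_rel``; identity (hence all angles
    zero) when the joint is in the calibration pose.
    """
    return quat_multiply(quat_conjugate(quat_normalize(q_rel_upright)),
                         quat_normalize(q_rel))


def chordal_mean(q: np.ndarray) -> np.ndarray:
    """Hemisphere-aligned component-wise mean of a quaternion series.

    Adequate for averaging tightly clustered orientations such as a static
    calibration window; all samples are first flipped into the hemisphere of
    the first sample.
    """
    q = quat_normalize(np.atleast_2d(q))
    dots = q @ q[0]
    q = q * np.where(dots < 0, -1.0, 1.0)[:, np.newaxis]
    return quat_normalize(q.mean(axis=0))


# ---------------------------------------------------------------------------
# swing-twist decomposition and the tilt/sway/twist system
# ---------------------------------------------------------------------------

def swing_twist_decompose(
    q: np.ndarray, twist_axis: Iterable[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor q into swing ⊗ twist with the twist about *twist_axis*.

    The twist quaternion's rotation axis is parallel to *twist_axis*; the
    swing's axis is orthogonal to it.  Returns ``(swing, twist, singular)``
    where *singular* flags the undefined case of a 180-degree rotation
    perpendicular to the twist axis (twist is set to identity there).
    """
    axis = np.asarray(twist_axis, dtype=float)
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("twist_axis must be unit-norm")
    q = quat_normalize(q)
    single = q.ndim == 1
    qb = np.atleast_2d(q)
    p = qb[:, 1:] @ axis  # projection of the vector part onto the axis
    twist = np.concatenate([qb[:, :1], p[:, np.newaxis] * axis[np.newaxis, :]], axis=-1)
    tn = np.linalg.norm(twist, axis=-1)
    singular = tn < 1e-9
    twist = np.where(
        singular[:, np.newaxis], IDENTITY, twist / np.where(tn < 1e-9, 1.0, tn)[:, np.newaxis]
    )
    swing = quat_multiply(qb, quat_conjugate(twist))
    if single:
        return swing[0], twist[0], singular[0]
    return swing, twist, singular


def _twist_angle_deg(q: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed twist angle about *axis* in (-180, 180], with singular flag."""
    single = np.asarray(q).ndim == 1
    qb = np.atleast_2d(quat_normalize(q))
    # flip each sample so the scalar part is >= 0; keeps the angle in (-180, 180]
    qb = quat_canonical(qb)
    p = qb[:, 1:] @ axis
    singular = (np.abs(qb[:, 0]) < 1e-9) & (np.abs(p) < 1e-9)
    ang = np.degrees(2.0 * np.arctan2(p, qb[:, 0]))
    ang = np.where(singular, 0.0, ang)
    if single:
        return ang[0], singular[0]
    return ang, singular


def tilt_sway_twist(
    q_cal: np.ndarray,
    axes: SegmentAxes | None = None,
    signs: SignConvention | None = None,
) -> TiltSwayTwist:
    """Tilt / sway / twist / swing angles of a calibrated relative rotation.

    Let ``v`` be the image of the secondary segment's longitudinal axis
    under ``q_cal``.  Tilt is the sagittal-plane angle
    ``atan2(v·anterior, v·longitudinal)``; sway is the elevation of ``v``
    out of the sagittal plane, ``atan2(v·lateral, ||sagittal component||)``;
    swing is the total unsigned deviation ``angle(u, v)``; twist is the
    signed swing–twist angle about the longitudinal axis.  Tilt and sway are
    defined purely from ``v`` (no rotation-sequence dependence) and reduce
    to the sagittal/frontal Euler angles exactly — in the planar cases and
    in general, since they parametrize the same swing of the longitudinal
    axis.  Angles in degrees with anatomical signs applied.
    """
    axes = axes or SegmentAxes()
    q_cal = quat_normalize(q_cal)
    single = q_cal.ndim == 1
    qb = np.atleast_2d(q_cal)
    u = axes.longitudinal
    v = quat_rotate(qb, u)
    va = v @ axes.anterior
    vl = v @ axes.longitudinal
    vr = v @ axes.lateral

    sag_norm = np.hypot(va, vl)  # length of v's sagittal-plane component
    singular = sag_norm < 1e-9  # v (anti)parallel to +/- lateral, or swing ~180 on the lateral axis
    antiparallel = vl < -1.0 + 1e-12  # swing ~ 180 deg: tilt/sway direction undefined
    tilt = np.degrees(np.arctan2(va, vl))
    sway = np.degrees(np.arctan2(vr, sag_norm))
    swing = np.degrees(np.arctan2(np.hypot(va, vr), vl))  # angle(u, v) >= 0
    _, twist_q, tw_singular = swing_twist_decompose(qb, u)
    twist, _ = _twist_angle_deg(twist_q, u)

    flag = singular | antiparallel | tw_singular
    if signs is not None:
        tilt = signs.sagittal * tilt
        sway = signs.frontal * sway
        twist = signs.transverse * twist
    if single:
        return TiltSwayTwist(tilt[0], sway[0], twist[0], swing[0], flag[0])
    return TiltSwayTwist(tilt, sway, twist, swing, flag)


# ---------------------------------------------------------------------------
# Euler sequence (sagittal -> frontal -> transverse)
# ---------------------------------------------------------------------------

def euler_sagittal_frontal_transverse(
    q_cal: np.ndarray,
    axes: SegmentAxes | None = None,
    signs: SignConvention | None = None,
) -> EulerAngles:
    """Intrinsic Euler decomposition resolving sagittal, frontal, transverse.

    First rotation about the mediolateral (right) axis, second about the
    anterior axis, third about the longitudinal axis.  Output in degrees
    with anatomical signs applied; frontal is confined to (-90, 90) and a
    gimbal warning is raised within 1 degree of +/-90 where the sequence
    degenerates (the sagittal and transverse axes align).
    """
    axes = axes or SegmentAxes()
    q_cal = quat_normalize(q_cal)
    single = q_cal.ndim == 1
    m = quat_to_matrix(np.atleast_2d(q_cal))
    # Express the rotation in the (anterior, longitudinal, lateral) basis.
    b = np.column_stack([axes.anterior, axes.longitudinal, axes.lateral])
    m = b.T[np.newaxis] @ m @ b[np.newaxis]
    # R = Rz(a) Rx(bf) Ry(c) in that basis (z = lateral, x = anterior, y = long.)
    v = m[:, :, 1]  # image of the longitudinal axis
    bf = np.arcsin(np.clip(v[:, 2], -1.0, 1.0))  # frontal raw (about anterior)
    a = np.arctan2(-v[:, 0], v[:, 1])  # sagittal raw (about lateral)
    gimbal = np.abs(np.degrees(bf)) > (90.0 - GIMBAL_LOCK_MARGIN_DEG)
    # strip the first two rotations, read the third from what remains
    ca, sa = np.cos(-a), np.sin(-a)
    cb, sb = np.cos(-bf), np.sin(-bf)
    rz = np.zeros((len(a), 3, 3))
    rz[:, 0, 0], rz[:, 0, 1], rz[:, 1, 0], rz[:, 1, 1], rz[:, 2, 2] = ca, -sa, sa, ca, 1.0
    rx = np.zeros_like(rz)
    rx[:, 0, 0], rx[:, 1, 1], rx[:, 1, 2], rx[:, 2, 1], rx[:, 2, 2] = 1.0, cb, -sb, sb, cb
    ry = rx @ rz @ m
    c = np.arctan2(ry[:, 0, 2], ry[:, 0, 0])

    sagittal = -np.degrees(a)  # flexion positive = longitudinal axis tips anteriorly
    frontal = np.degrees(bf)
    transverse = -np.degrees(c)  # internal rotation of a right-side segment positive
    if signs is not None:
        sagittal = signs.sagittal * sagittal
        frontal = signs.frontal * frontal
        transverse = signs.transverse * transverse
    if single:
        return EulerAngles(sagittal[0], frontal[0], transverse[0], gimbal[0])
    return EulerAngles(sagittal, frontal, transverse, gimbal)


def compose_sagittal_frontal_transverse(
    sagittal_deg: float | np.ndarray,
    frontal_deg: float | np.ndarray = 0.0,
    transverse_deg: float | np.ndarray = 0.0,
    signs: SignConvention | None = None,
) -> np.ndarray:
    """Inverse of :func:`euler_sagittal_frontal_transverse`.

    Builds the relative rotation whose Euler decomposition returns the given
    anatomical angles; used by the simulator to realise ground-truth joint
    profiles.
    """
    sag = np.asarray(sagittal_deg, dtype=float)
    fro = np.asarray(frontal_deg, dtype=float)
    tra = np.asarray(transverse_deg, dtype=float)
    if signs is not None:
        sag = signs.sagittal * sag
        fro = signs.frontal * fro
        tra = signs.transverse * tra
    qz = quat_from_axis_angle(LATERAL, np.radians(-sag))
    qx = quat_from_axis_angle(ANTERIOR, np.radians(fro))
    qy = quat_from_axis_angle(LONGITUDINAL, np.radians(-tra))
    return quat_multiply(quat_multiply(qz, qx), qy)


# ---------------------------------------------------------------------------
# SLERP
# ---------------------------------------------------------------------------

def slerp(
    q0: np.ndarray, q1: np.ndarray, t: float | np.ndarray
) -> np.ndarray:
    """Spherical linear interpolation along the shorter arc.

    Constant-angular-speed interpolation from q0 (t=0) to q1 (t=1); q1 is
    negated when the 4-vector dot product is negative so the shorter arc is
    taken.  Nearly antipodal endpoints (|dot| < 1e-6) fall back to
    normalized linear interpolation.
    """
    q0 = quat_normalize(np.asarray(q0, dtype=float))
    q1 = quat_normalize(np.asarray(q1, dtype=float))
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("interpolation fraction t must lie in [0, 1]")
    dot = np.sum(q0 * q1, axis=-1)
    q1 = q1 * np.where(dot < 0, -1.0, 1.0)[..., np.newaxis] if q1.ndim > 1 else (q1 * (-1.0 if dot < 0 else 1.0))
    dot = np.abs(dot)
    tshape = t[..., np.newaxis] if t.ndim else t
    if np.any(dot < 1e-6):
        # antipodal: slerp ill-conditioned; nlerp is the documented fallback
        out = (1.0 - tshape) * q0 + tshape * q1
        return quat_normalize(out)
    dotc = np.clip(dot, -1.0, 1.0)
    theta = np.arccos(dotc)
    near = theta < 1e-8
    sin_theta = np.where(near, 1.0, np.sin(theta))
    w0 = np.where(near, 1.0 - t, np.sin((1.0 - t) * theta) / sin_theta)
    w1 = np.where(near, t, np.sin(t * theta) / sin_theta)
    out = w0[..., np.newaxis] * q0 + w1[..., np.newaxis] * q1 if t.ndim else w0 * q0 + w1 * q1
    return quat_normalize(out)
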