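"""Synthetic single-leg-squat generator.

A four-segment rigid-body chain (trunk tracked at the sternal manubrium,
pelvis at the sacrum, stance-side thigh and shank) performs a metronome-paced
single leg squat: 2 s descent, 2 s ascent, joint angles following
``peak * sin^2(pi t / 4)`` over the 4 s trial.  Each trial is rendered twice,
the way the two measurement systems would see it:

* a 120 Hz optical stream — four-marker clusters rigidly attached to each
  segment, corrupted by soft-tissue artefact (a correlated Gaussian process)
  and white marker noise;
* a 50 Hz inertial stream — one orientation quaternion per segment, composed
  with a constant per-subject mounting misalignment and perturbed by
  small-angle orientation noise.

A 1 s static upright capture of both streams accompanies every trial for
calibration, and the noise-free ground-truth joint-angle curves are retained.
Per-subject peak angles are drawn from the study population's descriptive
distributions (trial-1 means/SDs of the five reported variables), with
within-subject between-trial jitter on top.

Everything is deterministic for a fixed seed: a ``numpy.random.SeedSequence``
is spawned per subject/trial so trials are independent yet reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import (
    IDENTITY,
    compose_sagittal_frontal_transverse,
    quat_from_axis_angle,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    sign_convention,
)

__all__ = [
    "VARIABLES",
    "SEGMENTS",
    "JOINTS",
    "PopulationSpec",
    "BodyModel",
    "SquatProfile",
    "SyntheticTrial",
    "sample_population",
    "forward_kinematics",
    "render_markers",
    "render_imu",
    "make_trial",
    "generate_dataset",
]

#: The five reported variables, in report order.
VARIABLES = (
    "knee_flexion",
    "hip_flexion",
    "hip_sway",
    "spine_flexion",
    "spine_sway",
)

SEGMENTS = ("trunk", "sacrum", "thigh", "shank")

#: joint -> (primary segment, secondary segment)
JOINTS = {
    "spine": ("sacrum", "trunk"),
    "hip": ("sacrum", "thigh"),
    "knee": ("thigh", "shank"),
}

_MS = 1.0  # metres


@dataclass(frozen=True)
class PopulationSpec:
    """Population- and noise-model parameters of the synthetic study.

    Peak-angle means/SDs (degrees) default to the reference system's trial-1
    descriptives of the study population: knee flexion 73.8 (9.1), hip
    flexion 60.8 (14.7), hip sway -8.1 (17.1), spine flexion 13.8 (10.9),
    spine lateral flexion 3.8 (5.7).  ``between_trial_sd`` is the
    within-subject trial-to-trial jitter; noise magnitudes parametrize the
    soft-tissue artefact (STA), marker white noise and IMU orientation /
    mounting errors.
    """

    peak_mean: dict[str, float] = field(
        default_factory=lambda: {
            "knee_flexion": 73.8,
            "hip_flexion": 60.8,
            "hip_sway": -8.1,
            "spine_flexion": 13.8,
            "spine_sway": 3.8,
        }
    )
    peak_sd: dict[str, float] = field(
        default_factory=lambda: {
            "knee_flexion": 9.1,
            "hip_flexion": 14.7,
            "hip_sway": 17.1,
            "spine_flexion": 10.9,
            "spine_sway": 5.7,
        }
    )
    between_trial_sd: dict[str, float] = field(
        default_factory=lambda: {
            "knee_flexion": 3.0,
            "hip_flexion": 3.0,
            "hip_sway": 2.0,
            "spine_flexion": 2.0,
            "spine_sway": 2.0,
        }
    )
    # soft tissue artefact RMS amplitude per segment, mm
    sta_amp_mm: dict[str, float] = field(
        default_factory=lambda: {"trunk": 5.0, "sacrum": 5.0, "thigh": 10.0, "shank": 5.0}
    )
    #: fraction of STA variance common to all markers of a cluster (bulk
    #: skin/tape translation); the remainder is independent per marker
    sta_common_fraction: float = 0.8
    sta_correlation_time_s: float = 0.5
    marker_white_mm: float = 0.5
    imu_noise_deg: float = 1.0
    mounting_deg: float = 5.0
    n_subjects: int = 44
    n_trials: int = 3
    duration_s: float = 4.0
    calibration_s: float = 1.0
    fs_marker: float = 120.0
    fs_imu: float = 50.0
    side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be positive")
        for d in (self.peak_sd, self.between_trial_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")

    def replace(self, **kw) -> "PopulationSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(**d)

    def noise_free(self) -> "PopulationSpec":
        """Copy with every stochastic amplitude set to zero."""
        return self.replace(
            sta_amp_mm={s: 0.0 for s in SEGMENTS},
            marker_white_mm=0.0,
            imu_noise_deg=0.0,
            mounting_deg=0.0,
        )


def _default_clusters() -> dict[str, np.ndarray]:
    """Four-marker cluster templates (local mm), one per segment.

    Rigid plates of roughly 12 cm extent with one marker raised out of
    plane, the shape of clinical cluster plates; local frames coincide with
    the segment frame so orientation recovery is direct.
    """
    plate = np.array(
        [
            [60.0, 60.0, 0.0],
            [-60.0, 60.0, 0.0],
            [-60.0, -60.0, 0.0],
            [60.0, -60.0, 30.0],
        ]
    )
    return {s: plate.copy() for s in SEGMENTS}


@dataclass(frozen=True)
class BodyModel:
    """Segment geometry: lengths, cluster templates, joint offsets.

    Lengths are field-typical adult values (m).  ``cluster_mm`` holds the
    4-marker local templates; origins chain the ankle -> knee -> hip ->
    sacrum -> manubrium through per-segment local offsets.
    """

    shank_length: float = 0.43 * _MS
    thigh_length: float = 0.45 * _MS
    sacrum_offset: np.ndarray = field(
        default_factory=lambda: np.array([-0.09, 0.10, -0.08])
    )  # hip centre -> sacrum cluster, pelvis frame (right stance: medial is -z)
    trunk_offset: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.45, 0.0])
    )  # sacrum -> sternal manubrium, trunk frame
    cluster_mm: dict[str, np.ndarray] = field(default_factory=_default_clusters)

    def __post_init__(self) -> None:
        for seg, c in self.cluster_mm.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (4, 3):
                raise ValueError(f"cluster for {seg} must be 4 markers x 3 coords")
            # non-collinearity: centred marker matrix must have rank >= 2
            s = np.linalg.svd(c - c.mean(axis=0), compute_uv=False)
            if s[1] < 1e-6:
                raise ValueError(f"cluster for {seg} is collinear")


@dataclass(frozen=True)
class SquatProfile:
    """Per-joint peak angles realising one squat repetition.

    The time course of every component is ``peak * sin^2(pi t / T)`` with
    T = 4 s: zero at the endpoints, maximal at 2 s, matching the 2 s-down /
    2 s-up metronome protocol.
    """

    peaks: dict[str, float]  # keys = VARIABLES
    duration_s: float = 4.0

    def shape(self, t: np.ndarray) -> np.ndarray:
        return np.sin(np.pi * np.asarray(t) / self.duration_s) ** 2

    def angles(self, t: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Ground-truth anatomical angles per joint: sagittal/frontal/transverse."""
        s = self.shape(t)
        z = np.zeros_like(s)
        return {
            "knee": {"sagittal": self.peaks["knee_flexion"] * s, "frontal": z, "transverse": z},
            "hip": {
                "sagittal": self.peaks["hip_flexion"] * s,
                "frontal": self.peaks["hip_sway"] * s,
                "transverse": z,
            },
            "spine": {
                "sagittal": self.peaks["spine_flexion"] * s,
                "frontal": self.peaks["spine_sway"] * s,
                "transverse": z,
            },
        }


@dataclass
class SyntheticTrial:
    """One simulated squat with everything both pipelines need.

    Holds the rendered 120 Hz marker table and 50 Hz quaternion table, the
    matching static upright calibration captures, and the noise-free
    ground-truth joint-angle curves.
    """

    subject: int
    trial: int
    seed: int
    profile: SquatProfile
    truth: pd.DataFrame  # time_s + <joint>_<plane>_deg
    markers: pd.DataFrame  # time_s + <segment>_m<i>_{x,y,z} (mm)
    imu: pd.DataFrame  # time_s + <segment>_{w,x,y,z}
    cal_markers: pd.DataFrame
    cal_imu: pd.DataFrame
    side: str = "right"


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def sample_population(spec: PopulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-subject, per-trial peak-angle sets.

    Subject-level peaks are Normal(mean, SD^2) per variable; each trial adds
    independent Normal(0, between_trial_SD^2) jitter.  Returns an array of
    shape ``(n_subjects, n_trials, len(VARIABLES))``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.peak_mean[v] for v in VARIABLES])
    sd = np.array([spec.peak_sd[v] for v in VARIABLES])
    bsd = np.array([spec.between_trial_sd[v] for v in VARIABLES])
    subj = mu + sd * rng.standard_normal((spec.n_subjects, 1, len(VARIABLES)))
    jitter = bsd * rng.standard_normal((spec.n_subjects, spec.n_trials, len(VARIABLES)))
    return subj + jitter


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(
    model: BodyModel, profile: SquatProfile, t: np.ndarray, side: str = "right"
) -> dict[str, dict[str, np.ndarray]]:
    """World pose (position m + quaternion) of each segment at times *t*.

    The chain is rooted at the stance ankle (origin): shank -> knee -> thigh
    -> hip -> pelvis(sacrum) -> spine -> trunk.  Joint rotations realise the
    profile's anatomical angles exactly under the package sign conventions,
    and the upright pose (all profile angles zero) puts every segment at the
    identity orientation.  The pelvis drops and translates as dictated by
    the leg geometry; translation does not enter any orientation-based angle.
    """
    t = np.asarray(t, dtype=float)
    ang = profile.angles(t)
    q_joint = {
        j: compose_sagittal_frontal_transverse(
            ang[j]["sagittal"], ang[j]["frontal"], ang[j]["transverse"],
            signs=sign_convention(j, side),
        )
        for j in JOINTS
    }
    n = len(t)

    # Orientations: distribute the squat between shank and pelvis so the
    # chain stays roughly balanced over the ankle.  The shank dorsiflexes by
    # a fixed fraction of knee flexion; every other segment follows from the
    # joint rotations.  Only *relative* orientations matter downstream.
    q_shank = compose_sagittal_frontal_transverse(
        0.35 * ang["knee"]["sagittal"], 0.0, 0.0, signs=sign_convention("knee", side)
    )
    # knee: shank relative to thigh -> q_shank = q_thigh ⊗ q_knee
    q_thigh = quat_multiply(q_shank, _conj(q_joint["knee"]))
    # hip: thigh relative to sacrum -> q_thigh = q_sacrum ⊗ q_hip
    q_sacrum = quat_multiply(q_thigh, _conj(q_joint["hip"]))
    # spine: trunk relative to sacrum
    q_trunk = quat_multiply(q_sacrum, q_joint["spine"])

    # positions: chain from the fixed ankle; segment y-axes point proximally
    ankle = np.zeros((n, 3))
    knee = ankle + quat_rotate(q_shank, np.array([0.0, model.shank_length, 0.0]))
    hip = knee + quat_rotate(q_thigh, np.array([0.0, model.thigh_length, 0.0]))
    sacrum = hip + quat_rotate(q_sacrum, model.sacrum_offset)
    manubrium = sacrum + quat_rotate(q_trunk, model.trunk_offset)

    return {
        "shank": {"pos": knee * 0.5, "quat": quat_normalize(q_shank)},
        "thigh": {"pos": (knee + hip) * 0.5, "quat": quat_normalize(q_thigh)},
        "sacrum": {"pos": sacrum, "quat": quat_normalize(q_sacrum)},
        "trunk": {"pos": manubrium, "quat": quat_normalize(q_trunk)},
    }


def _conj(q: np.ndarray) -> np.ndarray:
    return q * np.array([1.0, -1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _sta_process(
    rng: np.random.Generator, n: int, dt: float, amp_mm: float, tau_s: float, shape: tuple
) -> np.ndarray:
    """Stationary AR(1) (correlation time tau, RMS amp_mm) of given shape + (n,)."""
    if amp_mm == 0.0 or n == 0:
        return np.zeros(shape + (n,))
    rho = np.exp(-dt / tau_s)
    x = np.empty(shape + (n,))
    x[..., 0] = amp_mm * rng.standard_normal(shape)
    innov = amp_mm * np.sqrt(1.0 - rho**2) * rng.standard_normal(shape + (n - 1,))
    for k in range(1, n):
        x[..., k] = rho * x[..., k - 1] + innov[..., k - 1]
    return x


def render_markers(
    poses: dict[str, dict[str, np.ndarray]],
    model: BodyModel,
    spec: PopulationSpec,
    rng: np.random.Generator,
    t: np.ndarray,
) -> pd.DataFrame:
    """Render noisy world marker positions (mm) at the marker rate.

    World position of marker *i* of a segment is the rigid transform of its
    template, plus soft-tissue artefact (AR(1) with 0.5 s correlation time,
    split into a cluster-common component and per-marker residuals) and
    isotropic white noise.
    """
    n = len(t)
    dt = 1.0 / spec.fs_marker
    cols: dict[str, np.ndarray] = {"time_s": np.round(np.asarray(t), 9)}
    for seg in SEGMENTS:
        tmpl_m = model.cluster_mm[seg] / 1000.0
        world = poses[seg]["pos"][:, np.newaxis, :] + quat_rotate(
            poses[seg]["quat"][:, np.newaxis, :], tmpl_m[np.newaxis, :, :]
        )  # (n, 4, 3) metres
        world_mm = world * 1000.0
        amp = spec.sta_amp_mm[seg]
        common = _sta_process(
            rng, n, dt, amp * np.sqrt(spec.sta_common_fraction),
            spec.sta_correlation_time_s, (3,),
        )  # (3, n)
        resid = _sta_process(
            rng, n, dt, amp * np.sqrt(1.0 - spec.sta_common_fraction),
            spec.sta_correlation_time_s, (4, 3),
        )  # (4, 3, n)
        noise = spec.marker_white_mm * rng.standard_normal((n, 4, 3))
        world_mm = world_mm + common.T[:, np.newaxis, :] + np.moveaxis(resid, -1, 0) + noise
        for i in range(4):
            for k, ax in enumerate("xyz"):
                cols[f"{seg}_m{i + 1}_{ax}"] = world_mm[:, i, k]
    return pd.DataFrame(cols)


def _small_rotations(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    """n random small rotations: rotation-vector components iid N(0, (sd/sqrt3)^2)."""
    if sd_deg == 0.0:
        return np.broadcast_to(IDENTITY, (n, 4)).copy()
    rv = np.radians(sd_deg / np.sqrt(3.0)) * rng.standard_normal((n, 3))
    angle = np.linalg.norm(rv, axis=1)
    axis = np.where(angle[:, None] > 1e-12, rv / np.where(angle[:, None] == 0, 1, angle[:, None]), [1.0, 0.0, 0.0])
    q = np.empty((n, 4))
    q[:, 0] = np.cos(angle / 2)
    q[:, 1:] = np.sin(angle / 2)[:, None] * axis
    return q


def render_imu(
    poses: dict[str, dict[str, np.ndarray]],
    mounts: dict[str, np.ndarray],
    spec: PopulationSpec,
    rng: np.random.Generator,
    t: np.ndarray,
) -> pd.DataFrame:
    """Render sensor quaternions at the IMU rate.

    Per segment, sensor reading = segment world orientation ⊗ constant
    mounting rotation, right-perturbed by a small-angle orientation noise
    rotation with total SD ``imu_noise_deg``.
    """
    n = len(t)
    cols: dict[str, np.ndarray] = {"time_s": np.round(np.asarray(t), 9)}
    for seg in SEGMENTS:
        q = quat_multiply(poses[seg]["quat"], mounts[seg][np.newaxis, :])
        q = quat_multiply(q, _small_rotations(rng, n, spec.imu_noise_deg))
        q = quat_normalize(q)
        for k, comp in enumerate("wxyz"):
            cols[f"{seg}_{comp}"] = q[:, k]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# trial assembly and dataset generation
# ---------------------------------------------------------------------------

def _time_grid(duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs)) + 1
    return np.arange(n) / fs


def make_trial(
    peaks: dict[str, float],
    spec: PopulationSpec,
    model: BodyModel,
    seed_seq: np.random.SeedSequence,
    subject: int = 0,
    trial: int = 0,
) -> SyntheticTrial:
    """Assemble one trial: ground truth, both rendered streams, calibration."""
    rng = np.random.default_rng(seed_seq)
    profile = SquatProfile(peaks=dict(peaks), duration_s=spec.duration_s)
    side = spec.side

    # constant per-subject/trial sensor mounting misalignment
    mounts = {seg: _small_rotations(rng, 1, spec.mounting_deg)[0] for seg in SEGMENTS}

    t_mark = _time_grid(spec.duration_s, spec.fs_marker)
    t_imu = _time_grid(spec.duration_s, spec.fs_imu)
    t_cal_mark = _time_grid(spec.calibration_s, spec.fs_marker)
    t_cal_imu = _time_grid(spec.calibration_s, spec.fs_imu)

    poses_mark = forward_kinematics(model, profile, t_mark, side)
    poses_imu = forward_kinematics(model, profile, t_imu, side)
    upright = SquatProfile(peaks={v: 0.0 for v in VARIABLES}, duration_s=spec.duration_s)
    cal_mark_poses = forward_kinematics(model, upright, t_cal_mark, side)
    cal_imu_poses = forward_kinematics(model, upright, t_cal_imu, side)

    markers = render_markers(poses_mark, model, spec, rng, t_mark)
    imu = render_imu(poses_imu, mounts, spec, rng, t_imu)
    cal_markers = render_markers(cal_mark_poses, model, spec, rng, t_cal_mark)
    cal_imu = render_imu(cal_imu_poses, mounts, spec, rng, t_cal_imu)

    ang = profile.angles(t_mark)
    truth_cols: dict[str, np.ndarray] = {"time_s": np.round(t_mark, 9)}
    for j in JOINTS:
        for plane in ("sagittal", "frontal", "transverse"):
            truth_cols[f"{j}_{plane}_deg"] = ang[j][plane]
    truth = pd.DataFrame(truth_cols)

    return SyntheticTrial(
        subject=subject,
        trial=trial,
        seed=int(seed_seq.entropy) if isinstance(seed_seq.entropy, int) else 0,
        profile=profile,
        truth=truth,
        markers=markers,
        imu=imu,
        cal_markers=cal_markers,
        cal_imu=cal_imu,
        side=side,
    )


def iter_trials(spec: PopulationSpec, model: BodyModel | None = None):
    """Yield every SyntheticTrial of the dataset, deterministically.

    Peak sampling and per-trial noise both derive from ``spec.seed`` via
    spawned SeedSequences, so a dataset is fully reproducible from the spec.
    """
    model = model or BodyModel()
    root = np.random.SeedSequence(spec.seed)
    peak_seq, trial_root = root.spawn(2)
    peaks = sample_population(spec, np.random.default_rng(peak_seq))
    trial_seqs = trial_root.spawn(spec.n_subjects * spec.n_trials)
    k = 0
    for s in range(spec.n_subjects):
        for tr in range(spec.n_trials):
            pk = {v: float(peaks[s, tr, i]) for i, v in enumerate(VARIABLES)}
            yield make_trial(pk, spec, model, trial_seqs[k], subject=s + 1, trial=tr + 1)
            k += 1


def generate_dataset(
    spec: PopulationSpec, out_dir: str | Path, model: BodyModel | None = None
) -> Path:
    """Write the full dataset to *out_dir*; returns the manifest path.

    Layout: ``subject_SS/trial_T/{markers,imu,cal_markers,cal_imu,truth}.csv``
    plus a top-level ``manifest.json`` recording the spec (including the
    seed) and every trial directory, sufficient to regenerate the dataset
    bit-for-bit.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out}: {e}") from e
    trials = []
    for trial in iter_trials(spec, model):
        tdir = out / f"subject_{trial.subject:02d}" / f"trial_{trial.trial}"
        tdir.mkdir(parents=True, exist_ok=True)
        try:
            trial.markers.to_csv(tdir / "markers.csv", index=False, float_format="%.6f")
            trial.imu.to_csv(tdir / "imu.csv", index=False, float_format="%.9f")
            trial.cal_markers.to_csv(tdir / "cal_markers.csv", index=False, float_format="%.6f")
            trial.cal_imu.to_csv(tdir / "cal_imu.csv", index=False, float_format="%.9f")
            trial.truth.to_csv(tdir / "truth.csv", index=False, float_format="%.6f")
        except OSError as e:
            raise OSError(f"failed writing trial files under {tdir}: {e}") from e
        trials.append(str(tdir.relative_to(out)))
    manifest = {
        "format_version": 1,
        "spec": spec.to_dict(),
        "n_trials_written": len(trials),
        "trials": trials,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return mpath


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
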