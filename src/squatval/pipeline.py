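"""End-to-end orchestration: simulate -> both pipelines -> peaks -> report.

These helpers bind the stages together for the CLI and for in-memory use
(stochastic calibration studies re-run the whole chain over many seeds
without touching disk).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import optical as O
from . import peaks as P
from . import sensor as Q
from . import simulate as S
from . import stats as V

__all__ = ["process_trial", "run_study", "run_study_from_dir"]

log = logging.getLogger(__name__)


def process_trial(trial: S.SyntheticTrial) -> tuple[P.PeakExtract, P.PeakExtract, list[str]]:
    """Run both measurement pipelines on one trial; return (optical, sensor) peaks.

    The sensor stream is SLERP-resampled onto the optical 120 Hz timeline
    before angle computation; each modality locates its own peak-knee-flexion
    instant.  Warnings from both paths are collected.
    """
    opt = O.optical_joint_angles(
        O.MarkerFrameSeries(trial.markers),
        O.MarkerFrameSeries(trial.cal_markers),
        side=trial.side,
    )
    sen = Q.sensor_joint_angles(
        Q.quaternion_series_from_frame(trial.imu),
        Q.quaternion_series_from_frame(trial.cal_imu),
        side=trial.side,
        ref_time=opt["knee"].time,
    )
    e_opt = P.extract_at_peak(opt, subject=trial.subject, trial=trial.trial)
    e_sen = P.extract_at_peak(sen, subject=trial.subject, trial=trial.trial)
    warns = sorted({w for s in (*opt.values(), *sen.values()) for w in s.warnings})
    return e_opt, e_sen, warns


def run_study(
    spec: S.PopulationSpec, model: S.BodyModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the whole dataset in memory and analyse it.

    Returns (optical peaks table, sensor peaks table, validity table).
    """
    ext_opt, ext_sen = [], []
    for trial in S.iter_trials(spec, model):
        e_opt, e_sen, warns = process_trial(trial)
        for w in warns:
            log.warning("subject %d trial %d: %s", trial.subject, trial.trial, w)
        ext_opt.append(e_opt)
        ext_sen.append(e_sen)
    peaks_opt = P.peaks_to_frame(ext_opt)
    peaks_sen = P.peaks_to_frame(ext_sen)
    table = V.build_validity_table(peaks_opt, peaks_sen)
    return peaks_opt, peaks_sen, table


def _read_trial_dir(tdir: Path, subject: int, trial: int, side: str) -> S.SyntheticTrial:
    return S.SyntheticTrial(
        subject=subject,
        trial=trial,
        seed=0,
        profile=S.SquatProfile(peaks={v: float("nan") for v in S.VARIABLES}),
        truth=pd.read_csv(tdir / "truth.csv") if (tdir / "truth.csv").exists() else pd.DataFrame(),
        markers=pd.read_csv(tdir / "markers.csv"),
        imu=pd.read_csv(tdir / "imu.csv"),
        cal_markers=pd.read_csv(tdir / "cal_markers.csv"),
        cal_imu=pd.read_csv(tdir / "cal_imu.csv"),
        side=side,
    )


def run_study_from_dir(
    dataset_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Analyse a dataset previously written by ``generate_dataset``."""
    import json

    root = Path(dataset_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    side = manifest["spec"].get("side", "right")
    ext_opt, ext_sen = [], []
    for rel in manifest["trials"]:
        tdir = root / rel
        subject = int(tdir.parent.name.split("_")[1])
        trial = int(tdir.name.split("_")[1])
        tr = _read_trial_dir(tdir, subject, trial, side)
        e_opt, e_sen, _ = process_trial(tr)
        ext_opt.append(e_opt)
        ext_sen.append(e_sen)
    peaks_opt = P.peaks_to_frame(ext_opt)
    peaks_sen = P.peaks_to_frame(ext_sen)
    return peaks_opt, peaks_sen, V.build_validity_table(peaks_opt, peaks_sen)
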