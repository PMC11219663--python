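"""Plain-text file formats: per-patient recordings, cohort tables, epoch
series, labels and feature tables, all as CSV for transparency at desk
scale.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import OutcomeLabel
from .signal_prep import EpochSeries
from .simcohort import RawRecording

__all__ = [
    "read_recording_csv",
    "write_recording_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_epoch_csv",
    "write_labels_csv",
    "read_labels_csv",
]

RECORDING_HEADER = ["time_s", "icp_mmhg", "map_mmhg", "amp_mmhg"]


def write_recording_csv(rec: RawRecording, path) -> None:
    t = np.arange(len(rec.icp)) * rec.sample_period_s
    df = pd.DataFrame(
        {
            "time_s": t,
            "icp_mmhg": rec.icp,
            "map_mmhg": rec.abp_mean,
            "amp_mmhg": rec.amp,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_recording_csv(path, patient_id: str | None = None) -> RawRecording:
    """Parse a recording CSV; header must carry the four standard columns.

    Time must be strictly monotone and uniformly spaced; unknown extra
    columns are ignored with a warning; missing columns are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in RECORDING_HEADER]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)
    bad = df[RECORDING_HEADER].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed/missing values at line(s) {lines}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or (dt <= 0).any():
        raise ValueError(f"{path}: time_s must be strictly increasing")
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: time_s must be uniformly spaced")
    return RawRecording(
        patient_id=patient_id or Path(path).stem,
        sample_period_s=float(dt[0]),
        icp=df["icp_mmhg"].to_numpy(dtype=float),
        abp_mean=df["map_mmhg"].to_numpy(dtype=float),
        amp=df["amp_mmhg"].to_numpy(dtype=float),
    )


def write_cohort_csv(baselines: pd.DataFrame, path) -> None:
    cols = ["patient_id", "age", "sex", "gcs", "is_ih", "is_sih", "onset_hours"]
    baselines[cols].to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "age", "sex", "gcs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort CSV missing column(s) {sorted(missing)}")
    return df


def write_epoch_csv(es: EpochSeries, path) -> None:
    df = pd.DataFrame(
        {
            "epoch_idx": np.arange(es.n_epochs),
            "t_mid_s": es.midpoints_s(),
            "icp": es.icp,
            "map": es.map_,
            "cpp": es.cpp,
            "amp": es.amp,
            "valid": es.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_labels_csv(labels: list[OutcomeLabel], excluded: list[tuple[str, str]], path) -> None:
    rows = [
        {
            "patient_id": lab.patient_id,
            "ih": int(lab.ih),
            "sih": int(lab.sih),
            "time_to_ih_h": np.nan if lab.time_to_ih_h is None else lab.time_to_ih_h,
            "time_to_sih_h": np.nan if lab.time_to_sih_h is None else lab.time_to_sih_h,
            "excluded": 0,
            "reason": "",
        }
        for lab in labels
    ]
    rows += [
        {
            "patient_id": pid,
            "ih": "",
            "sih": "",
            "time_to_ih_h": np.nan,
            "time_to_sih_h": np.nan,
            "excluded": 1,
            "reason": reason,
        }
        for pid, reason in excluded
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
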