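"""Per-patient feature assembly.

Each included patient yields an 11-feature vector: three baseline
covariates (age, sex, admission GCS), four linear features (6-h means of
ICP, CPP, PRx and RAP) and four nonlinear features (SampEn and LZc of the
6-h ICP and CPP epoch series).  All signal-derived features come from the
first 6 h of monitoring only; outcomes are assessed strictly afterwards, so
the feature table is leakage-free by construction.

Sex is encoded 0 = female, 1 = male.  Missing features (e.g. PRx over a
degenerate zero-variance window) stay NaN in the table; the modeling module
imputes them by training-set medians.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import cvx_indices, signal_prep
from .complexity import ComplexityParams, complexity_features
from .simcohort import RawRecording

__all__ = ["PatientFeatures", "FEATURE_COLUMNS", "featurize_patient", "build_feature_table"]

FEATURE_COLUMNS = [
    "age",
    "sex",
    "gcs",
    "icp_m",
    "cpp_m",
    "prx_m",
    "rap_m",
    "icp_sampen",
    "cpp_sampen",
    "icp_lzc",
    "cpp_lzc",
]


@dataclass(frozen=True)
class PatientFeatures:
    """The 11-column feature vector for one patient."""

    patient_id: str
    age: float
    sex: int
    gcs: int
    icp_m: float
    cpp_m: float
    prx_m: float
    rap_m: float
    icp_sampen: float
    cpp_sampen: float
    icp_lzc: float
    cpp_lzc: float

    def __post_init__(self) -> None:
        if not 3 <= self.gcs <= 15:
            raise ValueError("gcs must be in [3, 15]")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (female) or 1 (male)")

    def to_dict(self) -> dict:
        return asdict(self)


def featurize_patient(
    rec: RawRecording,
    baseline: dict,
    feature_window_h: float = 6.0,
    epoch_s: float = 12.0,
    smooth_span: int = 4,
    prx_window_epochs: int = cvx_indices.WINDOW_EPOCHS_DEFAULT,
    rap_window_epochs: int = cvx_indices.WINDOW_EPOCHS_DEFAULT,
    cparams: ComplexityParams = ComplexityParams(),
) -> PatientFeatures:
    """Run signal prep, index and complexity extraction on the 6-h window."""
    for key in ("age", "sex", "gcs"):
        if key not in baseline:
            raise ValueError(f"baseline covariates missing field {key!r}")
    es = signal_prep.preprocess(rec, epoch_s=epoch_s, span=smooth_span)
    es6 = signal_prep.extract_window(es, 0.0, feature_window_h)
    valid = es6.valid
    icp_m = cvx_indices.window_mean(np.where(valid, es6.icp, np.nan))
    cpp_m = cvx_indices.window_mean(np.where(valid, es6.cpp, np.nan))
    prx_m = cvx_indices.window_mean(cvx_indices.prx(es6, prx_window_epochs).values)
    rap_m = cvx_indices.window_mean(cvx_indices.rap(es6, rap_window_epochs).values)
    cx = complexity_features(es6, cparams)
    return PatientFeatures(
        patient_id=rec.patient_id,
        age=float(baseline["age"]),
        sex=int(baseline["sex"]),
        gcs=int(baseline["gcs"]),
        icp_m=icp_m,
        cpp_m=cpp_m,
        prx_m=prx_m,
        rap_m=rap_m,
        **cx,
    )


def build_feature_table(
    cohort: list[tuple[PatientFeatures, "OutcomeLabel"]],
    min_patients: int = 10,
) -> pd.DataFrame:
    """Assemble the cohort feature table with outcome columns.

    ``cohort`` pairs each included patient's features with their outcome
    label.  Raises on duplicated patient ids or fewer than ``min_patients``
    rows; missingness per feature is reported via the returned frame's
    ``attrs["missing"]``.
    """
    if not cohort:
        raise ValueError("no included patients to tabulate")
    rows = []
    for feats, label in cohort:
        if feats.patient_id != label.patient_id:
            raise ValueError(
                f"feature/label mismatch: {feats.patient_id} vs {label.patient_id}"
            )
        row = feats.to_dict()
        row["ih"] = int(label.ih)
        row["sih"] = int(label.sih)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicated patient_id(s): {dupes}")
    if len(table) < min_patients:
        raise ValueError(f"need >= {min_patients} included patients, got {len(table)}")
    table = table[["patient_id", *FEATURE_COLUMNS, "ih", "sih"]]
    table.attrs["missing"] = table[FEATURE_COLUMNS].isna().sum().to_dict()
    return table
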