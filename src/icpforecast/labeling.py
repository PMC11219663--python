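"""Threshold-duration event detection and cohort inclusion rules.

Intracranial hypertension (IH) is defined as epoch-mean ICP strictly above
22 mmHg sustained strictly longer than 5 min; severe IH (SIH) as the same
excursion sustained strictly longer than 1 h.  Outcomes are assessed on the
monitoring period *after* the 6-h feature-extraction window; an episode
counts if any part of it lies after hour 6.  Both inequalities are strict
and no gap tolerance is applied: a single sub-threshold (or invalid) epoch
resets the run.

Detection runs on the unsmoothed epoch means: the causal span-4 smoothing
used for feature extraction would delay the threshold crossing by several
epochs, whereas the outcome is defined on ICP itself.

Inclusion filters mirror the cohort-selection rules: recordings shorter
than 18 h, recordings with more than 30% invalid epochs, and patients whose
ICP already exceeds 22 mmHg persistently during the first 6 h (mean > 22
AND > 80% of epochs above threshold) are excluded, each with a
machine-readable reason code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_prep import EpochSeries

__all__ = [
    "Episode",
    "OutcomeLabel",
    "detect_episodes",
    "label_outcomes",
    "exclusion_reason",
    "apply_inclusion_filters",
    "RecordingExcluded",
]

IH_THRESHOLD_MMHG = 22.0
IH_MIN_DURATION_MIN = 5.0
SIH_MIN_DURATION_MIN = 60.0
MIN_RECORD_H = 18.0
ARTIFACT_MAX_INVALID_FRAC = 0.30
EARLY_IH_EPOCH_FRAC = 0.80


class RecordingExcluded(ValueError):
    """Raised when a recording fails an inclusion precondition."""


@dataclass(frozen=True)
class Episode:
    """A maximal run of epochs with ICP above threshold."""

    start_epoch: int
    end_epoch: int  # inclusive
    duration_min: float
    peak_icp: float


@dataclass(frozen=True)
class OutcomeLabel:
    """IH/SIH outcome for one patient, with event latencies.

    Latencies are hours from the end of the feature window to the start of
    the first qualifying episode.
    """

    patient_id: str
    ih: bool
    sih: bool
    time_to_ih_h: float | None = None
    time_to_sih_h: float | None = None

    def __post_init__(self) -> None:
        if self.sih and not self.ih:
            raise ValueError("sih implies ih")


def detect_episodes(
    icp_epochs: np.ndarray,
    threshold_mmHg: float = IH_THRESHOLD_MMHG,
    min_duration_min: float = IH_MIN_DURATION_MIN,
    epoch_s: float = 12.0,
) -> list[Episode]:
    """Maximal runs of consecutive epochs with ICP strictly above threshold.

    Only runs strictly longer than ``min_duration_min`` are returned;
    invalid (NaN) epochs break runs.  The returned list is ordered and
    non-overlapping.
    """
    if threshold_mmHg <= 0:
        raise ValueError("threshold must be positive")
    icp = np.asarray(icp_epochs, dtype=float)
    above = np.zeros(icp.size + 2, dtype=bool)
    above[1:-1] = icp > threshold_mmHg  # NaN compares False: breaks runs
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    episodes = []
    for s, e in zip(starts, ends):
        duration_min = (e - s + 1) * epoch_s / 60.0
        if duration_min > min_duration_min:
            episodes.append(
                Episode(
                    start_epoch=int(s),
                    end_epoch=int(e),
                    duration_min=float(duration_min),
                    peak_icp=float(np.nanmax(icp[s : e + 1])),
                )
            )
    return episodes


def label_outcomes(
    es: EpochSeries,
    feature_window_h: float = 6.0,
    threshold_mmHg: float = IH_THRESHOLD_MMHG,
    ih_min_duration_min: float = IH_MIN_DURATION_MIN,
    sih_min_duration_min: float = SIH_MIN_DURATION_MIN,
    min_record_h: float = MIN_RECORD_H,
) -> OutcomeLabel:
    """IH/SIH flags from the post-feature-window monitoring period."""
    if es.duration_hours < min_record_h:
        raise RecordingExcluded(
            f"{es.patient_id}: recording {es.duration_hours:.2f} h "
            f"< required {min_record_h} h"
        )
    mid = es.midpoints_s()
    post = mid >= feature_window_h * 3600.0
    offset = int(np.argmax(post))  # first post-window epoch index
    episodes = detect_episodes(
        es.icp[post],
        threshold_mmHg=threshold_mmHg,
        min_duration_min=ih_min_duration_min,
        epoch_s=es.epoch_s,
    )

    def start_hours(ep: Episode) -> float:
        start_s = es.t0_offset_s + (offset + ep.start_epoch) * es.epoch_s
        return start_s / 3600.0 - feature_window_h

    ih_eps = episodes
    sih_eps = [ep for ep in episodes if ep.duration_min > sih_min_duration_min]
    return OutcomeLabel(
        patient_id=es.patient_id,
        ih=bool(ih_eps),
        sih=bool(sih_eps),
        time_to_ih_h=start_hours(ih_eps[0]) if ih_eps else None,
        time_to_sih_h=start_hours(sih_eps[0]) if sih_eps else None,
    )


def exclusion_reason(
    es: EpochSeries,
    min_record_h: float = MIN_RECORD_H,
    max_invalid_frac: float = ARTIFACT_MAX_INVALID_FRAC,
    feature_window_h: float = 6.0,
    threshold_mmHg: float = IH_THRESHOLD_MMHG,
    early_ih_epoch_frac: float = EARLY_IH_EPOCH_FRAC,
) -> str | None:
    """Reason code for exclusion, or None if the patient is included.

    Codes: ``short_recording``, ``artifact``, ``early_persistent_ih``.
    """
    if es.duration_hours < min_record_h:
        return "short_recording"
    invalid_frac = 1.0 - es.valid.mean()
    if invalid_frac > max_invalid_frac:
        return "artifact"
    mid = es.midpoints_s()
    early = es.icp[(mid < feature_window_h * 3600.0) & np.isfinite(es.icp)]
    if early.size:
        frac_above = float((early > threshold_mmHg).mean())
        if early.mean() > threshold_mmHg and frac_above > early_ih_epoch_frac:
            return "early_persistent_ih"
    return None


def apply_inclusion_filters(
    cohort: list[EpochSeries], **kwargs
) -> tuple[list[EpochSeries], list[tuple[str, str]]]:
    """Split a cohort into included patients and (patient_id, reason) pairs."""
    if not cohort:
        raise ValueError("empty cohort")
    included, excluded = [], []
    for es in cohort:
        reason = exclusion_reason(es, **kwargs)
        if reason is None:
            included.append(es)
        else:
            excluded.append((es.patient_id, reason))
    return included, excluded
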