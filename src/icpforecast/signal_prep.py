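"""Epoch-level signal preparation.

Raw pressure channels are reduced to 12-s epoch means (suppressing pulse and
respiratory waves so only slow ICP dynamics remain), smoothed with a span-4
trailing moving average, and restricted to analysis windows.  Cerebral
perfusion pressure is derived as CPP = MAP - ICP from the (smoothed) epoch
series.  Invalid epochs (> 50% missing samples) are carried as NaN and
propagate through smoothing and all downstream consumers.

The smoothing window is trailing (causal) with a shortened leading edge:
``y[i] = mean(x[max(0, i-span+1) .. i])``.  A causal filter keeps the 6-h
feature window free of any future information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simcohort import RawRecording

__all__ = [
    "EpochSeries",
    "resample_epochs",
    "smooth_moving_average",
    "smooth_epoch_series",
    "extract_window",
    "extract_amp_from_pulse",
    "preprocess",
]

EPOCH_S_DEFAULT = 12.0


@dataclass
class EpochSeries:
    """Epoch-averaged ICP/MAP/CPP/AMP for one patient.

    All series share one length; ``valid`` marks epochs usable downstream
    (NaN in any channel marks an epoch invalid).  ``t0_offset_s`` is the
    start time of epoch 0 relative to the start of monitoring.
    """

    patient_id: str
    epoch_s: float
    t0_offset_s: float
    icp: np.ndarray
    map_: np.ndarray
    cpp: np.ndarray
    amp: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.icp)
        if not (len(self.map_) == len(self.cpp) == len(self.amp) == n):
            raise ValueError("all epoch series must have equal length")

    @property
    def valid(self) -> np.ndarray:
        return (
            np.isfinite(self.icp)
            & np.isfinite(self.map_)
            & np.isfinite(self.cpp)
            & np.isfinite(self.amp)
        )

    @property
    def n_epochs(self) -> int:
        return len(self.icp)

    def midpoints_s(self) -> np.ndarray:
        return self.t0_offset_s + (np.arange(self.n_epochs) + 0.5) * self.epoch_s

    @property
    def duration_hours(self) -> float:
        return (self.t0_offset_s + self.n_epochs * self.epoch_s) / 3600.0


def _epoch_mean(x: np.ndarray, n_per: int) -> np.ndarray:
    n_epochs = len(x) // n_per  # trailing partial epoch dropped
    blocks = x[: n_epochs * n_per].reshape(n_epochs, n_per)
    n_missing = np.isnan(blocks).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isnan(blocks), np.nan, blocks), axis=1)
    means[n_missing * 2 > n_per] = np.nan  # > 50% missing -> invalid
    return means


def resample_epochs(rec: RawRecording, epoch_s: float = EPOCH_S_DEFAULT) -> EpochSeries:
    """Average raw samples over consecutive ``epoch_s`` windows.

    ``epoch_s`` must be a positive integer multiple of the sample period.
    Epoch k covers samples in ``[k*epoch_s, (k+1)*epoch_s)``; a trailing
    partial epoch is dropped; epochs with more than half their samples
    missing are flagged invalid (NaN).
    """
    ratio = epoch_s / rec.sample_period_s
    if epoch_s <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"epoch_s={epoch_s} must be a positive multiple of the "
            f"sample period {rec.sample_period_s}"
        )
    n_per = int(round(ratio))
    icp = _epoch_mean(np.asarray(rec.icp, dtype=float), n_per)
    map_ = _epoch_mean(np.asarray(rec.abp_mean, dtype=float), n_per)
    amp = _epoch_mean(np.asarray(rec.amp, dtype=float), n_per)
    return EpochSeries(
        patient_id=rec.patient_id,
        epoch_s=float(epoch_s),
        t0_offset_s=0.0,
        icp=icp,
        map_=map_,
        cpp=map_ - icp,
        amp=amp,
    )


def smooth_moving_average(x: np.ndarray, span: int = 4) -> np.ndarray:
    """Trailing moving average with a shortened leading edge.

    ``y[i]`` averages the last ``min(span, i+1)`` values.  Any NaN inside a
    window makes the output NaN there, so invalid epochs propagate.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    out = np.empty_like(x)
    csum = np.cumsum(x)
    out[:span] = csum[:span] / (np.arange(min(span, x.size)) + 1)
    if x.size > span:
        out[span:] = (csum[span:] - csum[:-span]) / span
    # NaN contamination: cumsum already propagates NaN forward indefinitely,
    # so recompute windows explicitly where the fast path is poisoned
    bad = ~np.isfinite(out)
    if bad.any() and np.isfinite(x).any():
        for i in np.flatnonzero(bad):
            w = x[max(0, i - span + 1) : i + 1]
            out[i] = w.mean()  # stays NaN if the window truly contains NaN
    return out


def smooth_epoch_series(es: EpochSeries, span: int = 4) -> EpochSeries:
    """Smooth ICP, MAP and AMP; re-derive CPP from the smoothed series."""
    icp = smooth_moving_average(es.icp, span)
    map_ = smooth_moving_average(es.map_, span)
    amp = smooth_moving_average(es.amp, span)
    return replace(es, icp=icp, map_=map_, amp=amp, cpp=map_ - icp)


def extract_window(es: EpochSeries, start_h: float, end_h: float) -> EpochSeries:
    """Retain epochs whose midpoints fall in ``[start_h, end_h)`` hours."""
    if not 0 <= start_h < end_h:
        raise ValueError("need 0 <= start_h < end_h")
    if end_h > es.duration_hours + es.epoch_s / 3600.0:
        raise ValueError(
            f"window ({start_h}, {end_h}) h exceeds recording "
            f"length {es.duration_hours:.2f} h"
        )
    mid = es.midpoints_s()
    keep = (mid >= start_h * 3600.0) & (mid < end_h * 3600.0)
    if not keep.any():
        raise ValueError(f"window ({start_h}, {end_h}) h contains no epochs")
    idx = np.flatnonzero(keep)
    return EpochSeries(
        patient_id=es.patient_id,
        epoch_s=es.epoch_s,
        t0_offset_s=es.t0_offset_s + idx[0] * es.epoch_s,
        icp=es.icp[keep].copy(),
        map_=es.map_[keep].copy(),
        cpp=es.cpp[keep].copy(),
        amp=es.amp[keep].copy(),
    )


def extract_amp_from_pulse(
    pulse_icp: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 10.0,
    band_hz: tuple[float, float] = (0.66, 3.0),
) -> np.ndarray:
    """Pulse amplitude from a pulse-resolved ICP segment.

    Band-passes the cardiac band (0.66-3 Hz by default), then takes the
    peak-to-trough excursion per ``window_s`` window.  Requires at least
    20 Hz sampling (the cardiac pulse is unresolvable below that) and a
    segment of at least 60 s.
    """
    from scipy.signal import butter, filtfilt

    if sample_rate_hz < 20:
        raise ValueError("sample_rate_hz must be >= 20 to resolve the pulse")
    x = np.asarray(pulse_icp, dtype=float)
    if len(x) / sample_rate_hz < 60.0:
        raise ValueError("segment must be at least 60 s long")
    lo, hi = band_hz
    b, a = butter(3, [lo, hi], btype="bandpass", fs=sample_rate_hz)
    y = filtfilt(b, a, x)
    n_per = int(round(window_s * sample_rate_hz))
    n_win = len(y) // n_per
    blocks = y[: n_win * n_per].reshape(n_win, n_per)
    return blocks.max(axis=1) - blocks.min(axis=1)


def preprocess(
    rec: RawRecording, epoch_s: float = EPOCH_S_DEFAULT, span: int = 4
) -> EpochSeries:
    """Standard preparation: resample to epochs, then smooth (in that order)."""
    return smooth_epoch_series(resample_epochs(rec, epoch_s), span)
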