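"""Linear cerebrovascular indices: PRx and RAP.

Both indices are moving Pearson correlations over the 12-s epoch series:

* PRx (pressure reactivity index) correlates ICP with MAP; persistently
  positive values indicate impaired cerebral autoregulation.
* RAP (compensatory reserve index) correlates ICP pulse amplitude with ICP;
  values near 1 indicate exhausted cerebrospinal pressure-volume reserve.

The correlation window defaults to 30 epochs (6 min), the neuromonitoring
convention of ~30 samples per window; the update stride is one epoch.  A
window yields a valid value only when every epoch in it is valid and both
channels have nonzero variance; otherwise the position is invalid (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_prep import EpochSeries

__all__ = ["IndexSeries", "moving_pearson", "prx", "rap", "window_mean"]

WINDOW_EPOCHS_DEFAULT = 30


@dataclass
class IndexSeries:
    """A moving-correlation index series; invalid positions are NaN."""

    name: str
    values: np.ndarray
    window_epochs: int

    def __post_init__(self) -> None:
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9):
            raise ValueError(f"{self.name}: correlation values outside [-1, 1]")


def moving_pearson(x: np.ndarray, y: np.ndarray, window_epochs: int) -> np.ndarray:
    """Trailing-window Pearson correlation at every epoch.

    Value at position i is the correlation over epochs
    ``[i - window + 1, i]``; the first ``window - 1`` positions, windows
    containing any invalid epoch, and zero-variance windows are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    w = int(window_epochs)
    if w < 3:
        raise ValueError("window_epochs must be >= 3")
    n = x.size
    out = np.full(n, np.nan)
    if w > n:
        warnings.warn(
            f"window ({w}) longer than series ({n}); all values invalid",
            stacklevel=2,
        )
        return out
    xw = sliding_window_view(x, w)
    yw = sliding_window_view(y, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = xw - xw.mean(axis=1, keepdims=True)
        yc = yw - yw.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
        r = num / den
    r[(xc * xc).sum(axis=1) == 0] = np.nan
    r[(yc * yc).sum(axis=1) == 0] = np.nan
    out[w - 1 :] = np.clip(r, -1.0, 1.0)
    return out


def prx(es: EpochSeries, window_epochs: int = WINDOW_EPOCHS_DEFAULT) -> IndexSeries:
    """Pressure reactivity index: moving Pearson correlation of ICP and MAP."""
    return IndexSeries(
        name="PRx",
        values=moving_pearson(es.icp, es.map_, window_epochs),
        window_epochs=window_epochs,
    )


def rap(es: EpochSeries, window_epochs: int = WINDOW_EPOCHS_DEFAULT) -> IndexSeries:
    """Compensatory reserve index: moving Pearson correlation of AMP and ICP."""
    return IndexSeries(
        name="RAP",
        values=moving_pearson(es.amp, es.icp, window_epochs),
        window_epochs=window_epochs,
    )


def window_mean(xs: np.ndarray) -> float:
    """Arithmetic mean over valid (finite) entries; NaN if none are valid."""
    xs = np.asarray(xs, dtype=float)
    v = xs[np.isfinite(xs)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())
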