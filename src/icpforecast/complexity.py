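"""Nonlinear complexity features: sample entropy and Lempel-Ziv complexity.

Sample entropy (SampEn) quantifies irregularity as the negative log of the
conditional probability that two subsequences matching for m points (within
tolerance r, Chebyshev norm, self-matches excluded) still match at m+1
points.  The conventional parameters m = 2 and r = 0.2 * SD of the analysed
series are the defaults.

Lempel-Ziv complexity (LZ76, exhaustive parsing) counts the non-redundant
phrases of a symbol sequence: the counter advances whenever the next symbol
extends a pattern that cannot be reproduced from the previous history.
Numeric series are binarized (median split by default) before parsing, and
the count is reported normalized as ``c(n) * log2(n) / n`` so that values of
long equiprobable random strings approach 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ComplexityParams",
    "sample_entropy",
    "binarize",
    "lempel_ziv",
    "complexity_features",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Settings shared by the nonlinear features.

    m: embedding (template) length for SampEn.
    r_frac: SampEn tolerance as a fraction of the series SD.
    lzc_binarize: symbolization rule, ``"median"`` or ``"mean"``.
    lzc_normalized: report ``c(n) * log2(n) / n`` instead of the raw count.
    """

    m: int = 2
    r_frac: float = 0.2
    lzc_binarize: str = "median"
    lzc_normalized: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")
        if self.lzc_binarize not in ("median", "mean"):
            raise ValueError("lzc_binarize must be 'median' or 'mean'")


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(x, m)


def sample_entropy(x: np.ndarray, params: ComplexityParams = ComplexityParams()) -> float:
    """SampEn(m, r) = -ln(A / B) with Chebyshev distances.

    B counts pairs of m-length templates within r = r_frac * SD(x); A counts
    the same index pairs at length m + 1 (both over the N - m templates, the
    Richman-Moorman convention).  A constant series returns 0; if no m-match
    extends to m + 1, returns +inf.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"series too short for SampEn (need >= {m + 2} points)")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r_frac * sd
    # both template sets range over i = 0 .. N-m-1 so every m-template has an
    # (m+1)-extension
    tm = _embed(x, m)[:-1] if m >= 1 else None
    tm1 = _embed(x, m + 1)
    b = int((pdist(tm, metric="chebyshev") <= r).sum())
    a = int((pdist(tm1, metric="chebyshev") <= r).sum())
    if a == 0 or b == 0:
        return float("inf")
    return float(math.log(b / a))  # == -ln(A/B), avoids -0.0


def binarize(x: np.ndarray, rule: str = "median") -> str:
    """Symbolize a numeric series: '1' where x > threshold, else '0'.

    The threshold is the sample median (default) or mean.  A constant series
    yields an all-zero string with a warning.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 valid values to binarize")
    if rule == "median":
        thr = float(np.median(x))
    elif rule == "mean":
        thr = float(np.mean(x))
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    if np.all(x == x[0]):
        warnings.warn("constant series binarizes to all zeros", stacklevel=2)
    return "".join("1" if v > thr else "0" for v in x)


def lz76_phrases(s: str) -> int:
    """Raw LZ76 exhaustive-parsing phrase count c(n).

    A phrase grows while it can be copied from the prior history (overlap
    with the phrase itself allowed, so ``0|00...`` parses as two phrases);
    the final, possibly incomplete phrase is counted.
    """
    n = len(s)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    u, c = 0, 0
    while u < n:
        v = 1
        # extend while s[u:u+v] occurs starting before u (search window ends
        # one short of the phrase end, which permits self-overlap)
        while u + v <= n and s[u : u + v] in s[: u + v - 1]:
            v += 1
        c += 1
        u += v
    return c


def lempel_ziv(s: str, normalized: bool = True) -> float:
    """LZ76 complexity of a binary string; normalized as c(n)*log2(n)/n."""
    if set(s) - {"0", "1"}:
        raise ValueError("lempel_ziv expects a binary string of '0'/'1'")
    c = lz76_phrases(s)
    if not normalized:
        return float(c)
    n = len(s)
    return c * math.log2(n) / n


def complexity_features(
    es6h, params: ComplexityParams = ComplexityParams(), min_valid: int = 100
) -> dict[str, float]:
    """The four nonlinear features of a 6-h epoch-series window.

    SampEn is computed on the numeric ICP and CPP series (invalid epochs
    dropped); LZc on their binarized versions.  Fewer than ``min_valid``
    valid epochs yields NaN markers for all four.
    """
    valid = es6h.valid
    out = {k: float("nan") for k in ("icp_sampen", "cpp_sampen", "icp_lzc", "cpp_lzc")}
    if int(valid.sum()) < min_valid:
        return out
    for channel, series in (("icp", es6h.icp[valid]), ("cpp", es6h.cpp[valid])):
        out[f"{channel}_sampen"] = sample_entropy(series, params)
        out[f"{channel}_lzc"] = lempel_ziv(
            binarize(series, params.lzc_binarize), params.lzc_normalized
        )
    return out
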