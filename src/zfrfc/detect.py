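"""Onset detection for BOLD events.

The zero-frequency resonator (ZFR) is a second-order filter with a double
pole at zero frequency,

    y[n] = m[n] + 2 y[n-1] - y[n-2],        y[-1] = y[-2] = 0,

equivalent to taking the cumulative sum of the input twice.  An ideal
neuronal impulse has energy at every frequency, including zero, so the
resonator output preserves impulse timing while the sluggish hemodynamic
response and broadband noise are heavily attenuated relative to the
polynomially growing trend.  Subtracting a local mean over a window of
2*n1 + 1 samples removes that trend; in the resulting zero-frequency
filtered signal each event appears as a negative excursion terminated by a
positive zero-crossing (sign change from negative to non-negative).  By
default the onset is reported at the excursion's minimum, which tracks the
event to within about one repetition time; the raw crossing sample, which
recovers only after the local-mean window has passed the event, is
available as an alternative convention.

The baseline detector marks upward crossings of a z-score threshold
(default 1.0) on the standardized time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OnsetTrain, TimeCourse

__all__ = [
    "ZFRParams",
    "zfr_filter",
    "remove_local_mean",
    "positive_zero_crossings",
    "onsets_from_filtered",
    "detect_onsets_zfr",
    "detect_onsets_threshold",
    "zfr_filtered_signal",
]

# the resonator output grows polynomially; guard against overflow on
# pathologically long or large-valued inputs
_OVERFLOW_LIMIT = 1e300


@dataclass(frozen=True)
class ZFRParams:
    """Resonator configuration: local-mean half-window ``n1`` in samples.

    The mean window spans ``2*n1 + 1`` samples.  Defaults to 15, the choice
    for event-related designs at TR 2 s; block designs typically use 11.
    """

    n1: int = 15

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be >= 1")

    @property
    def window(self) -> int:
        return 2 * self.n1 + 1


def _values(tc) -> np.ndarray:
    if isinstance(tc, TimeCourse):
        return tc.values
    arr = np.asarray(tc, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    return arr


def zfr_filter(tc) -> np.ndarray:
    """Run the zero-frequency resonator (double cumulative sum).

    Accepts a :class:`TimeCourse` or array; for an N-D array the filter runs
    along the last axis (one time course per row).
    """
    m = _values(tc)
    y = np.cumsum(np.cumsum(m, axis=-1), axis=-1)
    peak = np.max(np.abs(y))
    if not np.isfinite(peak) or peak > _OVERFLOW_LIMIT:
        raise OverflowError("resonator output exceeded the double-precision guard")
    return y


def remove_local_mean(y: np.ndarray, params: ZFRParams | int = ZFRParams()) -> np.ndarray:
    """Subtract the local mean over a ``2*n1 + 1``-sample window.

    Boundary windows are clipped to the valid index range and the mean is
    taken over the samples actually available, so no samples are discarded.
    Operates along the last axis.
    """
    if isinstance(params, int):
        params = ZFRParams(params)
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if params.window >= n:
        raise ValueError(
            f"window {params.window} must be smaller than the signal length {n}"
        )
    ones = np.ones(params.window)
    counts = np.convolve(np.ones(n), ones, mode="same")

    def _one(row: np.ndarray) -> np.ndarray:
        return row - np.convolve(row, ones, mode="same") / counts

    if y.ndim == 1:
        return _one(y)
    flat = y.reshape(-1, n)
    return np.stack([_one(r) for r in flat]).reshape(y.shape)


def positive_zero_crossings(z: np.ndarray) -> np.ndarray:
    """Indices n with z[n-1] < 0 and z[n] >= 0 (negative-to-positive sign
    change; an exact zero counts as non-negative)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("need a 1-D signal with at least 2 samples")
    return np.flatnonzero((z[:-1] < 0) & (z[1:] >= 0)) + 1


def zfr_filtered_signal(
    tc, params: ZFRParams | int = ZFRParams(), demean: bool = True
) -> np.ndarray:
    """Resonator output with its local mean removed (the signal whose
    sign structure carries the event timing).

    A nonzero temporal mean ``B`` of the input survives the pipeline as a
    constant offset of about ``-n1*(n1+1)/6 * B`` in the filtered signal
    (the resonator turns it into a quadratic trend, of which the windowed
    mean removes only the constant and linear parts), which would bury the
    zero-crossings entirely for raw BOLD values sitting on a tissue
    baseline.  The input is therefore demeaned first (``demean=False``
    gives the raw composition).  Operates along the last axis.
    """
    m = _values(tc)
    if demean:
        m = m - m.mean(axis=-1, keepdims=True)
    return remove_local_mean(zfr_filter(m), params)


def onsets_from_filtered(z: np.ndarray, onset_at: str = "trough") -> np.ndarray:
    """Locate event onsets in a zero-frequency filtered signal.

    Each BOLD event deflects the filtered signal into a negative excursion
    that is terminated by a positive zero-crossing.  ``onset_at`` selects
    which point of the excursion is reported:

    - ``'trough'`` (default): the minimum of the excursion preceding each
      positive zero-crossing — the point of maximal resonator deflection,
      which tracks the event to within about one repetition time.
    - ``'crossing'``: the positive zero-crossing sample itself; this lags
      the event by roughly the half-window ``n1`` because the local mean
      must recover first.
    """
    crossings = positive_zero_crossings(z)
    if onset_at == "crossing":
        return crossings
    if onset_at != "trough":
        raise ValueError(f"unknown onset_at {onset_at!r}")
    onsets = []
    prev = 0
    for c in crossings:
        seg = z[prev:c]
        onsets.append(prev + int(np.argmin(seg)))
        prev = int(c)
    return np.unique(onsets).astype(np.int64)


def detect_onsets_zfr(
    tc: TimeCourse,
    params: ZFRParams | int = ZFRParams(),
    onset_at: str = "trough",
) -> OnsetTrain:
    """Detect BOLD-event onsets with the ZFR pipeline.

    The time course is resonated (double cumulative sum), the local mean
    over ``2*n1 + 1`` samples is removed, and onsets are read off the
    negative excursions of the filtered signal (see
    :func:`onsets_from_filtered`).  Onsets within ``n1`` samples of either
    end are flagged as boundary-unreliable (the mean window there is
    clipped) but retained.
    """
    if isinstance(params, int):
        params = ZFRParams(params)
    z = zfr_filtered_signal(tc, params)
    idx = onsets_from_filtered(z, onset_at=onset_at)
    n = len(tc)
    boundary = (idx < params.n1) | (idx >= n - params.n1)
    return OnsetTrain(idx, tr=tc.tr, detector="zfr", boundary=boundary, n_samples=n)


def detect_onsets_threshold(tc: TimeCourse, thresh: float = 1.0) -> OnsetTrain:
    """Baseline detector: upward crossings of ``thresh`` on the z-scored
    time course.  A plateau above threshold yields a single onset at its
    first sample; sample 0 is an onset if it already exceeds the threshold.
    """
    v = tc.values
    sd = v.std()
    if sd == 0:
        raise ValueError("threshold detector requires nonzero variance")
    zscored = (v - v.mean()) / sd
    above = zscored >= thresh
    crossing = above.copy()
    crossing[1:] &= ~above[:-1]
    idx = np.flatnonzero(crossing)
    return OnsetTrain(idx, tr=tc.tr, detector="threshold", n_samples=len(tc))
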