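"""Point-process and correlation metrics for pairwise co-activation.

Two event trains are compared through the *conditional rate* (CR): the
fraction of seed onsets for which a target onset occurs within a short
delay tolerance.  Co-activated voxels fire together, so their CR approaches
1; unrelated voxels score low.  The *HSNR correlation* instead keeps the
raw signal but restricts the Pearson correlation to high-signal-to-noise
windows around the seed's detected onsets, averaging over windows.  Plain
full-length Pearson correlation serves as the conventional reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OnsetTrain, TimeCourse, UndefinedMetricError
from .detect import ZFRParams, detect_onsets_threshold, detect_onsets_zfr

__all__ = [
    "MatchPolicy",
    "HSNRRegionSet",
    "match_onsets",
    "conditional_rate",
    "extract_hsnr_regions",
    "hsnr_correlation",
    "pearson_fc",
    "roi_connectivity_matrix",
]


@dataclass(frozen=True)
class MatchPolicy:
    """How a target onset may claim a seed onset.

    A target onset ``t`` matches seed onset ``s`` iff ``t`` lies in
    ``[s, s + max_delay]`` — the BOLD response can only lag its cause — or
    in ``[s - max_delay, s + max_delay]`` when ``allow_advance`` is set
    (used when the seed is an external stimulus train, whose clock is not
    the hemodynamic one).  ``one_to_one`` enforces that every onset is used
    in at most one pair, which caps the conditional rate at 1.
    """

    max_delay: int = 2
    allow_advance: bool = False
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.max_delay < 0:
            raise ValueError("max_delay must be >= 0")

    def interval(self, s: int) -> tuple[int, int]:
        lo = s - self.max_delay if self.allow_advance else s
        return lo, s + self.max_delay


def _indices(train) -> np.ndarray:
    if isinstance(train, OnsetTrain):
        return train.indices
    idx = np.asarray(train, dtype=np.int64).ravel()
    if idx.size and np.any(np.diff(idx) <= 0):
        raise ValueError("onset indices must be strictly increasing")
    return idx


def match_onsets(seed, target, policy: MatchPolicy = MatchPolicy()) -> int:
    """Count matched seed onsets under greedy earliest-first pairing.

    Seeds are scanned in order; each claims the earliest unused target
    onset inside its tolerance interval.  With ``one_to_one=False`` the
    count is instead the number of *target* onsets inside any seed
    interval (may exceed the seed count).
    """
    s_idx = _indices(seed)
    t_idx = _indices(target)
    if s_idx.size == 0 or t_idx.size == 0:
        return 0
    if not policy.one_to_one:
        hit = np.zeros(t_idx.size, dtype=bool)
        for s in s_idx:
            lo, hi = policy.interval(int(s))
            hit |= (t_idx >= lo) & (t_idx <= hi)
        return int(hit.sum())
    matched = 0
    j = 0
    for s in s_idx:
        lo, hi = policy.interval(int(s))
        while j < t_idx.size and t_idx[j] < lo:
            j += 1
        if j < t_idx.size and t_idx[j] <= hi:
            matched += 1
            j += 1
    return matched


def conditional_rate(seed, target, policy: MatchPolicy = MatchPolicy()) -> float:
    """Matched seed onsets divided by the seed onset count (in [0, 1] under
    one-to-one matching).  Undefined for an empty seed train."""
    s_idx = _indices(seed)
    if s_idx.size == 0:
        raise UndefinedMetricError("conditional rate is undefined for an empty seed train")
    return match_onsets(s_idx, target, policy) / s_idx.size


# ---------------------------------------------------------------------------
# HSNR regions


@dataclass(frozen=True)
class HSNRRegionSet:
    """High-SNR windows around detected onsets.

    For an onset at sample ``n_c`` the window is the inclusive interval
    ``[n_c - 2, n_c + w - 3]`` (length ``w``, default 6), clipped at the
    signal boundaries.  Overlapping windows are kept separate.
    """

    windows: tuple[tuple[int, int], ...]
    w: int = 6
    source_onsets: OnsetTrain | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for lo, hi in self.windows:
            if hi < lo:
                raise ValueError("window end before start")
            if hi - lo + 1 > self.w:
                raise ValueError("window longer than w")
        starts = [lo for lo, _ in self.windows]
        if sorted(starts) != list(starts):
            raise ValueError("windows must be sorted by start")

    def __len__(self) -> int:
        return len(self.windows)

    def total_samples(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.windows)


def extract_hsnr_regions(onsets, signal_length: int, w: int = 6) -> HSNRRegionSet:
    """Build the HSNR window set for a train of onsets."""
    if w < 3:
        raise ValueError("w must be >= 3 (window must cover the onset context)")
    idx = _indices(onsets)
    if idx.size and (idx[0] < 0 or idx[-1] >= signal_length):
        raise ValueError("onsets must lie within [0, signal_length)")
    windows = tuple(
        (max(0, int(n_c) - 2), min(signal_length - 1, int(n_c) + w - 3)) for n_c in idx
    )
    source = onsets if isinstance(onsets, OnsetTrain) else None
    return HSNRRegionSet(windows=windows, w=w, source_onsets=source)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise UndefinedMetricError("zero variance segment")
    return float((a @ b) / denom)


def hsnr_correlation(
    seed_tc: TimeCourse,
    target_tc: TimeCourse,
    regions: HSNRRegionSet,
    weight_by_length: bool = False,
) -> float:
    """Mean Pearson correlation between seed and target over the HSNR windows.

    Windows shorter than 3 samples or with zero variance in either segment
    are skipped; with no contributing window the score is undefined.
    ``weight_by_length`` switches the unweighted mean over windows to a
    sample-count-weighted one.
    """
    if len(seed_tc) != len(target_tc):
        raise ValueError("seed and target must have equal length")
    scores, weights = [], []
    for lo, hi in regions.windows:
        if hi - lo + 1 < 3:
            continue
        a = seed_tc.values[lo : hi + 1]
        b = target_tc.values[lo : hi + 1]
        try:
            r = _pearson(a, b)
        except UndefinedMetricError:
            continue
        scores.append(r)
        weights.append(hi - lo + 1)
    if not scores:
        raise UndefinedMetricError("no HSNR region with usable variance")
    if weight_by_length:
        return float(np.average(scores, weights=weights))
    return float(np.mean(scores))


def pearson_fc(seed_tc: TimeCourse, target_tc: TimeCourse) -> float:
    """Full-length Pearson correlation between two time courses."""
    if len(seed_tc) != len(target_tc):
        raise ValueError("seed and target must have equal length")
    return _pearson(seed_tc.values, target_tc.values)


# ---------------------------------------------------------------------------
# ROI matrices


def _detect(tc: TimeCourse, metric: str, zfr_params: ZFRParams, thresh: float) -> OnsetTrain:
    if metric == "cr_zfr":
        return detect_onsets_zfr(tc, zfr_params)
    return detect_onsets_threshold(tc, thresh)


def roi_connectivity_matrix(
    roi_timecourses,
    metric: str = "correlation",
    labels=None,
    policy: MatchPolicy = MatchPolicy(),
    zfr_params: ZFRParams = ZFRParams(),
    thresh: float = 1.0,
    w: int = 6,
) -> pd.DataFrame:
    """Pairwise connectivity among ROI-average time courses.

    metric is one of ``correlation``, ``cr_threshold``, ``cr_zfr``,
    ``hsnr``.  Entry (i, j) treats ROI i as seed and ROI j as target; CR
    matrices may be asymmetric because the seed normalisation differs.
    Undefined entries are NaN, never 0.  The diagonal is 1 by construction
    for every metric (identical trains / self-correlation).
    """
    tcs = list(roi_timecourses)
    if len(tcs) < 2:
        raise ValueError("need at least 2 ROIs")
    n_len = len(tcs[0])
    if any(len(tc) != n_len for tc in tcs):
        raise ValueError("ROI time courses must have equal lengths")
    if metric not in ("correlation", "cr_threshold", "cr_zfr", "hsnr"):
        raise ValueError(f"unknown metric {metric!r}")
    k = len(tcs)
    labels = list(labels) if labels is not None else [f"roi{i}" for i in range(k)]
    out = np.full((k, k), np.nan)

    trains = None
    if metric in ("cr_threshold", "cr_zfr"):
        trains = [_detect(tc, metric, zfr_params, thresh) for tc in tcs]
    regions = None
    if metric == "hsnr":
        regions = [
            extract_hsnr_regions(detect_onsets_zfr(tc, zfr_params), n_len, w=w)
            for tc in tcs
        ]
    for i in range(k):
        for j in range(k):
            if i == j:
                out[i, j] = 1.0
                continue
            try:
                if metric == "correlation":
                    out[i, j] = pearson_fc(tcs[i], tcs[j])
                elif metric == "hsnr":
                    out[i, j] = hsnr_correlation(tcs[i], tcs[j], regions[i])
                else:
                    out[i, j] = conditional_rate(trains[i], trains[j], policy)
            except UndefinedMetricError:
                pass  # leave as NaN
    return pd.DataFrame(out, index=labels, columns=labels)
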