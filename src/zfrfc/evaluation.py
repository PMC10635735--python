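"""Scoring detected onsets against ground truth and comparing maps.

Detections are matched to stimuli with a right-sided tolerance window: a
detection counts as a true positive only if it falls within ``tolerance``
samples *after* a stimulus (default 2 samples = 2 TR at a 2 s repetition
time), reflecting the hemodynamic lag.  Sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP); true negatives are all remaining samples, so in
sparse-event regimes specificity typically exceeds sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OnsetTrain, UndefinedMetricError
from .detect import ZFRParams, detect_onsets_threshold, detect_onsets_zfr
from .mapping import FCVolume
from .synthetic import HRFModel, NoiseSpec, canonical_hrf, synthesize_bold

__all__ = [
    "DetectionCounts",
    "ScoreSplit",
    "classify_detections",
    "sensitivity",
    "specificity",
    "jaccard",
    "split_scores",
    "detector_benchmark",
]


@dataclass(frozen=True)
class DetectionCounts:
    """TP/FP/FN/TN tallies from matching detections to stimuli."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_stimuli(self) -> int:
        return self.tp + self.fn


def _indices(train) -> np.ndarray:
    if isinstance(train, OnsetTrain):
        return train.indices
    idx = np.asarray(train, dtype=np.int64).ravel()
    if idx.size and np.any(np.diff(idx) <= 0):
        raise ValueError("indices must be strictly increasing")
    return idx


def classify_detections(
    stimuli, detected, n_samples: int, tolerance: int = 2
) -> DetectionCounts:
    """Match detections to stimuli and tally the confusion counts.

    Greedy earliest-first one-to-one matching: detection ``d`` may match
    stimulus ``s`` iff ``d`` lies in ``[s, s + tolerance]`` (right side
    only — the BOLD event can only lag the stimulus).  TP = matched
    stimuli, FN = unmatched stimuli, FP = unmatched detections, and every
    remaining sample is a true negative.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    s_idx = _indices(stimuli)
    d_idx = _indices(detected)
    tp = 0
    j = 0
    for s in s_idx:
        while j < d_idx.size and d_idx[j] < s:
            j += 1
        if j < d_idx.size and d_idx[j] <= s + tolerance:
            tp += 1
            j += 1
    fn = s_idx.size - tp
    fp = d_idx.size - tp
    tn = n_samples - tp - fn - fp
    if tn < 0:
        raise ValueError("n_samples smaller than the tally of events")
    return DetectionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(counts: DetectionCounts) -> float:
    """TP / (TP + FN); undefined with no stimuli."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined with no stimuli")
    return counts.tp / denom


def specificity(counts: DetectionCounts) -> float:
    """TN / (TN + FP); undefined with no negative samples."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise UndefinedMetricError("specificity undefined with no negatives")
    return counts.tn / denom


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B| between two binary masks on the same grid.

    Two empty masks are defined as identical (1.0, with a warning).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty: Jaccard defined as 1.0")
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class ScoreSplit:
    """Connectivity scores split into co-activation (inside the active
    region) and non-co-activation (outside) groups."""

    co_scores: np.ndarray
    non_co_scores: np.ndarray

    @property
    def co_mean(self) -> float:
        return float(np.mean(self.co_scores))

    @property
    def non_co_mean(self) -> float:
        return float(np.mean(self.non_co_scores))

    @property
    def co_std(self) -> float:
        return float(np.std(self.co_scores))

    @property
    def non_co_std(self) -> float:
        return float(np.std(self.non_co_scores))

    @property
    def mean_difference(self) -> float:
        return self.co_mean - self.non_co_mean


def split_scores(vol: FCVolume, active_mask: np.ndarray) -> ScoreSplit:
    """Partition the defined map values by an active-region mask."""
    active = np.asarray(active_mask, dtype=bool)
    if active.shape != vol.values.shape:
        raise ValueError("active mask must share the map's grid")
    defined = vol.defined
    co = vol.values[defined & active]
    non_co = vol.values[defined & ~active]
    if co.size == 0 or non_co.size == 0:
        raise ValueError("both partitions must be non-empty")
    return ScoreSplit(co_scores=co, non_co_scores=non_co)


# ---------------------------------------------------------------------------
# Monte-Carlo detector benchmark


def detector_benchmark(
    n_runs: int = 100,
    length: int = 400,
    n_events: int = 20,
    tr: float = 2.0,
    sigma: float = 0.2,
    tolerance: int = 2,
    min_gap: int = 0,
    zfr_params: ZFRParams = ZFRParams(),
    thresh: float = 1.0,
    seed=None,
    detectors=("zfr", "threshold"),
) -> pd.DataFrame:
    """Simulate noisy event-related courses and score each detector.

    Per run: ``n_events`` impulses at random distinct samples (at least
    ``min_gap`` samples apart, leaving room for the HRF rise at the end),
    convolution with the canonical HRF (unit peak), white Gaussian noise
    of standard deviation ``sigma`` (in units of the HRF peak; 0 disables
    noise), detection, and confusion tallies against the true impulses at
    the right-sided tolerance.  Returns the run-level table
    (detector, run, sensitivity, specificity, tp, fp, fn, tn).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    from .synthetic import ImpulseTrain

    ss = np.random.SeedSequence(seed)
    kernel = canonical_hrf(HRFModel(tr=tr))
    records = []
    for run, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        # distinct random onset samples; keep clear of the tail so every
        # event's response rise is observed
        hi = max(n_events + 1, length - len(kernel)) - n_events * min_gap
        if hi < n_events:
            raise ValueError("length too small for n_events at this min_gap")
        onsets = np.sort(rng.choice(hi, size=n_events, replace=False))
        onsets = onsets + np.arange(n_events) * min_gap
        train = ImpulseTrain(length=length, onsets=onsets)
        noise = NoiseSpec(kind="white_gaussian", sigma=sigma) if sigma > 0 else None
        tc = synthesize_bold(train, kernel, noise=noise, tr=tr, rng=rng)
        for det in detectors:
            if det == "zfr":
                found = detect_onsets_zfr(tc, zfr_params)
            elif det == "threshold":
                found = detect_onsets_threshold(tc, thresh)
            else:
                raise ValueError(f"unknown detector {det!r}")
            counts = classify_detections(onsets, found, n_samples=length, tolerance=tolerance)
            records.append(
                {
                    "detector": det,
                    "run": run,
                    "sensitivity": sensitivity(counts),
                    "specificity": specificity(counts),
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                }
            )
    return pd.DataFrame.from_records(records)
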