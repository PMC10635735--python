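"""Shared containers for 1-D BOLD time courses and event-onset trains.

The whole package works in discrete sample indices: a time course is a
uniformly sampled signal with repetition time ``tr`` (seconds per sample),
and an onset train is an ordered list of sample indices.  Seconds are always
``index * tr`` (0-based indexing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCourse", "OnsetTrain", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """A connectivity or evaluation metric is undefined for its input.

    Raised, e.g., for a conditional rate with an empty seed train or an
    aggregated correlation with no usable high-SNR region.  Callers that
    build maps or matrices catch this and record the cell as missing —
    an undefined value is never silently coerced to 0.
    """


def _as_1d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeCourse:
    """A uniformly sampled 1-D BOLD signal.

    Parameters
    ----------
    values : array-like of float
        The samples, at least 3 of them, with no missing values.
    tr : float
        Repetition time (sampling interval) in seconds; must be positive.
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        arr = _as_1d_float(self.values)
        object.__setattr__(self, "values", arr)
        if arr.size < 3:
            raise ValueError("a time course needs at least 3 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time course contains non-finite values")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total duration covered, in seconds."""
        return len(self) * self.tr

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based: seconds = index * tr)."""
        return np.arange(len(self)) * self.tr

    def discard_initial(self, n: int) -> "TimeCourse":
        """Drop the first ``n`` samples (pre-steady-state volumes)."""
        if n < 0:
            raise ValueError("n must be non-negative")
        return TimeCourse(self.values[n:], self.tr)


@dataclass(frozen=True)
class OnsetTrain:
    """Ordered sample indices of detected or ground-truth BOLD events.

    ``boundary`` flags onsets that fall inside the unreliable edge region of
    the local-mean window (they are retained, not dropped).  ``n_samples``
    records the length of the source signal when known; evaluation needs it
    to count true negatives.
    """

    indices: np.ndarray
    tr: float
    detector: str = "ground_truth"
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_samples: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("onset indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("onset indices must be non-negative")
        if self.n_samples is not None and idx.size and idx[-1] >= self.n_samples:
            raise ValueError("onset index beyond the signal length")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.boundary is None:
            object.__setattr__(self, "boundary", np.zeros(idx.size, dtype=bool))
        else:
            flags = np.asarray(self.boundary, dtype=bool).ravel()
            if flags.size != idx.size:
                raise ValueError("boundary flags must align with indices")
            object.__setattr__(self, "boundary", flags)

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times(self) -> np.ndarray:
        """Onset times in seconds."""
        return self.indices * self.tr
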