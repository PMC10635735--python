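"""Synthetic BOLD generator: sparse neuronal impulse trains, canonical
double-gamma HRF, additive Gaussian/Rician noise, and small 2-D phantoms
with known spatial components — so every downstream stage of the pipeline
has exact ground truth.

Forward model
-------------
A voxel time course is modelled as ``m[n] = s[n] * h[n] + eps[n]``: a sparse
impulse train (the neuronal activity signal) convolved with a hemodynamic
response kernel, plus measurement noise.  The phantom generalises this to a
linear combination of spatial components, each with its own impulse train,
on top of a constant tissue baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TimeCourse

__all__ = [
    "ImpulseTrain",
    "HRFModel",
    "NoiseSpec",
    "GaussianBlob",
    "PhantomComponent",
    "PhantomSpec",
    "Phantom",
    "generate_impulse_train",
    "canonical_hrf",
    "apply_noise",
    "synthesize_bold",
    "stimulus_function",
    "generate_phantom",
    "generate_subjects",
]


# ---------------------------------------------------------------------------
# impulse trains


@dataclass(frozen=True)
class ImpulseTrain:
    """A sparse train of positive impulses on ``[0, length)`` samples."""

    length: int
    onsets: np.ndarray
    amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        onsets = np.asarray(self.onsets, dtype=np.int64).ravel()
        object.__setattr__(self, "onsets", onsets)
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if onsets[0] < 0 or onsets[-1] >= self.length:
                raise ValueError("onsets must lie in [0, length)")
        if self.amplitudes is None:
            object.__setattr__(self, "amplitudes", np.ones(onsets.size))
        else:
            amp = np.asarray(self.amplitudes, dtype=float).ravel()
            if amp.size != onsets.size:
                raise ValueError("amplitudes must align with onsets")
            if np.any(amp <= 0):
                raise ValueError("amplitudes must be positive")
            object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return int(self.onsets.size)

    def to_signal(self) -> np.ndarray:
        """Dense impulse signal s[n] of length ``length``."""
        s = np.zeros(self.length)
        s[self.onsets] = self.amplitudes
        return s


def generate_impulse_train(length: int, prob: float, seed=None) -> ImpulseTrain:
    """Bernoulli impulse train: each sample is an onset with probability ``prob``.

    ``seed`` may be an int, a Generator, or None; a fixed seed reproduces the
    train bit-identically.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < prob < 1:
        raise ValueError("prob must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    onsets = np.flatnonzero(rng.random(length) < prob)
    return ImpulseTrain(length=length, onsets=onsets)


# ---------------------------------------------------------------------------
# hemodynamic response


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response.

    The kernel is the difference of two gamma densities,

        h(t) = g(t; peak_delay/d1, d1) - g(t; undershoot_delay/d2, d2) / ratio,

    sampled at ``t = 0, tr, 2*tr, ...`` up to ``duration`` and scaled to unit
    peak.  Defaults follow the standard convention: response peak at 6 s,
    undershoot at 16 s, unit dispersions, undershoot 1/6 of the peak, 32 s
    of support.
    """

    tr: float = 2.0
    duration: float = 32.0
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion_1: float = 1.0
    dispersion_2: float = 1.0
    undershoot_ratio: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "tr",
            "duration",
            "peak_delay",
            "undershoot_delay",
            "dispersion_1",
            "dispersion_2",
            "undershoot_ratio",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < self.tr:
            raise ValueError("duration must be at least one tr")


def canonical_hrf(model: HRFModel | None = None, **kwargs) -> np.ndarray:
    """Sample the double-gamma HRF of ``model`` on its TR grid (unit peak)."""
    if model is None:
        model = HRFModel(**kwargs)
    n = int(np.floor(model.duration / model.tr)) + 1
    t = np.arange(n) * model.tr
    peak = stats.gamma.pdf(
        t, a=model.peak_delay / model.dispersion_1, scale=model.dispersion_1
    )
    under = stats.gamma.pdf(
        t, a=model.undershoot_delay / model.dispersion_2, scale=model.dispersion_2
    )
    kernel = peak - under / model.undershoot_ratio
    top = kernel.max()
    if top <= 0:
        raise ValueError("HRF kernel has no positive peak on this grid")
    return kernel / top


# ---------------------------------------------------------------------------
# noise


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model.

    ``kind='white_gaussian'`` reads ``sigma`` (signal units).
    ``kind='rician'`` reads ``cnr``, the contrast-to-noise ratio in the
    simulation-toolbox convention: the temporal standard deviation of the
    clean signal divided by the noise standard deviation, so
    ``sigma = signal_sd / cnr``.  The magnitude of the clean signal plus a
    complex Gaussian perturbation is returned, so Rician-corrupted data
    are everywhere non-negative.  ``kind='none'`` disables noise.
    """

    kind: str = "white_gaussian"
    sigma: float | None = None
    cnr: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("white_gaussian", "rician", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "white_gaussian" and not (self.sigma and self.sigma > 0):
            raise ValueError("white_gaussian noise requires sigma > 0")
        if self.kind == "rician" and not (self.cnr and self.cnr > 0):
            raise ValueError("rician noise requires cnr > 0")


def apply_noise(
    clean: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    signal_scale: float | None = None,
) -> np.ndarray:
    """Corrupt ``clean`` according to ``spec``.

    For Rician noise the contrast-to-noise ratio fixes the noise level as
    ``sigma = signal_scale / cnr``; when ``signal_scale`` is not given,
    the temporal standard deviation of the clean signal is used.
    """
    if spec.kind == "none":
        return np.asarray(clean, dtype=float).copy()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    clean = np.asarray(clean, dtype=float)
    if spec.kind == "white_gaussian":
        return clean + spec.sigma * rng.standard_normal(clean.shape)
    # Rician: magnitude of the noisy complex signal
    if signal_scale is None:
        signal_scale = float(clean.std())
        if signal_scale <= 0:
            signal_scale = 1.0
    sigma = signal_scale / spec.cnr
    re = clean + sigma * rng.standard_normal(clean.shape)
    im = sigma * rng.standard_normal(clean.shape)
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# forward synthesis


def synthesize_bold(
    impulses: ImpulseTrain,
    hrf_kernel: np.ndarray,
    noise: NoiseSpec | None = None,
    tr: float = 2.0,
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """m[n] = s[n] * h[n] + eps[n]; zero-padded linear convolution truncated
    to the impulse-train length."""
    kernel = np.asarray(hrf_kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("HRF kernel must be non-empty")
    clean = np.convolve(impulses.to_signal(), kernel)[: impulses.length]
    if noise is None or noise.kind == "none":
        return TimeCourse(clean, tr)
    noisy = apply_noise(clean, noise, rng=rng)
    return TimeCourse(noisy, tr)


def stimulus_function(
    stimuli: ImpulseTrain, hrf_kernel: np.ndarray, tr: float = 2.0
) -> TimeCourse:
    """Reference signal: the stimulus train convolved with the HRF, noise-free."""
    return synthesize_bold(stimuli, hrf_kernel, noise=None, tr=tr)


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class GaussianBlob:
    """Isotropic Gaussian spatial weight on a 2-D grid, unit peak."""

    center: tuple[float, float]
    sigma: float
    amplitude: float = 1.0

    def weights(self, grid: tuple[int, int]) -> np.ndarray:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        yy, xx = np.mgrid[0 : grid[0], 0 : grid[1]]
        d2 = (yy - self.center[0]) ** 2 + (xx - self.center[1]) ** 2
        return self.amplitude * np.exp(-d2 / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class PhantomComponent:
    """A spatial component: a blob (or explicit weight map) plus its event rate."""

    blob: GaussianBlob | None = None
    weights: np.ndarray | None = None  # explicit per-voxel weights, alternative to blob
    event_prob: float = 0.07
    mask_level: float = 0.5  # ground-truth mask: weight >= mask_level * max weight

    def __post_init__(self) -> None:
        if (self.blob is None) == (self.weights is None):
            raise ValueError("give exactly one of blob or weights")
        if not 0 < self.event_prob < 1:
            raise ValueError("event_prob must lie in (0, 1)")

    def weight_map(self, grid: tuple[int, int]) -> np.ndarray:
        if self.blob is not None:
            w = self.blob.weights(grid)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != tuple(grid):
                raise ValueError("explicit weights must match the grid shape")
        if not np.any(w > 0):
            raise ValueError("component has an empty spatial support")
        return w

    def mask(self, grid: tuple[int, int]) -> np.ndarray:
        w = self.weight_map(grid)
        return w >= self.mask_level * w.max()


def _default_components() -> tuple[PhantomComponent, ...]:
    # two lateralised blobs, one per hemisphere analogue, sparse tone-like events
    return (
        PhantomComponent(blob=GaussianBlob(center=(50.0, 30.0), sigma=15.0)),
        PhantomComponent(blob=GaussianBlob(center=(50.0, 70.0), sigma=15.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of a 2-D two-component phantom.

    Defaults: 100x100 grid, 150 time points at TR 2 s, two Gaussian
    components each firing with per-sample probability 0.07, constant tissue
    baseline, Rician noise at CNR 1.0.
    """

    grid: tuple[int, int] = (100, 100)
    n_timepoints: int = 150
    tr: float = 2.0
    components: tuple[PhantomComponent, ...] = field(default_factory=_default_components)
    baseline: float = 100.0
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(kind="rician", cnr=1.0))
    hrf: HRFModel | None = None

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("at least one component required")
        hrf = self.hrf if self.hrf is not None else HRFModel(tr=self.tr)
        object.__setattr__(self, "hrf", hrf)
        kernel_len = int(np.floor(hrf.duration / hrf.tr)) + 1
        if self.n_timepoints < 2 * kernel_len:
            raise ValueError("n_timepoints must be at least twice the HRF kernel length")


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: data[y, x, t], ground-truth masks and trains."""

    data: np.ndarray
    masks: tuple[np.ndarray, ...]
    trains: tuple[ImpulseTrain, ...]
    component_timecourses: tuple[TimeCourse, ...]
    spec: PhantomSpec

    @property
    def label_map(self) -> np.ndarray:
        """Integer label image: 0 background, c for component c (1-based);
        overlaps resolved in favour of the later component."""
        lab = np.zeros(self.data.shape[:2], dtype=np.int16)
        for i, m in enumerate(self.masks, start=1):
            lab[m] = i
        return lab


def generate_phantom(spec: PhantomSpec, seed=None) -> Phantom:
    """Simulate the phantom: each voxel time course is

        baseline + sum_c weight_c(voxel) * (train_c * HRF) + noise.
    """
    rng = np.random.default_rng(seed)
    kernel = canonical_hrf(spec.hrf)
    trains, comp_tcs, weight_maps, masks = [], [], [], []
    for comp in spec.components:
        train = generate_impulse_train(spec.n_timepoints, comp.event_prob, rng)
        trains.append(train)
        comp_tcs.append(synthesize_bold(train, kernel, noise=None, tr=spec.tr))
        weight_maps.append(comp.weight_map(spec.grid))
        masks.append(comp.mask(spec.grid))
    clean = np.zeros(spec.grid + (spec.n_timepoints,))
    clean += spec.baseline
    for w, tc in zip(weight_maps, comp_tcs):
        clean += w[..., None] * tc.values
    if spec.noise.kind == "none":
        data = clean
    else:
        # CNR against the strongest component's temporal variation
        scale = max(float(tc.values.std()) for tc in comp_tcs)
        data = apply_noise(clean, spec.noise, rng=rng, signal_scale=scale)
    return Phantom(
        data=data,
        masks=tuple(masks),
        trains=tuple(trains),
        component_timecourses=tuple(comp_tcs),
        spec=spec,
    )


def generate_subjects(
    spec: PhantomSpec,
    n_subjects: int,
    seed=None,
    jitter_center: float = 3.0,
    jitter_sigma: float = 1.5,
    cnr_range: tuple[float, float] = (0.65, 1.0),
) -> list[Phantom]:
    """Simulate a cohort: per subject, component centres/spreads are jittered
    and a Rician CNR is drawn uniformly from ``cnr_range`` (only when the
    spec's noise kind is rician)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    subjects = []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        comps = []
        for comp in spec.components:
            if comp.blob is None:
                comps.append(comp)
                continue
            cy, cx = comp.blob.center
            blob = GaussianBlob(
                center=(
                    cy + rng.normal(scale=jitter_center),
                    cx + rng.normal(scale=jitter_center),
                ),
                sigma=max(1.0, comp.blob.sigma + rng.normal(scale=jitter_sigma)),
                amplitude=comp.blob.amplitude,
            )
            comps.append(
                PhantomComponent(
                    blob=blob, event_prob=comp.event_prob, mask_level=comp.mask_level
                )
            )
        noise = spec.noise
        if noise.kind == "rician":
            noise = NoiseSpec(kind="rician", cnr=float(rng.uniform(*cnr_range)))
        sub_spec = PhantomSpec(
            grid=spec.grid,
            n_timepoints=spec.n_timepoints,
            tr=spec.tr,
            components=tuple(comps),
            baseline=spec.baseline,
            noise=noise,
            hrf=spec.hrf,
        )
        subjects.append(generate_phantom(sub_spec, seed=rng))
    return subjects
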