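# Methods

## The problem

Task fMRI measures a blood-oxygen-level-dependent (BOLD) signal that is a
sluggish, noisy transform of the underlying neuronal activity.  The forward
model used throughout this package is

    m[n] = s[n] * h[n] + eps[n]

where `s[n]` is a sparse train of neuronal impulses, `h[n]` the hemodynamic
response function (HRF), `*` linear convolution and `eps[n]` measurement
noise.  Many functional-connectivity (FC) analyses need the *timing* of the
BOLD events — the onsets of `s[n]` — but both `s` and `h` are unknown, and
clinical or habituating subjects may not follow the nominal stimulus
schedule, so the onsets must be estimated from `m[n]` alone.

## Zero-frequency resonator detection

An ideal impulse has equal energy at all frequencies, including zero.  A
zero-frequency resonator — a second-order filter with a double pole at
`z = 1`,

    y[n] = m[n] + 2 y[n-1] - y[n-2],     y[-1] = y[-2] = 0,

equivalently the cumulative sum applied twice — therefore preserves the
impulse timing while averaging out broadband noise.  Its output grows
polynomially; the timing information lives in small fluctuations around
that trend, which are exposed by subtracting a local mean over a window of
`2*n1 + 1` samples:

    z[n] = y[n] - mean(y[n-n1 .. n+n1]).

Two implementation details matter and are worth stating precisely:

- **Input demeaning.**  The windowed mean removes the constant and linear
  parts of `y`, but a constant baseline `B` in the *input* becomes a
  quadratic in `y` and survives as a constant offset of about
  `-n1 (n1 + 1) / 6 * B` in `z`.  For raw BOLD values on a tissue baseline
  of a few hundred units this offset dwarfs the signal and suppresses every
  zero crossing, so the detector removes the temporal mean of the input
  first (`demean=True`; the raw composition is available for analysis).

- **Where the onset is read.**  Analysing the pipeline as a linear system
  shows `z ≈ -c · (locally demeaned, window-smoothed m)`: each BOLD event
  appears as a *negative excursion* of `z` whose positive zero-crossing
  occurs only after the local-mean window has cleared the response, i.e.
  roughly `n1` samples late.  The onset is therefore reported at the
  excursion's minimum (`onset_at='trough'`), the point of maximal resonator
  deflection, which lands within about one repetition time of the true
  impulse (a lone impulse at sample 50 is detected at sample 52 with
  TR 2 s).  The raw crossing convention (`onset_at='crossing'`) is kept as
  an option for studying the filter itself.

Onsets within `n1` samples of either end sit on clipped mean windows and
are flagged `boundary` (retained, not dropped).  The recurrence is computed
in double precision with an overflow guard at 1e300.

**Choosing `n1`.**  The window must be long enough to smooth TR-scale noise
but shorter than the typical inter-event interval, otherwise adjacent
events merge into one excursion.  Defaults: `n1 = 15` for event-related
single-course analysis (well-separated events), `n1 = 5` (window 11
samples) for the phantom pipeline, whose per-sample event probability 0.07
implies a mean inter-event gap of ~14 samples.  The parameter is exposed
everywhere; no automatic selection is attempted (a known limitation).

The baseline detector z-scores the time course and marks upward crossings
of a threshold (default 1.0); a contiguous supra-threshold plateau yields a
single onset at its first sample, and sample 0 counts if it already exceeds
the threshold.

## Connectivity metrics

- **Conditional rate (CR).**  Given seed and target onset trains, a target
  onset matches a seed onset if it falls within `max_delay` samples *after*
  it (default 2; the stimulus-reference variant `CR_e` also allows 2
  samples of advance, since detected BOLD events may straddle the stimulus
  clock).  Matching is greedy earliest-first and one-to-one, which caps CR
  at 1; CR = matched / seed-count.  An empty seed train makes CR undefined
  — it is signalled as such, never coerced to 0.  A many-to-one variant
  (`one_to_one=False`) exists for sensitivity analysis and may exceed 1.

- **High-SNR (HSNR) correlation.**  Around each detected onset `n_c` the
  window `m[n_c - 2 .. n_c + w - 3]` (default `w = 6`, clipped at the
  boundaries) carries most of the event's energy.  The metric computes the
  Pearson correlation between seed and target over each window (windows
  shorter than 3 samples or with zero variance are skipped) and averages
  over windows — unweighted by default, sample-count-weighted behind a
  flag.  Overlapping windows are kept separate, so an onset cluster
  up-weights its epoch; with `w` equal to the signal length and a single
  onset at sample 2 the metric degenerates exactly to the full-length
  Pearson correlation.

- **Pearson correlation** over the entire time course is the conventional
  reference metric.

ROI matrices apply any of the four metrics pairwise; CR matrices may be
asymmetric (the seed normalisation differs per row), undefined cells are
written as missing (`NA`), and the diagonal is 1.

## Seed-based maps

`seed_map` evaluates a metric between a seed (time course, stimulus-derived
reference, or onset train) and every in-mask voxel.  For the HSNR metric
the windows are derived once from the seed and the *same temporal windows*
are used in every target voxel.  Maps are post-processed by min-max
normalisation (undefined voxels excluded; a constant map normalises to
zero with a warning), top-fraction thresholding (default 20%, ties at the
cutoff kept inclusively so the result is order-independent), and a cluster
filter that removes connected components below a minimum extent (16 voxels
in 3-D, 8 in 2-D; faces+edges+corners connectivity).  The alternative
per-voxel reading — keep voxels with at least that many active neighbours —
is available behind a flag.  Group averages are voxel-wise means with a
minimum-subject-count rule (default: every subject must contribute).

## Evaluation

Detections are matched to ground-truth stimuli with a *right-sided*
tolerance window `[s, s + tolerance]` (default 2 samples = 2 TR), greedy
earliest-first and one-to-one; TP are matched stimuli, FN unmatched
stimuli, FP unmatched detections, and every remaining sample a TN.
Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); in sparse-event
regimes specificity exceeds sensitivity because non-events dominate.
Binary maps are compared with the Jaccard index (two empty masks count as
identical, with a warning).  `split_scores` partitions a map's values by an
active-region mask into co-activation and non-co-activation scores and
reports their means and difference.

## Synthetic data

The generator provides exactly the ground truth the pipeline needs:

- **Impulse trains**: per-sample Bernoulli events (default probability
  0.07), reproducible under a fixed seed.
- **HRF**: difference of two gamma densities (peak 6 s, undershoot 16 s,
  unit dispersions, undershoot ratio 6, 32 s support), sampled on the TR
  grid and scaled to unit peak.
- **Noise**: white Gaussian with a stated sigma, or Rician — the magnitude
  of the clean signal plus complex Gaussian noise, hence non-negative
  everywhere.  The Rician level is specified as a contrast-to-noise ratio
  in the simulation-toolbox convention, CNR = temporal SD of the clean
  component signal / noise SD (the peak-amplitude convention was
  considered and rejected: the reference synthetic datasets this design
  emulates state CNR 0.65–1.0 in the SD convention).
- **Phantoms**: a 100x100 grid, 150 samples at TR 2 s, two Gaussian
  spatial components (sigma 15 voxels, centred laterally like a left/right
  pair), each with its own impulse train, on a constant tissue baseline of
  100; ground-truth masks are the voxels with at least half the maximal
  component weight.  Cohorts add per-subject jitter of component centre
  and spread and draw a per-subject CNR uniformly from 0.65–1.0.

What the phantom does *not* emulate: scanner drift, physiological noise,
motion, spatial autocorrelation of noise, and 3-D geometry.  Tests passing
on it therefore demonstrate the pipeline's correctness and its behaviour
under white/Rician noise, not performance on acquired scans.

## Study conditions used by the built-in experiments

- Detector benchmark: 400-sample courses at TR 2 s, 20 events at random
  distinct samples, white Gaussian noise sigma = 0.2 of the unit response
  peak, 100 runs, right-sided 2-sample tolerance.  Under these conditions
  the threshold detector is close to a matched filter (its z-score
  threshold sits well above the noise and it fires within 1–2 samples of
  each response rise), and it attains higher sensitivity than the
  resonator detector, whose smoothing window merges adjacent events.  The
  resonator's advantages — far fewer extracted time points (about half)
  and higher specificity — appear in the same table, and its relative
  standing improves as noise grows or becomes structured.  The benchmark
  reports run-level values so either grouping can be summarised.
- Phantom pipeline: detect → CR map against each component's reference →
  min-max → top 20% → cluster filter (min 8).  Reference-seeded CR uses
  the ±2 (advance+delay) policy; voxel-to-voxel CR uses delays only.

## Numerical and degenerate-input choices

- Zero-crossing tie rule: an exact zero counts as non-negative, so a touch
  from below registers at the first non-negative sample.
- Convolution is zero-padded and truncated to the input length.
- Time is 0-based sample indexing; seconds = index × TR; TSV onset files
  always carry both columns.  TR precedence: explicit override > NIfTI
  header; a header TR of 0 means missing.
- Initial volumes (default 3) are discarded before detection and metrics
  in the CLI paths.
- Undefined metric values (empty seed train, zero variance, no usable
  HSNR region) raise a dedicated error in the library and become missing
  values (NaN / `NA`) in maps and matrices.

## Known limitations

- No sub-sample onset interpolation; onsets are whole sample indices.
- The local-mean window is user-chosen; mis-sizing it produces spurious
  onsets (too short) or merged events (too long).
- The cluster rule's neighbourhood convention and the component-size
  versus neighbour-count reading are both configurable because the
  convention is not standardised; defaults follow the cluster-extent
  convention.
- Statistical significance of connectivity values is out of scope.
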