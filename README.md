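# zfrfc — BOLD event onsets via a zero-frequency resonator, and the functional connectivity built on them

`zfrfc` estimates the temporal onsets of BOLD events in task-fMRI time
courses **without knowing the experimental paradigm**, and derives
functional connectivity (FC) from those events.  It is aimed at
neuroimaging researchers who want event-level, point-process FC — e.g. for
subjects who cannot follow a stimulus schedule reliably — and at anyone who
needs a fully ground-truthed synthetic bench for onset-detection methods.

## The model and the method

The observed BOLD signal is modelled as

```
m[n] = s[n] * h[n] + ε[n]
```

with `s[n]` a sparse train of neuronal impulses, `h[n]` the canonical
double-gamma hemodynamic response, and `ε[n]` noise.  An ideal impulse has
energy at every frequency — including zero — so passing `m[n]` through a
zero-frequency resonator (double pole at `z = 1`)

```
y[n] = m[n] + 2 y[n−1] − y[n−2]        (cumulative sum, twice)
```

preserves the impulse timing while suppressing the HRF's sluggish shape and
broadband noise.  Removing a local mean over `2·n1 + 1` samples,

```
z[n] = y[n] − (2N₁+1)⁻¹ Σ_{k=−N₁..N₁} y[n−k],
```

exposes one negative excursion of `z` per BOLD event; the excursion minimum
(terminated by a positive zero-crossing) marks the onset to within ~1 TR.

From detected onsets the package computes three event-level FC metrics
alongside plain Pearson correlation:

- **conditional rate (CR)** — the fraction of seed onsets matched by a
  target onset within a 2-sample delay tolerance (one-to-one matching, so
  CR ∈ [0, 1]);
- **HSNR correlation** — Pearson correlation restricted to the high-SNR
  windows `m[n_c−2 .. n_c+w−3]` (default `w = 6`) around the seed's
  onsets, averaged over windows;
- voxel-wise **seed maps** under any metric, with min-max normalisation,
  top-20% thresholding and cluster-extent filtering, plus ROI matrices,
  detection scoring (sensitivity/specificity against stimuli with a
  right-sided 2 TR window) and Jaccard map comparison.

A synthetic module generates impulse trains, HRF-convolved courses with
Gaussian or Rician noise, and two-component 2-D phantoms with ground-truth
masks and event trains, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from zfrfc import *

kernel = canonical_hrf(HRFModel(tr=2.0))
events = ImpulseTrain(length=400, onsets=[30, 80, 150, 210, 270, 330])
tc = synthesize_bold(events, kernel, NoiseSpec(kind="white_gaussian", sigma=0.2, seed=0), tr=2.0)

zfr = detect_onsets_zfr(tc, ZFRParams(15))
thr = detect_onsets_threshold(tc)
print("true events   :", events.onsets.tolist())
print("ZFR onsets    :", zfr.indices.tolist())
print("threshold     :", thr.indices.tolist())

counts = classify_detections(events.onsets, zfr, n_samples=400, tolerance=2)
print(f"ZFR: TP={counts.tp} FP={counts.fp} FN={counts.fn}  "
      f"sensitivity={sensitivity(counts):.2f} specificity={specificity(counts):.3f}")

cr = conditional_rate(events.onsets, zfr, MatchPolicy(max_delay=2, allow_advance=True))
print(f"conditional rate vs stimuli (+/-2): {cr:.2f}")
```

prints

```
true events   : [30, 80, 150, 210, 270, 330]
ZFR onsets    : [32, 82, 116, 151, 169, 212, 246, 271, 332, 353]
threshold     : [32, 47, 62, 66, 74, 79, 82, 152, 164, 168, 195, 211, 219, 233, 244, 247, 259, 270, 332, 348, 351, 354, 361, 396]
ZFR: TP=6 FP=4 FN=0  sensitivity=1.00 specificity=0.990
conditional rate vs stimuli (+/-2): 1.00
```

Every true event is recovered ~1 sample (2 s) late — the hemodynamic lag —
from only 10 extracted time points, while the threshold detector marks 24
supra-threshold crossings, many unrelated to events.  The conditional rate
against the stimulus train is 1.0: every stimulus is matched within ±2
samples.

## Command line

Each subcommand writes a JSON provenance sidecar so artifacts are
reproducible from disk:

```sh
zfrfc simulate --config phantom.yaml --seed 7 --out-dir sim/
zfrfc detect   --input sim/phantom.nii.gz --detector zfr --n1 5 --out onsets.tsv
zfrfc map      --input sim/phantom.nii.gz --stimuli sim/ground_truth_onsets.tsv \
               --metric cr-zfr --n1 5 --min-cluster 8 --out-dir map/
zfrfc matrix   --input rois.tsv --metric hsnr --out matrix.tsv
zfrfc evaluate --stimuli sim/ground_truth_onsets.tsv --detected onsets.tsv \
               --n-samples 150 --out eval.json
```

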