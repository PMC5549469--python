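# Methods

This note documents the models, parameter choices and numerical decisions
behind `fbcine`, and what the synthetic phantom does and does not show
about clinical data.

## Setting and assumptions

The input is one short-axis 2D+t slice of a free-breathing real-time cine:
`N` grayscale frames (nominally 84 frames of a 128×160 matrix at ~59.5 ms
per frame, ~5 s of acquisition) covering several cardiac cycles and at
least one full respiratory cycle. The method assumes:

- bright-blood contrast (SSFP-like): the LV blood pool is the brightest
  compact structure in the frame;
- respiratory motion of the heart is predominantly superior–inferior and
  slower than the cardiac cycle;
- the end-expiratory phase is a dwell: the heart sits highest (smallest
  image row) and stays there longer than at any other respiratory phase;
- the cardiac cycle length `N_f` (in frames) is stable across the slice.

## Pipeline

### LV localization

The default localizer is deterministic: the frame is thresholded at the
**upper cut of a three-class Otsu partition** and the brightest (highest
mean intensity) connected blob that is large (≥ 30 px) and compact
(solidity ≥ 0.75) is taken as the LV pool; its centroid is the seed.
Three classes are used because short-axis frames hold three intensity
populations — background/lung, myocardium, bright blood — with the pool by
far the smallest; a binary split on such class-imbalanced histograms can
land between background and myocardium and merge muscle with blood. The
solidity gate exploits the near-convexity of the pool and rejects the
ragged percolation regions that thresholded noise produces. Ties on mean
intensity break topmost-then-leftmost by bounding box. A frame with no
acceptable blob yields a failure record, not an exception.

The learned localizer mirrors the two-step mask-regression design: the
frame is zero-padded to square and downsampled to 64×64; a network of one
convolution layer (50 filters of 9×9, "valid" boundary, weights from a
zero-mean Gaussian with σ = 0.01), ReLU, 8×8 max-pooling at stride 8 and
a fully connected layer produces 4096 sigmoid outputs reshaped to a 64×64
mask (the arithmetic 64−9+1 = 56, 56/8 = 7, 7·7·50 → 4096 = 64² is
asserted at build time). Step 1 finds the heart and defines a 64×64
original-resolution crop; step 2 runs the same architecture on the crop to
output the LV mask, whose largest-component centroid is the seed. The
output head (per-pixel sigmoid binarized at 0.5) and the loss (per-pixel
binary cross-entropy, momentum SGD) are implementation choices; training
is deliberately toy-scale on phantom data, with translation/rotation/
intensity augmentation available. The fallback localizer remains the
pipeline default.

### LV-center refinement

Within a 64×64 region of interest around the seed: the pool threshold
(three-class Otsu as above, computed per frame on the ROI so the histogram
is not dominated by background), 4-connected region growing from the seed
(conservative against leakage through diagonal gaps), the convex hull of
the grown pool (the only papillary-muscle handling — the hull removes the
bites dark papillary muscle takes out of the pool), and a direct algebraic
least-squares conic fit constrained to an ellipse (Halir–Flusser
formulation) on the hull vertices. The fit gives a sub-pixel center,
semi-axes `a ≥ b`, orientation, and the area `πab` used later for ED/ES
ordering. Any stage can fail per frame (seed below threshold, degenerate
geometry); failures are returned as records naming the stage.

Hull areas are measured in rasterized pixels (pixels whose centers fall
inside the hull polygon, unioned with the pool), so the discrete hull is
a superset of the pool exactly as the continuous hull is.

### Respiratory motion signal

`H(t)` is the vertical distance from the fitted center row to the
inferior image boundary, so end-expiration maximizes `H`. The boundary and
axis choice reflect the dominantly superior–inferior respiratory motion of
the heart. Frames with failed fits (up to 20% of the slice) are linearly
interpolated; more than that aborts the trace with the failed frame list.

**Filter design.** The respiratory component is a zero-phase normalized
Hanning-weighted moving average of length `L = 2·N_f + 1`. At that length
the window's first spectral null lands exactly on the cardiac fundamental
`1/N_f`, so the heartbeat is removed rather than attenuated — a length-`N_f`
Hanning kernel leaves ~half of the cardiac amplitude in the "respiratory"
output (its main lobe still covers `1/N_f`). One twicing pass,
`respiratory = s + smooth(h − s)` with `s = smooth(h)`, flattens the
respiratory passband (gain ≈ 0.98 instead of 0.87 at a 60-frame breathing
period) while preserving every null, since the combined response
`2G − G²` vanishes wherever `G` does. Edges use reflection padding; a
transient of about `N_f` frames at each end retains some cardiac leakage,
which is why assertions about cardiac suppression are made on the series
interior. The cardiac component is defined as `h − respiratory`, making
the decomposition identity exact by construction. On slices too short for
`2·N_f + 1` the pipeline clamps the kernel to half the series length (the
decomposition degrades gracefully; the windowing and NCC stages do not
depend on it).

**Cardiac period.** `N_f` is estimated from the ellipse-area series — the
direct cardiac signal, unlike `H(t)` which mixes in respiration — as the
argmax of the biased autocorrelation of the detrended series over lags
`[4, N/2]`. A peak below 0.3 (relative to lag 0) means no significant
periodicity and is an error. Because the argmax can lock onto a multiple
of the fundamental on noisy series, a comparable peak (≥ 0.8× the best)
near `best/k` for `k = 2..4` wins; this sub-harmonic descent leaves clean
estimates untouched.

### End-expiration window

All `N − N_f + 1` contiguous windows of length `N_f` are scored by
`Σ H(t)`; the maximum (earliest on ties) is the end-expiration interval
`[A, B]`. The raw `H(t)` is used directly: summing over a full cardiac
cycle already averages the cardiac oscillation out of the score.

### ED/ES identification

For each frame in `[A, B]` a 40×40 patch is cropped at the rounded LV
center (for the even patch size the center pixel sits at position (20, 20)
1-based; out-of-image regions are zero-filled). Normalized
cross-correlation — the mean-subtracted, variance-normalized (Pearson)
similarity — is computed for all frame pairs. NCC lives in `[−1, 1]`;
values are kept signed (bright-blood frame pairs in practice correlate
positively, but clamping would discard discrimination). A constant patch
makes the similarity undefined; such pairs are marked invalid and excluded.
The argmin over valid off-diagonal entries (earliest pair on ties) gives
the two most dissimilar frames; the one with the larger fitted ellipse
area is ED. If areas tie exactly — pathological — the areas corrected for
their slow trend decide, then the earlier frame is taken as ED and the
result is flagged.

No minimum temporal separation is imposed on the argmin pair, and `N_f`
is estimated per slice.

## The phantom

The generator renders the study conditions the pipeline targets, with
ground truth for every stage:

| parameter | default | meaning |
|---|---|---|
| `n_frames` | 84 | ~5 s at 59.5 ms/frame |
| `frame_shape` | (128, 160) | acquisition matrix |
| `cardiac_period_frames` | 14 | ~0.83 s cardiac cycle |
| `resp_period_frames` | 60 | ~3.6 s breathing period |
| `resp_amplitude_px` | 6 | superior–inferior excursion |
| `pool_radius_ed_px` / `es` | 11 / 6.5 | maximal filling / contraction |
| `pool/myo/bg intensity` | 0.9 / 0.35 / 0.15 | bright-blood contrast |
| `noise_sd` | 0.02 | additive Gaussian noise |
| `n_papillary` | 2 | dark blobs inside the pool |

A bright elliptical pool (mild fixed elongation and orientation) sits in a
darker myocardial annulus over a smooth-textured thorax background; the
pool radius interpolates between the ED and ES radii with a raised cosine
(only the area *ordering* matters downstream, so the waveform shape is
free); the whole heart translates vertically with an asymmetric
respiratory waveform that spends 30% of each period in a near-flat
end-expiratory dwell, rounded by a shallow parabola so the best
end-expiratory window is unique. Physiologically the expiratory pause is
the longer, flatter phase, which is what gives the windowed-sum rule a
well-defined optimum; the dwell shape itself is a modeling choice, not a
measured waveform. Two papillary blobs are placed symmetrically about the
center so they bias segmentation (concavities for the hull to remove)
without biasing the true centroid. Rendering is deterministic per seed
(bit-identical stacks); edges are ~1 px anti-aliased so sub-pixel centroid
accuracy is measurable.

**What passing phantom tests does not show:** the phantom has no coil
shading, banding, flow artifacts, through-plane motion, arrhythmia, or
apical/basal geometry (tiny or absent LV chamber) — the regimes where the
method degrades on clinical data. Phantom results validate the pipeline's
logic and numerics, not clinical accuracy.

## Problem sizes

The test and acceptance suites run the full pipeline on 20 seeded phantoms
(84 frames each) at noise σ = 0.05, the brute-force window oracle on 1000
random series, the NCC oracle on 100 random pairs, and the ellipse
Monte-Carlo on 100 seeds; CNN training demonstrations use a handful of
64×64 pairs for a few epochs.

## Known limitations

- Single-slice: no consistency enforcement across a multi-slice stack.
- The NCC argmin can sit one frame off the visual ED/ES when consecutive
  frames are nearly identical; accuracy is therefore stated within ±1 frame.
- The CNN localizer is a faithful toy: numpy forward/backward at 64×64,
  not a GPU-scale trainable model, and it is not the pipeline default.
- `H(t)` uses only the vertical center coordinate; purely lateral
  respiratory drift is invisible to the windowing stage.
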