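# fbcine

Automatic detection of the **end-diastole (ED)** and **end-systole (ES)**
frames at **end-expiration** in free-breathing short-axis cardiac cine MRI.

## The problem

Real-time free-breathing cine acquisitions capture several cardiac cycles
while the heart translates with the diaphragm. Left-ventricular function
analysis needs the ED/ES pair from a cycle at end-expiration, and picking
those two frames out of ~84 by eye takes minutes per slice. `fbcine`
automates the selection for a single 2D+t slice:

1. **Localize** the LV in every frame — by default a deterministic
   brightest-compact-blob localizer; optionally a small mask-regression
   convolutional network (one 9×9×50 convolution, 8×8/8 max-pooling, a
   fully connected layer to a 64×64 sigmoid mask), trainable at toy scale
   on the bundled phantom.
2. **Refine the LV center** per frame: three-class Otsu threshold, seeded
   4-connected region growing of the blood pool, convex hull (to suppress
   papillary muscles), and a direct least-squares ellipse fit giving a
   sub-pixel center and the pool area.
3. **Extract respiratory motion**: the relative position
   `H(t) = rows − center_row(t)` (distance from the LV center to the
   inferior image edge) is decomposed into a respiratory component (a
   zero-phase Hanning-weighted moving average with one twicing pass) and a
   cardiac residual; the cardiac-cycle length `N_f` comes from the
   autocorrelation of the ellipse-area series.
4. **Find end-expiration**: among all `N − N_f + 1` windows of length
   `N_f`, the one maximizing `Σ H(t)` — the heart dwells highest after
   exhalation — gives the interval `[A, B]`.
5. **Identify ED and ES**: all pairs of 40×40 LV-centered patches within
   `[A, B]` are compared by normalized cross-correlation
   `NCC = Σ(F₁−F̄₁)(F₂−F̄₂) / √(Σ(F₁−F̄₁)² Σ(F₂−F̄₂)²)`;
   the **minimum** of the pair matrix is the most dissimilar — the
   (ED, ES) pair — and the member with the larger fitted ellipse area is ED.

A synthetic phantom module renders free-breathing cine stacks with known
ground truth (center trace, ED/ES indices, end-expiration window) so every
stage is testable without clinical data. All public frame indices are
1-based.

## Worked example

```python
from fbcine import phantom, detect_slice

slc, truth = phantom.generate_cine(phantom.PhantomConfig(seed=1))
rep = detect_slice(slc)                      # fallback localizer
r = rep.result
print(f"n_f        = {rep.n_f}")
print(f"window     = frames {r.window.first}..{r.window.last}")
print(f"ED frame   = {r.ed}  (area {r.ed_area:.1f} px^2)")
print(f"ES frame   = {r.es}  (area {r.es_area:.1f} px^2)")
print(f"NCC minimum= {r.ncc_min:.3f}")
```

prints

```
n_f        = 14
window     = frames 24..37
ED frame   = 29  (area 375.1 px^2)
ES frame   = 36  (area 129.5 px^2)
NCC minimum= 0.746
```

The phantom's true ED frames are 1, 15, **29**, 43, … and true ES frames
8, 22, **36**, 50, …: the detected pair lands exactly on the ED/ES pair of
the cycle dwelling at end-expiration. The areas confirm the ordering
(maximal filling ≈ 375 px² vs maximal contraction ≈ 130 px²), and the NCC
minimum of 0.75 marks those two frames as the least similar patch pair in
the window.

The same pipeline runs from the shell:

```bash
fbcine simulate --out sim/ --seed 1
fbcine detect --input sim/cine.npz --out report.json
fbcine trace  --input sim/cine.npz --out trace.csv
fbcine train  --out checkpoints/ --seed 0        # optional toy CNN training
```

`detect` writes a schema-versioned JSON report (ED/ES indices, window,
`N_f`, NCC minimum, per-frame fits) plus a CSV of `H(t)` and its
components, and exits nonzero when detection fails.

## Documentation

`docs/methods.md` describes the model assumptions, the phantom's study
conditions, filter design, numerical choices and known limitations.
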