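# Methods note

This note records the computational model behind `bpfqa`: what the
simulator does and does not emulate, how the detection and picket-fence
analyses work, and the numerical choices that matter for accuracy.

## Geometry and conventions

All positions are millimetres at the isocenter plane on the Varian IEC X
scale (X1 jaw on the negative side). The machine model is a
Millennium-120-style MLC — 60 opposing leaf pairs; pairs 1–10 and 51–60
project to 10 mm width, pairs 11–50 to 5 mm, spanning Y ∈ [−200, 200] mm;
pairs 1–30 are the "lower" leaves (Y < 0), 31–60 the "upper" leaves —
and an aS1200-like EPID: 1280 × 1280 pixels at 0.336 mm pitch. With
SID = 100 cm the imager plane coincides with isocenter scale, so no
magnification handling is needed. Detector column `c` maps to
`x = (c − (N−1)/2) · pitch`, row `r` to `y = ((N−1)/2 − r) · pitch`.

## The BPF pattern

Eight static segments. The upper-leaf slit stops at +70, +50, …, −70 mm;
the lower-leaf slit at −70, −50, …, +70 mm (2-mm aperture). Jaws follow

```
x1 = min(c_low + w/2, c_up − w/2) − r
x2 = max(c_up + w/2, c_low − w/2) + r
```

with w = 2 mm, r = 5 mm. This yields the planned positions
X1 = −74, −54, −34, −14, −16, −36, −56, −76 and
X2 = 76, 56, 36, 16, 14, 34, 54, 74 mm. A useful identity:
`x1(−c_up, −c_low) = −x2(c_up, c_low)` (segment 1 mirrors segment 8).
Note the jaw-to-nearest-slit-edge gap is `r − w = 3 mm` in half of the
segments, not `r`; this gap budget drives several detection choices below.
Total 120 MU at 600 MU/min, 6 MV; gantry either static (0°/90°/270°) or
stepped over a full rotation.

## Imaging model (simulator)

Per segment, relative fluence on the pixel grid is the product of

* an MLC factor per leaf row: 1 inside the open slit, `t_mlc = 0.015`
  elsewhere, with exact fractional-pixel coverage at slit edges;
* a jaw factor: 1 inside the X×Y jaw field, `t_jaw = 0.005` outside
  (jaws always sit behind closed leaves in this pattern, so the factors
  multiply — outside a jaw the signal is `t_mlc · t_jaw = 7.5 × 10⁻⁵`).

The map is blurred once with a Gaussian of σ = 0.7 mm (source size +
detector glare), then each of the 5 frames per segment adds i.i.d.
Gaussian noise with σ = 0.01 of the open-field signal, clipped at zero,
stored as float32. A single seeded generator is threaded through the
whole delivery, so every result is reproducible from one seed.

**Not modelled:** scatter, beam profile (flatness/horns),
tongue-and-groove, rounded leaf ends, Poisson statistics, and frames
acquired during leaf/jaw motion (real cine streams contain transition
frames; the analysis discards frames whose slit positions match no
segment within 1 mm).

## Jaw-edge detection

The jaw shadow's contrast against the MLC-transmission background is
`t_mlc (1 − t_jaw) ≈ 0.0149` — only ≈1.5× the per-pixel noise σ. Three
measures keep the classic field-edge recipe (histogram equalisation →
Otsu → morphological closing → Canny → column-sum profile → sub-pixel
peaks) well conditioned at that contrast:

1. **Denoise** each frame with a 1.5-px Gaussian before the pipeline, so
   the two intensity classes Otsu must separate no longer overlap.
2. **Mask the aperture** (columns brighter than 0.3× the max, dilated by
   1.3 mm) by per-row linear interpolation, and run equalise + Otsu on a
   ±10 mm band around each *expected* jaw edge. Inside the band the two
   classes are roughly balanced; a whole-frame histogram would inherit a
   large threshold bias from the very unequal jaw/field areas (in
   segments 4–5 the jaw covers >90 % of the frame).
3. **Refine** the pixel-quantised peak from the binary pipeline to
   sub-pixel precision via the 50 %-level crossing of the row-averaged
   intensity ramp (the standard half-maximum field-edge convention,
   unbiased under symmetric penumbra blur). The low level is the median
   3–8 mm outside the coarse edge; the high level is the median of clean
   transmission columns ≥4 mm from jaws and slit centers.

The refinement profile is averaged over **the half-field whose slit is
farther from the jaw under test** (using the raw, un-interpolated image
there). The bidirectional pattern guarantees one such half exists for
each jaw. This matters when an inward jaw error narrows the jaw-to-slit
gap below the 3-mm design value: the near slit's penumbra tail
(≈0.004 at 2 mm, comparable to the 0.011 ramp height) would otherwise
bias the crossing by several tenths of a millimetre. With this choice,
injected offsets of ±0.5 and ±1.0 mm are recovered noise-free to
better than 0.01 mm.

Otsu's threshold is computed in-package with exact integer arithmetic
over 256 histogram bins (bin indices as values — an affine rescaling that
leaves the argmax unchanged). Between well-separated classes the
between-class variance is flat over the empty gap bins; float summation
noise would make the argmax fall anywhere on that plateau, whereas the
integer formulation deterministically picks the first maximising split
and agrees exactly with any faithful exhaustive scan.

Peak-to-role assignment is expectation-guided: each expected jaw edge
must have a peak within a 3-mm capture window, preferring full-height
peaks (a jaw edge crosses the whole field; an MLC slit spans only one
half). Per segment, frame-level positions are averaged (mean ± SD over
the 5 frames) and compared against the plan.

## Picket-fence analysis

All frames are summed pixel-wise. For each of the 40 thin central leaves
(all inside the ±100 mm Y field), a band-mean profile over the central
60 % of the leaf's rows limits penumbra cross-talk from neighbours. For
each expected picket (±10, ±30, ±50, ±70 mm — nominal pattern values, so
injected leaf errors are *reported* as errors), the local background
(median of flank columns 3.5–5.5 mm from the center) is subtracted and
the center is the intensity-weighted centroid within ±(w/2 + 2 mm).
A leaf passes when all its picket errors are below the tolerance
(default 0.5 mm); summary metrics are the passing percentage, the
absolute median error and the maximum error.

## Accuracy and known biases

* Noise-free, the full chain recovers jaw edges to <0.01 mm and picket
  centers to <0.02 mm.
* Under the default noise model, detected jaw positions are biased
  ≈0.1 mm **inward**. Cause: additive noise is clipped at zero, and on
  the dark side of the jaw edge (mean 7.5 × 10⁻⁵, σ = 0.01) clipping
  raises the plateau mean to ≈0.004, distorting the ramp's mid-level.
  This is a property of the simulated signal chain (real EPIDs also have
  a noise floor), is stable across seeds, and is an order of magnitude
  inside the 1.0-mm action level; it is deliberately not calibrated away.
* Inward jaw errors ≥ ≈1.5 mm push the jaw within ≈1.5 mm of the nearest
  slit; the error is still flagged, but its measured magnitude degrades
  as the edge ramp and slit penumbra merge.
* Frame-to-frame SD of detected positions is 0.01–0.05 mm, smaller than
  the 0.1–0.3 mm reported on real machines — the simulator has no
  mechanical jitter, gravity sag or output variation.

## Numerical choices

* Fractional-pixel (anti-aliased) edge rendering, so sub-pixel geometry
  survives into the image; blur applied once per segment, noise per frame.
* DICOM RT Plan stores coordinates as decimal strings with 4 decimals
  (round trip exact to 0.01 mm); RT Image frames are uint16 with a
  canonical 10-significant-figure rescale slope, making a second
  write/read cycle bit-stable. The portable `.npz` + JSON route is
  bit-exact and preserves segment labels.
* CSV/JSON outputs contain no timestamps; re-running with the same seed
  reproduces byte-identical files.
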