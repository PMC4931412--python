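# Methods

This note documents the detection model, the numerical choices behind
each stage, what the synthetic scenes do and do not emulate, and the
known limitations.

## The detection model

A micro-object on a lens-free sensor produces a radially symmetric
diffraction pattern.  The detector assumes only its qualitative
structure — a central lobe darker than the local background, a dark
annulus, and a first-order bright ring — and measures four parameters
on the horizontal (h) and vertical (v) profiles through a candidate
center:

| parameter | meaning | measurement |
|---|---|---|
| CMV | central maxima value (gray) | intensity at the midpoint |
| WCX | width of central maxima (px) | contiguous run through the midpoint with \|value − CMV\| ≤ `cmv_tol` |
| WCN | width of central minima (px) | dark lobe (value < CMV) immediately outside the central run, averaged over the two sides |
| PPD | peak-to-peak distance (px) | distance between the first-order peaks found on each side |

Size follows the linear calibration `Y = 0.28 · X` (µm per px of PPD).
The coefficient encodes one specific rig geometry (source–sample–sensor
distances, 2.2 µm pixel pitch); it is exposed in `QuantifyConfig`
because any other geometry needs recalibration.

## Stage-by-stage choices

**Adaptive threshold** (`signal_mask`).  Non-overlapping 10 × 10
tiling, contrast floor strictly `> 30` gray levels, midpoint threshold
`(max + min)/2` kept fractional and compared exactly.  Polarity is
`dark` by default — diffraction signals (central lobe ≈ 20 and annulus
≈ 35 gray levels below background) sit below the local midpoint —
with `bright` and `minority` modes available for other modalities.
Right/bottom remainder windows are processed at reduced size so no
frame area is blind.  The tiling is offset-invariant and local by
construction: adding a constant to the frame, or editing one window,
cannot change any other window's bits.  A whole-frame Otsu threshold is
kept as the baseline that the adaptive method is designed to beat on
gradient-lit frames; it has no defence against a background ramp and is
used only for comparison.

**Clustering** (`pattern_cluster`).  Within each 25 × 25 window, single
linkage with strict Euclidean distance < 3 px (so diagonal √2 and 2-px
gaps link, 3-px gaps do not), implemented as connected components of
the pair graph.  Two repair passes follow: (1) pixels within the
linkage distance of a window border are re-linked across windows, which
restores exactly the components full-image single linkage would
produce; (2) clusters whose midpoints lie within `merge_dist = 5` px
are merged — such near-coincident fragments (split by a border or by a
hole in the mask) always belong to one physical pattern, whose central
footprint is ≥ 10 px wide.  The isolated-pixel rule (`min_size = 2`)
is applied after the repairs so a small cluster straddling a border is
not lost.  Midpoints are coordinate-wise means rounded half away from
zero — deterministic and symmetric.  A brute-force breadth-first
full-image clusterer (`cluster_mask_oracle`) serves as the independent
reference in tests.

**Feature measurement** (`ring_features`).  Three robustness choices
matter at realistic noise (σ ≈ 3 gray levels on 8-bit frames):

* The frame is blurred once with a Gaussian of `denoise_sigma = 1` px
  before measurement (the threshold/cluster stages see the raw frame).
  The widths feeding the circularity filter are integers of order 4–10;
  a single noisy pixel at a run boundary would otherwise flip the
  verdict.  The blur is isotropic, so it cannot bias the h/v aspect
  ratios the filter compares.
* The working CMV is the median of the 3 × 3 neighbourhood around the
  midpoint rather than one pixel: the ±10 tolerance band around a
  single noisy pixel can drift onto the background level (backgrounds
  sit only ~20 levels above the central lobe).
* The first-order peak search smooths the profile with a 3-px moving
  average and takes, on each side beyond the central run, the first
  local maximum with ≥ `peak_prominence = 5` gray levels of topographic
  prominence (`scipy.signal.find_peaks`), scanning at most `scan_max =
  60` px from the midpoint.  Requiring prominence rejects noise
  wiggles; requiring the *first* such peak keeps the search local, so
  the ring of a neighbouring pattern (which can be < 30 px away for
  small objects) is never picked up.  PPD is reported when both sides
  of both axes yield a peak; the per-object value is the mean of the
  two axis estimates.

The WCN dark-run cut is the CMV itself (value < CMV), not
`CMV − cmv_tol`: the annulus floor lies ~15–19 levels below the CMV, so
this cut crosses the profile on its steep flank and the measured lobe
width is stable; a cut near the annulus floor would sit in the shallow
part of the profile where ±3 levels of noise move the boundary by
several pixels.

**Circularity** (`max_aspect = 1.5`).  Exact equality of integer widths
is impossible under noise; 1.5 admits the 8-vs-11 px spread seen across
real sample types while rejecting 2:1 elongated streaks.  A width pair
with exactly one zero fails (a one-sided annulus is not a ring); both
zero passes (no annulus detected on either axis — the PPD requirement
then decides).

**Pipeline order and rejection reasons.**  Candidates within `scan_max`
of the frame border are rejected `edge_truncated` (their rings leave
the frame) before measurement; then `not_circular`; then
`ppd_not_found` when either axis lacks a peak pair.  Every cluster
midpoint appears in the output with its fate — nothing is silently
dropped.  The pipeline is fully deterministic for a fixed frame and
configuration.

**Quantification.**  Sizes come from each accepted record's mean PPD;
the histogram uses fixed 2-µm bins anchored at 0.  Concentration uses
the geometric chamber model, accepted count / (frame area × chamber
depth), with the 0.1 mm disposable-chamber depth as default; 1 mm³ =
1 µL.

## The synthetic scenes

`synth_scene.render_scene` draws each object as a phenomenological
radial profile added to a background plane:

* central lobe: a flat-topped super-Gaussian of half-width 4 px,
  `center_drop = 20` levels below background;
* dark annulus: a quartic-exponential ring window of width 4 px,
  `annulus_depth = 35` levels below background;
* first-order ring: a Gaussian of σ = 2 px and `ring_gain = 15` levels
  above background, centred at radius `R = (size_um/0.28)/2` px.

Backgrounds default to gray level 165 with an optional linear gradient;
noise is additive Gaussian, seeded; everything is rounded and clipped
to [0, 255].  The default levels sit inside the ranges measured on real
bead and cell frames (central values ≈ 130–175 against backgrounds
≈ 160–180), and the lobe widths are nearly size-independent, as they
are on real patterns — only the ring radius grows with object size.
For objects below ~7 µm the lobe widths are capped to fractions of R so
the annulus stays inside the ring.

Ground truth ties size to ring radius by inverting the sizing
calibration, so a perfect detector reports PPD = 2R and recovers sizes
exactly; detector error shows up directly as size error.  Scene
generators enforce pairwise separation > R_i + R_j + 10 px and keep
centers ≥ 64 px from the frame border (rings and the outward peak scan
must stay inside the frame).

What the simulator does **not** model: physical Fresnel diffraction
(no secondary rings, no sub-pixel speckle), shot/fixed-pattern sensor
noise, overlapping or touching patterns, out-of-focus depth effects,
and the calibration scatter of a real rig.  Passing the synthetic
benchmarks therefore demonstrates the correctness and noise robustness
of the algorithm, not field performance on real samples: the synthetic
count/size agreement (r ≈ 1.0, slope ≈ 1.0, mean size error ≈ 0.2 µm
under σ = 3 noise and a 10-level gradient) is substantially better than
what a cross-modality comparison against a microscope can show, because
both sides here share the same ground-truth geometry.

## Benchmark problem sizes

The bundled experiments use full sensor-sized frames (1920 × 2560 px):
a 6-frame series with 20–200 objects per frame for count agreement and
4 frames × 50 objects (sizes drawn from {5, 10, 20, 30} µm) for sizing
error; the window-size sweep and gradient-robustness checks run on a
40-object 800 × 1000 px fixture.  A whole frame processes in well under
a second per stage on one CPU; the scripts and test suite complete in
tens of seconds.

## Known limitations

* PPD carries a small outward bias (≈ +1–2 px) for the smallest rings
  (R < 10 px), where the asymmetric shoulder between annulus and ring
  shifts the smoothed peak; at the 0.28 µm/px scale this is ≤ 0.6 µm.
* Under noise, windows that happen to span only a ring/background
  boundary can fire the contrast test and produce spurious candidates;
  the circularity and PPD filters reject nearly all of them, but a few
  per hundred objects can survive at σ = 3 (slope of detected vs true
  counts ≈ 1.03 rather than 1.00).
* Patterns closer than their summed ring radii are not modelled and not
  handled; real crowded fields with overlapping rings would need a
  deconvolution or model-fitting approach outside this package's scope.
* The circularity filter compares only axis-aligned widths; a pattern
  elongated at 45° passes it and must be caught by the PPD filter.
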