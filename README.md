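# lensfree-detect

Automated detection, counting and sizing of micro-objects (beads, red
blood cells, cultured cell lines) in **lens-free shadow images**.

In a lens-free imaging rig the sample sits in a thin counting chamber
directly on a CMOS sensor and is illuminated by a semi-coherent source;
each micro-object casts a ring-shaped diffraction pattern instead of a
focused image: a central lobe somewhat darker than the background, a
dark annulus around it, and an outer first-order bright ring.  The
sensor's large field of view (a whole 1920 × 2560 px frame at 2.2 µm
pitch, ≈ 24 mm²) makes manual counting impractical and the non-uniform
background defeats a single global threshold — so this package provides
the full automated pipeline:

1. **Adaptive local threshold** — the frame is tiled into 10 × 10
   windows; a window with local contrast `max − min > 30` gray levels
   marks its pixels below the midpoint threshold `T = (max + min)/2` as
   probable signal.
2. **Patch-wise clustering** — signal pixels are grouped per 25 × 25
   window by single linkage (Euclidean distance < 3 px), isolated
   pixels are discarded, and each cluster's rounded coordinate mean
   becomes a candidate pattern center.
3. **Diffraction parameters** — at each candidate the horizontal and
   vertical intensity profiles yield the four standard parameters:
   CMV (central maxima value), WCX (width of the central maxima),
   WCN (width of the central minima), and PPD (peak-to-peak distance
   between the two first-order bright peaks).
4. **Circularity filter** — true patterns are circular, so candidates
   whose WCX or WCN vertical/horizontal aspect ratio strays from 1 are
   rejected as noise.
5. **Sizing and counting** — the physical size follows the linear
   calibration **Y = 0.28 · X**, with *Y* the object size in µm and *X*
   the PPD in pixels; counts, size histograms and (optionally)
   concentrations per µL complete the report.

A synthetic scene renderer (`lensfree_detect.synth_scene`) generates
frames with exact ground truth — object centers, sizes, and expected
PPD = 2R with `R = (size/0.28)/2` px — so every stage is testable and
benchmarkable without sensor hardware.

## Worked example

Render a synthetic frame with three objects and run the detector on it:

```bash
cat > scene.yaml <<EOF
height: 600
width: 800
noise_sigma: 2.0
seed: 7
objects:
  - {center: [200, 250], size_um: 10.0}
  - {center: [350, 550], size_um: 20.0}
  - {center: [470, 210], size_um: 30.0}
EOF

lfdetect simulate --spec scene.yaml --out sim
lfdetect detect sim/scene_000.png --out det --overlay
```

The `detect` step prints `3 accepted / 3 candidates` and writes
`det/scene_000_detections.csv`:

```
id,row,col,cmv,wcx_h,wcx_v,wcn_h,wcn_v,ppd_px,size_um,accepted,rejection_reason
0,200,250,145,11,11,4,4,36.0,10.080000000000002,true,none
1,350,550,145,11,12,4,4,72.0,20.160000000000004,true,none
2,470,210,146,11,11,4,4,107.0,29.960000000000004,true,none
```

Each row is one candidate: its center `(row, col)`, the four
diffraction parameters per axis, and the size from `0.28 × PPD` — the
10 µm object was measured with PPD 36 px, hence 10.08 µm.  A JSON
summary (totals, size histogram, concentration, resolved config) and an
annotated overlay PNG land next to the CSV.  Scoring against the
simulator's ground truth:

```bash
lfdetect evaluate --truth sim/scene_000.json --detections det/scene_000_detections.csv
```

```json
{
  "true_positives": 3,
  "false_positives": 0,
  "false_negatives": 0,
  "precision": 1.0,
  "recall": 1.0,
  "mean_abs_size_error_um": 0.09333333333333371
}
```

All three objects were found at their true centers with a mean size
error below 0.1 µm.  `lfdetect sweep` re-runs the pipeline across
threshold/cluster window sizes and tabulates count error and wall time
per setting.

The same operations are available as a library:

```python
from lensfree_detect import run_pipeline, read_image

records, result = run_pipeline(read_image("frame.png"))
print(result.accepted_count, result.sizes_um)
```

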