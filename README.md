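# panicount

UAV-based rice (*Oryza sativa*) panicle counting and heading-date trait
extraction. Heading date — when a plot transitions from vegetative to
reproductive growth — is a key yield-determining trait, and scoring it
manually across hundreds of field plots is slow and error-prone. `panicount`
implements the image-analysis pipeline that turns a time series of aerial
frames, each centered on one field plot, into six heading-date-related
traits per plot:

1. **Plot locating.** Each pixel is mapped to the Color Index of Vegetation
   Extraction, CIVE = 0.441 R − 0.811 G + 0.385 B + 18.78754, which green
   vegetation minimises. The index is Otsu-binarised, white (vegetation)
   pixels are counted per row and column, the profiles are smoothed by a
   moving average (window 100), and a fixed-size window (3800 × 2000 px by
   default) is placed where its two boundary rows and columns hold the
   fewest white pixels — the bare-soil lanes between plots:
   row₀ = argminᵢ (Rowᵢ + Rowᵢ₊ₕ₋₁), and likewise for columns.
2. **Tiled detection.** The plot crop is split into 1000 × 1000 px tiles at
   25% overlap (the last tile on each axis clamped to the edge), a detector
   backend runs per tile, detections are lifted to plot coordinates,
   confidence-filtered at 0.3, and merged with class-agnostic greedy
   non-maximum suppression at IoU 0.25. The panicle count of the plot is
   the size of the merged set. Any detector fulfilling the
   `detect(tile) -> DetectionSet` contract can be plugged in (e.g. a trained
   YOLO-family network via COCO-JSON/YOLO-txt files); a deterministic
   colour-threshold blob detector is built in as the oracle for synthetic
   imagery.
3. **Trait extraction.** Per-plot counts over flight dates form a growth
   curve. With M the curve maximum, the heading date at fraction
   y ∈ {10%, 30%, 50%, 80%} is argmin over observed dates x of
   |count(x) − y·M| (earliest date on ties), and the heading-stage duration
   is hd80 − hd10 in days.

Detection and counting quality are scored with RMSE, R², AP@k under
101-point precision–recall interpolation, and mAP@50:5:95. Seeded synthetic
fixtures (field scenes with known plot windows and panicle boxes; logistic
count series with analytic crossing times) give every stage a ground-truth
oracle.

## Worked example

```python
from panicount import (PipelineConfig, generate_field_scene, generate_series,
                       process_frame, extract_traits)

# one synthetic frame: locate the plot, tile, detect, merge, count
scene = generate_field_scene(seed=1)
config = PipelineConfig(plot_height=600, plot_width=1000, tile_size=500)
window, detections, count = process_frame(scene.image, config)

print("located window :", (window.row0, window.col0),
      "true:", (scene.true_plot.row0, scene.true_plot.col0))
print("window IoU     :", round(window.iou(scene.true_plot), 4))
print("panicle count  :", count, "(true:", len(scene.true_panicles), ")")

# one synthetic campaign series: extract the six traits
sim = generate_series(seed=7)
traits = extract_traits(sim.curve)
print("max_count      :", traits.max_count)
print("hd10/30/50/80  :", traits.hd10, traits.hd30, traits.hd50, traits.hd80)
print("heading stage  :", traits.heading_stage, "days  (analytic ln36/r =",
      round(sim.true_traits.heading_stage, 2), ")")
```

Output:

```
located window : (194, 253) true: (195, 254)
window IoU     : 0.9947
panicle count  : 25 (true: 25 )
max_count      : 254
hd10/30/50/80  : 17 19 20 23
heading stage  : 6.0 days  (analytic ln36/r = 5.97 )
```

The locator recovers the true 600 × 1000 px plot window to within one pixel
(IoU 0.995); the tiled reference detector recovers the exact panicle count;
and the heading dates extracted from a noisy logistic series (plateau 254
panicles) sit within a day of the analytic crossings — the 10%→80% heading
stage of 6 days matches the analytic ln(36)/r = 5.97.

The same stages are available from the shell:

```sh
panicount simulate scene --seed 1 --out scratch/scenes
panicount locate --image scratch/scenes/scene_1.png \
    --plot-height 600 --plot-width 1000 --out-crop scratch/crop.png
panicount detect --plot-image scratch/crop.png --tile 500
panicount simulate series --seed 7 --n 10 --out scratch/series
panicount traits --counts scratch/series/counts.csv --out scratch/traits.csv
```

`panicount run --frames DIR --out OUT` orchestrates the whole campaign
(frames laid out as `<plot_id>/<date>.png`).

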