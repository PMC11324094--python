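# cucumorph

Cucumber fruit morphometry from calibrated RGB photographs.

Cucumber (*Cucumis sativus* L.) breeding programs phenotype thousands of
fruits for shape, surface and flesh traits that are slow and inconsistent to
measure by hand. `cucumorph` turns two standardized photographs per fruit —
a frontal view and a cross-section slice, each on a dark background next to
a reference color card of known size — into a 51-parameter trait table.

The pipeline:

1. **Calibrated foreground extraction.** The excess-green transform
   (2G − R − B) isolates the green objects; Otsu thresholding with
   morphological cleanup yields a binary mask. Of the two largest objects,
   the one that best fills its minimum-area enclosing rectangle is the
   reference card (giving px/cm from its long side); the other is the fruit.
2. **Medial centerline.** Zhang–Suen thinning, selection of the geodesically
   longest endpoint-to-endpoint trunk (pruning branch burrs), subsampling at
   step 5 with Savitzky–Golay smoothing (window 3, order 1), and linear
   extrapolation of both ends (5-point fits, 3 points per round) until the
   centerline meets the contour. Its calibrated arc length is the fruit
   length *Fl*; arc/chord is the curvature *Cv*.
3. **Five-segment partition.** Perpendicular chords at every centerline
   point give the transverse-diameter profile. On each fruit half, an Otsu
   split of the centerline-to-contour clearance locates the neck (and tip)
   boundary, and the maximum diameter gradient locates the stalk (and stem)
   boundary: stalk | neck | body | tip | stem.
4. **Traits.** Contour geometry (area *S*, perimeter *Lc*, fitted-ellipse
   axes, enclosing rectangle/circle, convex hull, maximum inscribed circle,
   circularity 4πS/Lc²), diameter statistics (*Fd*, fluctuation, neck/tip
   ratios), neck/tip descriptors (angle, index, proportion), volume
   V = π(Fd/2)²·Fl.
5. **Shape classification.** A three-stage decision tree: circle-filling
   rate > 0.75 → ball; else length < 10 cm → oval/finger at filling rate
   0.4; else a pluggable six-class model (rod, cylinder, ellipse,
   inverted-egg, spindle, heterotype) with rods/cylinders split long/short
   at 20 cm. The bundled baseline is a z-scored nearest-centroid classifier
   over nine dimensionless descriptors, serializable to JSON.
6. **Surface and flesh.** Tumor density (LoG blob detection in the
   skeleton-midpoint ROI), stripe proportion and 5-type stripe taxonomy,
   cross-section smoothness (convexity, circularity, centroid-distance
   variance *Cdv*), mesocarp/endocarp split with circular-equivalent
   thickness Tm = √((Ss+Se)/π) − √(Se/π), and carpel counting (2–5) from the
   angular spectrum of the endocarp boundary.

A seeded synthetic-scene generator (`cucumorph.synthetic`) renders frontal
and cross-section scenes with exact ground truth (masks, centerline, segment
boundaries, tumor centers, stripe masks, areas), so every stage is testable
without photographic data.

## Worked example

```python
from cucumorph.config import PipelineConfig
from cucumorph.pipeline import analyze_frontal
from cucumorph.synthetic import FrontalSpec, generate_frontal

spec = FrontalSpec(length_cm=20.0, body_diameter_cm=4.0, curvature_arc=1.02, seed=1)
image, truth = generate_frontal(spec)      # or: image = load_image("fruit.jpg")

cfg = PipelineConfig()
cfg.preprocess.card_length_cm = 3.0        # physical long side of the card
result = analyze_frontal(image, cfg)
t = result.traits
print(f"px/cm {result.scale.px_per_cm:.1f}  Fl {t.Fl:.2f} cm  "
      f"Fd {t.Fd:.2f} cm  Cv {t.Cv:.3f}  V {t.V:.1f} cm^3")
```

prints

```
px/cm 30.0  Fl 20.05 cm  Fd 4.00 cm  Cv 1.026  V 252.1 cm^3
```

i.e. the scale recovered from the 3-cm card, a 20.05 cm fruit of 4.00 cm
body diameter, a nearly straight centerline (arc/chord 1.026), and the
cylindrical-equivalent volume. `result.row` holds the full 51-column trait
record; `result.segmentation.lengths_cm` the five segment lengths.

From the shell:

```bash
cucumorph fruit photos/*.jpg --card-cm 3 --out results/          # frontal mode
cucumorph flesh slices/*.jpg --card-cm 3 --out results/          # cross-section mode
cucumorph synth fixtures/ --n-per-class 5 --seed 0               # synthetic corpus
```

Fruit mode writes `traits.csv` (or `--format xlsx`) plus segmentation and
stripe overlay PNGs; unreadable images become error rows without aborting
the batch.

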