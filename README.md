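# gastrumorph

Quantification of gastrulation morphogenesis from nuclear tracking data,
label masks and annotated photographs — for developmental biologists
analyzing convergent extension, involution and blastopore closure in
amphibian embryos (and anyone who needs the same motility/morphometry
toolbox on comparable data).

The package implements, as a tested and reusable pipeline:

* **Track motility** — instantaneous velocity `v = |Δr|/Δt`, directional
  persistence `P = d_net / L_path` (1 for straight motion), and the
  standard track filters (tracked ≥ 45 min, moved ≥ 20 μm, ended < 80 μm
  from the dorsal blastopore lip), plus the 0.05-interval persistence
  histogram.
* **Spatial organization** — Delaunay neighbor graphs of nucleus centers,
  per-nucleus mean neighbor distance, distance to an annotated lip curve,
  and overlapping-window stratification (30 μm windows, 25 μm step, 5 μm
  overlap).
* **Cell-shape polarity** — moment-matched-ellipse morphometrics from
  label masks: area, polarity index (major/minor axis), orientation
  relative to the mediolateral axis, and 11.25°-binned rose summaries
  over [0°, 90°].
* **Macro-morphometrics** — blastopore closure ratio (blastopore area /
  vegetal-hemisphere area, 0 = closed), expression-domain elongation
  ratios, and explant percent elongation relative to an uninjected
  reference group.
* **Intensity profiles** — normalized transverse fluorescence profiles
  `I_x / I_m` across a 25 × 100 μm rectangle placed 300 μm from the lip.
* **Statistics** — two-tailed Mann–Whitney U (exact or tie-corrected
  normal), Kruskal–Wallis with Dunn's post-hoc, chi-square on binned
  tables.
* **Synthetic data** — seeded generators (persistent random walks, graded
  hexagonal nucleus clouds, elongated-cell mosaics, vegetal-view
  annotations, fibril-band images) with known ground truth, so the whole
  pipeline is testable without any raw microscopy.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Simulate the default two-condition tracking dataset (a control-like group:
1.2 μm/min, 25° turning noise, strong lip drift; and a morphant-like
group: 0.8 μm/min, 30° turning noise, weak drift), then run the motility
analysis:

```sh
gastrumorph simulate tracks --n-cells 10 --seed 3 --out tracks.csv
# wrote 726 rows for 20 cells -> tracks.csv
gastrumorph tracks --table tracks.csv --lip tracks.lip.json --out summaries.csv
# 20/20 cells pass the filters; mean persistence 0.875
gastrumorph stats --input summaries.csv --group-col group \
    --value-col persistence --test mwu
# mann-whitney-u (asymptotic) control/morphant: statistic = 26.0000, p = 0.07566
```

`summaries.csv` holds one row per cell (duration, net displacement, path
length, persistence, mean speed, final lip distance, per-criterion filter
flags); the printed mean persistence 0.875 pools both groups, and at
n = 10 per group this seed's group difference is suggestive but not yet
significant (p ≈ 0.076) — at 40 cells per group the same conditions
separate at p < 1e-7 (`gastrumorph report tracks --n-cells 40 ...`).

The same works for shapes:

```sh
gastrumorph simulate mosaic --n-cells 60 --seed 1 --out mosaic.tif
gastrumorph shapes --mask mosaic.tif --pixel-size 1.0 --out shapes.csv --rose rose.csv
# 60 cells; mean polarity 1.898
```

The mosaic was generated with target aspect ratio 1.9; the measured mean
polarity index 1.898 recovers it. Or in Python:

```python
import gastrumorph as gm

bp, veg = gm.gen_embryo_vegetal_view(r_blastopore=250, r_vegetal=500)
print(gm.closure_ratio(bp, veg).ratio)   # 0.25 — area scales with r^2
```

Full figure-style runs (`gastrumorph report tracks|shapes --outdir ...`) write
per-cell CSVs, histogram/rose/window tables, test results and a manifest.

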