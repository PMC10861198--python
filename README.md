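# histoquant

Quantitative image analysis for multi-channel fluorescence tissue sections:

* **synthetic tissue generator** — two-population nuclear scenes (textured,
  irregular ellipses with controllable morphology/chromatin statistics),
  oriented fiber-texture images and Gaussian point patterns, all with exact
  ground truth and seeded determinism (`histoquant.synthetic`);
* **nuclear segmentation** — intersection of global and sliding-window local
  Otsu thresholds, 8-connected components, hole filling, area/intensity
  artifact filters (`histoquant.segmentation`);
* **nuclear morphometrics** — a 24-feature catalog in four groups
  (morphology, boundary, intensity, chromatin texture incl. masked GLCM at
  64 gray levels and top-hat chromatin foci) (`histoquant.morphometrics`);
* **cell-state scoring** — two-class LDA (closed form, pooled covariance
  shrunk toward its diagonal), balanced seeded 75/25 split, min-max
  normalized 0–1 state score, coefficient ranking (`histoquant.scoring`);
* **spatial statistics** — exact internuclear pairwise distance (IPD)
  matrices in µm, upper-triangle dispersion SD, HDBSCAN spatial clustering
  of scored nuclei and per-cluster axial angular differences
  (`histoquant.spatial`);
* **fiber alignment** — structure-tensor orientation/coherency/energy
  fields, axial orientation histograms with circular mean/width, HSB
  orientation maps (`histoquant.fibers`);
* **quantification** — ROI intensity fold changes vs a reference condition,
  2^(−ΔΔCt) relative expression, and Mann–Whitney / Tukey HSD / paired t /
  ANOVA wrappers with the figure star convention (`histoquant.quantify`).

Coordinate convention used throughout: centroids in Cartesian micrometres
with the origin at the image's lower-left corner (x right, y up; image row 0
is the top); orientations are axial degrees in (−90, 90], counterclockwise
from +x.

## Command line

```sh
histoquant simulate nuclei --n-per-pop 50 --dispersion 45 --seed 1 --out-prefix scene
histoquant segment scene_image.tif --pixel-size 0.5 --out-prefix seg
histoquant features scene_image.tif scene_labels.tif --pixel-size 0.5 --out features.csv
histoquant score-states features.csv --seed 1 --out-prefix lda
histoquant ipd seg_records.csv --out ipd.csv
histoquant clusters scored.csv --min-cluster-size 5 --out clusters.csv
histoquant fibers ecm.tif --pixel-size 1.0 --sigma 2 --reference-angle 30 --out-prefix fib
histoquant quantify ddct ct_table.csv --out folds.csv

histoquant init-config --kind rejuvenation --out cfg.yaml
histoquant run-rejuvenation cfg.yaml --out results/rejuv
histoquant run-wound wound.yaml --out results/wound
```

Every stochastic command requires an explicit `--seed`. Pipeline runs
serialize their full configuration into the output directory, stamp a
config hash into every CSV/JSON output, and write a machine-readable
`summary.json`.

## Known limitations

* Touching nuclei are not split (no watershed step); they merge into one
  component and are usually removed by the max-area filter.
* The nuclear feature catalog is a stated stand-in covering the four named
  feature groups, not a bit-for-bit reproduction of any external feature
  library.
* 2-D only.
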