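# edgewater

Quantification pipelines for the imaging and biochemical readouts used to
study how ion- and water-influx shape the leading edge of migrating T cells —
together with a synthetic ground-truth data generator that makes every
estimator testable by parameter recovery.

## Who this is for

Groups quantifying chemokine-driven T-cell migration from fluorescence
microscopy: cell tracking and shape metrics from under-agarose assays,
sub-cellular polarity profiling of signalling proteins, super-resolution
measurement of the plasma-membrane-to-cortical-F-actin spacing, kymograph
readout of retrograde actin flow, cell volumetry, ICP-MS / heavy-water NMR
normalization, hypotonic media design, and the accompanying statistics.

## The measurements

- **Tracking and shape** (`track_shape`): triangle auto-threshold
  segmentation, particle size gate of 38–60 µm² (inclusive), greedy
  mutual-nearest-neighbour linking, exclusion of propidium-iodide-positive
  cells and of tracks shorter than ½ (agarose) or ⅓ (collagen) of the video,
  mean speed = path length / duration, circularity = 4πA/P².
- **Polarity profiles** (`polarity_profiles`): direction-aligned mean
  projections; 12-bin intensity profiles along the cell length, 0–1
  normalized, oriented leading-edge-first with CDC42/CD44 as LE/TE anchors;
  perimeter polarization = fluorescence in the 25% of the perimeter centred
  on the maximum over the total; MPAct/CaaX ratio (membrane-proximal actin)
  with the front-3-bins / back-3-bins polarity scalar.
- **Membrane–F-actin spacing** (`edge_spacing`): a 30-px band along the
  leading edge is straightened, 20-px overlapping perpendicular lines are
  aligned on the membrane peak, and the distance to the highest F-actin
  signal within 400 nm towards the interior is read with sub-pixel parabolic
  refinement (the side spacing, ~43 nm, is below one pixel).
- **Retrograde flow** (`retro_flow`): kymographs along a sampling line;
  stripe slope by a Radon-style orientation scan with a long-lag correlation
  refinement; flow = tan θ · pixel / Δt.
- **Volumes and chemistry** (`quant_chem`): z-slice area summation and modal
  (Coulter-style) volumes; the medium tonicity calculator
  (`iso·(1−f)`, reproducing 292 → 277.4 / 262.8 / 248.2 / 233.6 mOsm/l for
  f = 0.05…0.20, with non-ionic osmolytes at 1 mOsm/l per mM); the ICP-MS
  chain (internal standard → blank correction → six-point calibration →
  per-cell and vs-control normalization); heavy-water NMR dioxane ratio.
- **Statistics** (`stats_infer`): two-sided Mann–Whitney U (exact for small
  tie-free samples), Kruskal–Wallis, Pearson correlation, and the two-stage
  step-up FDR (adaptive Benjamini–Krieger–Yekutieli) producing q-values.
- **Synthetic data** (`synthetic_cells`): polarized cells built from two
  half-ellipses with a cortical actin band offset inward by a configurable
  spacing (174 nm at the front, 43 nm at the side by default), membrane
  reporters with configurable front enrichment/depletion, cortical speckle
  flow, dead cells, z-stacks, volume populations and raw ICP-MS plates — all
  with per-cell ground truth for recovery testing.

## Worked example

```python
from edgewater import GeneratorConfig, generate_cell_movie
from edgewater.pipeline import track_movie, profile_movie

cfg = GeneratorConfig(image_size_px=(512, 512), n_frames=6, n_cells=3, seed=5,
                      speed_um_min=4.0, mpact_front_depletion=0.5,
                      cell_area_um2_range=(42, 56))
movie, truth = generate_cell_movie(cfg)
table, metrics = track_movie(movie)
print(metrics.round(3))
print(profile_movie(movie, table).round(3))
```

prints

```
   track_id  n_frames  speed_um_min
0         0         6         3.897
1         1         6         3.778
2         2         6         4.333
   track_id  frame  direction_rad  mpact_polarity  perimeter_polarization
0         0      3         -0.330           0.596                   0.314
1         1      3          0.761           0.590                   0.339
2         2      3          2.634           0.593                   0.332
```

The recovered speeds match the generator's realized per-cell speeds (4.33,
3.90, 3.78 µm/min) and the MPAct/CaaX polarity of ~0.59 matches the ground
truth of 0.596 implied by the configured 50% front depletion: with half the
membrane-proximal actin signal at the front, the front-3/back-3 ratio of the
(max-normalized) MPAct/CaaX profile is 0.5625/0.9375 ≈ 0.6, not 0.5.

The same stages are available from the shell:

```bash
edgewater simulate --config cfg.yaml --out sim/ --seed 7
edgewater track   --movie sim/movie.ome.tiff --min-frac 0.5 --out tracks.csv
edgewater profile --movie sim/movie.ome.tiff --tracks tracks.csv --out profiles.csv
edgewater spacing --movie sim/movie.ome.tiff --window-nm 400 --out spacing.csv
edgewater flow    --movie tirf.ome.tiff --out flow.csv
edgewater media   --replace-frac 0.15 --target 292
```

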