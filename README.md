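# dcmigration

Quantitative analysis of dendritic-cell (DC) migration in 3D collagen
matrices, for cell biologists and imaging scientists who quantify amoeboid
leukocyte motility. The package covers the full measurement chain of a
typical DC-migration study:

* **Track kinematics** — per-cell mean velocity (path length / time), the
  group mean squared displacement MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ corrected for
  unequal tracking lengths, and the Euclidean distance |r(T) − r(0)| reached
  after a fixed horizon (default T = 60 min).
* **Chemotaxis directionality** — tracks are rigidly rotated/shifted so the
  chemokine-source border lies on the x axis and the gradient along +y; each
  cell's displacement angle θ = arccos(Δŷ) ∈ [0°, 180°] scores 0° for
  movement directly up the gradient and averages 90° without chemotaxis.
  Groups are compared by a percentile bootstrap of the difference in mean
  angle with a 95% confidence interval.
* **Front–rear polarity** — cells are segmented by global thresholding, the
  polarity axis is the principal axis through the nucleus centroid, the rear
  is the side with the shorter nucleus-edge-to-cell-edge distance, and the
  rear/front intensity ratio, nucleus–edge distances, width-averaged line
  profiles (rear/front 25 µm, normalized per cell), and foci densities are
  reported.
* **Nanoscale clustering** — the pair correlation function g(r) of per-cell
  single-molecule localizations (translational edge correction) is fitted
  with the Gaussian-cluster model g(r) = c + A·exp(−r²/4σ²); the reported
  cluster diameter is 4σ.
* **Population indices** — transwell percent migration, within-donor
  relative migration, and the two-dye homing index
  HI = (%FR_tissue/%V_tissue)/(%FR_input/%V_input).

A synthetic-data module generates ground-truth inputs for every stage:
biased persistent-random-walk tracks, polarized cell images with a known
rear:front ratio, Thomas-process clustered point patterns, and binomial
migration counts.

## Worked example

Simulate an unstimulated and a chemokine-stimulated group of 50 cells each,
then run the kinematics and the chemotaxis comparison:

```bash
dcmig simulate tracks --n-tracks 50 --n-steps 24 --bias 0   --seed 11 --out wt_noccl21.csv
dcmig simulate tracks --n-tracks 50 --n-steps 24 --bias 0.4 --seed 12 --out wt_ccl21.csv
dcmig tracks wt_ccl21.csv --frame-interval 4 --horizon 60 --out-dir stats
# 50 tracks | mean velocity 4.00 µm/min | mean Euclidean displacement (60 min) 111.2 µm
dcmig chemotaxis wt_noccl21.csv wt_ccl21.csv --frame-interval 4 \
    --bootstrap 10000 --seed 13 --out-dir chemo
# mean angle A 78.2° | B 44.4° | diff (B-A) -33.8° [-51.3, -16.1]
```

The simulated cells move at exactly 4 µm/min (the generator's step speed);
the gradient-biased group's mean displacement angle (44.4°) is well below
the unbiased group's (78.2°, consistent with the 90° null at n = 50), and the
bootstrap CI of the difference excludes 0 — the stimulated group is
directional. Per-track angles, the MSD curve, and the bootstrap summary are
written as CSV/JSON in the output directories.

Cluster sizing on simulated localization data (true σ = 25 nm, i.e. true
diameter 4σ = 100 nm):

```bash
dcmig simulate pattern --sigma 25 --seed 14 --out cell1.csv
dcmig simulate pattern --sigma 25 --seed 15 --out cell2.csv
dcmig clusters cell1.csv cell2.csv --window 0,5000,0,5000 --out-dir clusters
# 2 cell(s): mean cluster diameter 99 ± 3 nm
```

The same operations are available as library functions
(`dcmigration.track_stats`, `.chemotaxis`, `.polarity`, `.clustering`,
`.counts`, `.synthetic`); the CLI is a thin wrapper and writes a JSON run
manifest (parameters, seed, version) next to every output set.

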