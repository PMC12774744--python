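# isletmito

Quantitative image analysis for mitochondrial behaviour in pancreatic islet
cells. The package implements three measurement pipelines plus the synthetic
data needed to validate them end to end:

1. **Mitochondrial motility** from whole-islet confocal time-lapse
   recordings. Tracking individual mitochondria is unreliable in primary
   islet cells because organelles drift in and out of a ~1 µm optical
   section, so motility is instead quantified per pixel as the temporal
   standard deviation of the mitochondrial channel: a time series
   `I_p(t)` collapses to `SD_p = sqrt( Σ_t (I_p(t) − Ī_p)² / (T−1) )`.
   Per cell, the SD image is normalized to the maximal value observed in
   that cell, radial line ROIs are cast from the nucleus centroid every
   θ degrees (θ = 10° → 36 lines, θ = 1° → 360), each profile starts at the
   nucleus periphery, and profiles spanning a fixed 7 µm cytosolic fraction
   are averaged into the per-cell motility score. The temporal-mean image is
   kept as a bleaching / membrane-potential control and its correlation with
   the SD image is a per-cell QC statistic.
2. **TEM morphometry** from manual organelle polygon annotations
   (plasma membrane, nucleus, Golgi components, mitochondria): per
   mitochondrion, area, perimeter, fitted-ellipse length/width,
   aspect ratio AR = length/width, form factor FF = perimeter²/(4π·area),
   circularity = 4π·area/perimeter² (= 1/FF), shortest Euclidean distance
   to the nucleus and to the nearest Golgi component (an absent Golgi is
   reported as missing, never as distance 0), plus cell area and
   mitochondrial density (Σ mito area / cell area).
3. **Ratiometric ATP/ADP biosensor analysis** (PercevalHR-style dual
   excitation): per-pixel ratio R = I476/I405 with a denominator floor,
   averaged in the sub-plasma-membrane shell (cytosol within 4 µm of the
   cell boundary, via a Euclidean distance transform), with detection of
   contiguous high-ratio microdomains inside the shell, rolling-ball
   background subtraction (default radius 300 px) and immunofluorescence
   knockdown-efficiency quantification.

A seeded synthetic-data generator produces two-channel movies of cells with
elongated Gaussian-blob mitochondria performing reflected random walks,
ratio-sensor movies with planted sub-membrane microdomains, and TEM-style
polygon annotations with brute-force ground-truth distances — so every
claim the analysis makes can be tested against known truth without any
real microscopy data.

## Worked example

```python
from isletmito.synthetic import MovieConfig, simulate_movie
from isletmito.motility import analyze_movie

# 4 synthetic islet cells, 18 frames at 5 s, 0.3 µm per-frame step SD
stack, annotations, truth = simulate_movie(MovieConfig(seed=1))
results, table = analyze_movie(stack, annotations, classify=True,
                               fixed_threshold=1000)
print(table.df[["cell_id", "class", "n_lines", "mean_norm_motility"]])
```

prints

```
   cell_id      class  n_lines  mean_norm_motility
0  cell_00      alpha       36            0.121421
1  cell_01      alpha       36            0.102575
2  cell_02  non_alpha       36            0.111479
3  cell_03  non_alpha       36            0.088614
```

Each cell retains all 36 radial lines (every ray spans ≥ 7 µm of cytosol),
and `mean_norm_motility` is the average normalized temporal SD over those
lines — the per-cell motility score in [0, 1]. On this seed all four cells
were simulated with the same step size, so their scores agree to within
noise; increasing `step_sigma_um` raises the score monotonically
(see `tests/test_acceptance.py`).

The same movie/annotation objects round-trip through OME-TIFF and GeoJSON
(`isletmito.io`), and the command line mirrors the library:

```sh
isletmito simulate movie --out-dir demo --seed 1
isletmito motility --stack demo/movie.ome.tif --annotations demo/movie.geojson --out demo/motility.csv
isletmito tem --annotations cells.geojson --pixel-size 0.02 --out morpho.csv
```

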