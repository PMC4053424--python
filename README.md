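# pbodytrack

Detection, tracking and motion statistics for **P-bodies** (cytoplasmic
RNA–protein granules) in time-lapse fluorescence microscopy of budding
yeast, together with a ground-truthed synthetic data generator that makes
every stage of the pipeline testable without microscope data.

The package is aimed at quantifying how a granule moves during one cell
division: free diffusion inside the mother cell, confined ("hovering")
motion near the future bud site, and a single directed mother→daughter
transport event at mitosis.

## What it computes

Given a fluorescence movie (or pre-extracted trajectories), the pipeline

1. **detects granules** per frame by Difference-of-Gaussians band-pass
   filtering, constant thresholding with size constraints, subpixel 2D
   Gaussian point-spread fitting, and a brightness/localization score
   (fitted peak amplitude / residual standard deviation) that removes
   false positives;
2. **segments cells** from two-plane bright-field focus stacks via the
   focus-differential image, thresholding + size constraints, and
   marker-based watershed, then assigns each granule to a cell and reports
   the fraction of cells with ≥ 1 P-body over time (20-min window means);
3. **links** detections into trajectories by greedy nearest-neighbour
   frame-to-frame matching;
4. **scores motion** per trajectory:
   - *k*-means (k = 2) clustering of the (x, y) positions, with cluster 1
     anchored to the earlier-occupied cluster;
   - reversibility rate **R_rev = τ/(n − 1)**, the fraction of adjacent
     time points at which the cluster affiliation changes — 0 for one
     irreversible mother→daughter transfer, → 1 for continual
     back-and-forth movement;
   - cluster betweenness **J₄ = tr(S_b)/tr(S_w)**, the ratio of
     between-class to within-class positional scatter — large when the two
     clusters are spatially well separated;
   - step sizes and velocities from successive coordinates, and the
     distance to an annotated bud site;
   - time-averaged **MSD** and diffusion coefficients from linear fits
     (MSD = 4Dt in 2D) over lags 1–4, including windowed estimates
     before / during / after budding;
   - a two-regime **hovering changepoint detector**: a high–low–high
     piecewise-constant fit to a sliding-window mobility series yields the
     hovering onset H_start, end H_stop and duration T_hov relative to bud
     emergence.

The synthetic-data module simulates all three motion classes (Brownian
steps; an exact discrete-time mean-reverting process around the bud site;
constant-velocity transport into the daughter), renders diffraction-limited
spots with Poisson noise and two-plane bright-field cell images, and writes
TIFF/CSV datasets with complete ground truth.

## Worked example

```python
from pbodytrack import (SimConfig, simulate_trajectory, cluster_positions,
                        windowed_diffusion, detect_hovering)

cfg = SimConfig(n_frames=240, dt=60.0, rng_seed=1)        # 4 h at 1 frame/min
track = simulate_trajectory(
    cfg, bud_time=120, bud_site=(2.2, 0.0), mother=((0.0, 0.0), 2.5),
    division_time=165, daughter=((4.3, 0.0), 1.8),
)

win = track.subwindow(120*60 - 1800, 120*60 + 5400)        # division window
clusters = cluster_positions(win, seed=0)
print(f"tau = {clusters.tau}, R_rev = {clusters.r_rev:.4f}, J4 = {clusters.j4:.2f}")

wd = windowed_diffusion(track, bud_time_s=120*60.0)
print(f"D before/during/after = {wd.D_before:.4f}/{wd.D_during:.4f}/{wd.D_after:.4f}")

hv = detect_hovering(track, bud_time_s=120*60.0)
print(f"H_start = {hv.H_start/3600:+.2f} h, H_stop = {hv.H_stop/3600:+.2f} h, "
      f"T_hov = {hv.T_hov/3600:.2f} h")
```

prints

```
tau = 1, R_rev = 0.0084, J4 = 1.63
D before/during/after = 0.0028/0.0000/0.0030
H_start = -0.45 h, H_stop = +0.23 h, T_hov = 0.68 h
```

One cluster transition (R_rev near 0) and well-separated clusters: the
granule moved to the daughter once and stayed — directed transport. The
diffusion coefficient collapses during the budding window, and the
changepoint detector places hovering from ~27 min before to ~14 min after
bud emergence (this track's simulated window was −30 to +15 min). At 1-min
sampling the absolute D values sit below the free-space input value because
the cell boundary itself confines the walk at these lag times; comparisons
*between* windows, which share that geometry, remain meaningful.

## Command line

```bash
pbody simulate --out data/ --seed 1 --n-cells 4
pbody detect   --in data/fluorescence.tif --out run/
pbody segment  --stack data/brightfield.tif --spots run/spots.csv --out run/
pbody motion   --spots run/spots.csv --data-dir data/ --out run/
pbody run-all  --out run/ --seed 1      # everything, end to end
```

Outputs are plain CSV/TIFF/JSON: per-frame spot tables, 16-bit label
images, per-cell counts, the P-body fraction time course, per-track motion
reports, and a provenance record (config + seed + versions).

## Documentation

`docs/methods.md` describes the motion models, the estimators and their
assumptions, parameter defaults with units, numerical choices, and what the
synthetic benchmark does and does not demonstrate about real microscope
data.
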