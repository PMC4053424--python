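# Methods

This note documents the models and estimators implemented in `pbodytrack`,
the defaults and why they were chosen, the numerical edge cases, and the
limits of what the synthetic benchmark can show.

## The biological setting

A budding-yeast mother cell carries a single fluorescently labelled P-body
(an RNA–protein granule) through one cell division. Three movement classes
are of interest: free diffusion within the mother, a confined ("hovering")
phase near the future bud site that begins before the bud is visible, and a
single directed translocation into the daughter around mitosis. The
statistics below are designed to separate these classes from 2D granule
trajectories sampled at a fixed frame interval (typically 60 s with
bright-field cell imaging, or 10 s fluorescence-only).

## Synthetic data model

`simulate.SimConfig` fixes the study conditions; all defaults are stated
here with units.

**Trajectory model** (`simulate_trajectory`). Positions evolve in
continuous µm coordinates at the frame interval `dt`:

- *Free diffusion*: per-axis Gaussian increments with variance `2·D_free·dt`.
  Default `D_free = 0.01 µm²/s`, a typical apparent mobility for a
  ~0.3 µm cytoplasmic granule.
- *Corralled (hovering)*: the exact one-step update of a discrete-time
  mean-reverting (Ornstein–Uhlenbeck) process centred on the bud site,
  with autocorrelation `exp(−dt/corral_tau)` and stationary per-axis
  standard deviation `corral_sigma`. Defaults: `corral_sigma = 0.2 µm`,
  `corral_tau = 20 s`. This is the simplest stationary confined process
  reproducing a reduced apparent diffusion. The hover window opens
  `hover_start_offset = −1800 s` relative to bud emergence and lasts
  `hover_duration = 2700 s` (i.e. −0.5 h to +0.25 h), matching the scale of
  confinement onset before budding that the analysis is meant to recover.
- *Transport*: from the division frame the granule moves deterministically
  in a straight line at `transport_speed = 0.3 µm/s` to a point inside the
  daughter, then diffuses freely there. A single irreversible translocation
  is modelled, not its molecular kinetics; at 60-s sampling the ~4 µm
  transfer completes within one frame, as observed transfers effectively do.

A radial reflecting boundary keeps the granule inside the current cell
outline shrunk by `boundary_margin = 0.4 µm` (granules stay in the
cytoplasm, clear of the wall). Regime labels (`free`, `corralled`,
`transport`) are recorded per frame: point *i* carries the regime that
generated the step *i* → *i+1*.

**Rendering.** Granules are isotropic 2D Gaussians of width
`spot_sigma = 2 px` whose integrated intensity is
`spot_amplitude = 3000 photons` on a `background = 100 photons` floor, with
Poisson noise by default (Gaussian read noise and noise-free rendering are
options). The pixel scale defaults to `0.2 µm/px`, a round value typical of
a 63× air objective with a standard CCD; it is configurable everywhere.
Bright-field stacks contain two focus planes in which cell interiors (a
parabolic dome profile) and rims carry opposite contrast, so the
focus-differential image peaks inside cell bodies; a common background
texture is identical in both planes and cancels exactly in the difference.

**Scenes** (`build_scene`). Mothers (radius 2.5 µm) sit on a jittered grid
with room for one daughter each (final radius 1.8 µm, linear growth from
1.0 µm between bud emergence and division, 2700 s apart). Each daughter has
one of three fates: `transported` (the mother's granule hovers, then
transfers), `de_novo` (the mother's granule stays; a new granule assembles
in the daughter after division), or `none`. Mothers of non-transported
granules skip the hover phase, emulating transport-machinery deletion
mutants. Datasets are fully reproducible from `rng_seed` and are written as
multi-frame TIFF plus CSV/JSON ground truth.

## Spot detection

The band-pass filter is a Difference of Gaussians with widths interpreted
as Gaussian standard deviations, defaults 3 and 9 px — the conventional DoG
parameterization bracketing diffraction-limited spot sizes at 0.2 µm/px.
The filtered image is thresholded at a constant `binary_threshold`; this is
deliberately a **required** parameter with no default, because it depends
on illumination and labelling intensity of each image set (a useful
starting point is 4–6× the filtered image's background noise level).
Connected components are size-filtered (`min_area = 4`,
`max_area = 400 px²`); components containing several band-pass maxima are
split at local maxima so nearby granules are fit separately.

Each candidate is fit by least squares with an isotropic Gaussian plus
offset over its bounding box padded by ~2·`sigma_small`. Fits that fail to
converge or pin the width at its bounds are flagged and dropped. The
false-positive score is the fitted peak amplitude divided by the residual
standard deviation of the fit — a signal-to-noise ratio that is large only
for bright, well-localized foci. An alternative reading, peak amplitude
over the fitted Gaussian σ, is available as `score_mode="psf_sigma"`; the
residual-based score is the default because it measures both brightness and
fit quality. The default `score_threshold = 3` passes true spots with peak
SNR ≥ 5 while rejecting flat-background fits (score ≲ 1), as calibrated on
the synthetic benchmark. Candidates touching the frame border are fit but
flagged.

## Cell segmentation

Cells are detected from the signed difference of two bright-field focus
planes. The magnitude of the differential, lightly smoothed
(`smoothing_sigma = 2 px`), is thresholded at `cell_threshold` (again
dataset-specific and required) and size-filtered
(`min_cell_area = 30 px²` keeps small buds; `max_cell_area = 20000 px²`
rejects chamber borders). Surviving components seed a marker-based
watershed on the negated smoothed magnitude, restricted to a foreground
mask at `mask_frac × cell_threshold` (default 1/8) — markers capture cell
cores, the mask extends labels to the weaker periphery, and the watershed
line splits touching cells between their interior maxima. Cells touching
the image border are retained (microfluidic chambers are crowded).

Spots are assigned to the label under their rounded centre; background
assignments are flagged rather than snapped to the nearest cell, keeping
the assignment unambiguous under a partition segmentation. The per-frame
fraction of cells with ≥ 1 granule is averaged over non-overlapping 20-min
windows to filter detection noise; frames with no segmented cells are
skipped with a warning.

Mother/daughter identity and bud times are **not** inferred from images:
they come from simulator ground truth or a user annotation CSV, mirroring
the manual curation such analyses require on real data.

## Trajectory linking

Greedy nearest-neighbour frame-to-frame linking, gated at `max_disp_um`;
ties break on the smaller displacement, then the lower spot index;
unmatched spots open new tracks. With ~1 granule per cell the assignment
problem is nearly trivial and a global tracker would be over-engineering.
The pipeline default gate is 4 µm/frame: at the study conditions
(D = 0.01 µm²/s, 60-s frames) free-diffusion steps exceed 2 µm about 5% of
the time, so a tighter gate fragments tracks, while 4 µm stays far below
the ≥ 6 µm separation between granules of neighbouring cells.

## Motion statistics

**Clustering.** k-means (k = 2, squared Euclidean, 10 restarts, fixed
seed) on the (x, y) coordinates only — time is deliberately excluded, so
any temporal structure in the affiliation series is a finding, not an
artifact. Labels are renumbered so cluster 1 has the earlier mean
membership time; a transported granule then reads 1 → 2. All-identical
points yield a flagged degenerate result.

**Reversibility rate.** `R_rev = τ/(n−1)` with τ the number of adjacent
affiliation changes. The denominator counts adjacent pairs, which gives
exactly the two required limits: a constant series scores 0, a single
transition scores 1/(n−1) → 0, and strict alternation scores exactly 1.

**Cluster betweenness.** `J₄ = tr(S_b)/tr(S_w)` with the pooled
within-class scatter `S_w = Σ_k Σ_{i∈k} (x_i−μ_k)(x_i−μ_k)ᵀ/N` and the
population-weighted between-class scatter
`S_b = Σ_k (N_k/N)(μ_k−μ)(μ_k−μ)ᵀ`. Scatter-matrix conventions differ by
normalization constants, but J₄ is invariant to any common scale factor on
both matrices, so only this ratio convention matters. `tr(S_w) = 0` (all
points at their cluster centres) flags J₄ = ∞.

**Steps, velocities, bud distance.** Computed directly from successive
coordinates (no distributional assumption). Non-uniform sampling uses
per-interval dt with a warning.

**MSD and diffusion.** Time-averaged MSD over all overlapping pairs; lags
with < 3 pairs are dropped with a record. D comes from a least-squares line
over lags 1–4 with a free intercept (absorbing static and dynamic
localization error), via the 2D relation MSD = 4Dt; negative slopes clip to
D = 0 with a flag, and a curvature check flags fits where a quadratic
(directed-motion) term dominates. D is computed per track and then
averaged across tracks, never the reverse. Windowed estimates use a during
window of `bud_time ± 900 s` (15 min either side of bud emergence) with
equal-length adjacent before/after windows; each window must contain ≥ 10
points. A general `diffusion_in_window(traj, t0, t1)` covers any other
window placement.

Note an important regime effect: at 60-s sampling, free MSD lags 1–4
(2.4–9.6 µm² at D = 0.01 µm²/s) already exceed the ~4 µm² displacement
ceiling a 2.5 µm cell imposes, so absolute windowed-D values inside cells
sit below the free-space D. Between-window comparisons share that geometry
and remain valid; absolute D estimation is best done at 10-s sampling,
which is exactly why the high-frequency acquisition mode exists.

**Hovering changepoints.** The mobility series is the squared step size,
winsorized at the track's 75th percentile and averaged over a centred
7-step window; a three-segment piecewise-constant high–low–high model is
fit by exhaustive search over changepoint pairs (minimum segment length 10
mobility points, ≥ 30 trajectory points required on each side of budding),
with the low segment constrained to bracket the bud time. Winsorizing
matters: entering confinement produces one large relaxation step toward the
bud site which otherwise blurs the onset by 2–3 frames. Hovering is
reported only when the low segment's mean squared step is below both
neighbours and at least 50% below their pooled mean. The 50% rule reflects
the effect class of bud-site confinement (diffusion reduced by more than
half) and sits well above the spurious ~30–35% drops the exhaustive search
extracts from homogeneous free diffusion; weaker reductions are reported as
"no hovering" rather than as unreliable windows. `H_start`/`H_stop` are the
segment boundaries in seconds relative to bud time; `T_hov` their
difference.

**Statistical comparison.** Two-sample Kolmogorov–Smirnov (asymptotic),
with a warning below 3 observations per sample.

## Benchmark scope and problem sizes

The test suite and acceptance script run entirely on simulated data at desk
scale: 50-trajectory ensembles of 240–600 frames for the diffusion and
changepoint benchmarks, and 30-frame, 6-cell rendered movies for the
detection/segmentation benchmarks — sizes at which the stochastic checks
are stable from seed to seed while the whole suite stays fast.

Cluster-transition benchmarks evaluate the division window
(bud − 30 min to bud + 90 min) rather than whole tracks, mirroring how
single divisions are selected for analysis in practice; over a long pre-bud
free phase the granule wanders territory that spatially overlaps the
bud-side cluster and an unwindowed k = 2 split can cut through the mother.

What passing these benchmarks does **not** show: the simulator has no cell
growth or shape change beyond linear bud growth, no photobleaching, no
focus drift, no 3D optics (granules never defocus), no granule fusion or
fission, and free parameters (PSF width, pixel size, photon counts) are
chosen as plausible rather than fit to any instrument. Real-data
percentages of transported / de-novo / absent granules across strains are a
property of biology, not of this code, and are represented only as
configurable scene fates. Thresholds (`binary_threshold`, `cell_threshold`)
must be recalibrated per image set on real data.

## Known limitations

- The linker has no gap closing: a missed detection splits a track.
- The hover detector assumes exactly one low-mobility episode bracketing
  budding; multiple hover episodes would be merged or missed.
- `R_rev` compares fairly across tracks of similar length only; very short
  tracks upper-bound τ at n − 1.
- Watershed labels can extend slightly beyond true cell outlines (the rim
  response widens the foreground mask), which is harmless for containment
  queries but makes label areas a biased estimator of cell area.
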