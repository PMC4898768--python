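# Methods

`endoquant` reimplements, as a tested library, the quantitative image- and
assay-analysis procedures used to measure changes in clathrin-mediated
endocytosis (CME) and fluid-phase uptake — for example after ultrasound-
microbubble (USMB) stimulation: detection and per-structure intensity
quantification of clathrin-coated pits (CCPs) in TIRF micrographs, per-cell
ROI quantification of epifluorescence images, Pearson colocalization,
uptake time-course analysis, and hierarchical condition statistics.  A
synthetic-data generator with exact ground truth stands in for micrographs
so every stage is verifiable end to end.

## Spot model and photometry

CCPs are sub-resolution objects, so a CCP's image is the microscope PSF,
modeled as an isotropic 2D Gaussian with width `sigma` (default 1.4 px for
a high-NA TIRF objective; configurable — pixel size and PSF width are
instrument properties, not constants of the method).  Because camera pixels
integrate photons over their area, both the renderer and the fitter use the
Gaussian *integrated over each pixel* (products of `erf` differences), not
point samples.  Consequences:

* the integrated intensity of a rendered spot is exactly `2*pi*A*sigma^2`;
* fitting the same model that generated the data makes amplitude recovery
  unbiased — a point-sampled fitter against pixel-integrated data would be
  biased low by ~3.5% at `sigma = 1.4`;
* the value of the central pixel of an on-center spot is `A` times an
  analytic integration factor (~0.96 at `sigma = 1.5`), slightly below the
  continuous peak `A`.

"Amplitude" throughout is the continuous Gaussian peak height above the
*local background* `c`, the same per-structure enrichment measure used for
per-CCP GFP-clathrin and cargo intensities.

## Detection pipeline

1. **Candidates.** The frame is matched-filtered with a Gaussian kernel of
   the PSF width after subtracting a coarse background estimate (Gaussian,
   `5*sigma`).  Local maxima above `median + k*MAD` of the filtered image
   become candidates.  Default `k = 7`: `k * 0.674 ≈ 4.7` Gaussian sigmas
   of the filtered noise, chosen so a pure-noise 256×256 frame produces
   fewer than ~1 spurious maximum (a per-frame multiplicity guard across
   ~6·10^4 pixels).  A permissive threshold (e.g. `k = 3`) admits hundreds
   of noise maxima per frame, and no per-candidate test at a fixed
   false-accept rate can then keep frame-level precision high.
2. **Fitting.** On a window of side `4*sigma` (rounded up to odd) around
   each candidate, `(x, y, A, c)` are fitted by least squares with `sigma`
   fixed (diffraction-limited assumption; a flag fits `sigma` per spot for
   validation).  The solver is a variable-projection Levenberg–Marquardt:
   the linear parameters `(A, c)` are profiled out exactly at every trial
   position, and a coarse profiled grid (0.25 px) first locates the global
   basin within the ±2 px position bound.  Convergence: projected-gradient
   correlation < 1e-4, relative step < 1e-9, or relative SSE decrease
   < 1e-9; the fit matches a dense grid-search oracle to better than 1e-6
   relative SSE.  Windows clipped by the image border are flagged `border`
   and excluded from intensity statistics (truncation bias); degenerate
   fits are flagged `not_converged`, never silently kept.
3. **Amplitude significance.** A detection is accepted when its statistic
   `A / SE(A)` (standard error from the fit covariance and residual SD)
   exceeds the `1 - alpha` quantile of the null distribution of the *same
   statistic under the same free-position fitting procedure* on pure-noise
   patches.  This null is estimated once per (window, sigma) by a seeded
   internal Monte-Carlo (4000 patches) and cached; free-position fitting
   biases null amplitudes upward, so a textbook t test would accept ~3x
   the nominal rate.  Reported p-values come from a smooth tail model (the
   null treated as the maximum of `m_eff` independent t variates, `m_eff`
   pinned to the Monte-Carlo 95th percentile), so they are monotone in the
   statistic and meaningful far into the tail; the accept/reject decision
   itself uses the empirical quantile.
4. **Merge.** Accepted detections closer than `2*sigma` are collapsed,
   keeping the higher amplitude (ties: lower (row, col)).

A second, co-registered channel is read out at the positions and width
fixed by the primary channel — a linear `(A, c)` fit per structure, with no
significance filter, so near-zero secondary amplitudes (absence of cargo)
remain meaningful.  Spot density is accepted detections per unit mask area.

## Per-cell quantification and colocalization

Cells are quantified as mean pixel intensity over manually-delineated (or
synthetic label-mask) ROIs, minus the mean of one coverslip-background ROI
per image; negative nets are flagged but kept, so condition averages stay
unbiased.  Saturation checks report the fraction of pixels at the camera
maximum.  Colocalization is the plain Pearson coefficient over all ROI
pixels — no intensity threshold or Costes masking — and zero-variance
channels yield "undefined" (NaN), never 0, since 0 is a real
colocalization value.

## Uptake time courses

Fluid-phase uptake readouts (HRP absorbance, dextran fluorescence) are
treated as accumulating linearly in time.  Per condition: an OLS line
through all replicate points (the t = 0 blank retained, absorbed by the
intercept), per-timepoint means ± SEM, and treated/control fold changes
with first-order (delta-method) standard errors.  Per-timepoint condition
comparisons use the same tests as the imaging statistics (pooled t for two
conditions, ANOVA + Newman–Keuls for more); a timepoint where every
condition is constant and equal (the blank) is reported not-significant
with NaN p rather than tested.

## Hierarchical statistics

The independent experiment — not the cell — is the unit of replication:
cells are averaged within (condition, experiment), and condition means,
SEMs and all tests operate on experiment means.  Pooling cells would
overstate n, because cells within an experiment share culture, staining and
imaging conditions.  Tests: classical one-way fixed-effects ANOVA (exact
sums of squares, F-distribution p) with the student-Newman-Keuls stepwise
studentized-range post test (critical values from
`scipy.stats.studentized_range`, cached; harmonic-mean n for unequal group
sizes; a non-significant stretch blocks every pair inside it), and a
pooled-variance two-sample t test (Welch behind a flag).  All tests are
two-sided at `alpha = 0.05` by default.  Effect sizes are percent change
and fold change with delta-method uncertainties.

## Synthetic-data generator

The generator emulates the statistical structure the measurements assume,
with known ground truth:

* **TIRF fields** — pixel-integrated Gaussian spots at uniform random
  positions with a minimum separation (default 6 px) and an 8 px edge
  margin, amplitudes from a configurable distribution (default lognormal,
  mean 300, CV 0.3, on a background of 100 — within the 16-bit working
  range typical of these images), Poisson photon noise plus Gaussian read
  noise (flat-field variance `level/photon_scale + read_sd^2`), optional
  linear background gradient, and an optional second channel carried by a
  configurable fraction of spots.
* **Cell fields** — disjoint random ellipses (semi-axes 10–20 px) whose
  interior mean is drawn per cell from a condition distribution; the
  default cell-to-cell CV of 0.15 reflects typical marker variability in
  cultured cells and, at the standard sampling depth of 20 cells × 3
  experiments, puts the SEM of a condition mean near 2%.
* **Uptake series** — control readout `slope*t`; treated conditions follow
  the control slope until an onset delay and an elevated slope after
  (defaults: slopes 1 and 3 units/min, delay 10 min, timepoints 0/10/20
  min — hence a 2-fold treated/control ratio at 20 min and none at 10).
  Replicates get additive Gaussian noise (sd 2) at t > 0 and are clipped
  at zero; the t = 0 readout is the assay blank, exactly zero.

One master seed drives everything; each generator draws from a named,
deterministically derived substream, so adding one generator call never
perturbs another's draws.  Identical spec + seed reproduce bit-identical
arrays and files (TIFF/CSV/JSON writers embed no timestamps, and every
result file carries the producing configuration hash and seed).

What the generator does *not* emulate — and hence what passing tests do not
show about real micrographs: spatially correlated backgrounds (cell
autofluorescence, uneven illumination), overlapping or clustered CCPs,
non-elliptical cell shapes and touching cells, chromatic misregistration,
photobleaching, and CCP lifetime dynamics (no time-lapse).  Results on real
data additionally depend on correct PSF width and pixel-size settings.

## Problem sizes and numerical choices

The validation suite exercises: fit-vs-oracle equivalence on 100 patches
(tolerance 1e-6 relative SSE), amplitude recovery on 500 spots with
amplitude/noise between 5 and 20 (median relative error < 5%; at
amplitude/noise = 5 exactly, the Cramér–Rao bound alone is ~6% median, so
the bound applies to the population), detection on 100 frames × 30 spots
at amplitude/noise = 10 (precision and recall ≥ 0.95, 2 px matching),
significance calibration on 10^4 null patches (false-accept 0.05 ± 0.01),
a ×1.3 amplitude shift at fixed density over 100 simulated two-condition
experiments, a −35% per-cell effect at 20 cells × 3 experiments over 100
repeats (recovery within ±5 points and ANOVA/NK significance), Pearson
recovery at ρ = 0.5 over 10^4 pixels, uptake delayed-onset recovery over
100 noisy repeats at 5 experiments, statistics oracles (closed forms to
1e-10; Newman–Keuls vs brute-force enumeration on 200 instances; type-I
rates at 10^4 null simulations), and byte-level determinism of all
pipelines.  `scripts/acceptance.py` re-runs the archetypes at these
sampling depths and writes the recovered quantities as JSON.

## Known limitations

* The candidate threshold and significance calibration assume roughly
  stationary noise within a frame; strongly structured backgrounds would
  need a local noise model.
* The Newman–Keuls procedure does not strongly control the family-wise
  error rate under partial null configurations (a known property of SNK);
  it is provided because it is the field-standard post test for this
  workflow.
* Fold-change standard errors use first-order propagation, which is
  anti-conservative when the control mean is within a few SEMs of zero.
* No segmentation: cell ROIs must be supplied (label image or polygons),
  mirroring manual delineation.
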