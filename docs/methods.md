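# Methods

`fmriverse` implements a multiverse analysis of task-fMRI processing: it
enumerates every combination of ten analysis choices, runs each resulting
pipeline on a synthetic event-related cohort, thresholds every group map
under five multiple-comparison regimes, and quantifies how much the
outcome — activation strength, location, and significance — depends on the
choices rather than the data.  This note records the models, the defaults
and their rationale, the numerical choices, and the limits of what the
synthetic setting can show.

## The factor grid

Four pre-processing factors and six model-estimation factors are crossed
factorially:

| factor | options |
|---|---|
| despike | on, off |
| slice_timing | on, off |
| normalization | epi_template, t1_template, segmentation |
| smoothing_fwhm | 4, 8, 12 mm |
| order | normalize_first, model_first |
| highpass | cutoff_128s, off |
| autocorr | ar1, off |
| concat | on, off |
| basis | hrf, fir_34_vs_baseline, fir_interaction |
| motion | m6, m12, m24, none |

The product is 2·2·3·3·2·2·2·2·3·4 = 6,912 pipelines; with the five
thresholding regimes each group map yields five binary significance maps,
34,560 in total.  Constraining slice timing to on, autocorrelation
correction to on, and motion regression to any non-empty scheme leaves
1,296 pipelines.

## Synthetic cohort

The generator emulates a three-run event-related stop-signal experiment
(go, successful-stop and failed-stop trials) with 13 subjects.  Defaults
are desk-scale so factorial runs fit on one CPU: a 20×20×12 voxel grid at
3 mm isotropic, 3 runs × 80 volumes at TR 2 s.  The emulated acquisition
(176 volumes/run, 3.125×3.125×4 mm voxels) is reachable through
`SyntheticSpec` but is not the default.

Signal: each of three active regions is a sphere with a cosine-squared
amplitude taper; region amplitudes are percent signal change on a baseline
of 100 (defaults 1.5–3%, i.e. a contrast-to-noise ratio around 1–1.5 per
trial-type regressor).  The neural time course is a 1 s boxcar per trial
convolved with the canonical double-gamma HRF (peak ≈ 5 s, undershoot
≈ 15 s, undershoot weight 1/6) on a 0.02 s grid.  Slice k of volume i is
sampled at `i·TR + k·TR/n_slices` (ascending acquisition), which is what
makes slice-timing correction consequential.  Two regions respond more to
successful stops than to go trials (the truth-positive set for the
contrast of interest); a left "motor" region responds to go trials and
produces genuinely negative contrast.

Noise, per voxel within an ellipsoidal brain mask:

* AR(1) temporal noise, marginal SD 2.0 (signal units), lag-1 correlation
  0.3 — typical of short-TR EPI after scanner drift removal;
* slow drift as two cosines with periods 2T and T (T = run length; 320 s
  and 160 s at the default geometry), amplitude SD 2.0.  Both periods lie
  above the 128 s cutoff, so the high-pass factor removes the drift
  entirely when on and leaves it entirely when off;
* transient spikes: per volume with probability 0.02, all in-mask voxels
  at that volume are displaced by ±6 noise-SD scaled by a random spatial
  pattern — large enough that despiking matters, rare enough that the GLM
  survives without it;
* a motion-coupled intensity component at brain-edge voxels (the mask
  shell): a linear projection of the six z-scored motion parameters with
  per-voxel random weights, scaled by the noise SD.  This reproduces, as a
  testable property, the tendency of motion-regression effects to
  concentrate at the brain edge;
* head motion itself is a slow random walk (0.03 mm and 4·10⁻⁴ rad steps),
  restarted at each run boundary as after per-run realignment.

Between-subject variability is a single multiplicative amplitude factor
drawn N(1, 0.2) per subject.  Trial counts per run default to 24 go, 8
successful-stop, 8 failed-stop (the ~3:1 go:stop ratio typical of
stop-signal designs), 1 s trials with ≥ 2 s inter-trial interval and
Dirichlet-distributed onset jitter; neither trial counts nor ITIs are
dictated by the emulated design, so both are configurable.

Every random draw is keyed by (seed, subject, run, purpose) through
`SeedSequence`, so a cohort is bit-identical for a given spec.

What the generator does **not** emulate: anatomical structure and true
nonlinear anatomy-to-template correspondence, physiological (cardiac or
respiratory) noise, spatial noise correlation beyond what smoothing
induces, susceptibility distortion, and multi-site effects.  Passing tests
therefore show that the machinery is correct and calibrated under the
stated noise model, not that real-data effect sizes or the emulated
study's data-dependent numbers would be reproduced.

## Pre-processing operators

**Despiking** fits a per-voxel Legendre trend of order `2 + duration//150 s`,
scales residuals by σ = MAD/0.6745, and maps residuals above c1·σ through
`c1 + (c2−c1)·tanh((s−c1)/(c2−c1))` (defaults c1 = 2.5, c2 = 4.0, the
common command-line despiker's convention).  Samples below c1·σ are
returned exactly unchanged; constant series pass through (σ = 0 guard with
round-off headroom).

**Slice-timing correction** applies a frequency-domain phase ramp per
slice toward the first acquired slice's time.  The DC term is untouched
(means preserved exactly); for even-length series the Nyquist bin is
scaled by cos(2πfΔt), the proper real-valued band-limited shift.

**Spatial normalization** is deliberately a surrogate, not a
reimplementation of SPM's unified segmentation: a world-space affine
(translation + per-axis scale, clipped to [0.7, 1.4]) is estimated by
matching the intensity centroid and per-axis SD of a strategy-specific
source reference image to a matching canonical template image
(EPI-like uniform ellipsoid / T1-like radially profiled ellipsoid /
two-class weighted image), followed by trilinear resampling onto the
template grid.  The contract the multiverse needs — three distinct,
deterministic resamplings to one shared grid — is met; nonlinear warping
of synthetic ellipsoids would add cost without exercising any statistics.
In the model-first branch the transform is estimated from the functional
data and applied to the per-subject contrast volumes.

**Smoothing** is a separable Gaussian with σ = FWHM/(voxel·√(8 ln 2)),
zero-padded boundaries, no mask renormalization.  When normalization runs
first, smoothing happens on the template grid; in the model-first branch
smoothing happens in native space before estimation.

## Model estimation

The design matrix contains per-condition regressors (HRF-convolved
boxcars, or 8 FIR bins of width TR per condition), a motion block
(6 raw / 12 raw+lagged / 24 raw+lagged+squares / none), per-run DCT
high-pass nuisance columns with periods above 128 s (filtering and model
share one projection), and per-run intercepts.  Rank-deficient nuisance
columns are pruned by pivoted QR; pruning a condition column is an error.
Scan i is timed at i·TR, i.e. the first acquired slice is the reference.

With run concatenation off, each run is fitted separately and contrast
estimates are averaged across runs unweighted — transparent, if slightly
less efficient than precision weighting.

AR(1) correction estimates a single ρ pooled over in-mask voxels from the
OLS residuals (lag products never cross run boundaries), then prewhitens
data and design with the AR(1) inverse square-root filter.  A global ρ
keeps the factor cheap and deterministic, mirroring the pooled approach of
classic SPM.

Contrasts for successful stop vs go: under the HRF basis a t on (+1, −1);
under the 8-bin FIR basis a t on the mean of bins 3–4 (4–8 s post-onset at
TR 2 s, 1-based bins) of stop minus the same for go; under the interaction
reading an F over the eight per-bin differences (numerator df 8).  Bin
indexing and the direct-difference reading of the bins-3–4 contrast are
package choices where the emulated design is ambiguous.

Group stage: a one-sample t across subjects (df = n−1) for t-type
contrasts.  For the FIR-interaction contrast the per-subject 8-vectors of
bin differences enter a one-sample Hotelling T² converted to F (df 8,
n−8); this requires more than 8 subjects and is recorded as a pipeline
failure otherwise.  Group-stage statistics convert to Z through matched
tail areas (`z = Φ⁻¹(F_t(t))`, computed tail-wise so the map is exactly
antisymmetric; F maps one-sided).  Infinities (zero between-subject
variance) are capped at a ±40 sentinel.

## Thresholding regimes

All thresholding is one-sided on the positive tail (activation).

* **Monte-Carlo cluster extent** (voxel p < .01/.001/.0001): null fields are
  smoothed white noise on the mask grid, standardized within the mask,
  binarized at the z equivalent of the voxel p, labelled at 26-connectivity
  (configurable to 6/18); the cluster-size threshold is the smallest k for
  which the fraction of simulations whose largest cluster reaches k is
  ≤ 5%.  Default 1,000 simulations; thresholds are cached per (regime,
  rounded smoothness).
* **FDR**: Benjamini–Hochberg step-up at q = 0.05 on one-sided p values.
* **RFT**: the voxel z solving `R·(4 ln 2)^{3/2}(2π)^{−2}(z²−1)e^{−z²/2} = 0.05`
  (leading 3D Euler-characteristic term, R = in-mask volume / FWHM
  product), found by bracketed root-finding on the decreasing branch
  [√3, 40] and capped at the Bonferroni cutoff.

The smoothness fed to the Monte-Carlo and RFT corrections is estimated
from the group-stage residuals (per-subject contrast maps minus their
mean) by the spatial-derivative (Forman) estimator, floored at one voxel
per axis.  For the interaction basis the bin-averaged difference maps
stand in as the residual source.

## Variability metrics

Per voxel over the pipeline stack: mean activation, analytic range
(max − min Z), and the step-attributable range of each factor — the mean
absolute pairwise Z difference between that factor's options, averaged
over all settings of the other factors.  The step range of any factor can
never exceed the analytic range, which is asserted as an invariant.

Over the thresholded stack: significance proportion (fraction of maps
marking a voxel significant) and the discordance index min(p, 1−p), which
is 0 at unanimity and peaks at 0.5 when exactly half the maps agree.

Peak extraction reports the in-scope voxel of maximal Z per pipeline in
world mm, on the *unthresholded* maps; scope masks are the two hemispheres
(split at world x = 0, with the midline plane belonging to neither) and
two right-hemisphere ROIs.  Ties break to the lowest linear voxel index;
unique locations are counted after rounding world coordinates to three
decimals.

One scale caveat, visible at desk scale: the correlation between mean
activation and analytic range is computed over t-based contrast maps.
F-derived Z maps are one-sided (bounded below, recentred), and mixing the
two statistic types into a single stack makes the correlation reflect the
scale mismatch rather than the signal-dependence of variability; the
interaction basis is instead covered by the per-pipeline ground-truth
recovery checks.

## Execution and reproducibility

Pipelines are independent, deterministic work units: outputs depend only
on the cohort and the option assignment.  Stage memoization keys on the
upstream option prefix (despike/slice-timing, then
normalization/smoothing/order) and is semantically invisible — cached and
uncached runs are bit-identical, which is tested.  A stage failure aborts
only its pipeline, leaving a machine-readable record; failed slots hold
NaN/False and are excluded from metric stacks.

Problem sizes in the test suite are desk-scale by design: 1,000 null
simulations per cluster threshold, 500 fresh null maps for the
false-positive-rate check, 200 mixed maps for the FDR check, 13 subjects
for recovery, and 2×2 or 12-pipeline sub-grids for multiverse-level
checks.

## Known limitations

* The normalization surrogate has no nonlinear component, so the
  normalization factor perturbs maps less than a full segmentation
  pipeline would on real anatomy.
* The Monte-Carlo null and the smoothness estimator assume stationary
  Gaussian fields; real fMRI residuals are neither.
* RFT uses only the leading 3D EC term (no lower-dimensional boundary
  corrections), adequate for the mask sizes used here.
* The one-sample Hotelling group model for the FIR interaction needs
  n > 8 subjects; small-cohort runs of that basis fail by design.
* Data-dependent magnitudes of the emulated study (median analytic range,
  extent percentages, peak counts) are reproduced as procedures only;
  their numeric values on synthetic desk-scale data are not comparable.
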