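# Methods

## Pipeline overview

`tractprf` analyses a white-matter tract in four stages:

1. **Subdivision** (`subdivision`): streamlines are assigned to cortical
   subfields by the retinotopic labels nearest their cortical termination;
   sub-bundles become track-weighted volumes, overlaps are reallocated, and
   white-matter masks of two strictness levels are applied.
2. **pRF fitting** (`prf`): the compressive spatial summation (CSS) model is
   fit to the sub-bundle-averaged BOLD series recorded under retinotopic
   mapping stimuli.
3. **Task GLM** (`glm_wm`): block-design working-memory runs are bandpassed,
   censored for motion, and fit with an ordinary-least-squares GLM using a
   region-appropriate HRF; the 2-back − 0-back beta difference is the
   memory-load contrast.
4. **Statistics** (`stats`): d′, quadrant confusion matrices, Pearson and
   circular correlations, paired t-tests, Benjamini–Hochberg FDR.

## Coordinate conventions

Voxel indices are 0-based and map to world mm at the voxel center; streamlines
are world mm everywhere after I/O. Visual-field positions are modelled in
centred pixel units (x rightward with columns, y upward against rows) and
converted to degrees with the aperture movie's `deg_per_pixel` scale. Polar
angle runs counterclockwise from the right horizontal meridian: right upper
visual field [0°, 90°), left upper [90°, 180°), left lower [180°, 270°),
right lower [270°, 360°). Cortical label maps use the within-hemifield
convention [0°, 180°].

## Subdivision rules and parameters

- Subfield boxes: FVF ecc ≤ 3°; PUVF 3° < ecc ≤ 30°, 0° ≤ angle < 90°; PLVF
  3° < ecc ≤ 30°, 90° ≤ angle ≤ 180°. Locations beyond 30° stay unlabelled
  (the mapping stimulus cannot constrain the far periphery). The PLVF upper
  bound is closed at 180° so the hemifield is fully covered rather than
  leaving the vertical meridian unlabelled.
- Termination = whichever streamline endpoint is nearer the labelled map;
  distance is Euclidean point-to-point, threshold 2 mm (strict `<`), beyond
  which a streamline stays unassigned.
- Track weights count each streamline once per voxel it traverses; streamlines
  are resampled at 0.1 mm (configurable) before voxelization.
- Overlap reallocation keeps a voxel in the sub-bundle with the largest
  streamline count there; exact ties go to the lexicographically smallest
  subfield name, a deterministic and order-independent rule.
- Gray-matter dilation uses the face-adjacent (6-connected) structuring
  element, one voxel at a time — the most conservative reading of "dilated one
  voxel at a time"; 26-connected is available via `connectivity=3`. Standard
  mask = WM − dilate(GM, 1); strict = WM − dilate(GM, 2).
- Subject inclusion requires every sub-bundle mask (standard and strict,
  evaluated separately) to exceed 10 voxels — "greater than ten" is strict, so
  exactly 10 voxels excludes.

## The CSS pRF model and its fit

The stimulus drive is the per-frame dot product of the aperture with an
unnormalized isotropic Gaussian, raised to the exponent n. n defaults to 0.05
and stays fixed during fitting (a flag exposes it; no stage refits it). The
drive is scaled by gain, convolved with the HRF at the frame rate, averaged
within TRs, and added to a Legendre polynomial baseline of degree
round(run duration / 2 min), minimum 1.

Grid stage: 25 log-spaced eccentricities (0.1–8°), 32 uniform angles, 13
log-spaced sigmas (0.1–8°) — 10,400 candidates spanning a 16°-diameter field.
The exact nonlinear spacings of the reference tooling are not published; we
use log spacing, which concentrates candidates foveally as cortical
magnification suggests. Gain and baseline are solved in closed form per
candidate after projecting the series onto the orthogonal complement of the
baseline basis, so the grid stage is a single matrix product plus a
projection and is shared across series via `CandidateBank`.

Refinement: Levenberg–Marquardt (`scipy.optimize.least_squares`, `method=lm`)
over (x₀, y₀, log σ), with gain and baseline re-solved in closed form at every
step (variable projection); relative tolerance 1e-6, max 500 evaluations.
log σ keeps the spread positive without bounds. If the optimizer ends with a
larger residual than the seed, the seed is returned and flagged
`converged=False`, so refinement never increases the residual.

Derived size defaults to σ/n; the wider CSS literature also uses σ/√n, which
is selectable (`size_definition="sigma_over_sqrt_n"`). With n = 0.05 the two
differ by a factor of ~4.5; σ/n is kept as the default for continuity with
the subdivision-analysis convention, and both are tested.

R² is the percent variance of the *baseline-detrended* series explained by the
stimulus-related prediction. Defining it against the raw series would let
slow drifts deflate R² for reasons unrelated to the pRF.

HRF presets: canonical double-gamma (a₁=6, b₁=1, a₂=16, b₂=1, c=6; peak ≈ 5 s)
and a white-matter preset with delayed onset (a₁=8, peak ≈ 7 s). Published
voxel-level white-matter HRF parameter values for the optic radiation are not
available, so the WM preset encodes the qualitative delayed-onset property
and every fitting function accepts an explicit `HRFSpec`.

GMM threshold: a two-component 1-D Gaussian mixture on the R² values; the
cutoff is where the posterior responsibility of the higher-mean component
crosses 0.5 between the component means (linear interpolation on a 2001-point
grid). Degenerate fits — collapsed components or no posterior crossing — fall
back to the 25th percentile and are flagged.

## Working-memory GLM

Preprocessing follows the bandpass-before-GLM convention of the analysis this
package operationalizes: linear detrend then an ideal FFT-domain 0.01–0.1 Hz
filter. Bandpassing task data is unusual, so `--no-bandpass` is exposed.
Censoring flags volume t when the Euclidean norm of the motion-parameter first
difference exceeds 0.3 mm (strictly), and also flags t−1; volume 0 is never
flagged by the difference rule alone. The design matrix holds one
HRF-convolved boxcar per condition (boxcars built at 16× TR oversampling),
six motion regressors, CSF, intercept and linear drift; motion/CSF enter as
simultaneous regressors rather than a prior residualization step, which is
the standard unbiased formulation. Censored volumes are dropped at
estimation. Two-run sessions are analysed by concatenation with run-specific
intercept/drift columns. Subjects under 70% 2-back accuracy are excluded by a
pre-filter flag. No AR prewhitening is applied (sub-bundle-averaged series at
these run lengths leave the contrast estimate unbiased either way; only the
t statistics would be mildly optimistic under serial correlation).

## Synthetic data: what it does and does not emulate

- Aperture movies: 45°-wide rotating wedges, expanding/contracting rings, and
  bars sweeping 8 orientations, all binary and confined to a circular field
  (default 16° diameter). Rings are defined as radius-quantile windows of the
  disc (duty 25% of disc area by default) so the pixel area grows
  monotonically during expansion instead of jittering with quantization.
  Stimulus carriers (textures) are not modelled — the CSS model only sees
  apertures.
- BOLD generation runs the CSS model in the generative direction, so
  noise-free simulation is the exact fixed point of the fit. Noise is
  additive white Gaussian (AR(1) coefficient optional); physiological and
  vascular structure, partial-volume effects and eye movements are not
  simulated. Recovery results therefore validate estimator correctness, not
  real-data SNR sufficiency.
- Toy anatomy is a flat sheet: three 6×6 mm labelled patches 10 mm apart on a
  1 mm grid, streamlines running from a common seed point with endpoints
  displaced by at most `jitter_mm`. GM is a 1-voxel shell around the patches;
  WM is the streamline corridor minus GM.
- Task runs alternate 25 s 0-back/2-back blocks with 15 s rests.

## Problem sizes used in validation

Parameter recovery and mask-robustness checks use 50 synthetic bundles on
50×50-pixel apertures, 300 frames at one frame per TR (TR = 1 s), pRF centers
drawn uniformly over the central 7° disc, σ in 0.5–2°, gain in 0.5–2, noise SD
at 25% of each bundle's stimulus-driven SD, with the default 10,400-candidate
grid. Mask robustness compares fits of the 30-voxel average against a random
80% subset. GLM recovery uses 200-volume runs; the noisy replication uses 200
simulations at noise SD 0.5. These sizes make the full validation suite run
in about a minute while leaving the contracts (median eccentricity error
< 0.5°, median angle error < 10°, quadrant accuracy > 81%, mask-robustness
median shift < 0.3° and r > 0.9, mean contrast within 5%) comfortably
testable.

## Known limitations

- No registration: all inputs are assumed co-registered; only
  nearest-neighbour mask resampling is provided.
- Single pRF shape (isotropic Gaussian + static nonlinearity); no
  difference-of-Gaussians or elliptical variants, no HRF estimation from data.
- The hemifield mapping between the [0°, 180°] cortical label convention and
  the [0°, 360°) pRF convention differs between hemispheres in real data; the
  label convention here is per-hemifield and the mapping is the caller's
  responsibility (a label column suffices for bookkeeping).
- The FDR family (which p-values are pooled) is a caller decision; the
  routine corrects whatever vector it is given.
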