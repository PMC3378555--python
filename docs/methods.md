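# Methods

This note documents the models, conventions, and numerical choices behind
`retinowm`, in the spirit of a package methods appendix: what is simulated,
what is estimated, which knobs matter, and what the tests do and do not
establish.

## Coordinate conventions

Polar angle is measured in degrees clockwise from the upper vertical
meridian, matching the clockwise wedge rotation, so quadrant 1 (0–90°) is
the display's upper-right quadrant and quadrants proceed clockwise.
Diagonally opposite pairs are Q1↔Q3 and Q2↔Q4. Eccentricity is degrees of
visual angle from fixation. Stimulus dots occupy four radii — 1.875, 3.75,
5.625, 7.5° — with 10 positions per quadrant (2/3/2/3 per ring, angles
evenly spaced strictly inside the quadrant so no dot sits on a cross arm).
The literature on this task also quotes the rounded radii 1.9/3.8/5.6/7.5;
the analysis values above are used throughout.

## Mapping protocol and phase model

A mapping run is 8 cycles of 54 000 ms at one volume per 540 ms (100
volumes per cycle), with 27 000 ms blank fixation before and after: 900
volumes. (Some descriptions of such protocols quote 800 images; 8×100
cycle volumes + 2×50 blank volumes is the arithmetic honored here, with the
volume count derived from the protocol object, not hard-coded.)

The modeled activation of a visual-field point is a boxcar of 7 200 ms per
cycle whose onset phase encodes position. The boxcar is quantized to
round(7200/540) = 13 volumes. The same 7 200 ms window is used for wedge
and ring runs even though the geometric dwell times of the two stimuli at a
point differ; it is the modeled quantity, and simulator and analysis
template use it identically. A voxel's simulated neural drive is this
cyclic vector at the lag nearest its ground-truth phase (i.e. receptive
fields are quantized to the 100-lag grid — a deliberate simplification
that makes noiseless phase recovery exactly testable), convolved with the
HRF, scaled by the voxel's gain, plus drift and noise.

Phase decoding: lag L maps to polar angle 360·L/100 (3.6° bins) and to
ring-center eccentricity linearly from 1.15° (inner edge 0.4° plus half the
1.5° ring width) at lag 0 to 7.5° at lag 100. Because the correlation
template is itself HRF-convolved, no separate hemodynamic delay correction
is applied to the peak lag. Blank lead/trail volumes are included in the
correlation window (the template is zero there pre-convolution).

## Hemodynamics and filtering

The HRF is the canonical double-gamma: gamma density with shape 6 minus
1/6 of a shape-16 gamma density (1 s time scale), sampled at the volume
interval over 32 s and normalized to unit peak. With this normalization
the convolved mapping response at unit gain has temporal SD ≈ 2.6 signal
units — the reference point for noise levels below.

Drift removal uses the mean plus an 8-component discrete-cosine basis
(DCT-II, orthonormal, the 8 lowest nonzero frequencies) projected out by
OLS; the filter is idempotent and is applied identically to data and
correlation templates. Eight components over a 486 s mapping run give an
effective high-pass cutoff of ~8/972 ≈ 0.008 Hz. (A printed cutoff of
8.2×10⁻¹ Hz appears in the source literature for this protocol; a high-pass
at 0.82 Hz is impossible at a 0.93 Hz sampling rate and would remove the
signal band, so the eight-cosine specification is honored and the cutoff
derived from it — presumably the printed exponent dropped a sign or digits.)

Boxcar edges snap to the volume grid with floor(onset) / ceil(offset);
zero-duration events are unit impulses at floor(onset).

## Significance mask

Per-voxel p-values use the correlation t-transform with df = N−2 on the
peak correlation, uncorrected for the maximization over 100 lags (the
common practice for this mapping style); the activation mask is
Bonferroni-corrected over voxels at α = .05. Because of the uncorrected
peak selection the mask is *optimistic* on pure noise — the test suite
quantifies the inflation with a max-over-lags Monte-Carlo oracle rather
than pretending nominal control. At realistic mapping SNR the signal
correlations (r > 0.4 over 900 volumes) are so far beyond threshold that
the optimism is immaterial; treat the mask as descriptive, not inferential.
Constant (zero-variance) voxels are flagged invalid and excluded.

## Task model

Trial structure (cross-dot task): fixation 1 000 ms → S1 300 ms → jittered
retention 3 000–8 000 ms (uniform on a 1 000 ms grid; only the range is
prescribed by the task, the grid is this package's choice) → S2 300 ms →
response window 2 000 ms → 10 000 ms inter-trial interval. Task volumes
every 1 500 ms. A session holds 80 trials: 40 match, 30 non-match, 10
catch. Each of the 40 positions serves as S1 exactly twice — once in a
match trial and once in a non-match or catch trial — the most even usage
the 40/30/10 composition permits (descriptions of the task also claim
every position appears twice as S2 and once in each trial type, which is
arithmetically unsatisfiable with this composition; the composition wins).

Match rules: categorical — S2 in the quadrant diagonally opposite S1 (the
other three quadrants are non-matches); coordinate — S2 on S1's ring, any
quadrant. The non-constrained stimulus feature is drawn at random.

Simulated BOLD: S1/S2 add impulse responses to the voxels of the
(quadrant, ring) cell containing the dot; during each retention interval a
sustained amplitude is added to all voxels of the matching region
(`delay_match_amp`) and of the mismatching region (`delay_mismatch_amp`).
Catch trials present S1 only; their retention window — in the simulator
*and* in the model — runs from S1 offset for the median jitter (5 500 ms),
keeping the two consistent so noiseless recovery is exact. Noise is white
Gaussian per voxel (optional AR(1) filtering at stationary variance and
linear+cosine drift).

## Regions, the concatenated GLM, and identifiability

For the categorical instruction the matching region is the opposite
quadrant and the mismatching region is the *two* remaining quadrants: S1's
own quadrant is excluded so residual stimulus activation is not attributed
to the delay-mismatch factor (a config switch restores it for sensitivity
analyses). For the coordinate instruction the matching region is S1's ring
and the mismatching region the other three rings; here the matching ring
coincides with S1's ring, so delay-match and S1 residual activation share a
segment and are separated only temporally (impulse vs boxcar) — an
identifiability limit inherent to the design, not an implementation
artifact.

Ring-segment boundaries sit at the midpoints between adjacent radii,
lower-inclusive at the boundary; eccentricities beyond the extreme radii
clamp to rings 1 and 4. Quadrant bins are half-open [lo, hi), 360° wrapping
to quadrant 1.

The GLM concatenates the four segment means (length 4 T) and fits one
design: delay-match and delay-mismatch boxcars (S1 offset → S2 onset)
placed only in the blocks of the trial's matching/mismatching segments;
S1 and S2 impulses in the block of the containing segment; one pooled
eccentricity modulator (S1+S2 impulses scaled by mean-centered dot radius
— a single modulator rather than separate S1/S2 modulators, chosen for
parsimony); per-block constants and DCT columns so baselines do not couple
across blocks. All neural columns are HRF-convolved within their block, so
no hemodynamic spill crosses a concatenation seam. Estimation is plain OLS
(no prewhitening), with rank checking that names collinear columns.

For the stimulus analysis, S2 events split into S2-in-matching-region vs
S2-in-mismatching-region columns (equivalently: match vs non-match trials).
For the ROI-reliability "contrast activation" analysis the stimulus events
are modeled as present-segment vs absent-segments columns and the contrast
is their beta difference; since this analysis crosses instructions with
both segmentations, the match/mismatch delay split can span all four
segments and would be collinear, so that design carries a single pooled
delay nuisance column instead.

## Group statistics

All group designs are fully within-subject and are tested via orthonormal
contrasts of the cell means: the sphericity-assumed univariate F, its
Greenhouse–Geisser correction (ε from the contrast covariance, clamped to
[1/q, 1]), and the multivariate Hotelling T² (exact F(q, n−q) under
normality). Both univariate and multivariate families are reported because
published within-subject F statistics follow either convention and they
differ for multi-df effects. The univariate branch is cross-checked against
statsmodels' AnovaRM in the test suite. Post-hoc match-vs-mismatch
contrasts are uncorrected paired t-tests with Holm-adjusted p-values
alongside. Degenerate inputs (constant tables) return F = 0 rather than
0/0; identical-condition paired tests return t = 0, p = 1.

## Default study conditions and problem sizes

- Voxel sheets: ≥16 voxels per area tile the 16 (quadrant × ring) cells;
  receptive-field centers keep a 5° margin from quadrant borders and a
  ~0.24° margin from ring midpoints so noiseless decoding is exact.
- Default voxel noise SD 3.0 signal units at unit gain → mean peak mapping
  correlation ≈ 0.65, typical of good phase-encoded mapping voxels. The
  "half-correlation" stress test uses noise SD 4.5 (r ≈ 0.5).
- Cohorts: 10 subjects, matching the task's typical sample size; behavioral
  accuracies default to 97% (categorical) and 81% (coordinate) with RT
  means 900/1080 ms, the task's published performance regime.
- Test/validation problem sizes, chosen to keep recovery estimates stable:
  480-voxel sheets (160/area) for phase-recovery rates; 500 Monte-Carlo
  replicates for GLM bias; 1 000 null cohorts of n = 10 for type-I
  calibration (the null is simulated at the beta-table level — subject
  random effect plus iid cell noise — since it calibrates the statistics
  stage); three 10-subject cohorts with 32 voxels/area for the
  V3-pattern-recovery check.

## What the generator does and does not emulate

Emulated: retinotopic tiling with ground-truth labels, cyclic mapping
responses, trial-locked transient and sustained delay responses with
instruction-dependent spatial targets, temporal autocorrelation and slow
drift, behavioral accuracy/RT differences between instructions.

Not emulated: actual checkerboard stimulus rendering, receptive-field
*size* (voxels are points, so no pRF spread or cortical point-spread
blurring across segment borders), cortical magnification in voxel density,
head motion, physiological noise structure, spatially correlated noise,
hemispheric organization, or eye movements. Passing recovery tests
therefore demonstrates the correctness and calibration of the estimation
chain under the stated generative model — not robustness to these
real-data complications; the real-data entry points (NIfTI + events TSV +
label tables) exist precisely so the chain can be applied where those
complications are present.

## Known limitations

- Simulated receptive-field phases are quantized to the 100-lag grid, so
  noiseless decoding is exact by construction; dequantizing would add
  ≤ half-bin (1.8° / 0.03°) truncation error, immaterial next to noise.
- The second-level F statistics of any particular published cohort are not
  reproducible without that cohort's raw data; the pipeline validates
  calibration and qualitative pattern recovery instead.
- OLS ignores serial correlation; with AR(1) noise enabled the betas stay
  unbiased but their nominal standard errors are mildly optimistic. The
  group tests operate on per-subject betas and are unaffected.
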