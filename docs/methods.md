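# Methods

`pdprog` implements a complete severity-trajectory prediction pipeline for
Parkinson's disease from resting-state fMRI: voxelwise feature maps (ReHo,
ALFF, fALFF), nuisance-confound handling, atlas-based regional feature
extraction, cohort assembly around MDS-UPDRS totals, and machine-learning
evaluation under nested cross-validation with permutation chance levels.
Because the clinical databases such a study draws on are not redistributable,
the package ships a synthetic-data generator whose ground truth (local
temporal coherence, in-band spectral power, and a linear severity model with
known noise variance) lets every stage be verified end to end.

## Imaging features

**ReHo.** Regional homogeneity of a voxel is Kendall's coefficient of
concordance W between the voxel's timeseries and those of its neighbourhood
(27 voxels including the centre by default; 7- and 19-voxel connectivities
are available). Each of the K series is rank-transformed over its n
timepoints (midranks for ties) and

W = 12 S / (K² (n³ − n) − K T),

where S is the sum of squared deviations of the per-timepoint rank sums from
their mean and T is the tie-correction term, included only under the
`midrank_tie_correction` policy. The default omits the correction, matching
classic ReHo implementations; both policies are exposed. Under independent
rankings E[W] = 1/K, which is the chance level the null tests check. Edge
voxels use the in-mask subset of the neighbourhood rather than being
dropped, so the map support equals the mask; voxels with fewer than
`min_neighbors` (default 2) in-mask neighbours, and all-constant
neighbourhoods (undefined W), are set to 0.

The map computation is vectorised: per-timepoint rank sums are accumulated
by shifting the rank volume over the neighbourhood offsets, which makes the
whole-volume map a few matrix operations rather than a per-voxel loop. Tests
verify it voxel-by-voxel against an independent brute-force implementation.

**ALFF / fALFF.** Each in-mask voxel is linearly detrended and band-passed
to 0.01–0.1 Hz. ALFF is the standard deviation of the filtered series; fALFF
divides by the standard deviation of the unfiltered series. The default
filter zeroes FFT bins strictly outside the band (inclusive edges); with
that filter, fALFF² equals the in-band power fraction of the detrended
series (Parseval), which is the identity the spectral tests assert. A
zero-phase order-2 Butterworth variant is available for sensitivity
analysis. The fALFF denominator defaults to the detrended series, making the
ratio a pure band-power fraction; the raw series is available as a variant.
The band must contain at least one FFT bin, which bounds the minimum series
length for a given repetition time.

**Z-scoring.** Participant-level maps are standardised within the brain mask
using the population (1/N) standard deviation; out-of-mask voxels are set to
0. The convention is pinned so tests are exact; at realistic mask sizes the
sample-SD alternative differs negligibly.

## Confounds and quality control

Nuisance signals (6 rigid-body motion parameters, tissue mean timeseries,
any component regressors) are concatenated into one design matrix and
removed from every voxel timeseries in a single joint OLS fit. An intercept
is always included, so residuals are mean-zero; the operation is idempotent
and residuals are orthogonal to every confound column, both asserted as
contracts. Rank-deficient designs are reported (with the near-collinear
column pairs) and handled by pseudoinverse.

Framewise displacement is the sum of absolute volume-to-volume changes of
the six motion parameters, rotations converted to displacement on a 50 mm
sphere. The default conversion is the arc-length approximation (radius ×
angle); a 2π·radius variant found in some method descriptions is exposed via
`rotation_scale`, and both conventions are covered by hand-computed tests.
Mean FD above 0.55 mm flags a participant for reporting; no volumes are
censored — FD is quality control only.

## Parcellation

Custom atlases are built by merging label images in order (for example a
100-ROI cortical parcellation followed by 28 cerebellar and 7 striatal ROIs
into a 135-ROI atlas), offsetting each part's labels by the cumulative label
count. Overlaps default to later-part-overwrites — the subcortical parts are
merged last and refine the cortical parcels — with the overlap volume logged
for audit; a first-wins policy is available because the right resolution is
genuinely ambiguous.

Label resampling is nearest-neighbour in world coordinates through both
affines. Exact half-distance ties resolve to the higher source index, the
convention under which doubling the resolution of a single-voxel ROI yields
the expected 2×2×2 block. Out-of-field target voxels become background, and
no new labels can be created. Regional features are plain within-label means
of the map; labels left empty after resampling propagate as missing values
and are median-imputed inside each training fold by the modelling layer,
never silently zeroed. Conservation (Σ region mean × voxel count = masked
map sum) is asserted against brute-force oracles.

Region naming for importance reports locates each ROI's world-space centroid
(affine-aware, not voxel indices) in a reference atlas; centroids falling in
reference background take the nearest labelled reference voxel, with exact
distance ties going to the lower label for determinism.

## Cohort logic

The prediction target is the MDS-UPDRS total: parts Ia + Ib + II + III + IV,
with a missing part-IV value counted as zero; a missing mandatory part is an
error naming the row. Follow-up visits match Year 1/2/4 when their date lies
within ±60 days of 365/730/1460 days after baseline; among several matches
the closest-to-target wins and exact ties go to the earliest visit. An
ON-medication filter drops motor-exam rows whose page name marks an
OFF-medication assessment.

Clinical/demographic encoding produces binary indicators (male sex,
right-handedness, right dominant side, tremor/rigidity/postural-instability
presence), integer codes for race and ethnicity from a shipped, overridable
code map, and pass-through continuous columns (age, education years, disease
and symptom duration, GDS, MoCA, and the baseline total when predicting
follow-up). The shipped code map is a documented stand-in — the original
study's exact encodings are not public — and is recorded in the feature
matrix's JSON sidecar together with per-column provenance
(imaging/clinical/demographic/baseline_score). Rows with missing continuous
values are excluded with a log entry rather than imputed. The high/low
severity threshold is the mean of the median total at the four time points.

## Evaluation

Four model families are supported: elastic net, linear-kernel SVR, random
forest, gradient boosting (scikit-learn implementations), each with a
documented default hyperparameter grid (elastic net: regularisation strength
× mixing ratio; SVM: cost; trees: size/depth/learning rate), overridable per
`ModelSpec`.

Two nested schemes share one code path. Per-combination (the default): for
each model family × parcellation, a 10-fold inner loop on the n−1 training
participants selects the grid point with the lowest mean RMSE, which is
refit on all training participants to predict the held-out participant of
the leave-one-out outer loop. Joint: the inner loop searches model family ×
hyperparameters × parcellation at once and the single winner predicts the
held-out participant; with one family and one parcellation it reduces
bitwise to the per-combination scheme, which is tested. A fixed-model mode
evaluates one named family × parcellation. R² and RMSE are computed on the
pooled out-of-fold predictions (per-fold R² is undefined for LOO); the
inner-loop score is the mean of per-inner-fold RMSEs.

Leakage contract: median imputation and standardisation of continuous
columns (indicators pass through raw) are fit on the training participants
of each fold only, and every random seed fans out from one master seed by a
counter-based scheme keyed on fold, family and permutation indices — never
on data. The contract is asserted by mutation tests: perturbing a held-out
target leaves its prediction bitwise unchanged under both schemes.

Chance level is the distribution of pooled R² after permuting the targets,
with a fixed elastic-net model and 5-fold outer and inner loops. Out-of-
sample R² under permuted labels is non-positive in expectation, which the
tests check within Monte-Carlo error.

Post-hoc severity classification thresholds predictions and truths at the
cohort-derived severity threshold; totals at or above the threshold are the
positive ("high severity") class — the ≥ convention is pinned here since
either reading is defensible. PPV/NPV/sensitivity/specificity come from the
2×2 table; AUC ranks the *continuous* predictions against the thresholded
truths (thresholded predictions would make the AUC degenerate).

Feature importance: signed coefficients for the linear families; impurity
importance signed by the univariate correlation of the (preprocessed)
feature with the training targets for the tree families; per-feature median
across the outer-fold fits, sorted by magnitude. Importances come from the
per-fold refits on the training participants, not from a final refit on
everyone.

## Synthetic data

The generator produces every input the pipeline consumes. Voxel timeseries
in region r follow

x_v(t) = √ρ_r · L_r(t) + √(1 − ρ_r) · ε_v(t),

with the regional latent L_r and the voxel-private ε_v both spectrally
shaped so that a fraction φ_r of their power lies in 0.01–0.1 Hz (in-band
and out-of-band Gaussian components built in the frequency domain, DC
excluded, unit variance, mixed √φ/√(1−φ)). ρ_r is the coherence ground
truth: at ρ = 1 all series in a region are identical (ReHo 1), at ρ = 0 they
are independent (mean ReHo 1/K); √φ is the fALFF ground truth. Motion traces
are Gaussian random walks whose step SDs can be calibrated in closed form
(E|step| = sd·√(2/π)) to a target mean FD; the shipped study targets
0.258 mm, a typical value for an early-PD cohort.

Cohort totals follow a stated linear model: baseline total = intercept +
Σ β·(sample-standardised feature) + Gaussian noise, clipped to [0, 199] and
rounded; follow-up totals add α × baseline total plus their own imaging
terms. Betas are in score points per sample SD so variance contributions are
transparent. When a target R² is requested the noise SD is set in closed
form to sd(predictor)·√((1−R²)/R²), making the recorded theoretical R² =
explained/total variance exact up to rounding and clipping; a Monte-Carlo
regression over 10,000 simulated subjects confirms it within ±0.02. Totals
are decomposed into the five part scores with a fixed Dirichlet
(concentration 2, 2, 5, 10, 0.7 — the motor part dominates); part IV is
generated missing with probability 0.3, in which case it is generated as
zero so that the missing-to-zero rule reconstructs the total exactly.
Retention across Year 1/2/4 is enforced non-increasing (defaults mirror a
typical 82→51→41→30 attrition profile), and visit dates are jittered
uniformly within ±45 days so all synthetic visits fall inside the ±60-day
matching windows; out-of-window visits are constructed only in dedicated
fixtures. Demographic marginals (age ≈ 62 ± 10, two-thirds male, ~15.6
years of education, MoCA ≈ 26.7, GDS ≈ 5.4) mirror a typical early-PD
cohort.

The shipped study (`simulate_study`) uses 120 participants, a 12³ grid with
a 6-slab truth atlas plus a 12-region refinement, 120 timepoints at TR
2.4 s, per-participant regional ρ ~ U(0.1, 0.9) and φ ~ U(0.2, 0.8) (so the
extracted regional features carry between-participant signal), clinical
betas on disease/symptom duration, MoCA, GDS, age and tremor, imaging betas
on the truth-atlas ReHo means, and a theoretical baseline R² of 0.5. The
grid, series length and cohort size are fixture-scale choices — small
enough that the whole study regenerates deterministically from per-
participant seeds in seconds — not claims about real acquisitions.

**What the generator does not emulate:** anatomical structure, scanner
artifacts and physiological noise, spatial autocorrelation beyond the
regional latent, registration error, and site effects. Passing tests
therefore demonstrate that the pipeline's computations are correct and
leak-free and that it recovers known signal at realistic sample sizes; they
do not certify performance on real scanner data.

## Numerical choices and problem sizes

- Elastic-net fits use `tol=1e-3, max_iter=5000`: z-scored regional means
  are near-collinear (within-mask standardisation imposes an approximate
  linear constraint), where tiny-alpha coordinate descent converges very
  slowly at stricter tolerances; predictions are insensitive to the looser
  stop, verified bitwise against a plain leave-one-out oracle with a
  singleton grid.
- Inner-loop grid ties break to the first grid point in deterministic
  enumeration order; equidistant follow-up visits break to the earliest;
  centroid-naming distance ties break to the lower reference label.
- The ReHo chance-level check averages a stride-3 interior subsample:
  neighbouring ReHo values share voxels and are correlated, so a naive
  standard error over all voxels would be an underestimate; disjoint
  neighbourhoods give independent W values and a calibrated test.
- The default test suite and the acceptance script evaluate the shipped
  study with the four model families on the truth parcellation
  (leave-one-out, n=120, 10-fold inner); the joint scheme and
  multi-parcellation searches are exercised at smaller n. Permutation nulls
  use 100 permutations.
- All randomness derives from `numpy.random.SeedSequence` fan-out of one
  master seed; identical seeds give bit-identical studies, folds and
  reports.

## Known limitations

- Preprocessing upstream of denoising (motion correction, brain extraction,
  registration, ICA-based component estimation, tissue segmentation) is out
  of scope; tissue masks and motion traces are inputs. Alternative
  preprocessing pipelines are representable only as alternative
  confound/mask inputs.
- The categorical code map is a stand-in; analyses sensitive to the exact
  race/ethnicity/side encodings should override it.
- Whether the within-mask z-scoring matches the original study's (unshared)
  convention is unverifiable; within-mask was chosen and pinned.
- Importance values across model families are on different scales
  (coefficients vs impurity shares); only within-family rankings are
  meaningful.
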