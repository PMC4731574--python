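# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `fairmirror`, in the spirit of a statistical appendix.

## The design being emulated

The simulator reproduces the structure of a social action-observation
experiment. Each of 15 subjects completes three perception runs of 32
blocks; each block shows three stimuli of one type, crossing modality
(visual/auditory), content (action/control), and the confederate's
fairness role (fair/unfair). Acquisition is sparse: one volume is
collected in 1.23 s followed by 4.0 s of silence (stimuli play in the
gap), one stimulus per 5.23 s cycle, and consecutive blocks are separated
by three silent cycles (~16 s onset asynchrony within a block sequence).
Two odd-ball attention blocks per subject, plus any block with a button
press or error, are excluded from analysis.

Crucially, each subject sees one confederate per role, so identity,
shirt colour, and role are *confounded within subject*; the confederate→
role and confederate→colour mappings are counterbalanced *across*
subjects (exactly when the subject count is divisible by 4, to within one
subject otherwise).

### Odd-ball scheduling

Whether odd-ball blocks replaced or extended the 32-block runs is left
open by the design description, so both modes exist. `replace` (default)
flags existing blocks in place: 96 blocks per subject, 94 analyzable,
factor cells unbalanced by at most one block. `add` inserts extra blocks:
98 total, all 8 cells exactly 12 analyzable blocks. Downstream, the
balanced-averaging step subsamples every class to the smallest class size
before averaging, so either mode yields balanced examples.

## Planted signals

`SignalSpec` controls three orthogonal effects, all in the same units as
the noise standard deviation:

| parameter | default | meaning |
| --- | --- | --- |
| `shared_amplitude` | 1.0 | action>control offset inside `shared_region` (stand-in for shared perception/execution circuits) |
| `role_pattern_amplitude` | 0.5 | signed multivoxel pattern **w** (unit RMS in `role_pattern_region`), added as +A**w** to fair and −A**w** to unfair *action* blocks, identical in every subject |
| `confound_pattern_amplitude` | 0.5 | identity-linked patterns added to each identity's action blocks; orthogonalized against **w** (zero dot product) so role and confound amplitudes have independent meaning |
| `noise_sd` | 1.0 | white Gaussian noise per block image |
| `smooth_fwhm_mm` | 4.0 | FWHM of an additional spatially smoothed noise component |
| `subject_offset_sd` | 0.5 | per-subject constant random offset field |

Role and confound patterns ride on the *action* conditions only, so they
survive the action−control subtraction used to build classification
examples. The confound patterns emulate whatever distinguishes the two
confederates (face, hands, colour); because the identity→role mapping is
counterbalanced, they carry no role information across subjects.

A block's parameter-estimate image is then
`template + subject offset + smoothed noise + white noise`. This beta-level
shortcut stands in for first-level output; the time-series route
(`simulate_timeseries` → `build_design_matrix` → `fit_glm`) forward-
generates sparse-sampled series from known coefficients and is used to
validate the GLM stage (zero-noise recovery is exact to machine
precision; parameter recovery at noise 0.5 is unbiased to <2%).

The execution localizer needed by the shared-voxel conjunction is not
simulated at the time-series level; `simulate_execution_maps` emits
synthetic per-subject contrast maps (shared-region effect + noise), which
is sufficient to exercise and test the conjunction logic.

## First-level model

- **HRF**: canonical double gamma — gamma(6,1) minus gamma(16,1)/6,
  truncated at 32 s, positive lobe normalized to unit sum; sampled at a
  0.1 s microtime grid. The positive-lobe mode is at 5 s.
- **Design**: block boxcars (block duration = 3 stimulus cycles)
  convolved at the microtime grid and sampled at acquisition *midpoints*
  (sparse sampling makes slice-timing irrelevant). `per_condition` mode
  yields one regressor per cell per run; `per_block` one per analyzable
  block; flagged blocks pool into a single nuisance regressor. Sampling
  agrees with a dense dt = 0.01 s convolution oracle to within 0.03.
- **High-pass**: cosine drift columns per run with periods ≥ the cutoff,
  where the cutoff is 110% of the maximum stimulus onset asynchrony
  between same-cell blocks. Drift columns are an OLS-equivalent
  alternative to pre-filtering with a simpler contract.
- **Fit**: per-voxel OLS; rank deficiency is detected by pivoted QR and
  reported with the offending column names; residual variance = RSS/df.
- **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in
  voxel units, reflecting boundaries (conserves the volume sum and avoids
  edge darkening on small volumes). Applied only on the univariate path
  (6 mm default); MVPA uses unsmoothed images.

## Second-level statistics

One-sample t against zero with df = n−1; zero-variance voxels are NaN and
excluded from multiple-testing pools. All map thresholds are one-tailed
(the t > 2.98 ⇔ p < .005 at df = 14 identity fixes the convention). FDR
is the classic Benjamini–Hochberg step-up on the voxelwise p values — the
independence-assuming form standard in neuroimaging — returning both the
mask and the data-dependent cutoff p(k). The t→z conversion matches upper
tail probabilities through log-space (`ndtri_exp∘logsf`), stable far past
p = 1e-10. Clusters are connected components (default 18-connectivity,
configurable 6/26) with ≥ `min_size` voxels, reported with peak voxel
value and unweighted centre of mass in mm through the volume affine.

The shared-voxel mask intersects (i) perception voxels surviving FDR at
q = .05 with (ii) execution-localizer clusters at p < .001 uncorrected,
≥ 10 voxels; the minimum-size filter is applied to the conjunction last
by default (applying it to the perception map first is exposed as an
option, since either order is defensible).

## MVPA

Examples are built per subject: block images centered to an across-voxel
mean of zero, averaged per condition after random subsetting to the
smallest class (seeded), and reduced to fair/unfair action−control
subtraction images — one example per class per subject, so chance is
exactly 0.5. All preprocessing is per-subject, so leave-one-subject-out
folds cannot leak statistics across the train/test boundary.

The classifier is a linear SVM with hinge loss and fixed cost c = 1,
solved by libsvm through scikit-learn's bundled low-level binding (the
estimator wrapper adds ~30× call overhead, which matters inside
permutation loops); the test suite asserts prediction-level equivalence
with `sklearn.svm.SVC(kernel="linear")` on random problems. Determinism:
examples are canonicalized (sorted by subject, then label) before
fitting, and a decision value of exactly zero predicts the
lexicographically first class — degenerate inputs (e.g. identical
patterns in both classes) therefore score exactly 0.5 on balanced test
sets instead of failing.

Searchlights are Euclidean lattice balls: all integer offsets with
‖δ‖ ≤ r, clipped to the analysis mask, with no minimum-occupancy rule; a
radius of 3 voxels gives 123 offsets. (Descriptions of comparable
analyses sometimes cite different counts for a "3-voxel/6 mm" sphere —
e.g. 263 — which no lattice-ball definition reproduces; the shape is
therefore configurable via explicit offset lists and the ball is the
default.)

## Permutation inference

The exchangeability unit is the subject: a relabeling scheme flips (or
not) the two class labels of each subject and travels with the subject
into both train and test roles. Schemes are sampled uniformly without
replacement from the 2ⁿ−1 non-identity flip vectors (all of them, with a
warning, if fewer than m exist). p = (1+b)/(1+m) where b counts null
accuracies ≥ the observed one, so p ≥ 1/(m+1) — .001 at the m = 1000
default — and ties count against the observed value. Searchlight maps
reuse one scheme list across all centres, preserving the spatial
structure of the null map. ROI families use Bonferroni (min(1, p·k)).

Under a fully null generator the ROI permutation p values are uniform
(the calibration suite checks the fraction below .05 over 200 simulated
datasets at m = 100).

### Below-chance accuracy under confound-only data

With the role amplitude at zero and confounds planted, between-subject
accuracy is not merely at chance — its expectation sits slightly *below*
0.5 (measured ≈ 0.42–0.47 depending on scale). The mechanism: with 15
subjects the counterbalance cells split 8/7, so folds holding out a
minority-pairing subject train on a composition whose majority associates
the confound patterns with the opposite role, and the margin classifier
systematically anti-predicts the held-out subject. This "anti-learning"
is the mirror image of leakage — confounds can only push between-subject
accuracy *down*, never up — and is precisely why inference here uses the
permutation null (which shares the bias) rather than a binomial test
against 0.5. Within-subject partitioning on the same data classifies far
above chance, demonstrating the leakage that leave-one-subject-out
partitioning removes.

## Problem sizes and determinism

Simulation-heavy tests run at desk scale, chosen once: a 12×12×8 voxel
volume (2 mm voxels, affine centred at 0 mm) with 16 blocks per run for
MVPA/permutation datasets, 10×10×6 with 8 blocks per run for the
200-dataset calibration suite, and the full 24×24×18 / 32-block design
for the univariate shared-voxel analysis. Geometry is carried by an
affine throughout, so coordinate reporting is scale-independent. Every
random draw flows through explicit integer seeds (per-purpose seeds are
derived by hashing a master seed with a tag); equal seeds give
bit-identical outputs, recorded with checksums in the pipeline manifest.

## What the synthetic data does and does not show

The generator captures the design's factorial and counterbalance
structure, sparse timing, planted univariate and multivoxel effects, and
Gaussian (white + smoothed) noise with subject offsets. It does not model
hemodynamic nonlinearity, physiological or motion artifacts, anatomical
variability, or realistic spatial covariance beyond smoothing. Passing
tests therefore validate the *analysis machinery* — estimator
correctness, calibration, confound logic — not the detectability of any
effect in real data.

## Known limitations

- The execution localizer is a contrast-map-level stand-in, not a
  simulated motor task.
- OLS without prewhitening ignores temporal autocorrelation; harmless for
  the white-noise generator, optimistic for real sparse-sampled series.
- `p_value`s from permutation are granular (multiples of 1/(m+1)); small
  m makes thresholded maps blocky.
- The searchlight loop is pure Python over centre voxels; it is fast at
  desk scale but not optimized for full-brain grids.
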