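# fairmirror

Does the brain's action-observation machinery respond differently when we
watch the hand actions of someone we consider *fair* versus someone we
consider *unfair*? Answering that question with fMRI requires an unusual
analysis: confederate identity, shirt colour, and fairness role are
perfectly confounded *within* any one participant (each participant saw one
person per role), but counterbalanced *across* participants. Within-subject
decoding of "role" could therefore succeed for entirely uninteresting
reasons (shirt colour), and only **between-subject** analyses — training a
classifier on n−1 participants and testing on the held-out one — can
isolate a fairness-linked signal.

`fairmirror` is a tested, reusable Python implementation of that analysis
pipeline, exercised end to end on a synthetic multi-subject dataset
generator that emulates the experimental design, for methodologists who
want to study (or teach) between-subject MVPA, permutation inference, and
the confound structure of social-fMRI block designs without any scanner
data.

## What it implements

- **Synthetic data** (`fairmirror.simulate`): a 2 (visual/auditory) × 2
  (action/control) × 2 (fair/unfair) block design, 3 runs × 32 blocks of 3
  stimuli, sparse-sampling acquisition (1.23 s scan burst + 4 s silence),
  odd-ball attention blocks, per-subject confederate counterbalancing, and
  planted signals: a univariate action>control region, a shared multivoxel
  role pattern ±A·**w** (fair/unfair), and identity-linked confound
  patterns orthogonal to **w**.
- **First-level GLM** (`fairmirror.glm`): canonical double-gamma HRF,
  boxcar convolution sampled at sparse acquisition midpoints, per-block or
  per-condition designs with a pooled nuisance regressor, cosine high-pass
  drift at 110% of the maximum same-type SOA, per-voxel OLS
  (β̂ = (XᵀX)⁻¹Xᵀy), and FWHM-parameterized Gaussian smoothing.
- **Second-level statistics** (`fairmirror.univariate`): one-sample
  t-tests (t = m̄/(s/√n), df = n−1), one-tailed p values,
  Benjamini–Hochberg voxelwise FDR, t→z tail-matching conversion
  (z = Φ⁻¹(1 − p_t), computed in log space), connected-component clusters
  (6/18/26-connectivity) with peak and centre-of-mass coordinates in mm,
  and the shared-voxel conjunction (perception FDR mask ∩ execution
  localizer mask).
- **MVPA** (`fairmirror.mvpa`): across-voxel centering, balanced
  averaging (random subsetting to the smallest class), action−control
  subtraction images, linear SVM (c = 1) with leave-one-subject-out
  folds, ROI accuracies, and lattice-ball searchlight accuracy maps.
- **Permutation inference** (`fairmirror.permutation`): per-subject label
  relabelings applied identically in train and test (the exchangeability
  unit is the subject), p = (1+b)/(1+m) with a .001 floor at m = 1000,
  and Bonferroni adjustment over ROIs.
- **IO + pipeline + CLI** (`fairmirror.io`, `fairmirror.pipeline`,
  `fairmirror.cli`): NIfTI-1 volumes, TSV schedules and cluster tables, a
  seeded end-to-end pipeline with a JSON manifest (seeds, thresholds,
  checksums, timings), and a `fairmirror` command with `simulate`, `glm`,
  `univariate`, `mvpa`, `permute`, and `all` subcommands.

## Worked example

Simulate 15 subjects with a moderate planted role pattern, build the
per-subject fair/unfair subtraction images, and test the role-region ROI
with a leave-one-subject-out SVM and 1000 subject-level relabelings:

```python
from fairmirror.config import SimConfig, default_signal_spec
from fairmirror.pipeline import simulate_role_examples
from fairmirror.mvpa import loso_folds, roi_accuracy
from fairmirror.permutation import roi_permutation_test, bonferroni_adjust

sim = SimConfig(n_subjects=15, volume_dims=(12, 12, 8),
                blocks_per_run=16, error_rate=0.0)
spec = default_signal_spec(sim, role_pattern_amplitude=1.0)
examples = simulate_role_examples(sim, spec, seed=7)
folds = loso_folds(examples.subject_ids)
result = roi_permutation_test(examples, folds, spec.role_pattern_region,
                              m=1000, seed=8)
p_bonf = bonferroni_adjust([result.p_value], 6)[0]
print(f"role-region ROI: accuracy={result.observed:.3f}  "
      f"p={result.p_value:.3f}  p_bonferroni={p_bonf:.3f}  "
      f"(m={result.m} relabelings, chance=0.5)")
```

Output:

```
role-region ROI: accuracy=1.000  p=0.001  p_bonferroni=0.006  (m=1000 relabelings, chance=0.5)
```

The held-out subject is classified perfectly in every fold because the
planted role pattern is shared across subjects; the permutation p value
sits at its floor 1/(m+1) ≈ .001, and survives a six-ROI Bonferroni
correction. Setting `role_pattern_amplitude=0.0` (confound patterns only)
drops between-subject accuracy to chance while *within-subject*
partitioning on the same data still classifies well above 0.5 — the
leakage that makes leave-one-subject-out folds mandatory for this design.

The same machinery runs from the shell:

```bash
fairmirror all --out out/ --seed 1 --m-permutations 200
```

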