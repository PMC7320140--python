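# tmsnet

Behavioral effects of non-invasive brain stimulation differ widely between
people. One candidate explanation is that the outcome of a focal
perturbation depends on the functional network state the brain is in.
`tmsnet` implements an inference chain for testing that idea at the
individual level: it asks which voxels' functional-connectivity state
explains between-subject variation in the behavioral effect of inhibitory
(1 Hz) right-parietal rTMS on visuospatial target detection, using
whole-brain voxel-wise features and a sparse association model.

The chain, end to end:

1. **Cleaning** — per subject and session, voxel BOLD series are residualized
   on 13 confound series (6 motion, 4 white-matter, 3 CSF), linearly
   detrended, and band-pass filtered (Chebyshev Type 1, order 8, 0.01–0.1 Hz,
   zero-phase).
2. **Connectivity features** — Fisher z-transformed Pearson correlations
   between all voxel pairs; negative links deleted; each voxel summarized by
   its mean intra-hemispheric and cross-hemispheric connectivity (2V
   regressors).
3. **Preselection** — keep voxels with |r| ≥ 0.1 to the stimulated-site seed
   in an independent reference map, then drop columns below the 20th
   percentile of across-subject mean connectivity within each link class.
4. **Association model** — elastic net

   min<sub>β₀,β</sub> (1/2N) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ Σⱼ [ (1−α)/2 βⱼ² + α|βⱼ| ]

   fit by coordinate descent over 100 log-spaced λ ∈ [0.01, 0.61] and
   α ∈ {0.1, …, 0.9, 0.99}, where y is the per-subject change in
   bilateral-target accuracy (TMS − sham).
5. **Inference** — leave-one-subject-out cross-validation (fold-wise
   standardization), λ* by minimum prediction error, R²_cv against the
   intercept-only model, one-sided permutation tests of the error reduction
   (selection-aware sign-flip of the paired fold errors), and a consistency
   analysis of which regressors are selected by *every* significant model.
6. **Behavioral / confound statistics** — repeated-measures ANOVA of
   accuracy, permutation correlation tests, sequential (type-I) ANCOVAs for
   motor threshold / head motion / administration order, and partial
   correlations controlling post-TMS accuracy.

No public dataset accompanies the original analysis, so the package ships a
first-class synthetic cohort generator that plants a known
connectivity→behavior effect in the post-TMS session (and only there),
with realistic dimensions (20 subjects, 400 voxels, 527 rest / 781 task
volumes at TR 1.5 s), nuisance contamination, anticorrelated region pairs,
and trial-level behavior. Every statistical claim in the test suite is made
against that generator's ground truth. See `docs/methods.md` for the model,
the generator's calibrated operating point, and all pinned conventions.

## Worked example

```bash
tmsnet simulate --out cohort/ --seed 1 --subjects 20 --voxels 400
tmsnet fit --cohort cohort/ --out results.json --b 10000 --seed 1
```

which prints:

```
sham: significant=False best p=0.8918 at alpha=0.1
tms: significant=True best p=0.0032 at alpha=0.1
tms_minus_sham: significant=False best p=0.9731 at alpha=0.3
```

Read: the post-TMS connectivity state explains the individual behavioral
TMS effects (permutation p ≈ 0.003 against the intercept-only model), while
connectivity after sham stimulation and the TMS-induced *change* in
connectivity do not — the planted condition pattern.
`results.json` contains the per-alpha p-values, the full (α, λ) R²_cv
surface, the λ* per alpha, the consistency intersection (regressor columns
selected by every significant model, here voxels of the planted informative
regions), the behavioral ANOVA table, and the confound ANCOVAs.

The same stages are importable as a library:

```python
from tmsnet import (CohortConfig, generate_cohort, run_condition_scan,
                    build_feature_table)
from tmsnet.pipeline import preprocess_cohort
from tmsnet.behavior import summarize_behavior

cohort = generate_cohort(CohortConfig(seed=1), conditions=("sham", "tms"))
clean = preprocess_cohort(cohort, ("sham", "tms"))
tables = {c: build_feature_table(clean, c)
          for c in ("sham", "tms", "tms_minus_sham")}
y = summarize_behavior(cohort.behavior).effect_vector("bilateral")
scan = run_condition_scan(tables, y.to_numpy(), seed_map=cohort.seed_map,
                          b=100_000, seed=1)
```

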