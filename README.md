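# sesimclr

Identifying students who lack mathematical education from structural brain
MRI is a weakly-supervised, multi-instance problem: each subject contributes
a 20×20×20-voxel volume of interest (VOI) from the left middle frontal gyrus
(MFG), viewed as a bag of 20 two-dimensional slices whose individual labels
are only weakly informative.  `sesimclr` implements a complete workflow for
this setting:

1. **Subspace-enhanced contrastive learning (SeSimCLR).**  A ResNet-style
   encoder *F* and projection MLP *G* are trained self-supervised on slice
   pairs (T₁(x), T₂(x)) drawn from one augmentation family, minimizing

   L = L₀ + ρ·L₁,

   where L₀ is the NT-Xent contrastive loss over a batch of 2N projections,

   L₀(zᵢ, zⱼ) = −log [ exp(sim(zᵢ, zⱼ)/τ) / Σ_{k≠i} exp(sim(zᵢ, z_k)/τ) ],

   with cosine similarity `sim` and temperature τ, and L₁(zᵢ, zⱼ) =
   max_k |zᵢ − zⱼ|_k is a subspace penalty that drives the two views'
   projections to put their mass on the same coordinates (trade-off ρ,
   default 0.01).  Setting ρ = 0 recovers plain SimCLR exactly.
2. **Per-slice-ID classification.**  Twenty sigmoid MLPs H₁…H₂₀ are trained
   on the frozen projections — classifier *i* only ever sees slice-ID-*i*
   instances — by minimizing mean squared error to the inherited student
   labels.
3. **Ensemble voting.**  A student's 20 hard slice labels l₁…l₂₀ are summed;
   the student is called non-math (class 1) iff Σ lᵢ > 10.  The vote
   fraction Σ lᵢ / 20 is the student-level ROC score.

Evaluation follows the study protocol: subject-level five-fold
cross-validation, confusion-matrix metrics at both the image and the student
level, rank-based AUC, per-slice-ID accuracy profiles, probability
histograms, paired fold-wise t-tests, and a PCA→t-SNE embedding map with a
single-layer linear probe.  A synthetic cohort generator reproduces the
study's structure (72 math + 51 non-math subjects, 20 slices each, a
slice-dependent class signal) so the whole pipeline runs and is tested
without any imaging data.

## Worked example

```python
import sesimclr as s

cohort = s.generate_cohort(s.CohortConfig(n_math=23, n_nonmath=17, seed=1))
result = s.run_cross_validation(cohort, s.tiny_config(seed=101))

st = result.student_table
print("student accuracy:", round((st.pred == st.label).mean(), 3))
print("student AUC:     ", round(s.roc_auc(st.score, st.label), 3))
psa = s.per_slice_accuracy(result.slice_table)
print("easy slices 13-19:", round(psa.loc[13:19].mean(), 2))
print("hard slices 1,2,9,20:", round(psa.loc[[1, 2, 9, 20]].mean(), 2))
```

prints

```
student accuracy: 0.925
student AUC:      1.0
easy slices 13-19: 0.94
hard slices 1,2,9,20: 0.44
```

i.e. on a 40-subject synthetic cohort the cross-validated ensemble recovers
the planted group signal at the student level (majority-class rate 0.575),
and the per-slice accuracy profile mirrors the configured effect profile:
slice IDs 13–19 carry a strong signal and classify well, IDs 1, 2, 9 and 20
carry none and sit at chance.  The same run through the shell:

```bash
sesimclr simulate --out cohort/ --n-math 23 --n-nonmath 17 --seed 1
sesimclr cv --manifest cohort/manifest.csv --variant tiny --out run/ --seed 101
sesimclr sweep --manifest cohort/manifest.csv --variant tiny \
    --rhos 0,0.01 --out sweep.csv --seed 101
```

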