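# morphorad

Deformation-based morphometry (DBM) and quantitative MRI mapping for
two-group longitudinal rodent brain studies — built around the question of
where healthy brain tissue is vulnerable to fractionated whole-brain
irradiation, and whether macrostructural change tracks microstructural
change.

The package takes a cohort of 3D MRI sessions (anatomical T2w, 30-direction
DWI, pre/post-contrast T2\*) and produces:

- **log-Jacobian maps** — each subject's T2w is registered (rigid MI +
  greedy LNCC demons) to a per-timepoint mean-control template; the
  deformation Φ(x) = x + u(x) yields J = det(I + ∇u), the local volume of
  the subject relative to the template, analysed as log J (>0 expansion,
  <0 contraction);
- **signed significance clusters** — voxel-wise two-group comparison with
  family-wise error control by maxT label permutation (variance-smoothed
  pseudo-t statistic), clusters signed by direction and reported as
  percentages of brain volume;
- **atlas-resolved structures** — a label atlas rigidly mapped into
  template space names the majority structure under each cluster;
- **quantitative maps** — diffusion-tensor scalars MD = tr(D)/3, AD = λ₁,
  RD = (λ₂+λ₃)/2 (μm²/s) from log-linear least squares, and steady-state
  cerebral blood volume CBV(%) = 100·(3/4π)·ΔR2\*/(γ·Δχ·B₀) with
  ΔR2\* = ln(S_pre/S_post)/TE;
- **ROI statistics** — per-subject means in the DBM-defined regions, feeding
  group×time ANOVA (Type II) with Fisher LSD post-hocs and Pearson
  correlation matrices with Fisher-z p-values (z = atanh(r)·√(n−3)).

Because no public dataset accompanies the problem, the package ships a
**synthetic phantom generator** (`morphorad.phantom`, `morphorad.cohort`)
that produces full cohorts — textured tissue anatomy, planted Gaussian-blob
volume changes with closed-form Jacobians, tensor-generated DWI,
susceptibility-contrast T2\* pairs, bias fields and Rician noise — so every
pipeline stage is testable against exact ground truth. See
`docs/methods.md` for the models and all numerical choices.

## Worked example

The `analysis/` scripts run the full synthetic study (9 controls vs 7
irradiated at 1 and 6 months; corpus-callosum contraction + MD drop planted
at 1M, cortical expansion + CBV drop at 6M):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_run_dbm.py --seed 0
python analysis/03_roi_statistics.py
```

which prints (seed 0; the whole chain takes about two minutes):

```
1M: 1 clusters; significant voxels -0.73% / +0.00% of brain; largest cluster
    negative (irradiated < control), majority structure: corpus_callosum
6M: 1 clusters; significant voxels -0.00% / +4.29% of brain; largest cluster
    positive (irradiated > control), majority structure: cortex

=== ROI DBM-1M (32 subject-sessions) ===
  JD: p(group)=0.00161 p(time)=0.00123 p(interaction)=6.62e-05
  MD: p(group)=1.46e-23 p(time)=1.33e-22 p(interaction)=4.94e-23
  ...
  anchored JD@1M: CBV@6M: r=+0.83 (p=1.54e-05)  MD@1M: r=+0.86 (p=3.53e-06)

=== ROI DBM-6M (32 subject-sessions) ===
  ...
  anchored JD@6M: CBV@6M: r=-0.91 (p=5.41e-08)  MD@1M: r=-0.85 (p=7.11e-06)
```

Reading: at 1M the only surviving cluster is *negative* (irradiated volume
below control) and sits in the corpus callosum; at 6M the cluster is
*positive* (expansion) and cortical — the planted structure-level pattern,
recovered end-to-end from the images. The ROI statistics show the planted
microstructural effects (group×time interactions for MD and CBV) and the
severity-driven couplings: in the corpus-callosum ROI, early volume change
tracks early MD (r = +0.86, both fall together); in the cortex ROI, the
late expansion runs opposite to early MD (r = −0.85) and late CBV
(r = −0.91). Cluster tables, ANOVA/LSD tables and correlation matrices are
written under `results/`.

The same stages are available as a CLI (`morphorad simulate | mask |
biascorrect | template | register | jacobian | dbm-stats | atlas-overlap |
dti | cbv | roistats | run`) and as plain library calls.

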