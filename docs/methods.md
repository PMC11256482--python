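# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `morphorad`, a deformation-based morphometry (DBM) and
quantitative MRI pipeline for two-group longitudinal rodent brain studies,
together with the synthetic phantom machinery used to validate every stage
against analytic ground truth.

## The scientific problem

Fractionated whole-brain irradiation produces delayed injury to healthy
brain tissue. DBM detects the resulting *macrostructural* change without any
tissue segmentation: every subject's anatomical T2w image is registered
non-linearly to a mean-control template, and the Jacobian determinant of the
template→subject mapping Φ(x) = x + u(x),

    J(x) = det(I + ∇u(x)),

measures the local volume of the subject relative to the template (J > 1:
the subject's tissue is locally larger; J < 1: locally smaller). Analysis is
performed on log J, which is zero at identity, symmetric between expansion
and contraction, and additive under composition of deformations (natural
log). Voxel-wise two-group comparison of log J maps with family-wise error
control yields signed clusters of significant change; a label atlas names
the structures beneath them. *Microstructural* correlates come from
quantitative maps — diffusion-tensor scalars (MD, AD, RD) and steady-state
cerebral blood volume (CBV) — extracted in the DBM-defined regions and fed
to group×time ANOVA and correlation analyses.

## Synthetic phantom and cohort generator

No public dataset accompanies this problem, so the package ships a
generator whose outputs have exact, analytic ground truth.

**Anatomy.** A 3D ellipsoidal "brain" with four tissue classes — cortex
shell, striatum (two deep ellipsoids), a corpus-callosum slab, and
ventricles — on a default 64×64×48 grid at 0.25×0.25×0.5 mm (twice the
in-plane spacing of a typical rodent T2w-RARE acquisition). Intensities are
T2w-like class means (CSF bright, white matter dark); geometry is defined in
world mm as fractions of the field of view, so coarser grids keep the same
physical anatomy. An optional *fixed* intra-tissue texture
(`texture_amplitude`, default 0) multiplies the class means by a smooth
random field that is part of the anatomy (identical for all subjects).
Without texture, piecewise-constant tissue makes interior deformation
unobservable to any registration algorithm — image forces exist only at
edges — so cohort simulations enable it (amplitude 0.15, correlation length
1 mm); with it the phantom behaves like real tissue, which carries intensity
microstructure everywhere.

**Planted deformations.** Focal volume changes are Gaussian-radial blobs

    u(x) = a (x − c) exp(−‖x − c‖² / 2σ²),   a = r^{1/3} − 1,

whose Jacobian at the centre is exactly the prescribed `volume_ratio` r, and
whose full Jacobian field has a closed form (the analytic evaluator is
returned next to the field). A planted r is always the Jacobian of the
*template→subject* map — the quantity registration is expected to recover —
so subjects are synthesised by pulling the phantom back through the
*numerically inverted* blob field (fixed-point iteration on
v(y) = −u(y + v(y)), exact to <1e−9 mm with the analytic closure). The blob
field is resolvable by a discrete deformation field only when σ spans at
least ~4 voxels; the finite-difference Jacobian of the generated field
matches the analytic one to <1e−3 in that regime.

**Degradation model.** Each subject-session applies, in order: subject-
specific anatomical jitter (weak random blobs, ~1% local volume, the
between-animal anatomical variability), a per-session rigid pose
(SD 1°/0.2 mm), an acquisition point-spread blur (`psf_fwhm_mm`, default 0;
the cohort studies use 1.2 mm — without a PSF the sub-voxel rendering of
sharp tissue edges differs with pose and masquerades as anatomical
variability), a smooth multiplicative bias field (random quadratic,
peak ±`bias_amplitude`), and Rician magnitude noise
√((s+n₁)² + n₂²), n₁,n₂ ~ N(0, σ) — the physically correct MR magnitude
model, Rayleigh-distributed where signal is zero. DWI signals follow the
monoexponential tensor model S = S₀ exp(−b gᵀDg) over 30 golden-angle unit
directions at b = 0/1000 s/mm² (five b0 images); per-tissue tensors are
isotropic except the corpus callosum (eigenvalues 1.5/0.394/0.394 ×10⁻³
mm²/s, principal axis +x), chosen so baseline MD values match the control
group means of the motivating study (e.g. CC ≈ 762 μm²/s). T2* pairs follow
the steady-state susceptibility model below with per-tissue baseline CBV
(cortex 6.83%, CC 3.20%, striatum 5%).

**Longitudinal cohorts.** Subjects are generated for each timepoint (1M,
3M, 6M by default) with jitter fixed per subject and pose redrawn per
session. Irradiated subjects carry a latent severity s ~ U(0.8, 1.2) — the
inter-animal response spread to a controlled, uniform radiation dose — that
scales every planted effect on the log scale (ratio^s), coupling macro- and
microstructural changes across subjects. Default effects mirror the studied
condition: at 1M a corpus-callosum contraction (volume ratio 0.9) with an MD
drop (×0.769 in CC, ×0.767 in cortex); at 6M a log-symmetric cortical
expansion (ratio 1/0.9) and CBV drops (×0.74 CC, ×0.75 cortex). The default
effect radius is σ = 3 mm — a regional effect spanning ≥4–5 voxels at the
analysis resolutions used here while staying mostly within its structure.
Everything is reproducible byte-for-byte from a single integer seed.

## Pipeline stages

**Masking.** Otsu threshold → largest 26-connected component →
morphological closing (ball radius 2) → hole filling; deterministic, with a
user-supplied mask override. Whole-brain volume is the foreground count ×
voxel volume.

**Bias correction.** The masked log-intensity is modelled as a
piecewise-constant tissue term plus an order-2 (10-coefficient) polynomial
in normalised world coordinates. Tissue classes come from deterministic 1-D
k-means (k = 4, quantile-initialised); the polynomial is fitted by least
squares to the residual from the class means, and class assignment and fit
are alternated (4 rounds). The alternation has two basins — classes can
absorb a strong bias — so both the classify-first and plain-fit-first
initialisations are run and the lower within-class residual wins. The fitted
log-bias is mean-centred and divided out; the masked median is preserved
exactly. On an inhomogeneity-free image the correction is the identity.

**Affine registration.** Rigid/similarity/affine transforms act on world
coordinates (rotation about the volume centre). The similarity metric is
mutual information (32-bin joint histogram, Parzen-smoothed), maximised by
Powell's method over a shrink-factor pyramid (default 4×, 2×, 1×), with
acceptance-only updates per level. Because a Parzen histogram is flat within
a fraction of a bin, a final full-resolution *polish* maximises the global
correlation coefficient on a strided voxel subset; this supplies the
sub-voxel precision (self-registration residual <0.1°/0.05 mm at the
default resolution). Initialisation is by intensity centre-of-mass.

**Non-linear registration.** Greedy compositive demons: forces are the
ascent direction of the local normalised cross-correlation (window radius 2
voxels) with respect to the displacement, evaluated on the warped moving
image; updates are step-normalised (0.8 voxel max), Gaussian-smoothed
(σ_update = 1 voxel), composed (u ← δ + u∘(id+δ)), and the accumulated field
is smoothed again (σ_total, default 0.5 voxel). Positivity of det(∇Φ) over
the mask is enforced by step halving, so the output is always
orientation-preserving. Iteration stops early when the masked mean LNCC
fails to improve for 10 iterations; the best-metric field is kept. The
stored field maps template coordinates to subject coordinates (pull-back
resampling), composed with the affine initialisation.

The per-iteration field smoothing acts as a diffusion regulariser, so the
recovered log-Jacobian of a planted blob equilibrates at roughly 65–75% of
the planted amplitude at the cohort's noise level; recovery is symmetric
between contraction and expansion and unbiased (±0.02 log units at the blob
centre) for σ ≈ 4 mm effects with σ_total = 1 voxel. Group inference
consumes the *sign and location* of change and tolerates this attenuation;
absolute log J values from any diffusion-regularised method share it.

**Templates.** The mean-control template is the voxel-wise mean of
affine-aligned control images, re-aligned to the evolving mean
(`iterations`, default 2; 1 in the scaled study). Templates are built per
timepoint so ageing never enters the group contrast.

**Morphometry.** ∇u is computed by spacing-aware central differences
(one-sided at boundary faces) in voxel-index space and mapped through the
inverse of the affine's linear block, so oblique orientations are handled.
J = det(I + ∇u); log J clamps J below at 1e−6 with clamped and non-positive
voxels counted and reported. Before group statistics the log J maps are
Gaussian-smoothed (default FWHM 3 mm, matched to the expected effect
scale), standard practice for deformation-field noise.

**Voxel-wise statistics.** Pooled-variance two-sample t per masked voxel
(df = n₁+n₂−2, zero-variance voxels flagged as t = 0). Family-wise error is
controlled by maxT label permutation: for every group relabeling the
statistic map is recomputed and its maximum |t| recorded; the adjusted p of
a voxel is the fraction of relabelings whose maximum reaches its observed
|t|. Relabelings are enumerated exhaustively when C(n, n₁) ≤ n_perm, else
sampled with the observed labeling always included; if fewer than 1/α
distinct relabelings exist the attainable α floor is reported with a
warning. At the 10–16 residual degrees of freedom typical here, the plain-t
maxT null is dominated by variance-lucky voxels, so the permutation
statistic is by default a variance-smoothed pseudo-t (pooled variance map
Gaussian-smoothed within the mask, FWHM 6 mm): the standard small-sample
companion of permutation inference. The *same* statistic is recomputed for
every relabeling, so FWE control remains exact regardless; the exported
t-map is the plain Student t. Signed significant voxels are grouped into
connected clusters (26-connectivity default; 6/18 available), sorted by
size, and summarised as percentages of brain volume per sign — the
longitudinal cluster-proportion curve.

**Atlas naming.** The atlas's intensity reference is rigidly registered to
the study template; labels follow by nearest neighbour (no new label values
can appear). Cluster voxels are tallied against labels; each cluster reports
its overlap histogram and majority structure. The shipped atlas is the
phantom's own 5-label map plus a CSV naming table; any NIfTI label map with
such a table plugs in unchanged.

**DTI.** Log-linear least squares on ln S = ln S₀ − b gᵀDg (6 unique tensor
elements + intercept, one pseudoinverse for all voxels); voxels with any
non-positive sample are excluded and counted; the design must have rank 7
(≥6 non-collinear directions plus b0, satisfied by the 30-direction
protocol, which makes the fit exact at machine precision noise-free).
Eigenvalues are sorted descending; negative ones are flagged, with a clamped
copy kept separately. MD = tr/3, AD = λ₁, RD = (λ₂+λ₃)/2, exported in μm²/s
(×10⁶ from mm²/s) to match the field's reporting scale.

**CBV.** ΔR2* = ln(S_pre/S_post)/TE (s⁻¹; TE default 13 ms), then
CBV(%) = 100 · (3/4π) · ΔR2*/(γ·Δχ·B₀). The product γ·Δχ·B₀ is a single
calibration constant (defaults: γ = 2.675×10⁸ rad s⁻¹ T⁻¹, B₀ = 7 T,
Δχ = 1×10⁻⁷, giving signal drops of ~40% at cortical CBV); the contrast
agent's true Δχ is contrast-agent-specific and not publicly calibrated, so
absolute CBV agreement with any particular study is not claimed — formula
correctness and exact round-trip identity are.

**ROI statistics.** ROI means are arithmetic means over cluster or atlas
masks (NaNs excluded and counted; ROI provenance is recorded because
extracting means of the *same* modality that defined the cluster is
circular — cross-modality reads such as CBV/MD in a JD-defined cluster are
the intended use). Two-way ANOVA (group × time, interaction) uses a cell-
means linear model with Type II sums of squares (robust to the unbalanced
cells of real cohorts), followed by Fisher LSD group contrasts per timepoint
using the pooled residual MSE, uncorrected and two-sided (the LSD
convention). Pearson matrices are pairwise-complete; p-values use the
Fisher z transform, z = atanh(r)·√(n−3) against the normal tail (a
t-distribution alternative would differ at these n; the z form is used
because it is the named convention here), with per-pair n always reported
and p undefined below n = 4. Time-anchored matrices correlate the
morphometric change at its cluster-defining timepoint against each
parameter at every timepoint, paired within subject.

## The scaled demonstration study

The end-to-end validation (and `analysis/` scripts) run a scaled instance
chosen to exercise every stage within a desktop compute envelope: grid
32×32×24 at 0.5×0.5×1.0 mm (same field of view, half the resolution per
axis), timepoints 1M and 6M, 9 controls vs 7 irradiated (the motivating
study's animal numbers), T2w noise σ = 1.5% of cortex signal (the protocol
averages 4 repetitions), PSF 1.2 mm, bias 3%, texture 15%, effects as above
with σ = 3 mm. Pipeline settings for this instance: single-level MI affine
plus NCC polish (pose jitter is ~1°), demons schedule (50, 35, 15) with
σ_total = 1 voxel, log J smoothing 3 mm, pseudo-t variance smoothing 6 mm,
α = 0.01 with 400 permutations (α floor 1/400). One seed runs in about a
minute; ten-seed reproduction of the planted structure-level finding (a
negative majority-corpus-callosum cluster at 1M and a positive
majority-cortex cluster at 6M) is the headline end-to-end check.

## What the synthetic validation does and does not show

The generator reproduces the *structure* of the real problem — geometry +
texture anatomy, multiplicative bias, Rician noise, rigid pose, coupled
macro/micro effects with subject heterogeneity, small unbalanced groups —
and therefore validates the algebra, conventions (sign, direction, units)
and statistical calibration of every stage against exact ground truth. It
does not emulate realistic rat neuroanatomy, partial-volume mixtures,
EPI/susceptibility distortion, motion, coil profiles beyond a smooth bias,
or contrast-agent kinetics beyond the steady-state assumption; passing
tests therefore certify the method's correctness, not its effect sizes on
real data. Registration-based log J is attenuated (see above), so absolute
effect magnitudes on real data should be read as lower bounds under
comparable regularisation.

## Numerical details and degenerate inputs

- World coordinates in mm throughout; voxel (0,0,0) at the affine origin;
  RAS+ canonicalisation on load; 0-based indexing.
- log J clamp at 1e−6; non-positive-Jacobian voxels are counted, never
  silently dropped. Orientation preservation in demons is guaranteed by
  construction (step halving, up to 6 halvings, then stop-with-warning).
- Permutation ties: adjusted p uses ≥ comparison with a 1e−12 tolerance;
  the observed labeling is always a member of the null set, making the test
  valid at finite n_perm.
- Cluster sorting is by size descending with lexicographic-centroid
  tie-break, so outputs are deterministic.
- Degenerate inputs rejected with messages: constant images (masking),
  empty ROIs/masks, n < 2 per group or cell, rank-deficient DWI designs,
  non-positive volume ratios, TE ≤ 0, singular affines.
- Every stochastic stage takes an explicit seed; the run manifest logs
  parameters, seeds and output checksums for each stage.

## Known limitations

- Greedy demons is not symmetric/inverse-consistent; template and subject
  roles are not interchangeable.
- The affine metric's optimum at coarse grids (≤32³) carries an
  interpolation-induced bias of up to ~0.7°; at the default 64-class grid
  it is <0.15°. The demons stage absorbs residual pose, which rotations
  leave invisible in log J.
- Absolute CBV depends on an unpublished susceptibility calibration; only
  relative/longitudinal comparisons are meaningful across studies.
- The ANOVA assumes independent observations per subject-timepoint (the
  generator draws sessions independently); repeated-measures or
  mixed-effects modelling is out of scope.
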