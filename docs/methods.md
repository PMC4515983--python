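# Methods

`mtlshape` implements the statistical side of shape diffeomorphometry for
medial temporal lobe structures (amygdala, entorhinal cortex, hippocampus):
constructing vertex-indexed atrophy markers from registered surfaces, fitting
mixed-effects and changepoint models per vertex, controlling the family-wise
error rate by max-statistic permutation, and comparing onset times across
structures by a paired bootstrap. Because cohort MRI data of this kind are
rarely shareable, the package is built around a synthetic-cohort generator
that reproduces the statistical structure the models assume, so every stage
is testable end to end.

## The morphometry marker

Each subject's structure surface is registered to a common triangulated
template; shape change is summarized per template vertex v as the log surface
Jacobian

    J_v = ln( A_v(subject) / A_v(template) ),

where A_v is the one-third barycentric vertex area (each triangle gives one
third of its area to each corner). This is a standard discrete surrogate for
the determinant of the tangential Jacobian of the deformation; we chose it
over interpolated per-face Jacobians because it is exactly conservative
(vertex areas sum to the surface area) and antisymmetric under exchanging
template and target. Negative J_v means local contraction — atrophy.
Volume-level analyses use the log structure volume as a one-dimensional
marker in the same machinery.

## Surface registration

Registration is large-deformation diffeomorphic surface matching by geodesic
shooting. Template vertices carry momenta p; the Gaussian kernel
k(x,y) = exp(−|x−y|²/σ_V²) (no ½ factor in the exponent — fixed so σ_V is
interpretable in mm) generates a Hamiltonian particle flow integrated with a
fixed-step midpoint (RK2) scheme, 10 steps by default. The data term is a
squared current norm: faces are represented by area-weighted normals at
centroids and compared under a Gaussian kernel of width σ_W, so the term
vanishes iff the oriented surfaces coincide as currents. The objective

    p0' K(q0) p0  +  λ Σ_i E(φ_{t_i}(template), target_i)

is minimized over the initial momentum only (the continuum minimizer is a
geodesic, so this loses nothing and halves the unknowns), with L-BFGS and
exact discrete-adjoint gradients of the RK2 scheme (verified against finite
differences in the test suite). Time series of targets attach at evenly
spaced trajectory times. Defaults σ_V = 8 mm, σ_W = 4 mm, λ = 50 suit
structures of ~10 mm scale; σ_V sets the deformation smoothness, σ_W the
geometric detail the match is sensitive to. Kinetic energy is conserved
along shot geodesics to well under 1% at 20 steps and converges at second
order under refinement, which is the practical check that the integrator and
momenta are consistent.

Rigid pre-alignment is closed-form Procrustes when vertex correspondence
exists, otherwise centroid/principal-axes initialization followed by ICP,
with an optional x-axis mirror so right-sided structures can be pooled with
left-sided ones. Atlas label maps are transported through a fitted
deformation by nearest-deformed-vertex lookup (the discrete realization of
L∘φ⁻¹).

## Mixed-effects models

Markers are analyzed per vertex under three designs (g group indicator, d
sex, i log intracranial volume, a_j scan age):

* cross-sectional (first scan): J = α + β g + γ d + δ i + ε. Age is
  included as a nuisance covariate by default (it is a confound whenever
  groups differ in entry age); a flag restores the literal no-age design.
* longitudinal: J = (α + α′a) + (β + β′a) g + γ d + δ i + ε.
* changepoint: J = α + α′a + β′ (a − (t_sym − Δ)) H(a − (t_sym − Δ))
  + γ d + δ i + ε, with H the Heaviside step and t_sym the subject's
  clinical symptom-onset age. Controls have no onset age and contribute
  only pre-changepoint information; there is no group offset (the mean is
  continuous at the switch by construction).

Longitudinal noise decomposes as ε = η(s) + ζ_j(s): a between-subject random
effect of variance ρσ² plus within-subject noise of variance σ², i.e. a
compound-symmetry per-subject covariance σ²(I + ρ11'). Estimation is
maximum likelihood, not REML: for fixed ρ, generalized least squares gives
the fixed effects and σ² in closed form (block-structured V⁻¹ applied by
per-subject shrinkage, never materialized); the scalar profile likelihood in
ρ is maximized on [0, 50] by a coarse grid followed by bounded scalar
refinement per vertex. The closed-form profile log-likelihood matches a
direct numerical maximization over all parameters to better than 1e-6 on
small datasets (an acceptance-level check). When every subject has a single
scan, ρ is unidentifiable and pinned to 0 with a flag, which reduces the
machinery exactly to the cross-sectional OLS fit. Rank-deficient design
columns (e.g. constant sex) are dropped and flagged per coefficient rather
than crashing. Ages and log-ICV are centered before fitting for
conditioning; intercepts are reported back-transformed. A residual variance
floor of 1e-15 keeps noiseless (exactly interpolated) toy data finite, with
a degeneracy flag.

The changepoint Δ — years before symptom onset at which atrophy accelerates
— is shared across the vertices of a structure and estimated by maximizing
the vertex-summed profile log-likelihood over a grid (default 0–15 y, step
0.25 y), ties broken toward smaller Δ so early-onset claims are
conservative. Its uncertainty is a stratified subject-level bootstrap SD.

Annualized atrophy rates fit a least-squares line of structure volume
against scan age per subject, expressed as percent of the subject's baseline
volume per year; subjects with fewer than three scans are excluded.

## Permutation inference

The test statistic per vertex is the log-likelihood-ratio S_v between the
nested alternative and null fits; the global statistic is S* = max_v S_v.
Inference is Freedman–Lane residual permutation at the subject level: null
fitted values plus permuted null residuals form pseudo-data on which both
hypotheses are refit. In longitudinal designs whole per-subject residual
blocks move together and are exchanged only among subjects with the same
scan count, preserving the within-subject covariance; permutations never
touch scans within a subject. The detected vertex set is D = {v : S_v ≥ q*}
with q* the upper-α empirical quantile of permuted S*, realized through
(b+1)/(B+1) corrected p-values so it stays valid under ties; this controls
the family-wise error rate at α (5% default). For the changepoint model Δ
is held at the observed-data estimate during permutation refits by default
(full re-estimation per permutation is available behind a flag); this is an
approximation trading a slightly optimistic null for tractability, and ρ is
profiled on the grid only (no scalar refinement) inside permutation loops so
observed and permuted statistics get identical treatment.

The adaptive sampler draws permutations in 100-sample batches (RNG streams
split per batch) and stops when z·sqrt((1−p̂)/(p̂B)) ≤ 0.10, i.e. when the
global p-value is estimated to 10% relative accuracy with high probability.
The default z = 2.4 sits deliberately above the two-sided 95% normal point:
because the rule fires at the first crossing — when p̂ is at its noisiest —
nominal z = 1.96 delivers only ~91% coverage of the stated accuracy in
calibration runs, while z = 2.4 restores ≥95%.

## Bootstrap comparison of onset times

Changepoint times of different structures are compared by a paired
subject-level bootstrap: within each replicate the same subject resample
(stratified within diagnostic groups, so no replicate loses its symptomatic
subjects) is applied to every structure and Δ re-estimated per structure.
Pairs are summarized by the median difference in years, a 0.5-y-bin
difference histogram, and the exceedance fraction. Because Δ̂ lives on a
grid, exact ties occur; the headline exceedance splits ties evenly (so two
interchangeable structures score exactly 0.5) and the strict >, < and tie
fractions, which partition to one, are reported alongside. Note that the
paired bootstrap conditions on the realized data: two structures generated
with identical parameters but independent noise will generally show an
exceedance away from 0.5, because the realized Δ̂ difference persists across
replicates — that is a property of the estimand, not a defect.

## LCDM thickness

Labeled cortical distance mapping computes, for every gray-matter voxel
center under the mask's affine, the unsigned Euclidean distance to the
nearest point on the gray/white surface (exact point-triangle distances,
vectorized; voxels on the white side are assumed excluded by the mask's
"cut-surface" construction). Thickness estimators: the 95th percentile of
the distance profile, and the zero-curvature approximation volume / surface
area. The percentile is the linear-interpolated empirical quantile, plus
half a voxel when the profile comes from voxelized data — each center
represents a cell extending half a voxel beyond it, so the quantile of the
cumulative profile sits half a voxel above the raw order statistic; without
the correction a 0.05 mm voxelization of a 3 mm slab reads 94.25% instead of
95% of the true thickness. For unbinned distances (voxel size 0) the plain
order-statistic convention applies unchanged. An optional per-vertex label
filter restricts distances to a labeled subregion of the surface when label
maps are available.

## Synthetic cohorts

The generator mirrors a three-group longitudinal ageing study: 221 controls,
50 preclinical and 20 symptomatic subjects by default, entering at mean ages
55 / 62 / 64 (SD 8), with Poisson-distributed scan counts (means 2.2 / 2.3 /
3.6, minimum one) at exponential inter-scan intervals of mean 2.02 years.
Ages are truncated normal at ±3 SD; symptom-onset ages of non-controls are
entry age plus a truncated-normal offset (mean 6, SD 3 years) and may fall
after the last scan, as for preclinical subjects whose symptoms emerge after
observation. The distributions themselves (normal entry, Poisson counts,
exponential gaps) are the simplest choices consistent with the summary
statistics being emulated, and are stated here because only means are pinned
down externally.

Markers follow the changepoint mean exactly — slope α′ before
t_sym − Δ and α′ + β′ after, continuous at the switch, plus an optional
group offset β — on a contiguous affected patch (breadth-first over mesh
edges when a template is supplied; an index block otherwise), with the
two-level Gaussian noise above. Defaults (α′ = −0.005/y, β′ = −0.02/y,
Δ = 7 y, σ² = 0.01, ρ = 0.5, 20% of vertices affected) put annualized
atrophy in the fraction-of-a-percent to few-percent range. Vertex noise is
independent across vertices by default; an optional smoothing half-width
induces spatial correlation, which only matters to the permutation null and
is handled nonparametrically there. A geometric twin,
`generate_deformed_meshes`, realizes the same mean field as smooth radial
contractions of a template with the true log-Jacobian recorded by direct
area recomputation, enabling end-to-end registration tests.

What the generator does not emulate: segmentation error, spatially
structured (anatomical) covariance beyond the optional smoothing kernel,
non-Gaussian heavy-tailed noise, informative dropout, or ApoE-type covariate
structure. Passing tests therefore demonstrate correctness of the
estimators and error control under the models' own assumptions, not
robustness to their violation on real MRI data.

## Problem sizes and numerical choices

Verification runs are sized for a single CPU: the family-wise error rate is
measured on 200 null cohorts of 100 subjects × 100 vertices at 500
permutations each; adaptive-sampler accuracy on 100 runs against a
200,000-permutation reference on a 60-subject, 50-vertex cohort; changepoint
recovery on 50 cohorts of 80 subjects at a 0.5-y grid; bootstrap summaries
in tests use 100–500 replicates (the library default is 10,000). Tolerances
asserted in tests come from the constructions themselves: machine-precision
identities where exact (area conservation, antisymmetry, OLS reductions),
integrator-order bounds for energy drift, and binomial/Monte-Carlo margins
for stochastic rates.

## Known limitations

* The matching functional's data term is a plain current norm; varifold-type
  terms (insensitive to orientation flips) are not offered.
* One Δ per structure: per-vertex changepoints are deliberately not offered,
  matching the single-onset-per-structure reporting the model is meant for.
* The changepoint permutation holds Δ̂ fixed by default (see above).
* ICP alignment without correspondence uses plain nearest neighbors and is
  intended for roughly overlapping shapes, not partial surfaces.
* LCDM assumes isotropic voxels and a mask already cut to the gray side.
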