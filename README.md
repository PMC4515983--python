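# mtlshape

Shape-diffeomorphometry statistics for medial temporal lobe
neurodegeneration: vertex-indexed log-Jacobian atrophy markers, vertex-wise
linear mixed-effects and changepoint models, max-statistic permutation
inference with family-wise error control, bootstrap comparison of onset
times across structures, simplified LDDMM surface matching, and LCDM
cortical thickness.

## Who this is for

Neuroimaging statisticians and methods researchers studying when and where
structures such as the entorhinal cortex, amygdala and hippocampus begin to
atrophy in preclinical Alzheimer's disease — and anyone who needs a tested,
reusable implementation of this analysis chain that runs end to end on
synthetic cohorts, since longitudinal clinical MRI cohorts of this kind are
generally not redistributable.

## The models

Registration of a template surface to each scan yields, per template vertex
*v*, the marker J_v = ln(A_v(subject)/A_v(template)), the log ratio of local
surface areas; negative values are local atrophy. Markers are modeled per
vertex with group indicator g, sex d, log intracranial volume i, scan age a:

* **Model I, longitudinal** — J = (α + α′a) + (β + β′a)·g + γd + δi + ε,
  reducing to the cross-sectional J = α + βg + γd + δi + ε on first scans.
* **Model II, changepoint** — J = α + α′a + β′(a − (t_sym − Δ))·H(a − (t_sym − Δ))
  + γd + δi + ε, with H the Heaviside step: atrophy follows the
  normal-aging slope α′ until Δ years before the subject's clinical symptom
  onset t_sym, then accelerates to α′ + β′, continuous at the switch. Δ is
  shared per structure and estimated by profile maximum likelihood.

Noise is ε = η(s) + ζ_j(s): a between-subject random effect (variance ρσ²)
plus within-subject noise (variance σ²), i.e. compound symmetry, fit by
maximum likelihood with ρ profiled per vertex. Hypotheses are compared per
vertex by the log-likelihood ratio S_v; the family-wise error rate over
vertices is controlled by permuting null-model residuals at the subject
level and referring each S_v to the permutation distribution of
S* = max_v S_v; the detected set is D = {v : S_v ≥ q*} with q* the 95th
percentile of permuted S*. Onset times of different structures are compared
with a paired subject-level bootstrap of Δ. LCDM thickness reads the 95th
percentile of the distances of gray-matter voxels to the gray/white surface.

## Worked example

The `mtlshape report` command runs the whole synthetic study — cohort
simulation, marker generation for two structures with different true onsets
(entorhinal cortex Δ = 9 y, amygdala Δ = 4 y), cross-sectional permutation
tests, changepoint fits with bootstrap SDs, and the paired onset
comparison:

```bash
mtlshape report --out-dir out
```

prints (seed 1, default configuration):

```
SYNTHETIC shape-diffeomorphometry analysis report
seed 1  config 66591c035050a220

Cross-sectional model (first scan only): p-values
structure           volume    vertex  #detected
erc               0.003322  0.003322         12
amygdala             0.103    0.9734          0

Changepoint model: onset of accelerated atrophy (years before symptoms)
structure          Delta      SD    true
erc                 9.00    0.23    9.00
amygdala            5.00    0.39    4.00

Paired bootstrap changepoint comparisons
  erc_vs_amygdala: Delta_A > Delta_B in 100.0% of replicates; median difference 4.50 y

Annualized atrophy rates (% of baseline volume per year, >=3 scans)
  erc: control: 0.89, preclinical: 2.07, symptomatic: 1.85
  amygdala: control: 0.47, preclinical: 1.25, symptomatic: 1.29
```

Reading it: the simulated entorhinal cortex, whose atrophy accelerates 9
years before symptom onset, is picked up by the cross-sectional test
(p ≈ 0.003, 12 of 60 vertices detected at 5% FWER) and its changepoint is
recovered at 9.0 ± 0.2 years; the amygdala, switching only 4 years before
onset, shows no detectable cross-sectional group difference at entry in
this cohort and a later estimated onset, so the bootstrap puts the
entorhinal changepoint earlier in 100% of replicates, median difference
4.5 years. Atrophy rates rise from under 1%/yr in controls to 1–2%/yr in
the affected groups. Library equivalents: `generate_cohort`,
`generate_markers`, `fit_changepoint`, `max_statistic_test`,
`bootstrap_deltas`; registration and thickness are available as
`match_surfaces` / `compute_lcdm` and the `register` / `lcdm` subcommands.

## Layout

| module | contents |
|---|---|
| `mtlshape.mesh` | `TriMesh`, OFF/legacy-VTK I/O, vertex areas, rigid alignment, log surface Jacobian |
| `mtlshape.lddmm` | Gaussian-kernel geodesic shooting, current mismatch, surface matching, label transport |
| `mtlshape.lme` | cross-sectional / longitudinal / changepoint ML fits, LR statistics, bootstrap Δ SD, atrophy rates |
| `mtlshape.permutation` | Freedman–Lane max-statistic test, FWER detection, adaptive sampling |
| `mtlshape.bootstrap` | paired bootstrap of changepoint times, pairwise summaries |
| `mtlshape.lcdm` | voxel-to-surface distance profiles, thickness estimators, slab phantom |
| `mtlshape.synthetic` | cohort / marker / deformed-mesh generators with seeded determinism |
| `mtlshape.pipeline`, `mtlshape.cli` | config-driven orchestration and the `mtlshape` command |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical choices.
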