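# Methods

Mathematical conventions, model definitions, and numerical choices. The
problem sizes quoted throughout (400 cortical regions, 58 nuclei, 60
resolutions, 250 Louvain runs, 10000 spins, …) are the package's default
study configuration; every one of them is a parameter.

## 1. Generative model

`simulate.GenerativeModel` produces regional BOLD-like time series from a
linear latent-factor model. For region *i* at time *t*:

    x_i(t) = baseline_i + Σ_f  Λ_{i,f} z_f(t) + σ_i ε_i(t)

with independent standard-normal latent signals `z_f` and private noise
`ε_i`. The expected functional connectome is therefore available in
closed form as the correlation matrix of `Λ Λᵀ + diag(σ²)`; tests verify
that the empirical FC converges to it.

### Geometry

Cortical regions sit quasi-uniformly on a single shared unit sphere (a
golden-angle Fibonacci lattice, scaled to `cortical_radius_mm`);
hemisphere is the sign of x. Brainstem nuclei occupy a narrow cylinder
inferior to the cortex: bilateral pairs mirrored in x plus a few midline
nuclei. Defaults: 400 cortical regions, 58 nuclei (25 bilateral pairs + 8
midline), 20 subjects × 3 runs × 210 timepoints at TR 2.5 s.

### Latent factors

1. **Global hub factor.** Every cortical region loads uniformly
   (`cortex_global_loading = 1.2`); nucleus *i* loads with hub weight
   `w_i` drawn from a log-normal-like positive distribution scaled by
   `hub_strength = 0.7`. This plants the dominant degree component.
2. **Gradient factor.** Loadings follow the planted unimodal–transmodal
   axis (a first-degree spherical harmonic along a fixed oblique axis),
   strength `gradient_strength = 1.4`.
3. **K community factors** (`K = 5`). Each nucleus loads on its
   community's factor; cortical loadings are
   `projection_strength (= 0.8) × proj_k + projection_offset (= 0.4)`,
   where `proj_k` is a z-scored von-Mises–Fisher bump
   (`projection_concentration = 12`) tilted along the gradient by
   `gradient_coupling = 0.4`. The constant offset models a diffuse
   ascending projection and makes brainstem–cortex coupling
   systematically positive.
4. **48 distance factors.** Localized vMF bumps on the cortical sphere
   (`distance_strength = 0.3`) that induce the distance-dependent decay
   of cortico-cortical FC.

Brainstem regions carry extra private variance
(`brainstem_private_sd = 1.0`), modelling the lower tSNR of deep
structures; this keeps within-brainstem FC weaker than brainstem–cortex
FC, as observed empirically.

Annotation maps (18 "receptor", 123 "term" maps) are linear mixtures of
the community projection maps plus a smooth nuisance bump, so decoding
and dominance analyses have known drivers.

All randomness derives from the model `seed` through independent salted
`SeedSequence` streams for structure, loadings, subjects, and
annotations; identical seeds reproduce datasets bit-for-bit.

## 2. Connectome construction

FC is the Pearson correlation of concatenated runs per subject;
zero-variance regions are masked as NaN rows/columns with a warning. The
group connectome is the element-wise mean of raw subject correlations
(NaNs averaged over the subjects where valid). Weighted degree from a
source block to a target block is the row sum of the corresponding FC
block; `sign_handling` selects signed, positive-only, or absolute sums
(signed by default).

## 3. Residual profiles and similarity

Each node's brainstem profile is OLS-residualized on `(1, degree)`; for
brainstem rows the self-connection is excluded. By construction the
residual profile of every node is exactly orthogonal to the degree
pattern (validated to r ≤ 1e-8). Similarity between residual profiles is
Spearman correlation, either nucleus-by-nucleus (over cortical rows) or
cortex-by-cortex (over nucleus rows).

## 4. Community detection

Signed modularity with resolution γ:

    Q = (1/v⁺) Σ_ij [ W⁺_ij − γ s⁺_i s⁺_j / v⁺ ] δ(c_i, c_j)
      − (1/(v⁺+v⁻)) Σ_ij [ W⁻_ij − γ s⁻_i s⁻_j / v⁻ ] δ(c_i, c_j)

where `W⁺/W⁻` are the positive/negative parts and `v±`, `s±` their total
and nodal strengths (ordered-pair sums). Optimization is Louvain: greedy
local moves (with an empty-community escape move), graph aggregation,
and refinement cycles until no move improves Q. `louvain()` defaults to
the best of `n_starts = 5` independent starts; on exhaustive benchmarks
(all partitions of random signed matrices with n ≤ 8) this attains the
global maximum in ≳95% of cases and never exceeds it. Ensemble runs use
single starts so that run-to-run variability is preserved for stability
scoring.

**Consensus.** For each γ, 250 Louvain runs form a co-classification
matrix; thresholding at the permutation-expected chance level and
re-clustering iterates to a fixed point. Partition agreement is measured
by the z-scored Rand index (z-Rand); identical partitions in an ensemble
are deduplicated with multiplicity weights, which is exactly equivalent
to the naive all-pairs computation.

**Resolution selection.** The sweep covers γ ∈ {0.1, 0.2, …, 6.0} (60
values). The reported partition comes from the longest contiguous
plateau of constant community number; ties break toward lower mean
z-Rand variance, and the plateau's representative is its middle γ. On
the default synthetic data the winning plateau is k = 5 (the planted
number) spanning roughly γ ∈ [1.5, 3.4].

## 5. Gradients

Similarity matrices are converted to affinities by row-wise
sparsification (keep the top `1 − sparsity` fraction per row, default
sparsity 0.9), followed by the normalized-angle kernel
`1 − arccos(cosine similarity)/π`. Diffusion-map embedding uses
anisotropic normalization with α = 0.5: `L_α = A / (d dᵀ)^α`, row
normalization to a Markov matrix, symmetric-conjugation eigendecomposition
(`eigh`), unit-norm eigenvectors, dropping the trivial constant
component, centering, and scaling by `λ/(1−λ)` with eigenvalues clipped
to [0, 1]. Tests verify agreement to 1e-8 with an independent dense
nonsymmetric eigensolver, and that a disconnected affinity graph raises
rather than silently embedding.

## 6. Spatial null models

Cortical map comparisons use a spin test: parcel sphere coordinates are
rotated by a Haar-uniform random rotation and values are reassigned via
the minimum-total-cost Hungarian assignment between original and rotated
coordinates. Because this package's parcellation tiles **one shared
sphere** (hemisphere = sign of x), the rotation is applied globally and
the assignment is solved globally: a rotated parcel may land in either
hemisphere. Per-hemisphere mirrored rotations — the standard recipe for
surface data where each hemisphere is its own registered sphere — are
invalid for this geometry: rotating a half-sphere point set pushes most
points into unoccupied territory, degrading the assignment into
variance-shrinking permutations and inflating false positives (measured
type-I ≈ 0.08 vs the nominal 0.05; the global rotation restores
calibration, ≈ 0.048–0.068 across map smoothness levels). p-values are
two-sided with the add-one convention `p = (1 + #{|r_null| ≥ |r|}) /
(1 + n_reps)`; the default table holds 10000 spins. Maps without a
spherical geometry (e.g. brainstem profiles) fall back to plain label
permutation. Multiple comparisons use Benjamini–Hochberg FDR.

## 7. Dominance analysis and decoding

Dominance analysis decomposes the full model's **adjusted** R² over
predictors by Shapley averaging of the adjusted-R² increments across all
submodels; the per-predictor dominances sum exactly to the full-model
adjusted R² (validated to 1e-10, and against literal submodel enumeration
at p = 3). Decoding correlates a cortical map against the term battery
(123 maps) with spin p-values and retains the top `floor(0.10 × n)` = 12
terms by absolute correlation.

## 8. Pipeline and provenance

`pipeline.run_all` chains every stage, writing TSV/JSON artifacts and a
manifest with the derived seeds, numpy/scipy/pandas versions, per-stage
summaries, runtime, and SHA-256 digests of all outputs. When the input is
simulated, a recovery block reports ARI against planted communities and
Pearson r against planted hub weights and gradient.

## 9. Scope and limitations

* The generator is a **linear** latent-factor model with Gaussian noise:
  no hemodynamics, autocorrelated noise, motion, or physiological
  confounds. It validates the *analysis machinery*, not fMRI realism.
* Some emergent magnitudes are stronger than typical empirical values
  because the synthetic world is clean: the brainstem-vs-within-block
  Welch t is ≈ +10, the cortical distance–FC correlation is ≈ −0.7, and
  the median degree-vs-profile correspondence is ≈ 0.86. These are
  emergent, not calibration targets.
* The spin test's calibration statement (type-I error ≈ 0.05) is
  specific to the single-sphere geometry and smooth Gaussian-mixture
  maps; parcel-based spin tests in general are approximate, not exact.
* Louvain's ≥95% exhaustive-equality rate is an empirical benchmark on
  small matrices, not a guarantee; only the never-exceeds property is
  structural.
* Dominance analysis enumerates all 2^p submodels; it is intended for
  small predictor batteries (p ≲ 15).
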