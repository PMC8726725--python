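# Methods

## Model

`gblica` factorizes K modality matrices `X_k` (features × subjects) as
`X_k = S_k diag(λ_k) H + E_k` with one shared subject-loading matrix `H`
(components × subjects), per-modality source maps `S_k`, non-negative
weights `λ_k`, and isotropic Gaussian noise with per-modality precision
`β_k`. Identifiability conventions: rows of `H` and columns of `S_k` are
unit Euclidean norm, so `λ_k,c²` is the variance component `c` explains in
modality `k`; components are ordered by `Σ_k λ_k,c²` descending and the
sign of each loading row is fixed so its largest-magnitude entry is
positive.

Source entries are a priori drawn from a two-component mixture of
zero-mean Gaussians per (modality, component): a wide slab for active
features and a narrow spike for inactive ones, with the mixing weight and
both variances estimated. The mixture's non-Gaussianity resolves the
rotational ambiguity that makes a plain SVD/PCA unidentifiable — this is
what makes the decomposition an ICA — and it provides automatic relevance
determination: for a component absent from a modality, the slab collapses
toward the spike and the weight `λ_k,c` shrinks toward zero.

## Estimation

Fitting is variational expectation-maximization in two phases that ascend
one objective.

**Phase 1 (orthonormal loadings).** With `H` constrained to orthonormal
rows, `W_k = X_k Hᵀ` carries independent Gaussian noise entrywise, the
source posterior factorizes, and the marginal likelihood is available in
closed form. The M-step for `H` is an orthogonal Procrustes solve on the
pooled cross-products `Σ_k β_k E[A_k]ᵀ X_k` (all modalities pooled,
weighted by their noise precisions and, through `E[A_k]`, their component
weights); mixture parameters and `β_k` have closed-form updates. Because
plain EM traverses near-flat rotation ridges extremely slowly — the slab
variance partially adapts to mixed columns — the fit additionally performs
Jacobi sweeps over Givens rotations of loading-row pairs, profiling each
candidate angle over the column's mixture parameters and accepting only
likelihood-increasing rotations; each pair is iterated to quiescence with
one grid-zoom refinement. Sweeps run on the first iterations and whenever
EM progress stalls; convergence requires both a stalled objective and a
quiescent sweep.

**Phase 2 (oblique refinement).** Real subject loadings are not mutually
orthogonal (independent loading rows drawn for n = 40 subjects correlate
at ~0.16 on average, occasionally ~0.4), and an orthonormal basis can cap
row recovery around |r| ≈ 0.83–0.96. Phase 2 therefore releases the
constraint and continues mean-field coordinate ascent: per-entry
spike/slab posteriors (all features of one component updated jointly,
cycling components), closed-form mixture updates, a pooled normal-equation
solve for `H`, and `β_k` updates. The evidence lower bound of this
mean-field family *equals* the phase-1 marginal likelihood whenever `H` is
orthonormal, so the concatenated trace is a single objective and is
monotone non-decreasing (verified to 1e-8 relative slack in the tests).
Row norms of the final `H` are folded into `λ_k` so the reported loadings
have unit-norm rows.

**Numerical safeguards.** The noise variance is floored at `1e-6` of the
modality mean square (this caps `β_k` on noiseless data while keeping the
noiseless rank-1 recovery of `λ` and the reconstruction exact to better
than 1e-6 relative). The spike variance is floored at `1e-4` of the
modality mean square: with an unbounded point-mass spike, exactly-zero
entries earn unbounded density rewards and the likelihood can prefer a
*mixed* pair of components over the aligned sparse pair whenever the true
loadings are oblique (the aligned solution inevitably carries small
leakage entries that a point mass cannot absorb); a floored free-variance
spike absorbs that leakage and restores identifiability. Mixing weights
are clipped to [1e-4, 1−1e-4]; the slab variance is floored at `1e-8` of
the modality mean square and kept at least as large as the spike variance.

**Defaults.** `n_components=10` (user-settable; the synthetic studies use
the planted number), `tol=1e-9` relative objective change, `max_iter=4000`
per phase. The tolerance is deliberately tight: the objective creeps by
~1e-6 relative per iteration while components disentangle, and a looser
tolerance stops the fit with visibly mixed components. Initialization is a
deterministic SVD of the row-stacked standardized modalities (removing
run-to-run rotation ambiguity); `n_restarts` seeded random rotations of
the initial subspace are available and the best final objective wins.

## Standardization and contribution fractions

Each feature is centered across subjects and each modality is globally
rescaled to unit mean-square (computed over its non-constant features).
Contribution fractions `P[k,c] = λ_k,c² / Σ_k' λ_k',c²` are defined on
this standardized scale; a modality with many features still carries more
total standardized energy than a small one (a 432-voxel network pair vs a
30-genus table gives the genus modality ~6.5% under equal per-entry
signal), which matches how the decomposition actually apportions variance.
The `>0.2` selection rule reads "brain" as the **sum** of the network
modalities' fractions; per-network exceedance flags are also emitted so
the per-network reading stays inspectable.

## Dual regression

Stage 1 regresses each fMRI volume jointly on *all* template maps (over
voxels) for subject-specific timecourses; stage 2 regresses each voxel's
time series jointly on all timecourses for subject-specific maps.
Intercepts are handled by demeaning over the regression dimension
(numerically identical to an explicit constant column). Stage-1
timecourses are variance-normalized before stage 2 so betas are comparable
across subjects; the default output converts each coefficient to
coefficient/SE and then t→z with the residual degrees of freedom (computed
through log tail probabilities, so large statistics stay finite and
monotone; z is clipped at ±40 where double precision underflows). Under
pure-noise input the z maps are standard normal, which the tests verify.
Network selection happens only at output stacking: the regressions always
condition on the full template set. Voxels with zero temporal variance in
any subject are excluded from the regressions for every subject, recorded
in the output masks, and zero-filled in the maps.

## Microbiome preparation

Counts are aggregated to genus by the `g__` rank token of the
semicolon-ranked lineage (taxa without a named genus pool under their
lowest named rank, prefixed `unclassified_`); genera detected (count > 0)
in fewer than 30% of samples are dropped, with the "at least" boundary
compared in exact rational arithmetic so threshold-exact prevalences are
retained; remaining counts are normalized to per-sample proportions.
Filtering precedes normalization by default, so retained genera
renormalize to sum 1; `order="normalize-first"` instead carries forward
proportions computed on the full table (rows then sum to < 1, and the
result is marked un-renormalized). No log-ratio or other transform is
applied before the factorization. Formats: a taxa-as-rows TSV dialect and
BIOM v1 JSON (read and written by a minimal built-in codec).

## Component QC and reporting

*Single-subject dominance*: `max_r H[c,r]² / Σ_r H[c,r]²`, flagged above
0.5 (the bound is 1/n_subjects for perfectly even loadings and 1 for a
one-hot row). *Constant maps*: a source column whose voxel-wise variance
is below `1e-8` of the modality's mean column variance (or numerically
zero) is flagged; for maps *estimated* from noisy data the recommended
threshold is `ESTIMATED_MAP_REL_VAR = 0.2`, because an estimated version
of a truly constant map is dominated by leakage from imperfect loading
recovery — a fraction ≈ (1−r²) of a typical unit-variance sparse column
mixes in at loading correlation r, putting its relative variance near or
below 0.1, while genuine sparse maps sit near 1.5. This detection setting
was calibrated once on the package's simulation suite and then validated
on an independent 20-seed suite (20/20 planted artifacts flagged on both
rules, zero false flags). Thresholded displays standardize each source
column to mean 0, sd 1 ("standardized loading z" — a display convention,
not a posterior statistic) and report two-sided exceedances, |z| > 3 for
brain maps and |z| > 2.3 for the sparser genus loadings, with signs.

## Synthetic cohorts

The generator plants exactly the structure the model assumes: unit-norm
Gaussian loading rows (optionally one row dominated by a single subject as
an artifact), sparse unit-norm source columns (a `sparsity` fraction of
standard-normal entries, optionally one column spatially constant),
effective weights `λ_k,c = w_k,c · sqrt(F_k · N)` so that a weight of 1
contributes unit signal variance per matrix entry regardless of modality
size, and i.i.d. Gaussian noise; features are centered across subjects.
Default conditions: 40 subjects, 2 networks on 6×6×6 voxel grids, 30
genera, 3 components, all weights 1, sparsity 0.1, noise sd 0.1,
sequencing depth 10,000 reads/sample — per-entry SNR 10, the regime where
both recovery and its failure modes are measurable at desk scale.

The genus modality additionally yields a compositional view: softmax of a
fixed baseline log-abundance (sd 1.5 across genera, giving realistically
skewed abundances) plus the planted signal, multinomially sampled at the
read depth. The linear modality matrices are the ground-truth-linked LICA
inputs; the composition/count tables exercise the preprocessing path. For
fMRI, networks are concatenated into one volume along z (block-wise
orthogonal templates), each subject's map is template-plus-planted
deviation, and the series is `maps · timecoursesᵀ + noise` — exactly
invertible by dual regression when noiseless. All randomness flows from
one seed through counter-based child seeds, so cohorts are bit-reproducible.

What the generator does *not* emulate: spatial autocorrelation of fMRI
noise, hemodynamics, phylogenetic covariance between genera, or
compositional closure effects on the linear modality. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the model's own assumptions, not performance on real cohort data.

## Simulation study sizes

Chosen so the full suite runs on one CPU in minutes: parameter recovery
uses the default cohort above; the QC flag suite runs 20 cohorts of 40
subjects with one 5×5×5 network plus the genus table at default SNR; the
noise-degradation study uses 30 subjects, one 5×5×5 network, 30 genera,
2 components, 20 seeds per noise level.

## Known limitations

- At very high SNR (noise sd ≲ 0.3 under default weights) recovery
  saturates around mean |r| ≈ 0.99 and is insensitive to the exact noise
  level; on *noiseless* data the likelihood is degenerate in rotation up
  to the prior, and recovery is very slightly worse than at small noise.
  Monotone degradation of recovery with noise holds from noise sd 0.3
  upward and is tested over {0.3, 1, 3, 10}.
- The oblique refinement is mean-field: posterior correlations between
  components induced by non-orthogonal loadings are ignored, which can
  bias slab variances slightly downward.
- Contribution fractions are defined as `λ²` shares on the standardized
  scale; other definitions (e.g., per-feature R²) would differ for very
  heterogeneous modalities.
- A single modality-wide noise precision is assumed; voxel-heteroscedastic
  noise is not modeled.
- Subjects must be complete cases across all modalities; missing-modality
  subjects are rejected at alignment.
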