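# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic test-bench does and does not
establish about real data.

## Dimension model

The number of significant principal components D is estimated from the
eigenvalues λ₁ ≥ … ≥ λ_p of the gene–gene correlation matrix (genes
standardized across samples; covariance is available via
`standardize=False`). The model assumes the data are Gaussian with d
structured components and an isotropic residual; profiling out the
component variances gives the per-observation score

f(d) = −½ [ Σ_{j≤d} log λⱼ + (p−d) log( mean of λ_{d+1..p} ) ],

and an exponentially decaying prior exp(−Θ·d) makes the MAP dimension
argmax_d f(d) − Θ·d. As Θ grows the MAP estimate steps downward; the
exact breakpoints are the slopes between vertices of the upper concave
hull of (d, f(d)), which the implementation walks directly rather than
scanning a Θ grid (a dense-grid brute force serves as the test oracle).
Penalizing f = ℓ/n rather than ℓ itself makes breakpoints O(1) and
independent of the sample count, so step lengths are comparable across
datasets. Candidate dimensions run from 0 ("no structure") to
min(p, n−1) − 1; the terminal dimension's Θ-interval is unbounded and is
excluded from all step-length statistics, which its infinite length would
otherwise dominate.

Three rules automate "pick the highest long step":

- **Twice Mean** — long = step length > 2 × mean finite step length.
- **CPT** — sort lengths ascending; fit a single mean-shift changepoint
  by exhaustive search (minimum within-segment squared error over every
  split); accept it when 2·ΔlogL > 3·log m for m steps, using the
  Gaussian likelihood with profiled common variance (an SIC-like penalty,
  chosen because the changepoint method itself does not fix one); the
  upper segment is long.
- **Kmeans3** — exact 1-D k-means with K=3 via dynamic programming over
  contiguous partitions of the sorted lengths (the optimal 1-D partition
  is always contiguous, so the DP is deterministic and globally optimal —
  it replaces the usual randomized k-means restarts without changing the
  objective); the upper two groups are long. With fewer than three
  distinct lengths the rule degrades to K=2; with one distinct length it
  falls back.

If no step qualifies as long, every rule falls back to the single longest
finite step; all ties anywhere resolve toward the smaller dimension
(parsimony).

## Loadings, outliers, clustering

On standardized data the weight of gene g on component j is
√λⱼ·v_j[g] — its Pearson correlation with the PC-j scores — so the
length of a gene's D-vector lies in [0, 1] and measures how much of the
gene's variance lives in structured directions. The scale-free default
cutoff 0.3 (strict inequality: length < 0.3 is removed) marks genes
carrying < 9% structured variance as outliers. Exactly constant genes are
outliers by definition. Eigenvector signs are fixed so the
largest-magnitude entry is positive, making every output deterministic.

Retained genes are clustered by unit direction with a K-component von
Mises–Fisher mixture, density C_D(κ)·exp(κ μᵀx) with
C_D(κ) = κ^{D/2−1} / ((2π)^{D/2} I_{D/2−1}(κ)). EM details:

- E-step in log space with exponentially scaled Bessel functions
  (`scipy.special.ive`), so κ up to 10⁵ cannot overflow; κ < 10⁻⁸ uses
  the uniform-sphere limit.
- M-step: μ_k is the normalized responsibility-weighted resultant; κ_k
  uses the closed-form mean-resultant approximation
  κ̂ = r̄(D − r̄²)/(1 − r̄²). Because this update is approximate rather
  than an exact maximizer, a step can overshoot; the loop reverts to the
  last ascent point and stops there, so the returned likelihood trace is
  monotone by construction.
- Initialization: spherical k-means++ (cosine dissimilarity), 20
  restarts, per-restart seeds spawned from one master seed; convergence
  at relative log-likelihood change < 10⁻⁶ or 200 iterations. An emptied
  component is re-seeded from the point with the lowest mixture density.
- Free parameters: D per component ((D−1) for μ, 1 for κ) plus K−1
  mixing weights, so AIC = 2(K·D + K − 1) − 2 log L, minimized over
  D ≤ K ≤ 2D (ties toward smaller K).

**Concentration bound.** Mixture likelihoods are unbounded when a
component collapses onto near-duplicate points (κ → ∞ is the spherical
analogue of a vanishing Gaussian variance), and AIC would reward such
degenerate splits. `fit_vmf_mixture` therefore bounds κ; the default
bound 10⁵ only prevents overflow, but `run_thresher` passes a bound equal
to the number of samples. The rationale: loading directions are estimated
correlations whose angular error scales like 1/√n, so concentration
beyond κ ≈ n describes structure finer than the estimate can resolve;
bounding κ there removes the degenerate maxima while leaving genuinely
tight (κ of a few hundred at n = 500) clusters representable.

The full run is a two-pass pipeline — dimension, loadings, outliers, then
dimension, loadings and clustering recomputed on the retained genes — and
executes both passes even when pass 1 removes nothing. Each final cluster
is validated: its members-only submatrix should have estimated dimension
≤ 1 and all first-PC weights of one sign. Cluster scores are plain means
of member expression (a sign-adjusted variant exists for clusters that
fail the sign check); genome-wide gene lists use inclusive |ρ| ≥ 0.5.

## Embedding

Sample scores on the top-D PCs are the projection Zᵀvⱼ of the
standardized matrix, sharing the loading sign convention, so the score
covariance is diag(λ₁…λ_D). The 2-D map wraps scikit-learn's t-SNE
(perplexity 30, 1000 iterations, random initialization, seeded): t-SNE is
established methodology, not this package's contribution, and the PC
scores already provide the input reduction. Layouts are
seed-deterministic but not canonical; only neighborhood structure, not
the visual arrangement, is meaningful.

## Synthetic data

`generate_factor_dataset` emulates the structure the pipeline assumes:
gene g in factor f of a sample in group c is
σ(g)·(M[c,f] + z_{f,s}) + ε, with independent standard-normal latent
factors z, group-specific means M, gene sign σ(g) ∈ {±1}, and Gaussian
noise ε with standard deviation `noise_sd`; pure-noise genes are ε alone.
Values are on the transformed (log-like) scale directly — counts,
library-size and batch effects are not simulated. `frac_negative_sign`
accepts one value per factor so a single factor can be sign-split.

The default bundle (`generate_default_bundle`) fixes the study
conditions used throughout the tests: 500 samples in 3 groups, 5 factors
× 8 genes with the last factor split 50/50, 10 noise genes,
`noise_sd = 1.0`, group means of 2.0 on one factor per group. The noise
scale deserves comment: at unit factor variance it gives within-factor
gene correlations near 0.5, typical of real co-expression modules. It is
also a structural requirement, not a free dial — standardized pure-noise
genes always contribute eigenvalues near 1, so they register as
*insignificant* only when the signal genes' residual eigenvalues are of
the same order. At much lower noise (e.g. 0.3 with near-0.9 within-factor
correlations) each unit-variance noise gene genuinely spans its own
significant dimension under the isotropic-residual model, the estimated
D becomes factors + noise genes, and magnitude filtering cannot remove
them; that regime contradicts the method's own outlier premise rather
than the implementation. The dimension-recovery checks accordingly use
signal-only data at noise 0.3, and the outlier/end-to-end checks use the
bundle at noise 1.0.

Because the generator matches the model's assumptions (Gaussian factors,
independent noise, one-dimensional clusters), passing tests demonstrate
correctness of the machinery, not robustness to real-data violations:
heavy tails, correlated noise, nested or overlapping programs, and
continuum structure between clusters are all outside what these tests
establish.

## Problem sizes and tolerances

Test-bench sizes were chosen to make every statistical check decisive at
desk scale: 200 random spectra for the step-function oracle, 50 seeds for
dimension recovery (≥ 90% required; observed 100%), 50 bundles for filter
sensitivity/specificity (≥ 95%; observed 100%), 20 seeds of two-component
κ = 50 vMF samples (means within 5°; mean κ error within 15% — per-draw
κ fluctuation at n = 200 exceeds 15% about 10% of the time even for the
known-label estimator, so the per-seed check compares against that oracle
instead). Numerical tolerances: eigendecompositions checked to 10⁻¹⁰
against dense oracles; AIC bookkeeping exact; breakpoint/grid agreement
within one 10⁻⁴ grid step; matrix writers emit shortest round-trip float
representations and `to_array` canonicalizes memory layout so repeated
runs are bit-identical.

## Known limitations

- The Θ-breakpoint values depend on the pinned profile likelihood;
  another implementation of the same graphical method may scale Θ
  differently, shifting breakpoints while preserving the step ordering
  and the selected dimensions on well-separated data.
- Whether loadings are √λ-scaled (as here, making the 0.3 cutoff a
  correlation length) or raw eigenvector entries changes the cutoff's
  meaning; comparisons with other implementations should check this
  convention first.
- AIC over K ∈ [D, 2D] assumes every cluster is vMF; strongly
  non-spherical clusters can still split.
- The CPT acceptance penalty (3 log m) and the κ resolution bound
  (κ ≤ n) are defaults with stated rationale, not universal constants;
  both are exposed as parameters.
- t-SNE coordinates are not comparable across seeds or implementations.
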