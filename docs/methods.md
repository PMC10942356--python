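# Methods

## Problem setting

High-dimensional per-subject measurements (the *data view*; in the motivating
application, vectorized voxel-wise GLM contrast betas per brain region) often
relate to outcomes through structure that is shaped by low-dimensional
*exogenous* covariates measured on the same subjects (family and neighborhood
adversity scores). Linear multivariate tools can recover main effects of
either view, but an outcome driven by the *interaction* of a latent data
coordinate and a latent environment coordinate is invisible to any model that
is linear in (features of view 1) ⊕ (features of view 2). The package's core
is an unsupervised embedding whose coordinates are nonlinear functions of
both views jointly, so that downstream linear prediction can read off such
interactions.

## Single-view diffusion embedding

Given an n × p matrix, the pipeline is:

1. **Distances.** Euclidean distances between subject rows.
2. **Adaptive bandwidths.** ε_i = distance from subject i to its k-th
   nearest neighbor (default k = 5). Zero bandwidths (exact duplicate rows,
   which occur in survey-derived matrices) are replaced by the smallest
   positive distance in the row, with a warning, rather than failing.
3. **Alpha-decay kernel.** K(i,j) = ½ exp(−(d/ε_i)^α) + ½ exp(−(d/ε_j)^α),
   default α = 40. The sharp default behaves like a soft k-NN graph; far
   pairs underflow to exactly zero, which is the correct limit. The kernel is
   symmetric, has unit diagonal, and is invariant to jointly rescaling
   distances and bandwidths.
4. **Transition operator.** Row-normalize K. Row sums are accumulated in
   sorted order so the operator is *bitwise* equivariant under subject
   permutation — a cheap guarantee that downstream results cannot depend on
   input row order.
5. **Diffusion time.** The spectrum is taken from the symmetric conjugate
   D^{1/2} P D^{−1/2} (real, stable, computed with `eigvalsh`); for fused
   operators without a symmetric source (transition-level products),
   eigenvalue magnitudes of the operator itself are used — a row-stochastic
   matrix has spectral radius 1 either way. The von Neumann entropy
   H(t) = −Σ η_i log η_i with η_i ∝ |λ_i|^t is evaluated for t = 1…t_max
   (default 150) and t is chosen at the knee: the t maximizing perpendicular
   distance to the chord joining (1, H(1)) and (t_max, H(t_max)), ties to the
   smallest t. The knee is invariant to affine rescaling of H.
6. **Potential distances.** U(i,j) = ‖log P^t(i,·) − log P^t(j,·)‖₂ with
   probabilities clamped at `log_floor` (default 1e−7) before the log; the
   floor prevents −∞ from entries that a t-step walk cannot reach and is the
   smallest transition probability that is meaningful at cohort sizes up to
   ~10⁴. Natural log; the base only changes a global scale.
7. **Metric MDS.** Classical (Torgerson) MDS provides the initialization
   (negative eigenvalues truncated at zero), refined by SMACOF majorization
   (Guttman transform, default 300 iterations, relative stress tolerance
   1e−6). SMACOF is written in-package because the per-iteration stress
   sequence is part of the contract (majorization guarantees it is
   non-increasing, and the tests assert this on every run); scikit-learn's
   `smacof` is used in the test suite as an independent cross-check on the
   final stress, never as the implementation. Initializing from classical
   MDS makes the whole pipeline deterministic: the recorded seed matters
   only if random restarts are enabled (they are off by default).

Embedding dimensionality defaults to D = 20 for analysis (2–3 for
visualization).

## Fusing the exogenous view

The exogenous view (q ≥ 1 covariate columns, z-scored by default since the
scores mix scales) gets its own alpha-decay kernel with a wider, softer
default: k_env = n/10 clamped to [5, 30], α_env = 5. A handful of coarse
scores yields coarsely quantized distances; a hard α = 40 cutoff at the
5-NN radius fragments such a view into shells, while a soft shoulder keeps
affinities graded.

Two fusion schemes are implemented:

* **Kernel fusion (default).** K_fused = K_data ∘ K_env (elementwise), unit
  diagonal restored, then row-normalized. Since exponents add, this is an
  alpha-decay kernel on the additive product metric: a fused-walk step must
  be local in *both* views. Diffusion therefore explores joint
  (data, environment) neighborhoods, and the embedding coordinates are
  nonlinear functions over the joint latent sheet — which is what makes a
  planted data-latent × environment-latent interaction linearly decodable
  from the coordinates. A uniform (all-ones) environment kernel — every
  subject environmentally identical — leaves K_fused = K_data bitwise, so a
  neutral environment reduces E-PHATE to PHATE exactly.
* **Operator fusion.** The classical dual-diffusion product
  P = P_data @ P_env (order configurable; the product does not commute).
  The product of row-stochastic matrices is row-stochastic, and an identity
  factor is returned unchanged with its kernel provenance intact, so the
  identity-environment reduction is exact down to the bit.

Kernel fusion is the default on structural grounds. A transition step of a
*single-view* operator moves to a neighbor in that view with the other view
unconstrained: many subjects share any given environment profile, so an
environment-local hop scrambles the data coordinate (and vice versa). Any
composition at the transition level — either product order, powered factors,
lazy/averaged variants — therefore encodes the second view only through the
walk's self-weight, and empirically leaves a planted interaction almost
undecodable from the embedding, while kernel fusion decodes it strongly.
This differs from the temporal multi-view setting that popularized the
operator product, where the second view is a near-banded chain with exactly
one item per position, so its hops cannot scramble the first view. The
operator path is retained as a first-class variant because it is the
construction the fused pipeline reduces through, and because it is the
appropriate choice precisely in such chain-structured second views.

Two benchmark baselines are built in: `phate_plus_env` (PHATE coordinates
concatenated with the z-scored covariates — the *linear* way to add the
second view) and `ephate_control` (the environment view replaced by seeded
standard-normal noise of matching shape — more data per subject, but no
environmental information). The first isolates nonlinearity of the
combination; the second isolates the information content of the view.

## Evaluation stack

* **Cross-validation.** Shuffled k-fold (default F = 20, i.e. 95/5 splits)
  keyed on *sorted subject IDs*, so fold membership is invariant to row
  order. Plain (non-stratified) splits; a grouping hook (family/site
  clustering) is out of scope.
* **Prediction.** OLS with intercept on the training subjects; rank-deficient
  designs fall back to the minimum-norm solution with a warning.
* **Scoring.** Partial Spearman: rank-transform predictions and truths
  (average ranks on ties), residualize both rank vectors on the covariate
  design (numeric columns as-is, categorical one-hot with reference level
  dropped, intercept always included), Pearson-correlate the residuals. With
  no covariates this equals plain Spearman to machine precision. The mean
  over folds carries a 95% t-interval across the F fold values.
* **Comparison.** Paired two-sided sign-flip permutation test on per-fold ρ
  differences: statistic = mean difference, signs flipped uniformly,
  p = (1 + #{|permuted mean| ≥ |observed mean|}) / (n_perm + 1), default
  n_perm = 10,000. Sign-flipping is the standard paired construction and is
  exact under exchangeability of the paired differences. Bonferroni
  correction over the set of pairs tested.
* **Task performance.** d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate) with the
  log-linear (Hautus) correction: 0.5 added to each cell, 1 to each trial
  total, keeping rates strictly inside (0, 1).

Note that fold-wise CV correlations share training data, so a single
replicate's mean ρ under the null wanders more than the fold count suggests;
null behavior is always assessed across replicates.

## Synthetic cohorts

The generator emulates the statistical shape of the target data at desk
scale, with every stage drawn from its own seeded stream so stages can be
regenerated in isolation and the whole dataset is bitwise reproducible from
(config, seed).

* **Latents.** The data-view latent b is an arc parameter drawn on a
  *jittered regular grid* over [0, 1] (one uniform draw per cell), then
  standardized. Jittered-grid sampling keeps the largest gap below ~2/n;
  with iid-uniform draws the largest gap grows like log(n)/n and routinely
  exceeds the adaptive 5-NN bandwidth, splitting the affinity graph into
  components that no diffusion method can order. The environment latent e
  is correlated with b at a configurable level (default 0.3 — a moderate
  brain–environment dependence).
* **Data view.** A fixed random sinusoidal feature map,
  x_j = sin(w_j b + φ_j) with w_j ~ N(0, 1), plus Gaussian noise
  (default SD 0.1). Smooth, fixed by seed, and genuinely nonlinear, so no
  linear method can read b off a single component, while local distances
  still track the latent.
* **Environment view.** q = 5 noisy linear mixes of e (noise SD 0.3), with
  column names matching the five adversity scores the method was designed
  around (FES, CRPBI, NCY, NSC, ADI).
* **Outcomes.** y = 0.3 b + 0.3 e + 1.0 b·e + scanner shift + noise
  (SD 0.5): interaction-dominant by default, with a categorical
  pseudo-scanner covariate (3 levels, small additive shifts) and an optional
  correlated baseline score for longitudinal-style analyses. Setting the
  weights to zero yields the null regime; zero interaction with nonzero main
  effects yields the regime where PHATE and E-PHATE should tie.

What the generator does **not** emulate: spatial autocorrelation of fMRI
noise, atlas geometry, item-level survey structure, site/family nesting.
Passing tests on these cohorts demonstrates the pipeline's mechanics and its
qualitative orderings, not effect sizes on real cohorts — with restricted
cohort sizes in the thousands and much lower signal-to-noise, real-data
correlations are an order of magnitude smaller than the synthetic ones.

## Problem sizes

The shipped analyses use n = 300 subjects, p = 200 features, q = 5 scores,
20-fold CV, and five replicate seeds — enough to exercise every code path,
estimate fold-level statistics stably, and keep a full benchmark run in
seconds on one core. Operators are dense; the implementation targets
cohorts up to a few thousand subjects (no landmarking or sparse
approximations).

## Known limitations

* **No out-of-sample extension.** The embedding is defined for the fitted
  cohort only (`fit`/`fit_transform`, no `transform` on new subjects).
* **Time-scale selection saturates on large noiseless chains.** The entropy
  knee (with t_max = 150) picks t ≈ 25–30 on a noiseless 1-D manifold almost
  independently of n; for cohorts much beyond ~100 on such a chain the t-step
  walk cannot mix end to end, potential distances saturate, and the leading
  MDS coordinate bends (the classic horseshoe), degrading rank recovery of
  the latent from ~1.0 (n = 60–80) to ~0.8 (n = 300). Realistic noise levels
  shrink the spectral gap and mask the effect; the noiseless recovery
  property is therefore exercised at n = 60–80.
* **Two views only.** The fusion is pairwise; weighting schemes and >2 views
  are out of scope.
* **Coordinates are not directional.** As with any MDS-based embedding,
  individual axes have arbitrary sign and no voxel-level interpretation.
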