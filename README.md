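# ephate

Multi-view diffusion manifold learning for subject-level biomedical data.

`ephate` implements **E-PHATE** (exogenous PHATE): a nonlinear embedding that
fuses a diffusion operator built from a high-dimensional per-subject data view
(for example, vectorized voxel-wise fMRI task-contrast betas for a region)
with an affinity built from a handful of *exogenous* per-subject covariates
(for example, family conflict, caregiver acceptance, perceived neighborhood
safety, and neighborhood disadvantage). The fused operator is embedded with
metric MDS, and the resulting coordinates capture joint — including genuinely
nonlinear — structure between the two views, such as brain-by-environment
interactions that predict emotional and behavioral outcomes.

The package also ships the single-view **PHATE** pipeline, a PCA comparator,
a synthetic-cohort generator with planted interaction effects, and the full
evaluation stack used to score representations: k-fold cross-validated linear
prediction scored with partial Spearman correlation, fold-wise paired
sign-flip permutation tests with Bonferroni correction, and Hautus-corrected
d′ for n-back-style task performance.

## The model

For each view, an adaptive alpha-decay kernel is built on Euclidean
distances,

```
K(i,j) = 1/2 exp(-(d(i,j)/ε_i)^α) + 1/2 exp(-(d(i,j)/ε_j)^α),
```

with ε_i the distance from subject *i* to its k-th nearest neighbor. The
data view uses a sharp, narrow kernel (k = 5, α = 40); the exogenous view a
wider, softer one (k ≈ n/10, α = 5) suited to a few coarse z-scored scores.
The fused affinity is the elementwise product `K = K_data ∘ K_env`: a step of
the fused random walk must be plausible under *both* views, so diffusion
explores joint (data, environment) neighborhoods. Row-normalizing `K` gives
the transition operator `P`; the diffusion time `t` is chosen at the knee of
the von Neumann entropy of the operator spectrum; potential distances

```
U(i,j) = || log P^t(i,·) − log P^t(j,·) ||₂
```

are embedded into D dimensions (default 20) by classical MDS followed by
SMACOF metric-stress majorization. The classical transition-level fusion
`P = P_data @ P_env` (dual diffusion by operator product) is also available
(`fusion="operator"`); with an identity environment operator it reduces to
single-view PHATE exactly, bit for bit.

Representations are scored by training ordinary least squares on 95% of
subjects to predict an outcome and computing the partial Spearman ρ between
predicted and true scores on the held-out 5%, controlling for covariates
(e.g. scanner ID), averaged over 20 folds; representations are compared with
paired sign-flip permutation tests on the per-fold ρ differences.

## Worked example

```python
from ephate import SyntheticConfig, generate_dataset, EPHATE, PHATE
from ephate import benchmark_representations

# cohort with a planted brain-latent x environment-latent interaction
ds = generate_dataset(SyntheticConfig(n=300, p=200, q=5, seed=0))

emb = EPHATE(n_components=20).fit_transform(ds.brain.values, ds.env.values)
print(emb.shape)                       # (300, 20)

scores, comparisons = benchmark_representations(ds, seed=0)
for name, s in scores.items():
    print(f"{name:16s} mean rho = {s.mean_rho:+.3f}")
```

Output from the run above:

```
(300, 20)
voxel            mean rho = +0.024
pca              mean rho = +0.240
phate            mean rho = +0.258
phate_plus_env   mean rho = +0.228
ephate           mean rho = +0.595
ephate_control   mean rho = +0.270
```

The raw 200-feature view barely predicts the interaction-driven outcome
(OLS overfits high-dimensional noise), PCA and PHATE recover only the
main-effect share carried by the brain latent, appending the environment
scores linearly (`phate_plus_env`) adds only the environment main effect —
while the fused embedding (`ephate`) also captures the interaction term.
Replacing the environment view with random noise of the same shape
(`ephate_control`) collapses the advantage back to PHATE's level, showing
the gain comes from environmental information, not from extra dimensions.

The same pipeline is scriptable from the shell:

```bash
ephate simulate --seed 0 --out run/
ephate evaluate --brain run/brain.csv --env run/environment.csv \
    --outcomes run/outcomes.csv --seed 0 --out run/results/
```

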