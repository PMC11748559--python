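# crlatent

Generative modeling of host-associated microbiomes derived from the
consumer/resource (C/R) framework.

## The problem

Microbiome cohorts are small (hundreds of hosts), high-dimensional
(hundreds of taxa), and strongly context-dependent, which makes
off-the-shelf generative models prone to overparameterization and hard to
interpret. The C/R framework explains community variation mechanistically
— species grow according to their preferences toward resources — but
fitting raw C/R dynamics requires temporal resource measurements that
cross-sectional studies never have.

`crlatent` closes that gap. Integrating the C/R growth equation shows that
a species' abundance depends on the *time-integrated histories* of
effective resources, `z_k = -∫ r_k dτ`, through universal species
preferences `θ_ko`:

```
q_so = exp(-Σ_k z_sk θ_ko) / Ω_s
```

so relative abundances are a softmax over `-ZΘ` and can be fit directly to
a sample-by-taxon table as a nonlinear low-rank factorization. Host
phenotypes `m_sp` share the latent space through a linear head `M ≈ ZL`,
with a combined loss

```
C = α·Ce + (1-α)·Cm,    Ce = Σ_so x_so log(x_so / q_so),    Cm = Σ_sp (m_sp - [ZL]_sp)²
```

minimized by constant-step gradient descent (α = 1 fits the microbiome
alone; joint fits here use α = 0.975). A BIC-selected Gaussian mixture
p₀(z) over the fitted embeddings makes the model generative: sampling z
and composing through Θ (and L) yields realistic in-silico
microbiome/phenotype cohorts, assigns likelihoods to unseen communities,
and — by tilting the latent density with a quadratic penalty
`log p(z) = log p₀(z) - Σ γ(ẑ·L - target)²` sampled via Metropolis MCMC —
designs communities matching user-specified host phenotypes.

The package is aimed at microbiome researchers and engineers who want to
ask: which host phenotypes constrain community composition, how
context-specific are taxon/phenotype associations, and what microbiomes
plausibly accompany a desired host state?

## Worked example

```python
import numpy as np
import crlatent as cr

# generate a synthetic cohort with planted rank-3 structure and 3 phenotypes
cohort = cr.model_based_cohort(K_true=3, S=120, O=25, P=3, seed=7)

# joint fit: microbiome + phenotypes share the latent space
model = cr.LatentCompositionModel(n_latent=3, alpha=0.975, random_state=0)
model.fit(cohort.table, phenotypes=cohort.phenotypes)
Q = model.predict_composition()
X = cohort.table.to_relative().values
bc = np.mean([cr.bray_curtis(x, q) for x, q in zip(X, Q)])
print(f"converged after {model.n_iter_} iterations; mean Bray-Curtis(fit, data) = {bc:.4f}")

# latent distribution and unbiased generation
mixture = cr.LatentGaussianMixture(n_restarts=10, random_state=0).fit(model.embedding_)
print(f"BIC selected {mixture.n_components_} mixture component(s)")
cohort_gen = cr.sample_cohort(mixture, model, n=5000, random_state=1)
report = cr.generative_diagnostics(cohort.table, cohort_gen, random_state=1)
r = np.corrcoef(report.taxon_mean_real, report.taxon_mean_generated)[0, 1]
print(f"taxon mean abundances, real vs generated: r^2 = {r**2:.4f}")

# biased sampling toward a +2 SD phenotype target
spec = cr.BiasSpec(targets={"p0": 2.0}, gamma=2.0)
biased = cr.sample_biased(mixture, model, spec, cr.MCMCConfig(seed=2))
print(f"mean z-scored p0: unbiased {cohort_gen.phenotypes_z[:, 0].mean():+.3f}, "
      f"biased {biased.phenotypes_z[:, 0].mean():+.3f}")
```

Output:

```
converged after 13200 iterations; mean Bray-Curtis(fit, data) = 0.0050
BIC selected 1 mixture component(s)
taxon mean abundances, real vs generated: r^2 = 0.9971
mean z-scored p0: unbiased -0.059, biased +1.595
```

The fit reproduces the observed compositions almost exactly (mean
Bray-Curtis 0.005 on a 0–1 scale); the generated cohort reproduces the
per-taxon mean abundances of the data; and the γ = 2 biased sampler moves
the target phenotype from its unbiased mean of ≈0 to ≈+1.6 SD while
keeping every generated community inside the model's feasible set.

The same pipeline is scriptable from a shell — `crlatent fit`, `embed`,
`scan`, `gmm`, `generate`, `design`, `predict`, `constraint-profile`,
`local-corr`, `diagnostics`, `simulate` — with TSV tables in and out and a
JSON config snapshot written next to every output.

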