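# Methods

## Model

The package models relative abundances of O taxa across S hosts as a
softmax over a low-rank product,

    q_so = exp(-Σ_k z_sk θ_ko) / Ω_s,   k = 1..K,

which follows from formally integrating consumer/resource dynamics: a
species' log-abundance is the time integral of its growth rate, growth
rates are linear in resource abundances weighted by species preferences,
and so log-abundances are linear in the integrated resource histories
z_k = -∫ r_k dτ. The key structural assumptions are (i) preferences θ_ko
are universal across hosts of one system while the latent variables z_sk
are host-specific, and (ii) a small number K of *effective* resources
suffices — the latent variables are emergent combinations of factors that
positively and negatively affect growth, not concentrations of specific
nutrients at a specific time. The death/dilution term is absorbed as one
extra latent dimension (z = elapsed time, θ = death rates), which is why
fits to raw consumer/resource simulations use K = (number of resources) + 1.

Host phenotypes enter through a linear head M ≈ Z L with identity link.
The joint objective is

    C = α·Ce + (1-α)·Cm

with Ce the KL divergence Σ x log(x/q) between observed and modelled
compositions (equivalent, up to the data entropy, to the multinomial
cross-entropy / negative log-likelihood) and Cm the squared error over
observed phenotype entries. α always weights the microbiome term: α = 1 is
a microbiome-only fit, and joint fits default to α = 0.975, which strongly
favors the microbiome while letting phenotypes shape the latent space.
Missing phenotype entries are masked out of Cm and its gradients;
phenotypes are z-scored per column before fitting and the scaling
statistics are stored for inverse transforms.

Only the product ZΘ is identifiable — (Z, Θ) → (ZA, A⁻¹Θ) leaves every
composition unchanged — so all quality measures compare compositions (or
the singular spectrum of ZΘ), never raw factors.

## Fitting

Parameters are learned by constant-step gradient descent with analytic
gradients (∂Ce/∂Z = (X-Q)Θᵀ, ∂Ce/∂Θ = Zᵀ(X-Q), and the usual least-squares
forms for the phenotype head). Z, Θ, L are initialized from seeded
Gaussians with scale 0.1, which starts the model near the uniform
composition and keeps early gradients small. Descent stops when the sum
over updated matrices of ‖gradient‖₂/‖matrix‖₂ drops below `grad_tol`
(default 1e-2; recovery studies tighten this to 1e-3–2e-3) or at
`max_iter`. The default learning rate is 1e-3; the loss is checked at
trace checkpoints and a divergent or underflowing iterate raises with
advice to reduce it. Transient loss increases (constant-step overshoot)
are recorded as warnings rather than aborting. A zero-norm matrix in the
stopping ratio contributes 0 with a warning. New samples are embedded by
the same descent with Θ (and L) frozen; taxa are matched to the trained
model by label.

Numerical conventions: softmax rows are max-shifted before
exponentiation, so compositions are always strictly positive and no
pseudo-counts are needed; 0·log 0 := 0 throughout; entropies and KL use
natural logarithms (the species-abundance power-law slope alone uses
log10, matching how such fits are usually displayed). θ is fit
unconstrained: although raw consumer/resource preferences are
nonnegative, the latent representation absorbs death rates and signed
effective-resource combinations.

Rare taxa (mean relative abundance below 0.1% by default) can be
aggregated into a single trailing "OTHER" taxon that stays in the model;
this mirrors the usual technical-noise floor for 16S surveys.

## Latent distribution and generation

A Gaussian mixture with full covariances is fit to the training
embeddings by EM; the component count (1–5) is chosen by BIC, with many
restarts per count (the best-likelihood restart at a fixed count is also
the lowest-BIC one) and ties broken toward fewer components. Covariance
eigenvalues are floored by a 1e-6 regularization. Full covariances are
used because latent dimensions are correlated by construction. Cohorts
are generated by sampling z from the mixture, composing abundances
through Θ, optionally drawing multinomial reads at a requested depth, and
emitting phenotypes as Z L mapped back to original units. Generated
phenotypes are noiseless by default; a Gaussian residual (SD in z-score
units) can be added.

## Design analyses

*Biased sampling.* The latent log-density is tilted by
-Σ_targets γ(ẑL - target)² with targets in z-score units (γ = 2 by
default, γ = 0 recovering the unbiased model) and sampled by random-walk
Metropolis: 100 chains of 5,000 steps, 1,000-step burn-in, thinning 10,
isotropic Gaussian proposals. The default proposal scale is 0.25 times
the mean component SD of the mixture — small enough to keep acceptance
high in every latent geometry we generate, large enough to mix within a
chain; an overall acceptance rate below 1% triggers a warning. Pooled
chains are used without deduplication.

*Partial-phenotype prediction.* Samples are drawn from the unbiased
model and retained when every constrained phenotype prediction falls
within 0.2 SD of its target; the prediction is the renormalized mean
composition of the retained samples.

*Constraint profiles.* Samples are split into 10 equal-count bins of one
phenotype; the mean Bray-Curtis over 1,000 random pairs within each bin
is divided by the same quantity over unconstrained pairs. Pairs are drawn
sample-disjoint (random pairings of a shuffled index list), which makes
the per-bin dissimilarities independent draws and the reported standard
errors valid; the normalized value's SE propagates the baseline
uncertainty to first order.

*Local correlations.* For each real host, the 500 generated communities
closest in Bray-Curtis form its neighborhood; per-taxon Pearson
correlations with the phenotype are computed inside the neighborhood and
globally, and the slope of mean-local on global correlations summarizes
attenuation. Constant taxa within a neighborhood get correlation 0 with
an explicit flag rather than NaN. Phenotype enrichment among top
associations uses the upper-tail hypergeometric test.

## Synthetic data

Two generators provide ground truth. `model_based_cohort` draws from the
model class itself (Gaussian or Gaussian-mixture latents, Gaussian Θ and
L with unit scales by default, optional multinomial reads and phenotype
noise) and exposes every generating parameter for recovery tests.
`simulate_cr` integrates the raw consumer/resource ODEs (LSODA, rtol
1e-8, with the latent integrals tracked as extra state; negative
excursions beyond 1e-8 are an error, smaller ones are clipped at save
points), and `snapshot_cohort` builds cross-sectional tables from hosts
that share preferences but differ in resource inflows — data the latent
model class did *not* literally generate, used to test the integration
argument itself. The default C/R family uses uniform(0,1) preferences,
unit efficiencies, uniform(0.1,0.3) death rates, per-host constant
inflows in (1,10), and a snapshot at t = 10, which yields diverse,
non-equilibrium communities dominated by a handful of taxa per host. The
ODE lower integration limit is t = 0 with n(0) as initial condition (an
absorbable constant relative to an infinite-past formulation).

What the generators do **not** emulate: real sequencing artifacts beyond
multinomial sampling (chimeras, copy-number variation, compositional
bias), host covariate structure (farm, diet, breed), phylogenetic
correlation among taxa, and temporal autocorrelation within hosts.
Passing the validation battery therefore shows that the estimators
recover the model's own structure and the C/R bridge at realistic sizes —
not that any particular real ecosystem satisfies the model's assumptions.

## Validation study sizes

The standard studies (`crlatent.experiments`) use scaled-down cohorts
chosen to be representative of, and faster than, typical published
cohorts: 40–150 hosts, 10–40 taxa, latent ranks 2–4, read depths 10⁴,
50-host held-out sets, 20 repetitions for mixture selection, 100 MCMC
chains, 20,000-sample generated cohorts for the constraint analyses, and
30 + 10 consumer/resource hosts for the bridge. In the mixture-recovery
study the matched mean error is reported as the average over repetitions:
at 250 draws per component in 4 dimensions the estimation-noise floor on
a single component mean is ~0.13, so the average — not the worst case —
is the stable summary at this size.

## Known limitations

The latent space is emergent and not guaranteed to align with measurable
resources; the phenotype head is linear by design; sampling is
correlational — biased cohorts are plausible states, not predicted
outcomes of interventions; embeddings are identifiable only up to the
gauge; and joint learning of the embedding and the mixture (EM-style) is
out of scope, as is any processing of raw sequencing reads.
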