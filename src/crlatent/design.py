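"""Community design via biased sampling and phenotype-constraint analyses.

Three questions about a fitted microbiome/phenotype model are answered here:
which host phenotypes constrain community composition and how strongly; what
microbiome does a host with partially known phenotypes plausibly carry; and
how context-specific are taxon/phenotype associations.  The engine for all
of them is the generative model: the latent prior p0(z) can be tilted toward
target phenotype values by a quadratic penalty,

    log p(z) = log p0(z) - sum_targets gamma * (predicted phenotype - target)^2

(phenotypes predicted as z @ L in z-score units), and sampled by
Metropolis random-walk MCMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.utils import check_random_state

from .metrics import bray_curtis
from .mixture import GeneratedCohort, LatentGaussianMixture
from .model import LatentCompositionModel, compose

__all__ = [
    "BiasSpec",
    "MCMCConfig",
    "biased_log_density",
    "sample_biased",
    "predict_from_partial_phenotypes",
    "phenotype_constraint_profile",
    "local_correlations",
    "enrichment_test",
]


@dataclass
class BiasSpec:
    """Phenotype targets for biased sampling.

    ``targets`` maps phenotype id to a target value in z-score units;
    ``gamma`` sets the strength of the quadratic pull (0 disables the bias,
    2 is the default used for design runs).
    """

    targets: dict
    gamma: float = 2.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings: 100 chains of 5,000 steps by default,
    1,000-step burn-in, thinning every 10 retained states."""

    n_chains: int = 100
    n_steps: int = 5000
    burn_in: int = 1000
    proposal_scale: float | None = None  # default: 0.25 * mean component SD
    thin: int = 10
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_chains, self.n_steps, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("chain settings must be positive")
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")


def _target_columns(spec: BiasSpec, phenotype_ids):
    cols, values = [], []
    for pid, val in spec.targets.items():
        if phenotype_ids is None:
            col = int(pid)  # integer-indexed loadings
        else:
            if pid not in phenotype_ids:
                raise KeyError(f"unknown phenotype id {pid!r}")
            col = phenotype_ids.index(pid)
        cols.append(col)
        values.append(float(val))
    return np.asarray(cols, dtype=int), np.asarray(values, dtype=float)


def biased_log_density(
    mixture: LatentGaussianMixture, L: np.ndarray, spec: BiasSpec, z: np.ndarray,
    phenotype_ids=None,
) -> np.ndarray:
    """log p0(z) minus gamma times squared phenotype-target mismatch.

    ``z`` may be a single K-vector or an (n, K) batch; predicted phenotypes
    are z @ L in z-score units.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    cols, targets = _target_columns(spec, phenotype_ids)
    logp = mixture.score_samples(z)
    pred = z @ np.asarray(L, dtype=float)[:, cols]
    penalty = spec.gamma * ((pred - targets) ** 2).sum(axis=1)
    return logp - penalty


def sample_biased(
    mixture: LatentGaussianMixture,
    model: LatentCompositionModel,
    spec: BiasSpec,
    mcmc: MCMCConfig | None = None,
) -> GeneratedCohort:
    """Sample the phenotype-biased latent distribution by Metropolis MCMC.

    Chains start from draws of the unbiased mixture, use an isotropic
    Gaussian proposal, and are pooled after burn-in and thinning.  The
    retained latent points are composed into microbiomes and phenotypes
    exactly as in unbiased generation.
    """
    if model.loadings_ is None:
        raise ValueError("biased sampling needs a model with a phenotype head")
    mcmc = mcmc or MCMCConfig()
    rng = check_random_state(mcmc.seed)
    scale = mcmc.proposal_scale
    if scale is None:
        comp_sd = np.sqrt(
            np.mean([np.trace(c) / c.shape[0] for c in mixture.covariances_])
        )
        scale = 0.25 * comp_sd
    L = model.loadings_

    def logp(z):
        return biased_log_density(mixture, L, spec, z, model.phenotype_ids_)

    pos = mixture.sample(mcmc.n_chains, random_state=rng)
    lp = logp(pos)
    kept = []
    n_accept = 0
    n_prop = 0
    for step in range(1, mcmc.n_steps + 1):
        prop = pos + rng.normal(scale=scale, size=pos.shape)
        lp_prop = logp(prop)
        accept = np.log(rng.uniform(size=len(lp))) < lp_prop - lp
        pos = np.where(accept[:, None], prop, pos)
        lp = np.where(accept, lp_prop, lp)
        n_accept += int(accept.sum())
        n_prop += len(accept)
        if step > mcmc.burn_in and (step - mcmc.burn_in) % mcmc.thin == 0:
            kept.append(pos.copy())
    rate = n_accept / n_prop
    if rate < 0.01:
        warnings.warn(
            f"MCMC acceptance rate {rate:.3f} is below 1%; consider a smaller proposal_scale"
        )
    Z = np.vstack(kept)
    comps = compose(Z, model.preferences_)
    phen_z = Z @ L
    phen = phen_z * model.phenotype_sd_ + model.phenotype_mean_
    cohort = GeneratedCohort(
        Z=Z,
        compositions=comps,
        phenotypes_z=phen_z,
        phenotypes=phen,
        taxon_ids=model.taxon_ids_,
        phenotype_ids=model.phenotype_ids_,
        seed=mcmc.seed,
    )
    cohort.acceptance_rate = rate
    return cohort


def predict_from_partial_phenotypes(
    mixture: LatentGaussianMixture,
    model: LatentCompositionModel,
    constraints,
    n_draws: int = 100_000,
    tolerance: float = 0.2,
    random_state=None,
):
    """Predict a microbiome from partially known host phenotypes.

    Draws ``n_draws`` samples from the unbiased generative model, keeps
    those whose predicted phenotypes fall within ``tolerance`` (in SD
    units, default 0.2) of every constrained value, and returns the
    renormalized mean composition of the retained samples together with
    the match count.

    ``constraints`` is a list of ``(phenotype_id, value)`` or
    ``(phenotype_id, value, tolerance)`` with values in z-score units.
    """
    if model.loadings_ is None:
        raise ValueError("prediction needs a model with a phenotype head")
    rng = check_random_state(random_state)
    Z = mixture.sample(n_draws, random_state=rng)
    pred = Z @ model.loadings_
    keep = np.ones(n_draws, dtype=bool)
    phen_ids = model.phenotype_ids_
    for item in constraints:
        pid, value = item[0], float(item[1])
        tol = float(item[2]) if len(item) > 2 else tolerance
        if phen_ids is not None:
            if pid not in phen_ids:
                raise KeyError(f"unknown phenotype id {pid!r}")
            col = phen_ids.index(pid)
        else:
            col = int(pid)
        keep &= np.abs(pred[:, col] - value) <= tol
    n_matched = int(keep.sum())
    if n_matched == 0:
        raise ValueError(
            "no generated samples matched the constraints; "
            "increase n_draws or the tolerance"
        )
    comps = compose(Z[keep], model.preferences_)
    mean_comp = comps.mean(axis=0)
    mean_comp /= mean_comp.sum()
    return mean_comp, n_matched


def phenotype_constraint_profile(
    cohort: GeneratedCohort,
    phenotype_id,
    n_bins: int = 10,
    pairs_per_bin: int = 1000,
    random_state=None,
) -> pd.DataFrame:
    """How strongly does fixing one phenotype constrain the microbiome?

    Samples are binned into ``n_bins`` equal-count (quantile) bins of the
    phenotype; within each bin the mean Bray-Curtis over random pairs is
    computed and divided by the mean Bray-Curtis over equally many
    unconstrained random pairs.  Values well below 1 in a bin mean that
    specifying the phenotype in that range narrows the space of feasible
    communities; an uninformative phenotype stays near 1 everywhere.

    Returns a DataFrame with bin centers, normalized dissimilarity and
    standard errors; bins with fewer than 2 samples are reported as NaN.
    """
    if cohort.phenotypes_z is None:
        raise ValueError("cohort has no phenotypes")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    rng = check_random_state(random_state)
    if cohort.phenotype_ids is not None and phenotype_id in cohort.phenotype_ids:
        col = cohort.phenotype_ids.index(phenotype_id)
    else:
        col = int(phenotype_id)
    phen = cohort.phenotypes_z[:, col]
    X = cohort.compositions
    edges = np.quantile(phen, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-12
    baseline_pairs = _random_pair_bc(X, np.arange(len(phen)), pairs_per_bin, rng)
    baseline = baseline_pairs.mean()
    base_rel_var = baseline_pairs.var(ddof=1) / len(baseline_pairs) / baseline**2
    rows = []
    for b in range(n_bins):
        sel = np.where((phen >= edges[b]) & (phen < edges[b + 1]))[0]
        center = 0.5 * (edges[b] + edges[b + 1])
        if sel.size < 2:
            rows.append(
                {"bin": b, "phenotype_center": center, "n_samples": int(sel.size),
                 "normalized_bc": np.nan, "se": np.nan}
            )
            continue
        pairs = _random_pair_bc(X, sel, pairs_per_bin, rng)
        ratio = pairs.mean() / baseline
        # pairs are sample-disjoint, so both mean SEs are valid; the ratio SE
        # combines them by first-order propagation
        rel_var = pairs.var(ddof=1) / len(pairs) / pairs.mean() ** 2
        rows.append(
            {
                "bin": b,
                "phenotype_center": center,
                "n_samples": int(sel.size),
                "normalized_bc": ratio,
                "se": ratio * np.sqrt(rel_var + base_rel_var),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["baseline_bc"] = float(baseline)
    df.attrs["baseline_se"] = float(baseline_pairs.std(ddof=1) / np.sqrt(len(baseline_pairs)))
    return df


def _random_pair_bc(X, idx, n_pairs, rng):
    """Bray-Curtis over random sample-disjoint pairs within ``idx``.

    Pairs come from random pairings of shuffled indices (consecutive
    elements), so within one round no sample appears twice and the pair
    dissimilarities are independent draws; multiple rounds are used only
    when more pairs are requested than the bin can host disjointly.
    """
    idx = np.asarray(idx)
    if idx.size < 2:
        raise ValueError("could not draw distinct pairs")
    out = []
    remaining = n_pairs
    while remaining > 0:
        perm = idx[rng.permutation(idx.size)]
        take = min(remaining, idx.size // 2)
        a = perm[: 2 * take : 2]
        b = perm[1 : 2 * take : 2]
        diffs = np.abs(X[a] - X[b]).sum(axis=1)
        sums = (X[a] + X[b]).sum(axis=1)
        out.append(diffs / sums)
        remaining -= take
    return np.concatenate(out)


@dataclass
class LocalCorrelationResult:
    """Host-specific vs global taxon/phenotype correlations."""

    local: np.ndarray  # hosts x taxa local Pearson correlations
    global_: np.ndarray  # per-taxon global Pearson correlations
    constant_flags: np.ndarray  # hosts x taxa; True where a taxon was constant
    slope: float  # least-squares slope of mean-local vs global
    neighborhood_size: int = 0
    extras: dict = field(default_factory=dict)


def _pearson_columns(X, y):
    """Pearson correlation of each column of X with y; constant columns -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    flags = (sx == 0) | (sy == 0)
    denom = np.where(flags, 1.0, sx * sy)
    r = (Xc * yc[:, None]).mean(axis=0) / denom
    r = np.where(flags, 0.0, r)
    return r, flags


def local_correlations(
    cohort: GeneratedCohort,
    real_hosts,
    phenotype_id,
    neighborhood_size: int = 500,
    random_state=None,
) -> LocalCorrelationResult:
    """Context-specific taxon/phenotype associations around each real host.

    For every real host the ``neighborhood_size`` generated communities
    closest in Bray-Curtis are selected and the per-taxon Pearson
    correlation with the phenotype computed inside that neighborhood;
    the global correlation uses all generated samples.  The summary slope
    regresses mean-local on global correlations — a slope below 1 indicates
    that associations attenuate (or flip) across host contexts.
    """
    if neighborhood_size < 10:
        raise ValueError("neighborhood_size must be at least 10")
    if cohort.phenotypes_z is None:
        raise ValueError("cohort has no phenotypes")
    from .tables import AbundanceTable

    if isinstance(real_hosts, AbundanceTable):
        H = real_hosts.to_relative().values
    else:
        H = np.asarray(real_hosts, dtype=float)
    if cohort.phenotype_ids is not None and phenotype_id in cohort.phenotype_ids:
        col = cohort.phenotype_ids.index(phenotype_id)
    else:
        col = int(phenotype_id)
    y = cohort.phenotypes_z[:, col]
    X = cohort.compositions
    if neighborhood_size > X.shape[0]:
        raise ValueError("neighborhood_size exceeds the cohort size")
    global_r, _ = _pearson_columns(X, y)
    local = np.empty((H.shape[0], X.shape[1]))
    flags = np.zeros_like(local, dtype=bool)
    for h in range(H.shape[0]):
        d = np.abs(X - H[h]).sum(axis=1) / (X + H[h]).sum(axis=1)
        nbr = np.argsort(d)[:neighborhood_size]
        local[h], flags[h] = _pearson_columns(X[nbr], y[nbr])
    mean_local = local.mean(axis=0)
    slope, _ = np.polyfit(global_r, mean_local, 1)
    return LocalCorrelationResult(
        local=local,
        global_=global_r,
        constant_flags=flags,
        slope=float(slope),
        neighborhood_size=neighborhood_size,
    )


def enrichment_test(hits_in_category, draws, category_size, population_size) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= hits).

    The probability of seeing at least ``hits_in_category`` members of a
    category of size ``category_size`` among ``draws`` draws without
    replacement from a population of ``population_size``.
    """
    hits, n, Kc, N = (int(hits_in_category), int(draws), int(category_size), int(population_size))
    if not (0 <= hits <= min(n, Kc) and Kc <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: hits={hits}, draws={n}, category={Kc}, population={N}"
        )
    return float(hypergeom.sf(hits - 1, N, Kc, n))
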