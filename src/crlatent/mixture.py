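"""Gaussian-mixture model of the latent space and cohort generation.

A mixture of full-covariance multivariate Gaussians is fit to the latent
embeddings of the training samples; the number of components (1-5 by
default) is chosen by BIC over many restarts.  Sampling latent points from
the fitted mixture and pushing them through the composition model (and the
linear phenotype head, when present) generates realistic in-silico
microbiome/phenotype cohorts and assigns a likelihood to any latent
coordinate profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils import check_random_state

from .model import LatentCompositionModel, compose

__all__ = ["LatentGaussianMixture", "GeneratedCohort", "sample_cohort", "generative_diagnostics"]


class LatentGaussianMixture(BaseEstimator, DensityMixin):
    """BIC-selected Gaussian mixture over latent coordinates.

    For each candidate component count (1..max_components) the EM fit is
    restarted ``n_restarts`` times and the best (highest-likelihood, hence
    lowest-BIC at fixed component count) solution kept; the component count
    with the overall lowest BIC wins, ties going to the smaller model.

    Attributes
    ----------
    n_components_ : selected number of components.
    weights_, means_, covariances_ : mixture parameters.
    bic_ : BIC of the selected model; bics_ maps component count to BIC.
    """

    def __init__(
        self,
        max_components=5,
        n_restarts=100,
        reg_covar=1e-6,
        max_iter=500,
        random_state=None,
    ):
        self.max_components = max_components
        self.n_restarts = n_restarts
        self.reg_covar = reg_covar
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, Z, y=None):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2:
            raise ValueError("Z must be 2-d (samples by latent dimensions)")
        S, K = Z.shape
        if S < 2:
            raise ValueError("need at least 2 samples to fit a mixture")
        if S <= K:
            import warnings

            warnings.warn(
                f"fewer samples ({S}) than latent dimensions + 1 ({K + 1}); "
                "covariances rely on the regularization floor"
            )
        rng = check_random_state(self.random_state)
        best = None
        self.bics_ = {}
        for k in range(1, int(self.max_components) + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=self.reg_covar,
                max_iter=self.max_iter,
                n_init=self.n_restarts,
                random_state=rng.randint(2**31 - 1),
            ).fit(Z)
            bic = gm.bic(Z)
            self.bics_[k] = float(bic)
            if best is None or bic < best[0] - 1e-12:  # ties keep fewer components
                best = (bic, k, gm)
        self.bic_, self.n_components_, self.gmm_ = best
        self.weights_ = self.gmm_.weights_
        self.means_ = self.gmm_.means_
        self.covariances_ = self.gmm_.covariances_
        self.n_features_in_ = K
        return self

    def score_samples(self, Z):
        """Per-sample log-density under the fitted mixture."""
        self._check_fitted()
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.gmm_.score_samples(Z)

    def score(self, Z, y=None):
        return float(self.score_samples(Z).mean())

    def sample(self, n, random_state=None):
        """Draw n latent points; fully determined by ``random_state``."""
        self._check_fitted()
        rng = check_random_state(random_state)
        comps = rng.choice(len(self.weights_), size=int(n), p=self.weights_)
        Z = np.empty((int(n), self.means_.shape[1]))
        for c in range(len(self.weights_)):
            idx = np.where(comps == c)[0]
            if idx.size:
                Z[idx] = rng.multivariate_normal(
                    self.means_[c], self.covariances_[c], size=idx.size
                )
        return Z

    def _check_fitted(self):
        if not hasattr(self, "gmm_"):
            raise ValueError("mixture is not fitted; call fit first")


@dataclass
class GeneratedCohort:
    """An in-silico cohort: latent draws, compositions, optional phenotypes.

    ``phenotypes_z`` holds z-scored values (the scale the latent model works
    on); ``phenotypes`` holds the same values mapped back to original units.
    ``counts`` is present only when a sequencing depth was requested.
    """

    Z: np.ndarray
    compositions: np.ndarray
    phenotypes_z: np.ndarray | None = None
    phenotypes: np.ndarray | None = None
    counts: np.ndarray | None = None
    taxon_ids: list | None = None
    phenotype_ids: list | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.compositions.shape[0]


def sample_cohort(
    mixture: LatentGaussianMixture,
    model: LatentCompositionModel,
    n: int,
    random_state=None,
    depth: int | None = None,
    phenotype_noise_sd: float | None = None,
) -> GeneratedCohort:
    """Generate an in-silico cohort from a fitted mixture and model.

    Latent points are drawn from the mixture and composed into relative
    abundances; when the model carries a phenotype head, phenotypes are
    emitted as Z @ L (noiseless by default; ``phenotype_noise_sd`` adds a
    Gaussian residual in z-score units).  ``depth`` additionally draws
    multinomial read counts per sample.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = check_random_state(random_state)
    Z = mixture.sample(n, random_state=rng)
    comps = compose(Z, model.preferences_)
    phen_z = phen = None
    if model.loadings_ is not None:
        phen_z = Z @ model.loadings_
        if phenotype_noise_sd is not None and phenotype_noise_sd > 0:
            phen_z = phen_z + rng.normal(scale=phenotype_noise_sd, size=phen_z.shape)
        phen = phen_z * model.phenotype_sd_ + model.phenotype_mean_
    counts = None
    if depth is not None:
        counts = np.vstack([rng.multinomial(int(depth), row) for row in comps])
    return GeneratedCohort(
        Z=Z,
        compositions=comps,
        phenotypes_z=phen_z,
        phenotypes=phen,
        counts=counts,
        taxon_ids=model.taxon_ids_,
        phenotype_ids=model.phenotype_ids_,
    )


@dataclass
class DiagnosticsReport:
    """Summary statistics comparing a real table against a generated cohort."""

    taxon_mean_real: np.ndarray
    taxon_mean_generated: np.ndarray
    taxon_sd_real: np.ndarray
    taxon_sd_generated: np.ndarray
    covariance_real: np.ndarray
    covariance_generated: np.ndarray
    shannon_real: np.ndarray
    shannon_generated: np.ndarray
    bc_random_real: np.ndarray
    bc_random_generated: np.ndarray
    bc_nearest_real: np.ndarray
    bc_nearest_generated: np.ndarray
    sad_grid: np.ndarray
    sad_real: np.ndarray
    sad_generated: np.ndarray
    sad_slope_real: float | None = None
    sad_slope_generated: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        payload = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                payload[k] = v.tolist()
            else:
                payload[k] = v
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DiagnosticsReport":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {}
        for k, v in payload.items():
            if isinstance(v, list):
                kwargs[k] = np.asarray(v, dtype=float)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def _bc_pairs(X, n_pairs, rng):
    from .metrics import bray_curtis

    S = X.shape[0]
    i = rng.randint(0, S, size=n_pairs)
    j = rng.randint(0, S, size=n_pairs)
    keep = i != j
    return np.array([bray_curtis(X[a], X[b]) for a, b in zip(i[keep], j[keep])])


def _bc_nearest(X):
    """Per-sample Bray-Curtis to the closest other sample."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(D, np.inf)
    return D.min(axis=1)


def generative_diagnostics(
    real,
    generated: GeneratedCohort,
    n_random_pairs: int = 2000,
    sad_grid=None,
    random_state=None,
) -> DiagnosticsReport:
    """Compare low-order statistics of real vs generated cohorts.

    Computes per-taxon means and SDs, the taxon-taxon covariance of
    abundance fluctuations, Shannon-diversity distributions, Bray-Curtis
    distributions over random and nearest-neighbor pairs, and the inverse
    cumulative species-abundance distribution with its power-law slope on
    [1e-3, 1e-1] (slopes omitted when too few curve points fall in range).
    """
    from .metrics import (
        abundance_moments,
        inverse_cdf_sad,
        power_law_slope,
        shannon_diversity,
    )
    from .tables import AbundanceTable

    if isinstance(real, AbundanceTable):
        Xr = real.to_relative().values
    else:
        Xr = np.asarray(real, dtype=float)
    Xg = generated.compositions
    if Xr.shape[1] != Xg.shape[1]:
        raise ValueError(
            f"taxon count mismatch: real {Xr.shape[1]} vs generated {Xg.shape[1]}"
        )
    if Xr.shape[0] < 2 or Xg.shape[0] < 2:
        raise ValueError("need at least 2 samples on each side")
    rng = check_random_state(random_state)
    mean_r, sd_r, cov_r = abundance_moments(Xr)
    mean_g, sd_g, cov_g = abundance_moments(Xg)
    if sad_grid is None:
        sad_grid = np.logspace(-5, 0, 60)
    sad_grid = np.asarray(sad_grid, dtype=float)
    sad_r = inverse_cdf_sad(Xr, sad_grid)
    sad_g = inverse_cdf_sad(Xg, sad_grid)

    def _maybe_slope(curve):
        try:
            return power_law_slope(sad_grid, curve)
        except ValueError:
            return None

    return DiagnosticsReport(
        taxon_mean_real=mean_r,
        taxon_mean_generated=mean_g,
        taxon_sd_real=sd_r,
        taxon_sd_generated=sd_g,
        covariance_real=cov_r,
        covariance_generated=cov_g,
        shannon_real=np.array([shannon_diversity(x) for x in Xr]),
        shannon_generated=np.array([shannon_diversity(x) for x in Xg]),
        bc_random_real=_bc_pairs(Xr, n_random_pairs, rng),
        bc_random_generated=_bc_pairs(Xg, n_random_pairs, rng),
        bc_nearest_real=_bc_nearest(Xr),
        bc_nearest_generated=_bc_nearest(Xg),
        sad_grid=sad_grid,
        sad_real=sad_r,
        sad_generated=sad_g,
        sad_slope_real=_maybe_slope(sad_r),
        sad_slope_generated=_maybe_slope(sad_g),
    )
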