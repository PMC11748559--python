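"""Model archives: lossless save/load of fitted models and mixtures.

A fitted :class:`LatentCompositionModel` (and optionally the latent
Gaussian mixture trained on its embedding) is stored in a single
numpy ``.npz`` archive together with estimator parameters, label lists,
phenotype scaling statistics, the loss trace and a format version string.
Round trips are exact to float64 precision.
"""

from __future__ import annotations

import json

import numpy as np

from .mixture import LatentGaussianMixture
from .model import LatentCompositionModel

FORMAT_VERSION = "crlatent-model-1"

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]


def save_model(model: LatentCompositionModel, path, mixture: LatentGaussianMixture | None = None) -> None:
    """Write a fitted model (and optional mixture) to a single archive."""
    model._check_fitted()
    meta = {
        "format_version": FORMAT_VERSION,
        "params": model.get_params(),
        "sample_ids": model.sample_ids_,
        "taxon_ids": model.taxon_ids_,
        "phenotype_ids": model.phenotype_ids_,
        "converged": bool(model.converged_),
        "n_iter": int(model.n_iter_),
        "has_mixture": mixture is not None,
    }
    arrays = {
        "embedding": model.embedding_,
        "preferences": model.preferences_,
        "loss_trace": model.loss_trace_,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.loadings_ is not None:
        arrays["loadings"] = model.loadings_
        arrays["phenotype_mean"] = model.phenotype_mean_
        arrays["phenotype_sd"] = model.phenotype_sd_
    if mixture is not None:
        mixture._check_fitted()
        arrays["gmm_weights"] = mixture.weights_
        arrays["gmm_means"] = mixture.means_
        arrays["gmm_covariances"] = mixture.covariances_
        arrays["gmm_bic"] = np.array([mixture.bic_])
        meta["gmm_params"] = mixture.get_params()
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    """Load a model archive; returns (model, mixture-or-None).

    Raises a clean error on truncated files or version mismatches; no
    partially initialized state escapes.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # zipfile/OSError on truncation
        raise ValueError(f"could not read model archive {path}: {exc}") from exc
    if "meta" not in arrays:
        raise ValueError(f"{path} is not a crlatent model archive")
    meta = json.loads(bytes(arrays["meta"].tobytes()).decode())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"archive format {version!r} does not match expected {FORMAT_VERSION!r}"
        )
    model = LatentCompositionModel(**meta["params"])
    model.embedding_ = arrays["embedding"]
    model.preferences_ = arrays["preferences"]
    model.loss_trace_ = arrays["loss_trace"]
    model.sample_ids_ = meta["sample_ids"]
    model.taxon_ids_ = meta["taxon_ids"]
    model.phenotype_ids_ = meta["phenotype_ids"]
    model.converged_ = meta["converged"]
    model.n_iter_ = meta["n_iter"]
    model.n_features_in_ = model.preferences_.shape[1]
    if "loadings" in arrays:
        model.loadings_ = arrays["loadings"]
        model.phenotype_mean_ = arrays["phenotype_mean"]
        model.phenotype_sd_ = arrays["phenotype_sd"]
    else:
        model.loadings_ = None
        model.phenotype_mean_ = None
        model.phenotype_sd_ = None
    mixture = None
    if meta.get("has_mixture"):
        mixture = _rebuild_mixture(meta, arrays)
    return model, mixture


def _rebuild_mixture(meta, arrays):
    from sklearn.mixture import GaussianMixture

    mixture = LatentGaussianMixture(**meta["gmm_params"])
    weights = arrays["gmm_weights"]
    means = arrays["gmm_means"]
    covs = arrays["gmm_covariances"]
    k, dim = means.shape
    gm = GaussianMixture(n_components=k, covariance_type="full", reg_covar=mixture.reg_covar)
    gm.weights_ = weights
    gm.means_ = means
    gm.covariances_ = covs
    from scipy.linalg import solve_triangular

    eye = np.eye(dim)
    gm.precisions_cholesky_ = np.array(
        [solve_triangular(np.linalg.cholesky(c), eye, lower=True).T for c in covs]
    )
    gm.converged_ = True
    gm.n_iter_ = 0
    mixture.gmm_ = gm
    mixture.weights_ = weights
    mixture.means_ = means
    mixture.covariances_ = covs
    mixture.n_components_ = k
    mixture.bic_ = float(arrays["gmm_bic"][0])
    mixture.bics_ = {k: mixture.bic_}
    mixture.n_features_in_ = dim
    return mixture
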