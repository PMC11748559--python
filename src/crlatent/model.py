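"""Latent-variable composition model derived from consumer/resource dynamics.

Formally integrating consumer/resource (C/R) dynamics shows that a species'
abundance is (approximately) an exponential function of latent variables
``z_k`` — the time-integrated histories of effective resources — weighted by
species-specific preferences ``theta_ko`` that are shared across hosts of the
same system.  Relative abundances are therefore a softmax over ``-Z @ Theta``:

    q_so = exp(-sum_k z_sk theta_ko) / Omega_s

Fitting this to a cross-sectional sample-by-taxon table is a nonlinear
low-rank factorization, done here by constant-step gradient descent on the
KL divergence between observed and modelled compositions, optionally sharing
the latent space with a linear model of host phenotypes:

    C = alpha * Ce + (1 - alpha) * Cm

with ``Ce = sum_so x_so log(x_so / q_so)`` and ``Cm`` the squared error of
``M ~ Z @ L`` over observed phenotype entries.  ``alpha = 1`` fits the
microbiome alone.

Only the product ``Z @ Theta`` (and hence the compositions) is identifiable:
``(Z, Theta) -> (Z A, A^-1 Theta)`` leaves the model unchanged for any
invertible ``A``, so analyses compare compositions, never raw factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state

from .tables import AbundanceTable, PhenotypeMatrix

__all__ = [
    "compose",
    "microbiome_loss",
    "phenotype_loss",
    "combined_loss",
    "gradients",
    "LatentCompositionModel",
    "scramble_preferences",
    "singular_spectrum",
    "SingularSpectrum",
    "dimension_scan",
]


def compose(Z: np.ndarray, Theta: np.ndarray) -> np.ndarray:
    """Model compositions q = softmax(-Z @ Theta), row-wise.

    Uses a per-row max shift so the exponentials never overflow; every row
    of the result sums to 1 and all entries are strictly positive.
    """
    Z = np.asarray(Z, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    if Z.ndim != 2 or Theta.ndim != 2 or Z.shape[1] != Theta.shape[0]:
        raise ValueError(
            f"latent dimension mismatch: Z has shape {Z.shape}, Theta has shape {Theta.shape}"
        )
    logits = -Z @ Theta
    logits -= logits.max(axis=1, keepdims=True)
    Q = np.exp(logits)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q


def microbiome_loss(X: np.ndarray, Q: np.ndarray) -> float:
    """KL divergence Ce = sum_so x_so log(x_so / q_so), with 0 log 0 := 0.

    This equals the cross-entropy between data and model minus the data
    entropy, so minimizing it is equivalent to maximizing the multinomial
    likelihood of the observed compositions.
    """
    X = np.asarray(X, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if X.shape != Q.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Q {Q.shape}")
    if np.any(Q <= 0):
        raise ValueError("model compositions must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(X > 0, X * (np.log(X) - np.log(Q)), 0.0)
    return float(terms.sum())


def phenotype_loss(
    M: np.ndarray, Z: np.ndarray, L: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Squared L2 loss Cm = sum over observed (s,p) of (m_sp - [Z L]_sp)^2."""
    M = np.asarray(M, dtype=float)
    pred = np.asarray(Z, dtype=float) @ np.asarray(L, dtype=float)
    if M.shape != pred.shape:
        raise ValueError(f"shape mismatch: M {M.shape} vs Z @ L {pred.shape}")
    resid = M - pred
    if mask is not None:
        resid = np.where(mask, resid, 0.0)
    return float((resid**2).sum())


def combined_loss(X, Q, M=None, Z=None, L=None, alpha=1.0, mask=None):
    """C = alpha * Ce + (1 - alpha) * Cm; returns (C, Ce, Cm)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    ce = microbiome_loss(X, Q)
    cm = 0.0
    if M is not None and L is not None:
        cm = phenotype_loss(M, Z, L, mask)
    return alpha * ce + (1.0 - alpha) * cm, ce, cm


def gradients(X, Z, Theta, M=None, L=None, alpha=1.0, mask=None):
    """Analytic gradients of the combined loss.

    dCe/dZ = (X - Q) Theta^T, dCe/dTheta = Z^T (X - Q);
    dCm/dZ = -2 R L^T, dCm/dL = -2 Z^T R with R the masked residual M - Z L.
    Returns (dC/dZ, dC/dTheta, dC/dL) with dC/dL None when no phenotype head.
    """
    Q = compose(Z, Theta)
    X = np.asarray(X, dtype=float)
    if X.shape != Q.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs model {Q.shape}")
    diff = X - Q
    dZ = alpha * (diff @ Theta.T)
    dTheta = alpha * (Z.T @ diff)
    dL = None
    if M is not None and L is not None:
        resid = np.asarray(M, dtype=float) - Z @ L
        if mask is not None:
            resid = np.where(mask, resid, 0.0)
        dZ = dZ + (1.0 - alpha) * (-2.0 * resid @ L.T)
        dL = (1.0 - alpha) * (-2.0 * Z.T @ resid)
    return dZ, dTheta, dL


def _grad_ratio(grads, mats):
    """Sum of ||grad|| / ||matrix|| over the updated matrices (stopping rule)."""
    total = 0.0
    for g, m in zip(grads, mats):
        if g is None:
            continue
        norm = np.linalg.norm(m)
        if norm == 0:
            warnings.warn("zero-norm matrix in stopping ratio; term treated as 0")
            continue
        total += np.linalg.norm(g) / norm
    return total


def _descend(
    X,
    Z,
    Theta,
    M=None,
    L=None,
    mask=None,
    alpha=1.0,
    eta=1e-3,
    grad_tol=1e-2,
    max_iter=50_000,
    update_theta=True,
    update_l=True,
    trace_every=10,
):
    """Constant-step gradient descent shared by fit and embed."""
    trace = []
    prev_c = np.inf
    increase_iters = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dZ, dTheta, dL = gradients(X, Z, Theta, M, L, alpha, mask)
        Z = Z - eta * dZ
        if update_theta:
            Theta = Theta - eta * dTheta
        if update_l and dL is not None:
            L = L - eta * dL
        if it % trace_every == 0 or it == 1:
            Q = compose(Z, Theta)
            if not np.all(np.isfinite(Z)) or np.any(Q <= 0):
                raise FloatingPointError(
                    f"iterates diverged at iteration {it} (compositions underflowed); "
                    f"try a smaller learning rate (eta={eta})"
                )
            c, ce, cm = combined_loss(X, Q, M, Z, L, alpha, mask)
            if not np.isfinite(c):
                raise FloatingPointError(
                    f"loss diverged at iteration {it}; try a smaller learning rate (eta={eta})"
                )
            trace.append((it, c, ce, cm))
            if c > prev_c + 1e-12:
                increase_iters.append(it)
            prev_c = c
            ratio = _grad_ratio(
                (dZ, dTheta if update_theta else None, dL if update_l else None),
                (Z, Theta, L),
            )
            if ratio < grad_tol:
                converged = True
                break
    if increase_iters:
        warnings.warn(
            f"loss increased transiently at {len(increase_iters)} checkpoints "
            f"(first at iteration {increase_iters[0]}); constant-step descent can overshoot"
        )
    return Z, Theta, L, np.array(trace), converged, it


class LatentCompositionModel(BaseEstimator, TransformerMixin):
    """Low-rank softmax factorization of microbiome compositions.

    Parameters
    ----------
    n_latent : dimension K of the latent space.
    alpha : weight of the microbiome term in the combined loss; 1.0 fits
        the microbiome alone, values below 1 share the latent space with
        a linear phenotype model (the analyses here use 0.975).
    learning_rate : constant gradient-descent step size.
    grad_tol : stopping threshold on the summed relative gradient norms
        (sum over matrices of ||grad||/||matrix||).
    max_iter : iteration cap.
    init_scale : sd of the seeded Gaussian initialization of Z, Theta, L;
        small values start the model near the uniform composition.
    trace_every : loss-trace / convergence-check cadence in iterations.
    random_state : seed for initialization.

    Attributes
    ----------
    embedding_ : (S, K) fitted latent coordinates of the training samples.
    preferences_ : (K, O) fitted species preferences toward latent variables.
    loadings_ : (K, P) phenotype loadings, or None without a phenotype head.
    loss_trace_ : array of (iteration, C, Ce, Cm) checkpoints.
    converged_, n_iter_ : stopping diagnostics.
    """

    def __init__(
        self,
        n_latent=16,
        alpha=1.0,
        learning_rate=1e-3,
        grad_tol=1e-2,
        max_iter=50_000,
        init_scale=0.1,
        trace_every=10,
        random_state=None,
    ):
        self.n_latent = n_latent
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.grad_tol = grad_tol
        self.max_iter = max_iter
        self.init_scale = init_scale
        self.trace_every = trace_every
        self.random_state = random_state

    # -- data coercion -------------------------------------------------
    def _coerce_X(self, X, match_fitted=False):
        if isinstance(X, AbundanceTable):
            if match_fitted and self.taxon_ids_ is not None:
                X = X.reorder_taxa(self.taxon_ids_)
            table = X.to_relative()
            return table.values, list(table.sample_ids), list(table.taxon_ids)
        if isinstance(X, pd.DataFrame):
            return self._coerce_X(
                AbundanceTable(
                    list(X.index),
                    list(X.columns),
                    X.to_numpy(dtype=float),
                    is_relative=not np.all(X.to_numpy().sum(axis=1) > 1 + 1e-8),
                ),
                match_fitted,
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d sample-by-taxon array")
        sums = X.sum(axis=1)
        if np.any(X < 0):
            raise ValueError("abundances must be nonnegative")
        if not np.allclose(sums, 1.0, atol=1e-8):
            X = X / sums[:, None]  # counts -> relative
        return X, None, None

    @staticmethod
    def _coerce_M(M):
        if M is None:
            return None, None, None, None, None
        if isinstance(M, PhenotypeMatrix):
            return M.values, M.mask, list(M.phenotype_ids), M.mean, M.sd
        M = np.asarray(M, dtype=float)
        mask = np.isfinite(M)
        return np.where(mask, M, 0.0), mask, None, np.zeros(M.shape[1]), np.ones(M.shape[1])

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None, phenotypes=None):
        """Fit Z, Theta (and L when phenotypes are given) by gradient descent.

        ``X`` may be an :class:`AbundanceTable`, DataFrame or array; counts
        are converted to relative abundances.  ``phenotypes`` may be a
        :class:`PhenotypeMatrix` or an array with NaN for missing entries.
        """
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        Xv, sample_ids, taxon_ids = self._coerce_X(X)
        self.sample_ids_ = sample_ids
        self.taxon_ids_ = taxon_ids
        Mv, mask, phen_ids, phen_mean, phen_sd = self._coerce_M(phenotypes)
        alpha = self.alpha if Mv is not None else 1.0
        if Mv is not None and mask is not None:
            empty = ~mask.any(axis=0)
            if empty.any():
                warnings.warn(
                    f"{int(empty.sum())} phenotype column(s) entirely missing; they contribute 0"
                )
        S, O = Xv.shape
        K = int(self.n_latent)
        if K < 1:
            raise ValueError("n_latent must be positive")
        rng = check_random_state(self.random_state)
        Z = rng.normal(scale=self.init_scale, size=(S, K))
        Theta = rng.normal(scale=self.init_scale, size=(K, O))
        L = None
        if Mv is not None:
            L = rng.normal(scale=self.init_scale, size=(K, Mv.shape[1]))
        Z, Theta, L, trace, converged, n_iter = _descend(
            Xv,
            Z,
            Theta,
            Mv,
            L,
            mask,
            alpha,
            self.learning_rate,
            self.grad_tol,
            self.max_iter,
            trace_every=self.trace_every,
        )
        self.embedding_ = Z
        self.preferences_ = Theta
        self.loadings_ = L
        self.phenotype_ids_ = phen_ids
        self.phenotype_mean_ = phen_mean
        self.phenotype_sd_ = phen_sd
        self.loss_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_features_in_ = O
        return self

    def transform(self, X):
        """Embed new samples under the fitted (fixed) preferences."""
        Z, _ = self.embed(X)
        return Z

    def embed(self, X, max_iter=None, random_state=None):
        """Optimize latent coordinates for new samples, Theta held fixed.

        Returns ``(Z_new, kl)`` where ``kl`` is the per-sample reconstruction
        KL divergence between the data and the embedded model composition.
        """
        self._check_fitted()
        Xv, _, _ = self._coerce_X(X, match_fitted=True)
        if Xv.shape[1] != self.preferences_.shape[1]:
            raise ValueError(
                f"X has {Xv.shape[1]} taxa but the model was fit with "
                f"{self.preferences_.shape[1]}"
            )
        rng = check_random_state(
            self.random_state if random_state is None else random_state
        )
        Z = rng.normal(scale=self.init_scale, size=(Xv.shape[0], self.preferences_.shape[0]))
        Z, _, _, _, _, _ = _descend(
            Xv,
            Z,
            self.preferences_,
            alpha=1.0,
            eta=self.learning_rate,
            grad_tol=self.grad_tol,
            max_iter=self.max_iter if max_iter is None else max_iter,
            update_theta=False,
            trace_every=self.trace_every,
        )
        Q = compose(Z, self.preferences_)
        kl = np.where(Xv > 0, Xv * (np.log(np.where(Xv > 0, Xv, 1.0)) - np.log(Q)), 0.0).sum(axis=1)
        return Z, kl

    def inverse_transform(self, Z):
        """Compositions generated by latent coordinates under fitted preferences."""
        self._check_fitted()
        return compose(np.asarray(Z, dtype=float), self.preferences_)

    def predict_composition(self, Z=None):
        """Model compositions for given (default: training) latent coordinates."""
        self._check_fitted()
        return self.inverse_transform(self.embedding_ if Z is None else Z)

    def predict_phenotypes(self, Z=None, original_units=False):
        """Linear phenotype predictions Z @ L (z-scored by default)."""
        self._check_fitted()
        if self.loadings_ is None:
            raise ValueError("model was fit without phenotypes")
        Z = self.embedding_ if Z is None else np.asarray(Z, dtype=float)
        pred = Z @ self.loadings_
        if original_units:
            pred = pred * self.phenotype_sd_ + self.phenotype_mean_
        return pred

    def score(self, X, y=None):
        """Negative mean per-sample reconstruction KL (higher is better)."""
        _, kl = self.embed(X)
        return -float(kl.mean())

    def _check_fitted(self):
        if not hasattr(self, "preferences_"):
            raise ValueError("model is not fitted; call fit first")


def scramble_preferences(Theta, seed=None) -> np.ndarray:
    """Permute the taxon columns of a preference matrix (null model).

    Destroys the learned taxon/preference pairing while preserving the
    multiset of entries, mirroring the scrambled-preference null used to
    test whether preferences are informative.
    """
    rng = check_random_state(seed)
    Theta = np.asarray(Theta, dtype=float)
    return Theta[:, rng.permutation(Theta.shape[1])]


@dataclass
class SingularSpectrum:
    """Singular values of the Z @ Theta product, sorted descending."""

    values: np.ndarray
    ratios: np.ndarray  # successive ratios lambda_k / lambda_{k+1}


def singular_spectrum(Z, Theta) -> SingularSpectrum:
    """Singular values of Z @ Theta and their successive ratios.

    A sharp drop in the spectrum marks the effective dimension of the
    latent space needed to reproduce the compositions.
    """
    prod = np.asarray(Z, dtype=float) @ np.asarray(Theta, dtype=float)
    vals = np.linalg.svd(prod, compute_uv=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = vals[:-1] / vals[1:]
    return SingularSpectrum(values=vals, ratios=ratios)


def dimension_scan(
    X,
    k_list,
    alpha=1.0,
    learning_rate=1e-3,
    grad_tol=1e-2,
    max_iter=50_000,
    init_scale=0.1,
    random_state=None,
) -> pd.DataFrame:
    """Fit microbiome-only models over a list of latent dimensions.

    Returns a DataFrame with, for each K, the mean per-sample Jensen-Shannon
    distance and mean Bray-Curtis dissimilarity between each observed
    composition and its model fit.  Both metrics flatten once K exceeds the
    effective dimension of the data.
    """
    from .metrics import bray_curtis, kl_and_jsd

    ks = list(k_list)
    if len(set(ks)) != len(ks) or any(k < 1 for k in ks):
        raise ValueError("k_list must contain distinct positive integers")
    probe = LatentCompositionModel(n_latent=1)
    Xv, _, _ = probe._coerce_X(X)
    kmax = min(Xv.shape)
    if any(k > kmax for k in ks):
        raise ValueError(f"k_list exceeds min(S, O) = {kmax}")
    rows = []
    for k in ks:
        m = LatentCompositionModel(
            n_latent=k,
            alpha=1.0,
            learning_rate=learning_rate,
            grad_tol=grad_tol,
            max_iter=max_iter,
            init_scale=init_scale,
            random_state=random_state,
        ).fit(Xv)
        Q = m.predict_composition()
        jsd = np.mean([kl_and_jsd(x, q)[2] for x, q in zip(Xv, Q)])
        bc = np.mean([bray_curtis(x, q) for x, q in zip(Xv, Q)])
        rows.append({"K": k, "mean_jsd": jsd, "mean_bray_curtis": bc})
    return pd.DataFrame(rows)
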