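"""Compositional and diversity statistics shared across the package.

All entropy-based quantities use natural logarithms; only the power-law
slope of the species abundance distribution is computed in log10, matching
the usual presentation of such fits.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import braycurtis, jensenshannon
from scipy.stats import entropy

__all__ = [
    "bray_curtis",
    "kl_and_jsd",
    "shannon_diversity",
    "inverse_cdf_sad",
    "power_law_slope",
    "abundance_moments",
]


def _check_pair(p, q):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return p, q


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity; equals 0.5 * sum |p_i - q_i| on the simplex."""
    p, q = _check_pair(p, q)
    return float(braycurtis(p, q))


def kl_and_jsd(p, q):
    """(KL(p||q), symmetric KL, Jensen-Shannon distance), natural log.

    KL uses the convention 0 log 0 := 0 and is undefined when q_i = 0 at
    some p_i > 0 (an error naming the index); the Jensen-Shannon distance
    (square root of the JS divergence) is defined for any pair.
    """
    p, q = _check_pair(p, q)
    jsd = float(jensenshannon(p, q, base=np.e))
    bad = np.where((p > 0) & (q <= 0))[0]
    if bad.size:
        raise ValueError(
            f"KL(p||q) undefined: q is zero at index {int(bad[0])} where p > 0 "
            f"(JS distance for this pair is {jsd:.6g})"
        )
    kl_pq = float(entropy(p, q))
    bad_rev = np.where((q > 0) & (p <= 0))[0]
    sym = kl_pq + (float(entropy(q, p)) if not bad_rev.size else np.inf)
    return kl_pq, sym, jsd


def shannon_diversity(p) -> float:
    """Shannon diversity -sum p_i ln p_i (0 ln 0 := 0)."""
    return float(entropy(np.asarray(p, dtype=float)))


def inverse_cdf_sad(values, grid):
    """Empirical survival function P(abundance > a) over all table entries.

    ``values`` may be an abundance matrix or a flat vector of sample-taxon
    abundances; the curve is evaluated at each point of ``grid``.
    """
    flat = np.sort(np.ravel(np.asarray(values, dtype=float)))
    grid = np.asarray(grid, dtype=float)
    # count of entries strictly greater than each grid point
    n_greater = flat.size - np.searchsorted(flat, grid, side="right")
    return n_greater / flat.size


def power_law_slope(grid, survival, range_lo=1e-3, range_hi=1e-1) -> float:
    """Least-squares slope of log10(survival) vs log10(abundance) on a range.

    Summarizes the power-law regime of the species abundance distribution;
    host-associated microbiomes typically show slopes near -1 between
    relative abundances of 1e-3 and 1e-1.
    """
    grid = np.asarray(grid, dtype=float)
    survival = np.asarray(survival, dtype=float)
    sel = (grid >= range_lo) & (grid <= range_hi) & (survival > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 positive curve points in [{range_lo}, {range_hi}], "
            f"got {int(sel.sum())}"
        )
    slope, _ = np.polyfit(np.log10(grid[sel]), np.log10(survival[sel]), 1)
    return float(slope)


def abundance_moments(values):
    """Per-taxon mean and SD plus the taxon-taxon covariance of fluctuations.

    Covariance <dx_i dx_j> uses the unbiased S-1 denominator; requires at
    least two samples.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-d sample-by-taxon matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for SD and covariance")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(cov))
    return mean, sd, cov
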