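"""Ground-truth data generators: raw consumer/resource dynamics and
model-based cohorts with known parameters.

Two generators are provided.  ``simulate_cr`` integrates the mechanistic
consumer/resource ODEs

    dn_o/dt = n_o * (sum_k r_k(t) theta_ko - delta_o)
    dr_k/dt = J_k(t) - r_k(t) * sum_o n_o(t) theta_ko gamma_ko

recording the running integrals z_k(t) = -int_0^t r_k dtau that define the
latent variables; cohorts snapshotted from such trajectories test whether
the latent model captures data it did not literally generate.
``model_based_cohort`` draws directly from the model class (Gaussian-mixture
latents, Gaussian preferences/loadings, softmax compositions, multinomial
reads) for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.utils import check_random_state

from .model import compose
from .tables import AbundanceTable, PhenotypeMatrix, aggregate_rare_taxa  # noqa: F401

__all__ = [
    "CRSimParams",
    "Trajectory",
    "simulate_cr",
    "snapshot_cohort",
    "model_based_cohort",
    "SyntheticCohort",
    "aggregate_rare_taxa",
]


@dataclass
class CRSimParams:
    """Parameters of one consumer/resource world.

    theta (K x O): species preferences toward resources; gamma_eff (K x O):
    consumption efficiencies; delta (O): death/dilution rates; inflow (K):
    constant resource inflow rates J_k (or a callable J(t) -> K vector);
    n0, r0: strictly positive initial consumer and resource abundances.
    """

    theta: np.ndarray
    gamma_eff: np.ndarray
    delta: np.ndarray
    inflow: object
    n0: np.ndarray
    r0: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma_eff = np.asarray(self.gamma_eff, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        K, O = self.theta.shape
        if self.gamma_eff.shape != (K, O):
            raise ValueError("gamma_eff must match theta's shape")
        if self.delta.shape != (O,) or self.n0.shape != (O,) or self.r0.shape != (K,):
            raise ValueError("delta/n0/r0 shapes inconsistent with theta")
        for name, arr in [("theta", self.theta), ("gamma_eff", self.gamma_eff), ("delta", self.delta)]:
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any(self.n0 <= 0) or np.any(self.r0 <= 0):
            raise ValueError("initial abundances must be strictly positive")

    @property
    def n_resources(self) -> int:
        return self.theta.shape[0]

    @property
    def n_consumers(self) -> int:
        return self.theta.shape[1]

    def inflow_at(self, t: float) -> np.ndarray:
        if callable(self.inflow):
            return np.asarray(self.inflow(t), dtype=float)
        return np.asarray(self.inflow, dtype=float)


@dataclass
class Trajectory:
    """Saved C/R trajectory: consumer abundances n(t), resources r(t), and
    the latent integrals z_k(t) = -int_0^t r_k dtau (monotone non-increasing)."""

    times: np.ndarray
    n: np.ndarray  # T x O
    r: np.ndarray  # T x K
    z: np.ndarray  # T x K

    def relative_abundances(self, index: int = -1) -> np.ndarray:
        row = self.n[index]
        return row / row.sum()


_NEG_TOL = 1e-8


def simulate_cr(
    params: CRSimParams, t_end: float, dt_save: float, rtol: float = 1e-8, atol: float = 1e-10
) -> Trajectory:
    """Integrate the C/R ODEs, tracking the latent integrals.

    Uses adaptive LSODA stepping (stiffness-switching); tiny negative
    excursions below 1e-14 at save points are projected to zero, larger
    ones raise with a hint to tighten tolerances.
    """
    K, O = params.n_resources, params.n_consumers

    def rhs(t, y):
        n = y[:O]
        r = y[O : O + K]
        growth = r @ params.theta - params.delta
        dn = n * growth
        dr = params.inflow_at(t) - r * ((params.theta * params.gamma_eff) @ n)
        return np.concatenate([dn, dr, -r])

    y0 = np.concatenate([params.n0, params.r0, np.zeros(K)])
    t_eval = np.arange(0.0, t_end + 0.5 * dt_save, dt_save)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    Y = sol.y.T
    n, r, z = Y[:, :O], Y[:, O : O + K], Y[:, O + K :]
    if np.any(n < -_NEG_TOL) or np.any(r < -_NEG_TOL):
        raise RuntimeError(
            "state went negative beyond tolerance; tighten rtol/atol or reduce dt_save"
        )
    n = np.clip(n, 0.0, None)
    r = np.clip(r, 0.0, None)
    return Trajectory(times=sol.t, n=n, r=r, z=z)


def snapshot_cohort(
    params_list,
    t_snapshot: float,
    depth: int | None = None,
    seed=None,
    rtol: float = 1e-8,
):
    """Simulate one C/R world per host and snapshot compositions.

    All hosts must share the preference matrix (per-host variation enters
    through inflows and initial conditions).  Returns ``(table, truth)``:
    the observed table (multinomial counts at ``depth``, or the exact
    relative abundances when depth is None) and the true compositions.
    """
    rng = check_random_state(seed)
    theta0 = params_list[0].theta
    comps = []
    for p in params_list:
        if p.theta.shape != theta0.shape or not np.allclose(p.theta, theta0):
            raise ValueError("all hosts must share the same preference matrix")
        traj = simulate_cr(p, t_snapshot, t_snapshot / 4, rtol=rtol)
        final = traj.n[-1]
        if final.sum() < 1e-12:
            raise RuntimeError("community went extinct before the snapshot")
        comps.append(final / final.sum())
    truth = np.vstack(comps)
    sample_ids = [f"host{i}" for i in range(len(params_list))]
    taxon_ids = [f"taxon{j}" for j in range(truth.shape[1])]
    if depth is None:
        table = AbundanceTable(sample_ids, taxon_ids, truth, is_relative=True)
    else:
        counts = np.vstack([rng.multinomial(int(depth), row) for row in truth])
        table = AbundanceTable(sample_ids, taxon_ids, counts, is_relative=False)
    return table, truth


@dataclass
class SyntheticCohort:
    """A model-class cohort with its generating parameters exposed."""

    table: AbundanceTable
    phenotypes: PhenotypeMatrix | None
    Z: np.ndarray
    Theta: np.ndarray
    L: np.ndarray | None
    true_compositions: np.ndarray
    extras: dict = field(default_factory=dict)


def _draw_latents(S, K, latent_spec, rng):
    if latent_spec is None:
        return rng.normal(size=(S, K))
    weights = np.array([c[0] for c in latent_spec], dtype=float)
    weights /= weights.sum()
    comps = rng.choice(len(latent_spec), size=S, p=weights)
    Z = np.empty((S, K))
    for c, (_, mean, cov) in enumerate(latent_spec):
        idx = np.where(comps == c)[0]
        if idx.size:
            Z[idx] = rng.multivariate_normal(
                np.asarray(mean, dtype=float), np.asarray(cov, dtype=float), size=idx.size
            )
    return Z


def model_based_cohort(
    K_true: int,
    S: int,
    O: int,
    P: int | None = None,
    seed=None,
    latent_spec=None,
    theta_scale: float = 1.0,
    loading_scale: float = 1.0,
    depth: int | None = None,
    phenotype_noise_sd: float = 0.0,
) -> SyntheticCohort:
    """Draw a cohort from the model class itself, with known parameters.

    Latents come from a standard Gaussian by default, or from a mixture
    given as ``latent_spec`` = list of (weight, mean, cov); preferences and
    loadings are seeded Gaussians with the given scales.  ``depth`` adds
    multinomial sampling noise; ``phenotype_noise_sd`` adds Gaussian noise
    to the (then z-scored) phenotypes.
    """
    if K_true > min(S, O):
        raise ValueError("K_true must not exceed min(S, O)")
    rng = check_random_state(seed)
    Z = _draw_latents(S, K_true, latent_spec, rng)
    Theta = rng.normal(scale=theta_scale, size=(K_true, O))
    truth = compose(Z, Theta)
    sample_ids = [f"s{i}" for i in range(S)]
    taxon_ids = [f"t{j}" for j in range(O)]
    if depth is None:
        table = AbundanceTable(sample_ids, taxon_ids, truth, is_relative=True)
    else:
        counts = np.vstack([rng.multinomial(int(depth), row) for row in truth])
        table = AbundanceTable(sample_ids, taxon_ids, counts, is_relative=False)
    L = None
    phen = None
    if P is not None:
        L = rng.normal(scale=loading_scale, size=(K_true, P))
        raw = Z @ L
        if phenotype_noise_sd > 0:
            raw = raw + rng.normal(scale=phenotype_noise_sd, size=raw.shape)
        import pandas as pd

        phen = PhenotypeMatrix.from_raw(
            pd.DataFrame(raw, index=sample_ids, columns=[f"p{j}" for j in range(P)])
        )
    return SyntheticCohort(
        table=table,
        phenotypes=phen,
        Z=Z,
        Theta=Theta,
        L=L,
        true_compositions=truth,
    )


def random_cr_hosts(
    n_hosts: int,
    n_resources: int = 3,
    n_consumers: int = 25,
    seed=None,
    inflow_range=(1.0, 10.0),
):
    """A family of C/R worlds sharing preferences, varying only in inflows.

    Preferences are uniform(0, 1), efficiencies 1, death rates
    uniform(0.1, 0.3); each host draws its own constant resource inflows
    from ``inflow_range``.  This emulates hosts of one system whose resource
    environments differ while species preferences stay universal.
    """
    rng = check_random_state(seed)
    theta = rng.uniform(0.0, 1.0, size=(n_resources, n_consumers))
    gamma = np.ones_like(theta)
    delta = rng.uniform(0.1, 0.3, size=n_consumers)
    hosts = []
    for _ in range(n_hosts):
        hosts.append(
            CRSimParams(
                theta=theta,
                gamma_eff=gamma,
                delta=delta,
                inflow=rng.uniform(*inflow_range, size=n_resources),
                n0=np.full(n_consumers, 0.01),
                r0=rng.uniform(0.5, 1.5, size=n_resources),
            )
        )
    return hosts
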