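"""Realization of network genotypes into expression phenotypes.

The model is a discrete-time Wagner-type gene network with gene-specific
intrinsic noise.  A genotype is a regulatory matrix W plus a vector eta of
per-gene noise variances.  Starting from the basal state, each step draws
every gene's next expression level from a Gaussian whose mean is the basal
level plus the summed regulatory input and whose variance is that gene's
eta, then clamps it to [s_min, s_max]:

    a_i(t)   = sum_j w_ij * s_j(t)
    s_i(t+1) ~ N(s_basal + a_i(t), eta_i),  clamped to [s_min, s_max]

All genes update synchronously from the same previous state.  With eta = 0
the realization is fully deterministic and seed-independent.  A trajectory
is classified as stable (non-oscillating) iff the mean distance between the
final state and the preceding tau states,

    Phi = (1/tau) * sum_{theta=t-tau..t} D(S(theta), S(t)),
    D(S1, S2) = mean_i |S1_i - S2_i|,

falls below epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationParams
from .rng import realization_streams
from .topology import WeightedDigraph

__all__ = [
    "NetworkGenotype",
    "RealizationResult",
    "activation_rates",
    "realize",
    "realize_population",
    "stability_check",
    "stability_measure",
]


@dataclass
class NetworkGenotype:
    """One individual's heritable state: regulatory matrix + noise vector.

    ``eta`` holds the VARIANCE of each gene's per-step expression draw
    (squared expression units); the sampler uses sqrt(eta) as scale.
    """

    graph: WeightedDigraph
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.shape != (self.graph.n_genes,):
            raise ValueError("eta length must equal n_genes")
        if np.any(self.eta < 0):
            raise ValueError("eta entries must be nonnegative (variances)")

    @property
    def n_genes(self) -> int:
        return self.graph.n_genes

    @classmethod
    def deterministic(cls, graph: WeightedDigraph) -> "NetworkGenotype":
        return cls(graph, np.zeros(graph.n_genes))


@dataclass
class RealizationResult:
    """Outcome of realizing one genotype for t_r steps."""

    final_state: np.ndarray  # the phenotype, sampled at t = t_r
    stable: bool
    trajectory: np.ndarray | None = None  # (t_r + 1, n) when retained
    n_clamped: int = 0  # number of draws clipped at a bound


def activation_rates(graph: WeightedDigraph, state: np.ndarray) -> np.ndarray:
    """Summed regulatory input a_i = sum_j w_ij s_j (no clamping here)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (graph.n_genes,):
        raise ValueError(
            f"state length {state.shape} does not match n_genes={graph.n_genes}"
        )
    return graph.weights @ state


def stability_measure(trajectory: np.ndarray, tau: int, ) -> float:
    """Phi at the final row: mean distance to the preceding tau states / tau.

    The sum runs over theta = t - tau .. t inclusive (tau + 1 terms, the
    theta = t term being zero) and is divided by tau.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[0] < tau + 1:
        raise ValueError(f"trajectory must have at least tau+1 = {tau + 1} rows")
    window = trajectory[-(tau + 1):]
    dists = np.mean(np.abs(window - window[-1]), axis=1)  # D per theta
    return float(dists.sum() / tau)


def stability_check(trajectory: np.ndarray, tau: int, epsilon: float) -> bool:
    """True iff the trajectory is stable (non-oscillating): Phi < epsilon."""
    return stability_measure(trajectory, tau) < epsilon


def realize(
    genotype: NetworkGenotype,
    params: SimulationParams,
    seed=0,
    keep_trajectory: bool = False,
) -> RealizationResult:
    """Realize one genotype for ``params.t_r`` synchronous update steps.

    ``seed`` may be an integer, a SeedSequence, or a Generator (the latter
    is consumed; one length-n standard-normal draw per step).  With all
    eta = 0 no random numbers are consumed and the result is
    seed-independent.
    """
    n = genotype.n_genes
    deterministic = not np.any(genotype.eta)
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = realization_streams(seed, 1)[0]
    scale = np.sqrt(genotype.eta)
    w = genotype.graph.weights
    state = np.full(n, params.s_basal)
    traj = np.empty((params.t_r + 1, n))
    traj[0] = state
    n_clamped = 0
    for t in range(params.t_r):
        mean = params.s_basal + w @ state
        if deterministic:
            state = mean
        else:
            state = mean + scale * rng.standard_normal(n)
        clipped = np.clip(state, params.s_min, params.s_max)
        n_clamped += int(np.count_nonzero(clipped != state))
        state = clipped
        traj[t + 1] = state
    stable = stability_check(traj, params.tau, params.epsilon)
    return RealizationResult(
        final_state=state,
        stable=stable,
        trajectory=traj if keep_trajectory else None,
        n_clamped=n_clamped,
    )


def realize_population(
    weights: np.ndarray,
    eta: np.ndarray,
    params: SimulationParams,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Realize a population in one vectorized pass.

    Parameters
    ----------
    weights:
        Either a shared (n, n) regulatory matrix (noise-evolution stage:
        identical W across the population) or an (N, n, n) stack of
        per-individual matrices (establishment stage).
    eta:
        (N, n) per-individual noise variances.
    seed:
        Root for the per-individual realization streams; row ``k`` of the
        output is bitwise equal to ``realize`` driven by
        ``realization_streams(seed, N)[k]``.

    Returns
    -------
    (states, stable):
        (N, n) terminal expression matrix and length-N stability flags.
    """
    eta = np.asarray(eta, dtype=float)
    n_pop, n = eta.shape
    weights = np.asarray(weights, dtype=float)
    shared_w = weights.ndim == 2
    deterministic = not np.any(eta)
    if deterministic:
        z = None
    else:
        streams = realization_streams(seed, n_pop)
        # One block draw per individual consumes the stream exactly like
        # t_r successive per-step draws in `realize`.
        z = np.stack([g.standard_normal((params.t_r, n)) for g in streams])
    scale = np.sqrt(eta)
    states = np.full((n_pop, n), params.s_basal)
    tail = [states.copy()]  # sliding window of the last tau+1 states
    for t in range(params.t_r):
        # batched matvec (not a gemm): keeps each row bitwise identical to a
        # standalone `realize` call, which uses w @ state
        mean = params.s_basal + np.matmul(weights, states[..., None])[..., 0]
        if deterministic:
            states = mean
        else:
            states = mean + scale * z[:, t, :]
        np.clip(states, params.s_min, params.s_max, out=states)
        tail.append(states.copy())
        if len(tail) > params.tau + 1:
            tail.pop(0)
    final = tail[-1]
    dists = np.stack([np.mean(np.abs(s - final), axis=1) for s in tail])  # (tau+1, N)
    phi = dists.sum(axis=0) / params.tau
    return final, phi < params.epsilon
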