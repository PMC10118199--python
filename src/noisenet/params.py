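"""Simulation parameters for the stochastic gene network model.

All model and evolution constants live in a single frozen-by-convention
dataclass so that a run is fully described by (params, topology, seed).
Defaults follow the study conditions of the underlying model: a 40-gene
network realized for 50 time steps from a basal expression level of 20,
bounded in [0, 100], evolved in populations of 1,000 individuals for
10,000 generations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationParams"]


@dataclass
class SimulationParams:
    """Every model/evolution constant with its default.

    Parameters
    ----------
    n_genes:
        Number of genes (network nodes).
    s_basal:
        Basal expression level; the initial state and the constant offset of
        every update (expression units).
    s_min, s_max:
        Hard clamping bounds on expression levels.
    t_r:
        Number of realization (dynamics) steps per generation.
    n_pop:
        Population size N, constant across generations.
    t_gen:
        Number of generations T per evolutionary stage.
    mu_eta:
        Per-gene, per-replication mutation probability of the intrinsic-noise
        genotype.
    noise_mut_mean, noise_mut_spread:
        Mean and standard deviation of the replacement distribution for noise
        mutations, N(100, 40); draws are clamped below at 0 (eta is a
        variance).
    mu_w:
        Per-edge mutation probability of nonzero regulatory weights during
        network establishment.
    w_mut_mean, w_mut_spread:
        Mean and standard deviation of the additive perturbation applied to a
        mutated regulatory weight, N(0, 2).
    recomb_rate:
        Per-offspring probability of a single-breakpoint recombination of the
        noise genotype.
    tau, epsilon:
        Window length and threshold of the oscillation criterion: a
        trajectory is stable iff the mean over the last tau+1 states of the
        mean absolute per-gene distance to the final state, divided by tau,
        is below epsilon.
    rho:
        Per-gene fitness contribution (scaling of the fitness decay);
        default: all ones.  ``rho_mode`` selects whether rho divides the
        per-gene deviation ("divide", the literal published form) or
        multiplies it ("multiply"); the two coincide at rho = 1.
    s_opt:
        Per-gene optimal expression level; None until a stage sets it.
    pressure_threshold:
        Selective-pressure cut above which a gene is called responsive.
    sp_sampling_stride:
        Generation stride at which noise-genotype trajectories are recorded
        (every 2nd generation by default).
    """

    n_genes: int = 40
    s_basal: float = 20.0
    s_min: float = 0.0
    s_max: float = 100.0
    t_r: int = 50
    n_pop: int = 1000
    t_gen: int = 10_000
    mu_eta: float = 0.01
    noise_mut_mean: float = 100.0
    noise_mut_spread: float = 40.0
    mu_w: float = 0.1
    w_mut_mean: float = 0.0
    w_mut_spread: float = 2.0
    recomb_rate: float = 0.05
    tau: int = 10
    epsilon: float = 1e-6
    rho: np.ndarray | None = None
    rho_mode: str = "divide"
    s_opt: np.ndarray | None = None
    pressure_threshold: float = 0.5
    sp_sampling_stride: int = 2

    def __post_init__(self) -> None:
        if self.rho is None:
            self.rho = np.ones(self.n_genes)
        else:
            self.rho = np.asarray(self.rho, dtype=float)
        if self.s_opt is not None:
            self.s_opt = np.asarray(self.s_opt, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (self.s_min < self.s_basal < self.s_max):
            raise ValueError("require s_min < s_basal < s_max")
        if self.t_r <= self.tau:
            raise ValueError("require t_r > tau")
        for name in ("mu_eta", "mu_w", "recomb_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if np.any(self.rho <= 0):
            raise ValueError("rho entries must be strictly positive")
        if len(self.rho) != self.n_genes:
            raise ValueError("rho length must equal n_genes")
        if self.rho_mode not in ("divide", "multiply"):
            raise ValueError("rho_mode must be 'divide' or 'multiply'")
        if self.sp_sampling_stride < 1:
            raise ValueError("sp_sampling_stride must be >= 1")

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rho"] = np.asarray(self.rho).tolist()
        d["s_opt"] = None if self.s_opt is None else np.asarray(self.s_opt).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        """Stable short hash of the parameter set, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
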