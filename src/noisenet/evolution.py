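"""Two-stage forward-in-time evolution of gene network populations.

Stage 1 — network establishment: starting from a random connected topology,
the regulatory weights evolve under deterministic dynamics (eta = 0) toward
an intermediate target expression (s_max / 2 for every gene) through rounds
of realization, fitness evaluation, fitness-proportional reproduction and
additive weight mutation.  Oscillating individuals receive fitness 0.  The
highest-fitness stable individual of the final generation founds the noise-
evolution stage; genes whose steady state sits at an expression bound are
flagged for exclusion from downstream analysis.

Stage 2 — noise evolution: the regulatory matrix is frozen and each gene's
intrinsic-noise variance eta becomes the evolving trait.  The per-gene
expression optimum is the founder's deterministic steady state, so
stabilizing selection acts purely on expression variability.  Each
generation runs stochastic realization, fitness (or a neutral constant),
Wright–Fisher reproduction, replacement mutation of eta, and single-
breakpoint recombination of the eta vector.

Fitness of a phenotype s is

    F(s) = exp(-sum_i |s_opt_i - s_i| / (n * rho_i)),

i.e. exponential decay in the rho-weighted mean absolute deviation from the
optimum; F = 1 iff the phenotype matches the optimum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetworkGenotype, realize, realize_population
from .params import SimulationParams
from .rng import child_seed, substream
from .topology import WeightedDigraph

__all__ = [
    "PopulationState",
    "EvolutionRecord",
    "EstablishmentLog",
    "AllOscillatingError",
    "fitness",
    "fitness_population",
    "select_reproduce",
    "mutate_noise",
    "mutate_regulatory",
    "recombine",
    "establish_network",
    "evolve_noise",
]


class AllOscillatingError(RuntimeError):
    """Raised when an entire establishment population oscillates."""


@dataclass
class PopulationState:
    """A population snapshot: genotypes (stacked), fitnesses, generation.

    ``weights`` is (n, n) when the regulatory matrix is shared (noise
    evolution) or (N, n, n) during establishment; ``eta`` is (N, n).
    """

    weights: np.ndarray
    eta: np.ndarray
    fitnesses: np.ndarray | None = None
    generation: int = 0

    @property
    def n_pop(self) -> int:
        return self.eta.shape[0]

    @property
    def n_genes(self) -> int:
        return self.eta.shape[1]


@dataclass
class EstablishmentLog:
    """Per-run record of the network-establishment stage."""

    steady_state: np.ndarray  # deterministic final expression of the chosen genotype
    intermediate_mask: np.ndarray  # strictly inside (s_min, s_max)
    best_fitness: float
    best_index: int
    mean_fitness: np.ndarray  # per generation (stable individuals only count as-is)
    n_oscillating: np.ndarray  # per generation
    seed: int | None = None


@dataclass
class EvolutionRecord:
    """Per-generation population summaries of one noise-evolution run.

    Generations are recorded on an arithmetic grid (stride
    ``sp_sampling_stride`` starting at generation 1) with the final
    generation always appended.
    """

    generations: np.ndarray  # (G,)
    mean_expression: np.ndarray  # (G, n)
    var_expression: np.ndarray  # (G, n) sample variance, ddof=1
    mean_eta: np.ndarray  # (G, n)
    median_eta: np.ndarray  # (G, n)
    mean_fitness: np.ndarray  # (G,)
    mode: str = "selection"
    seed: int | None = None
    params_digest: str = ""
    s_opt: np.ndarray | None = None
    intermediate_mask: np.ndarray | None = None

    def to_frame(self):
        """Tidy (generation, gene, statistic, value) table."""
        import pandas as pd

        g_count, n = self.mean_expression.shape
        frames = []
        stats = {
            "mean_expression": self.mean_expression,
            "var_expression": self.var_expression,
            "mean_eta": self.mean_eta,
            "median_eta": self.median_eta,
        }
        for name, mat in stats.items():
            frames.append(
                pd.DataFrame(
                    {
                        "generation": np.repeat(self.generations, n),
                        "gene": np.tile(np.arange(n), g_count),
                        "statistic": name,
                        "value": mat.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Elementary operators


def fitness(
    state: np.ndarray,
    s_opt: np.ndarray,
    rho: np.ndarray | float = 1.0,
    gene_mask: np.ndarray | None = None,
    rho_mode: str = "divide",
) -> float:
    """Fitness of one phenotype: exp of minus the rho-weighted mean
    absolute deviation from the optimum, over masked genes.

    ``n`` in the exponent is the full gene count of the network, so masking
    a gene removes its term without rescaling the others.
    """
    state = np.asarray(state, dtype=float)
    s_opt = np.asarray(s_opt, dtype=float)
    n = state.shape[-1]
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (n,))
    if np.any(rho <= 0):
        raise ValueError("rho entries must be strictly positive")
    dev = np.abs(s_opt - state)
    terms = dev / (n * rho) if rho_mode == "divide" else dev * rho / n
    if gene_mask is not None:
        terms = terms * np.asarray(gene_mask, dtype=bool)
    return float(np.exp(-terms.sum()))


def fitness_population(
    states: np.ndarray,
    s_opt: np.ndarray,
    rho: np.ndarray | float = 1.0,
    gene_mask: np.ndarray | None = None,
    rho_mode: str = "divide",
) -> np.ndarray:
    """Vectorized fitness over an (N, n) phenotype matrix."""
    states = np.asarray(states, dtype=float)
    n = states.shape[1]
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (n,))
    if np.any(rho <= 0):
        raise ValueError("rho entries must be strictly positive")
    dev = np.abs(np.asarray(s_opt, dtype=float) - states)
    terms = dev / (n * rho) if rho_mode == "divide" else dev * rho / n
    if gene_mask is not None:
        terms = terms * np.asarray(gene_mask, dtype=bool)
    return np.exp(-terms.sum(axis=1))


def select_reproduce(
    population: PopulationState,
    mode: str = "selection",
    rng: np.random.Generator | int = 0,
) -> PopulationState:
    """Wright–Fisher reproduction: N offspring drawn with replacement with
    probability proportional to fitness (uniform under ``mode='neutral'``)."""
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng)
    n_pop = population.n_pop
    if n_pop < 2:
        raise ValueError("population size must be >= 2")
    if mode == "neutral":
        parents = rng.integers(n_pop, size=n_pop)
    elif mode == "selection":
        f = np.asarray(population.fitnesses, dtype=float)
        total = f.sum()
        if total <= 0:
            raise AllOscillatingError("all fitnesses are zero; no parent can reproduce")
        parents = rng.choice(n_pop, size=n_pop, p=f / total)
    else:
        raise ValueError("mode must be 'selection' or 'neutral'")
    weights = population.weights
    if weights.ndim == 3:
        weights = weights[parents]
    return PopulationState(
        weights=weights,
        eta=population.eta[parents],
        fitnesses=None,
        generation=population.generation + 1,
    )


def mutate_noise(
    eta: np.ndarray,
    mu_eta: float,
    mut_mean: float,
    mut_spread: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Replacement mutation of the noise genotype.

    Each (individual, gene) entry mutates independently with probability
    ``mu_eta``; a mutated entry is REPLACED by a draw from
    N(mut_mean, mut_spread) clamped below at 0 (eta is a variance).
    """
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng)
    eta = np.array(eta, dtype=float, copy=True)
    if mu_eta == 0:
        return eta
    hit = rng.random(eta.shape) < mu_eta
    n_hit = int(hit.sum())
    if n_hit:
        draws = mut_mean + mut_spread * rng.standard_normal(n_hit)
        eta[hit] = np.maximum(draws, 0.0)
    return eta


def mutate_regulatory(
    weights: np.ndarray,
    edge_mask: np.ndarray,
    mu_w: float,
    mut_mean: float,
    mut_spread: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Additive perturbation of nonzero regulatory weights.

    Only entries in ``edge_mask`` (the fixed topology) are eligible; each
    mutates independently with probability ``mu_w`` by adding a
    N(mut_mean, mut_spread) perturbation.  A weight landing exactly on 0 is
    nudged by a tiny amount so the edge set is preserved.
    """
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng)
    weights = np.array(weights, dtype=float, copy=True)
    rows, cols = np.nonzero(edge_mask)
    n_edges = rows.size
    if n_edges == 0 or mu_w == 0:
        return weights
    single = weights.ndim == 2
    stack = weights[None] if single else weights
    n_pop = stack.shape[0]
    hit = rng.random((n_pop, n_edges)) < mu_w
    n_hit = int(hit.sum())
    if n_hit:
        perturb = np.zeros((n_pop, n_edges))
        perturb[hit] = mut_mean + mut_spread * rng.standard_normal(n_hit)
        vals = stack[:, rows, cols] + perturb
        zeroed = vals == 0.0
        if np.any(zeroed):
            vals[zeroed] = np.finfo(float).tiny  # preserve the edge set
        stack[:, rows, cols] = vals
    return stack[0] if single else stack


def recombine(
    eta: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Single-breakpoint recombination of noise genotypes.

    Each offspring is selected independently with probability
    ``recomb_rate``; for each selected individual (in index order) a partner
    is drawn uniformly from the other offspring, a breakpoint b in
    {1..n-1} is drawn uniformly, and the eta segments beyond b are swapped.
    The per-locus multiset of eta values over the population is conserved.
    """
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng)
    eta = np.array(eta, dtype=float, copy=True)
    n_pop, n = eta.shape
    if n_pop < 2 or recomb_rate == 0:
        return eta
    chosen = np.nonzero(rng.random(n_pop) < recomb_rate)[0]
    for k in chosen:
        partner = int(rng.integers(n_pop - 1))
        if partner >= k:
            partner += 1  # uniform over the other individuals
        b = int(rng.integers(1, n))
        tmp = eta[k, b:].copy()
        eta[k, b:] = eta[partner, b:]
        eta[partner, b:] = tmp
    return eta


# ---------------------------------------------------------------------------
# Stage 1: network establishment


def establish_network(
    graph: WeightedDigraph,
    params: SimulationParams,
    seed=0,
) -> tuple[NetworkGenotype, EstablishmentLog]:
    """Evolve regulatory weights toward intermediate expression levels.

    Runs ``params.t_gen`` generations of deterministic realization,
    fitness toward s_opt = s_max/2 on all genes, fitness-proportional
    reproduction and additive regulatory mutation (no recombination).
    Oscillating individuals receive fitness 0 and cannot reproduce; if a
    whole generation oscillates, :class:`AllOscillatingError` is raised.

    Returns the highest-fitness stable genotype of the final generation
    (ties broken by lowest index) together with an :class:`EstablishmentLog`
    holding its deterministic steady state and the intermediate-expression
    mask used to filter genes from downstream analysis.
    """
    n = graph.n_genes
    n_pop = params.n_pop
    s_opt = np.full(n, params.s_max / 2.0)
    edge_mask = graph.edge_mask()
    weights = np.broadcast_to(graph.weights, (n_pop, n, n)).copy()
    eta = np.zeros((n_pop, n))
    root = child_seed(seed)
    mean_fitness = np.empty(params.t_gen)
    n_oscillating = np.empty(params.t_gen, dtype=int)
    best_idx, best_states = 0, None
    for gen in range(1, params.t_gen + 1):
        states, stable = realize_population(weights, eta, params, seed=root)
        fit = fitness_population(states, s_opt, params.rho, rho_mode=params.rho_mode)
        fit[~stable] = 0.0
        if not np.any(stable):
            raise AllOscillatingError(
                f"establishment generation {gen}: every individual oscillates"
            )
        mean_fitness[gen - 1] = fit.mean()
        n_oscillating[gen - 1] = int((~stable).sum())
        if gen == params.t_gen:
            best_idx = int(np.argmax(fit))  # argmax takes the lowest index on ties
            best_states = states
            best_fit = float(fit[best_idx])
            best_weights = weights[best_idx].copy()
            break
        pop = PopulationState(weights=weights, eta=eta, fitnesses=fit, generation=gen)
        pop = select_reproduce(pop, "selection", substream(root, 1, gen))
        weights = mutate_regulatory(
            pop.weights, edge_mask, params.mu_w, params.w_mut_mean,
            params.w_mut_spread, substream(root, 2, gen),
        )
        eta = pop.eta
    steady = best_states[best_idx]
    mask = (steady > params.s_min) & (steady < params.s_max)
    founder = NetworkGenotype(
        WeightedDigraph(best_weights, topology_model=graph.topology_model, seed=graph.seed),
        np.zeros(n),
    )
    log = EstablishmentLog(
        steady_state=steady.copy(),
        intermediate_mask=mask,
        best_fitness=best_fit,
        best_index=best_idx,
        mean_fitness=mean_fitness,
        n_oscillating=n_oscillating,
        seed=seed if isinstance(seed, int) else None,
    )
    return founder, log


# ---------------------------------------------------------------------------
# Stage 2: noise evolution


def _recorded_generations(t_gen: int, stride: int) -> np.ndarray:
    gens = np.arange(1, t_gen + 1, stride)
    if gens[-1] != t_gen:
        gens = np.append(gens, t_gen)
    return gens


def evolve_noise(
    founder: NetworkGenotype,
    params: SimulationParams,
    mode: str = "selection",
    seed=0,
    s_opt: np.ndarray | None = None,
    intermediate_mask: np.ndarray | None = None,
) -> EvolutionRecord:
    """Evolve the intrinsic-noise genotype on a frozen regulatory matrix.

    The founder population is N copies of ``founder`` with each individual's
    eta vector drawn entrywise from the mutation distribution
    N(noise_mut_mean, noise_mut_spread), clamped at 0.  The expression
    optimum is the founder's deterministic steady state (computed here
    unless supplied), so selection is stabilizing around the mean
    equilibrium expression of every gene.  Under ``mode='neutral'`` all
    fitnesses are a constant and reproduction is uniform.

    Per recorded generation the record holds per-gene population mean and
    sample variance of expression, mean and median eta, and mean fitness.
    """
    if mode not in ("selection", "neutral"):
        raise ValueError("mode must be 'selection' or 'neutral'")
    n = founder.n_genes
    n_pop = params.n_pop
    if s_opt is None:
        det = realize(founder if not np.any(founder.eta) else
                      NetworkGenotype.deterministic(founder.graph), params)
        if not det.stable:
            raise ValueError("founder realization oscillates; establish the network first")
        s_opt = det.final_state
    s_opt = np.asarray(s_opt, dtype=float)
    w = founder.graph.weights
    root = child_seed(seed)
    init_rng = substream(root, 0)
    eta = np.maximum(
        params.noise_mut_mean
        + params.noise_mut_spread * init_rng.standard_normal((n_pop, n)),
        0.0,
    )
    gens = _recorded_generations(params.t_gen, params.sp_sampling_stride)
    rec_set = set(int(g) for g in gens)
    g_count = len(gens)
    mean_expr = np.empty((g_count, n))
    var_expr = np.empty((g_count, n))
    mean_eta = np.empty((g_count, n))
    median_eta = np.empty((g_count, n))
    mean_fit = np.empty(g_count)
    rec_i = 0
    for gen in range(1, params.t_gen + 1):
        states, _ = realize_population(w, eta, params, seed=child_seed(root, 1, gen))
        if mode == "selection":
            fit = fitness_population(states, s_opt, params.rho, rho_mode=params.rho_mode)
        else:
            fit = np.ones(n_pop)
        if gen in rec_set:
            mean_expr[rec_i] = states.mean(axis=0)
            var_expr[rec_i] = states.var(axis=0, ddof=1)
            mean_eta[rec_i] = eta.mean(axis=0)
            median_eta[rec_i] = np.median(eta, axis=0)
            mean_fit[rec_i] = fit.mean()
            rec_i += 1
        if gen == params.t_gen:
            break
        pop = PopulationState(weights=w, eta=eta, fitnesses=fit, generation=gen)
        pop = select_reproduce(pop, mode, substream(root, 2, gen))
        eta = mutate_noise(
            pop.eta, params.mu_eta, params.noise_mut_mean, params.noise_mut_spread,
            substream(root, 3, gen),
        )
        eta = recombine(eta, params.recomb_rate, substream(root, 4, gen))
    return EvolutionRecord(
        generations=gens,
        mean_expression=mean_expr,
        var_expression=var_expr,
        mean_eta=mean_eta,
        median_eta=median_eta,
        mean_fitness=mean_fit,
        mode=mode,
        seed=seed if isinstance(seed, int) else None,
        params_digest=params.digest(),
        s_opt=s_opt,
        intermediate_mask=intermediate_mask,
    )
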