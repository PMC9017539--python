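"""Adaptive genetic algorithm driving topology-and-weight evolution.

The loop follows the classic speciated-neuroevolution recipe, with one
twist: the crossover and mutation probabilities are not fixed but follow an
inverse-cosine schedule of the population's convergence ratio f_ave/f_max.
A diverse population (ratio near 0) keeps the operators aggressive; as the
population converges (ratio → 1) the rates fall toward their floors, so a
nearly-converged species is refined rather than scrambled.

Fitness assignment can optionally pass through a rank-based transform
(linear or nonlinear ranking), which caps the reproductive advantage of
outlier individuals. Species compete through explicit fitness sharing: each
genome's fitness is divided by its species size and offspring slots are
allocated proportionally, so no single species can take over the population
before structural innovations have had time to be optimized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .genome import (
    CompatibilityCoefficients,
    Genome,
    InnovationRegistry,
    compatibility_distance,
    crossover,
    minimal_genome,
    mutate_add_connection,
    mutate_add_node,
    mutate_weights,
)

__all__ = [
    "AdaptiveRates",
    "PopulationStats",
    "RankingConfig",
    "ObjectiveTransform",
    "Species",
    "EvolutionConfig",
    "PopulationState",
    "EvolutionResult",
    "adaptive_rates",
    "objective_to_fitness",
    "rank_fitness_linear",
    "rank_fitness_nonlinear",
    "speciate",
    "share_fitness_and_allocate",
    "step_generation",
    "evolve_until",
]


@dataclass
class AdaptiveRates:
    """Current crossover/mutation probabilities and their schedule shape.

    ``k1``/``k2`` divide the inverse-cosine response (larger k = gentler
    rates); the floors keep evolution from freezing entirely once the
    population converges.
    """

    pc: float = 0.75
    pm: float = 0.25
    k1: float = 1.0
    k2: float = 2.0
    pc_floor: float = 0.05
    pm_floor: float = 0.01
    # exponent applied to the convergence ratio before the pm arccos
    pm_ratio_exponent: float = 1.0


@dataclass
class PopulationStats:
    f_max: float
    f_ave: float
    f_min: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.f_max, self.f_ave, self.f_min)):
            raise ValueError("population statistics must be finite")
        if not (self.f_min <= self.f_ave <= self.f_max):
            raise ValueError("need f_min <= f_ave <= f_max")

    @classmethod
    def from_fitnesses(cls, fitnesses) -> "PopulationStats":
        f = np.asarray(fitnesses, dtype=float)
        return cls(float(f.max()), float(f.mean()), float(f.min()))


@dataclass
class RankingConfig:
    """Rank-based fitness assignment: selective pressure and mode."""

    sp: float = 2.0
    mode: str = "linear"  # or "nonlinear"

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError("mode must be 'linear' or 'nonlinear'")
        if self.mode == "linear" and not (1.0 < self.sp <= 2.0):
            raise ValueError("linear ranking requires 1 < sp <= 2")


@dataclass
class ObjectiveTransform:
    """Turns a minimization objective into a non-negative fitness."""

    c_max: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.c_max):
            raise ValueError("c_max must be finite")


@dataclass
class Species:
    species_id: int
    representative: Genome
    members: list[Genome] = field(default_factory=list)
    best_fitness_history: list[float] = field(default_factory=list)
    staleness: int = 0


@dataclass
class EvolutionConfig:
    """Everything the generation loop needs, JSON-round-trippable."""

    n_inputs: int = 2
    n_outputs: int = 1
    population_size: int = 150
    # at this threshold a single add-node mutation (two new genes) already
    # founds a new species, so fitness sharing shields fresh structure
    delta_t: float = 2.0
    max_generations: int = 300
    fitness_threshold: float = 3.9
    elitism: int = 1
    elitism_min_species_size: int = 5
    stagnation_limit: int = 15
    seed: int = 0
    # operator shaping
    rates: AdaptiveRates = field(default_factory=AdaptiveRates)
    coeff: CompatibilityCoefficients = field(default_factory=CompatibilityCoefficients)
    ranking: RankingConfig | None = None
    # structural mutation coefficients, scaled by the current pm
    add_connection_coeff: float = 0.3
    add_node_coeff: float = 0.1
    # weight mutation (applied to every non-elite offspring)
    weight_perturb_prob: float = 0.8
    weight_sigma: float = 0.5
    weight_reset_prob: float = 0.1
    # reproduction
    survival_fraction: float = 0.5
    feed_forward: bool = True
    # refocusing: when the population best has not improved for this many
    # generations, only the top two species reproduce until it does
    refocus_after: int = 20

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvolutionConfig":
        payload = json.loads(text)
        if "rates" in payload and isinstance(payload["rates"], dict):
            payload["rates"] = AdaptiveRates(**payload["rates"])
        if "coeff" in payload and isinstance(payload["coeff"], dict):
            payload["coeff"] = CompatibilityCoefficients(**payload["coeff"])
        if payload.get("ranking") is not None and isinstance(payload["ranking"], dict):
            payload["ranking"] = RankingConfig(**payload["ranking"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# operator-rate schedule and fitness transforms
# ---------------------------------------------------------------------------

def adaptive_rates(stats: PopulationStats, rates: AdaptiveRates) -> AdaptiveRates:
    """Update pc and pm from the population's convergence ratio.

    pc = clamp((2/π)·arccos(r)/k1, pc_floor, 1) with r = f_ave/f_max clamped
    to [0, 1]; pm uses the same form with k2 and the ratio raised to the
    configured exponent. When f_max = 0 the ratio is treated as 1 (a fully
    degenerate population is considered converged).
    """
    if stats.f_max == 0:
        r = 1.0
    else:
        r = float(np.clip(stats.f_ave / stats.f_max, 0.0, 1.0))
    pc = min(1.0, (2.0 / math.pi) * math.acos(r) / rates.k1)
    r_m = r ** rates.pm_ratio_exponent
    pm = min(1.0, (2.0 / math.pi) * math.acos(r_m) / rates.k2)
    return AdaptiveRates(
        pc=max(rates.pc_floor, pc),
        pm=max(rates.pm_floor, pm),
        k1=rates.k1, k2=rates.k2,
        pc_floor=rates.pc_floor, pm_floor=rates.pm_floor,
        pm_ratio_exponent=rates.pm_ratio_exponent,
    )


def objective_to_fitness(objective_value: float, t: ObjectiveTransform) -> float:
    """Minimization objective -> non-negative fitness: max(C_max − f(x), 0)."""
    return max(t.c_max - objective_value, 0.0)


def rank_fitness_linear(n: int, sp: float) -> np.ndarray:
    """Linear ranking fitness, position 1 = least fit ... n = fittest.

    F(Pos) = 2 − sp + 2(sp − 1)(Pos − 1)/(n − 1); the returned vector has
    mean exactly 1 and spread controlled by the selective pressure sp.
    """
    if n < 2:
        raise ValueError("ranking needs n >= 2")
    if not (1.0 < sp <= 2.0):
        raise ValueError("linear ranking requires 1 < sp <= 2")
    pos = np.arange(1, n + 1, dtype=float)
    return 2.0 - sp + 2.0 * (sp - 1.0) * (pos - 1.0) / (n - 1.0)


def rank_fitness_nonlinear(n: int, sp: float) -> np.ndarray:
    """Nonlinear (geometric) ranking fitness.

    X is the absolute value of the admissible real root of
    (sp − n)·X^(n−1) + sp·X^(n−2) + … + sp·X + sp = 0; fitness at position
    Pos is n·X^(Pos−1) / Σ_i X^(i−1), so the vector sums to n and is
    geometric in rank.
    """
    if n < 2:
        raise ValueError("ranking needs n >= 2")
    # highest degree first for np.roots: [(sp - n), sp, sp, ..., sp]
    coeffs = np.full(n, sp, dtype=float)
    coeffs[0] = sp - n
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    candidates = np.abs(real[np.abs(real) > 1e-12])
    if candidates.size == 0:
        raise ValueError(
            "nonlinear ranking polynomial has no admissible real root for "
            f"(n={n}, sp={sp}); use linear ranking instead")
    # the admissible root is the positive one; prefer the largest, which
    # yields a strictly monotone geometric progression
    x = float(np.max(candidates))
    powers = x ** np.arange(n, dtype=float)
    fit = n * powers / powers.sum()
    if not np.all(np.isfinite(fit)):
        raise ValueError(
            f"nonlinear ranking overflowed for (n={n}, sp={sp}); "
            "use linear ranking instead")
    return fit


# ---------------------------------------------------------------------------
# speciation and fitness sharing
# ---------------------------------------------------------------------------

def speciate(genomes: list[Genome], previous_species: list[Species],
             delta_t: float, coeff: CompatibilityCoefficients,
             rng: np.random.Generator | None = None) -> list[Species]:
    """Partition genomes into species by compatibility distance.

    Each previous species contributes a representative picked at random
    from its previous-generation members. Every genome joins the first
    species (in stable species-id order) whose representative is within
    delta_t, or founds a new species. Empty species are dropped;
    staleness/history carry over for surviving species.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    rng = rng or np.random.default_rng()
    shells: list[Species] = []
    for sp in sorted(previous_species, key=lambda s: s.species_id):
        rep = sp.members[int(rng.integers(len(sp.members)))] if sp.members \
            else sp.representative
        shells.append(Species(sp.species_id, rep, [],
                              list(sp.best_fitness_history), sp.staleness))
    next_id = max((s.species_id for s in shells), default=-1) + 1
    for g in genomes:
        for sp in shells:
            if compatibility_distance(g, sp.representative, coeff) < delta_t:
                sp.members.append(g)
                break
        else:
            shells.append(Species(next_id, g, [g]))
            next_id += 1
    return [s for s in shells if s.members]


def share_fitness_and_allocate(species: list[Species],
                               population_size: int) -> dict[int, int]:
    """Explicit fitness sharing and largest-remainder offspring allocation.

    Each member's adjusted fitness is raw fitness divided by species size;
    species receive offspring proportional to their summed adjusted fitness.
    Counts always sum exactly to ``population_size``.
    """
    if not species:
        raise ValueError("no species to allocate over")
    sums: dict[int, float] = {}
    for sp in species:
        for g in sp.members:
            if g.raw_fitness is None:
                raise ValueError(
                    f"genome in species {sp.species_id} has unset raw_fitness")
            g.adjusted_fitness = g.raw_fitness / len(sp.members)
        sums[sp.species_id] = sum(g.adjusted_fitness for g in sp.members)
    total = sum(sums.values())
    ids = sorted(sums)
    if total <= 0:
        quotas = {sid: population_size / len(ids) for sid in ids}
    else:
        quotas = {sid: population_size * sums[sid] / total for sid in ids}
    counts = {sid: int(math.floor(quotas[sid])) for sid in ids}
    remainder = population_size - sum(counts.values())
    # largest fractional remainders get the leftover slots (ties by id)
    order = sorted(ids, key=lambda sid: (-(quotas[sid] - counts[sid]), sid))
    for sid in order[:remainder]:
        counts[sid] += 1
    return counts


# ---------------------------------------------------------------------------
# the generation loop
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    genomes: list[Genome]
    species: list[Species]
    rates: AdaptiveRates
    registry: InnovationRegistry
    rng: np.random.Generator
    generation: int = 0
    best_genome: Genome | None = None
    best_fitness: float = -math.inf
    # generations since the population best last improved
    global_staleness: int = 0


@dataclass
class EvolutionResult:
    best_genome: Genome
    best_fitness: float
    solved: bool
    generations: int
    history: pd.DataFrame


def initial_state(config: EvolutionConfig) -> PopulationState:
    rng = np.random.default_rng(config.seed)
    registry = InnovationRegistry()
    genomes = [minimal_genome(config.n_inputs, config.n_outputs, registry, rng)
               for _ in range(config.population_size)]
    registry.reset()
    return PopulationState(genomes=genomes, species=[],
                           rates=AdaptiveRates(**asdict(config.rates)),
                           registry=registry, rng=rng)


def _assign_fitness(genomes: list[Genome], evaluate: Callable[[Genome], float],
                    ranking: RankingConfig | None) -> None:
    for g in genomes:
        if g.raw_fitness is not None:
            continue  # already evaluated this generation (deterministic callback)
        f = float(evaluate(g))
        if not math.isfinite(f):
            raise ValueError(
                f"fitness callback returned non-finite value {f!r} for genome "
                f"with {len(g.connections)} connections")
        g.raw_fitness = f
    if ranking is not None:
        n = len(genomes)
        vec = (rank_fitness_linear(n, ranking.sp) if ranking.mode == "linear"
               else rank_fitness_nonlinear(n, ranking.sp))
        # position 1 = least fit; stable order for reproducibility
        order = sorted(range(n), key=lambda i: (genomes[i].raw_fitness, i))
        for pos, idx in enumerate(order):
            genomes[idx].raw_fitness = float(vec[pos])


def _reproduce_species(sp: Species, n_offspring: int, config: EvolutionConfig,
                       rates: AdaptiveRates, registry: InnovationRegistry,
                       rng: np.random.Generator) -> list[Genome]:
    members = sorted(sp.members, key=lambda g: g.raw_fitness, reverse=True)
    offspring: list[Genome] = []
    n_elite = config.elitism if len(members) >= config.elitism_min_species_size else 0
    for g in members[:min(n_elite, n_offspring)]:
        offspring.append(g.copy())
    pool = members[:max(2, math.ceil(len(members) * config.survival_fraction))]
    p_add_conn = min(1.0, config.add_connection_coeff * rates.pm)
    p_add_node = min(1.0, config.add_node_coeff * rates.pm)
    while len(offspring) < n_offspring:
        if rng.random() < rates.pc and len(pool) >= 2:
            i, j = rng.choice(len(pool), size=2, replace=False)
            child = crossover(pool[int(i)], pool[int(j)], rng,
                              feed_forward=config.feed_forward)
        else:
            child = pool[int(rng.integers(len(pool)))].copy()
        child.raw_fitness = None
        child.adjusted_fitness = None
        if rng.random() < p_add_node:
            mutate_add_node(child, registry, rng)
        if rng.random() < p_add_conn:
            mutate_add_connection(child, registry, rng,
                                  feed_forward=config.feed_forward)
        mutate_weights(child, config.weight_perturb_prob, config.weight_sigma,
                       config.weight_reset_prob, rng)
        offspring.append(child)
    return offspring


def step_generation(state: PopulationState, config: EvolutionConfig,
                    evaluate: Callable[[Genome], float]) -> PopulationState:
    """One generation: evaluate, adapt rates, speciate, share, reproduce."""
    _assign_fitness(state.genomes, evaluate, config.ranking)

    gen_best = max(state.genomes, key=lambda g: g.raw_fitness)
    if gen_best.raw_fitness > state.best_fitness:
        state.best_fitness = gen_best.raw_fitness
        state.best_genome = gen_best.copy()
        state.global_staleness = 0
    else:
        state.global_staleness += 1

    stats = PopulationStats.from_fitnesses([g.raw_fitness for g in state.genomes])
    state.rates = adaptive_rates(stats, state.rates)

    species = speciate(state.genomes, state.species, config.delta_t,
                       config.coeff, state.rng)

    # staleness bookkeeping and removal (the species holding the global best
    # is always kept so the incumbent solution cannot be discarded)
    best_id = None
    for sp in species:
        sp_best = max(g.raw_fitness for g in sp.members)
        if sp.best_fitness_history and sp_best <= max(sp.best_fitness_history):
            sp.staleness += 1
        else:
            sp.staleness = 0
        sp.best_fitness_history.append(sp_best)
        if any(g.raw_fitness == gen_best.raw_fitness for g in sp.members):
            if best_id is None:
                best_id = sp.species_id
    survivors = [sp for sp in species
                 if sp.staleness <= config.stagnation_limit
                 or sp.species_id == best_id]
    if not survivors:
        survivors = species

    # refocusing: a long population-wide plateau concentrates reproduction
    # in the two best species, trading diversity for exploitation
    if (config.refocus_after > 0
            and state.global_staleness >= config.refocus_after
            and len(survivors) > 2):
        survivors = sorted(
            survivors,
            key=lambda sp: max(g.raw_fitness for g in sp.members),
            reverse=True)[:2]
        for sp in survivors:
            sp.staleness = 0

    allocation = share_fitness_and_allocate(survivors, config.population_size)

    next_genomes: list[Genome] = []
    for sp in sorted(survivors, key=lambda s: s.species_id):
        next_genomes.extend(_reproduce_species(
            sp, allocation[sp.species_id], config, state.rates,
            state.registry, state.rng))
    # champion preservation: the best genome ever seen re-enters the
    # population unchanged, so the incumbent solution can never regress
    if state.best_genome is not None and next_genomes:
        next_genomes[-1] = state.best_genome.copy()
    state.genomes = next_genomes
    state.species = survivors
    state.registry.reset()
    state.generation += 1
    return state


def evolve_until(config: EvolutionConfig,
                 evaluate: Callable[[Genome], float]) -> EvolutionResult:
    """Run generations until the fitness threshold or the generation cap.

    Returns the best genome ever seen and a per-generation history
    (generation, best_fitness, mean_fitness, n_species, pc, pm).
    """
    state = initial_state(config)
    rows = []
    solved = False
    generation = 0
    while True:
        # evaluate the current population without advancing, so the stop
        # test sees generation `generation` itself
        _assign_fitness(state.genomes, evaluate, None)
        fitnesses = [g.raw_fitness for g in state.genomes]
        gen_best = max(state.genomes, key=lambda g: g.raw_fitness)
        if gen_best.raw_fitness > state.best_fitness:
            state.best_fitness = gen_best.raw_fitness
            state.best_genome = gen_best.copy()
        rows.append({
            "generation": generation,
            "best_fitness": float(max(fitnesses)),
            "mean_fitness": float(np.mean(fitnesses)),
            "n_species": max(len(state.species), 1),
            "pc": state.rates.pc,
            "pm": state.rates.pm,
        })
        if state.best_fitness >= config.fitness_threshold:
            solved = True
            break
        if generation >= config.max_generations:
            break
        state = step_generation(state, config, evaluate)
        generation = state.generation
    history = pd.DataFrame(rows)
    return EvolutionResult(best_genome=state.best_genome,
                           best_fitness=state.best_fitness,
                           solved=solved,
                           generations=generation,
                           history=history)
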