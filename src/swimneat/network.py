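"""Phenotype construction and activation, plus the XOR benchmark.

A genome's phenotype is a feed-forward network evaluated in topological
order with a steepened logistic activation. The XOR truth table is the
standard sanity benchmark for topology-evolving networks: the minimal
topology cannot solve it, so reaching the fitness threshold requires the
evolution loop to discover at least one hidden node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, NodeType

__all__ = [
    "Phenotype",
    "XorCase",
    "XOR_CASES",
    "build_phenotype",
    "activate",
    "activate_batch",
    "xor_fitness",
    "xor_fitness_from_outputs",
    "xor_evaluator",
]

DEFAULT_SIGMOID_SLOPE = 4.9


def sigmoid(x: np.ndarray | float, slope: float = DEFAULT_SIGMOID_SLOPE):
    return 1.0 / (1.0 + np.exp(np.clip(-slope * np.asarray(x, dtype=float),
                                       -60.0, 60.0)))


@dataclass(frozen=True)
class XorCase:
    inputs: tuple[float, float]
    target: float


XOR_CASES: tuple[XorCase, ...] = (
    XorCase((0.0, 0.0), 0.0),
    XorCase((0.0, 1.0), 1.0),
    XorCase((1.0, 0.0), 1.0),
    XorCase((1.0, 1.0), 0.0),
)


class CycleError(ValueError):
    """Enabled connections form a cycle in feed-forward mode."""


@dataclass
class Phenotype:
    """Evaluation-ready network: node order plus incoming edges per node."""

    input_ids: list[int]
    bias_ids: list[int]
    output_ids: list[int]
    # evaluation order over nodes that have incoming enabled connections
    order: list[int] = field(default_factory=list)
    # node -> list of (source node, weight)
    incoming: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    slope: float = DEFAULT_SIGMOID_SLOPE


def build_phenotype(g: Genome, slope: float = DEFAULT_SIGMOID_SLOPE) -> Phenotype:
    """Topologically sort a genome's enabled connections into a Phenotype.

    Disabled connections are excluded. A node with no incoming enabled
    connection rests at activation 0 (inputs and bias aside). Raises
    CycleError, naming the nodes involved, if the enabled edges are cyclic.
    """
    g.validate()
    incoming: dict[int, list[tuple[int, float]]] = {}
    out_edges: dict[int, list[int]] = {}
    indegree: dict[int, int] = {nid: 0 for nid in g.nodes}
    for c in g.enabled_connections():
        incoming.setdefault(c.out_node, []).append((c.in_node, c.weight))
        out_edges.setdefault(c.in_node, []).append(c.out_node)
        indegree[c.out_node] += 1

    # Kahn's algorithm over all nodes; deterministic via sorted ready set
    ready = sorted(nid for nid, d in indegree.items() if d == 0)
    order: list[int] = []
    indeg = dict(indegree)
    while ready:
        node = ready.pop(0)
        order.append(node)
        for nxt in sorted(out_edges.get(node, ())):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                ready.append(nxt)
        ready.sort()
    if len(order) != len(g.nodes):
        cyclic = sorted(set(g.nodes) - set(order))
        raise CycleError(f"enabled connections form a cycle among nodes {cyclic}")

    return Phenotype(
        input_ids=g.node_ids(NodeType.INPUT),
        bias_ids=g.node_ids(NodeType.BIAS),
        output_ids=g.node_ids(NodeType.OUTPUT),
        order=[nid for nid in order if nid in incoming],
        incoming=incoming,
        slope=slope,
    )


def activate_batch(p: Phenotype, X: np.ndarray) -> np.ndarray:
    """Activate the network on a batch: X is (n_samples, n_inputs).

    Returns (n_samples, n_outputs). Nodes with incoming connections apply
    the logistic to their weighted input sum; nodes without incoming
    connections hold their resting value 0 (bias nodes hold 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(p.input_ids):
        raise ValueError(
            f"expected {len(p.input_ids)} inputs, got {X.shape[1]}")
    n = X.shape[0]
    values: dict[int, np.ndarray] = {}
    for j, nid in enumerate(p.input_ids):
        values[nid] = X[:, j]
    ones = np.ones(n)
    for nid in p.bias_ids:
        values[nid] = ones
    zeros = np.zeros(n)
    for nid in p.order:
        total = zeros
        for src, w in p.incoming[nid]:
            total = total + w * values.get(src, zeros)
        values[nid] = sigmoid(total, p.slope)
    return np.column_stack([values.get(nid, zeros) for nid in p.output_ids])


def activate(p: Phenotype, inputs) -> np.ndarray:
    """Single-sample activation; returns a 1-D output vector."""
    return activate_batch(p, np.asarray(inputs, dtype=float)[None, :])[0]


def xor_fitness_from_outputs(outputs) -> float:
    """4 minus the summed squared error over the four XOR cases."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.array([c.target for c in XOR_CASES])
    if outputs.shape != targets.shape:
        raise ValueError("expected one output per XOR case")
    return float(4.0 - np.sum((targets - outputs) ** 2))


def xor_fitness(g: Genome, slope: float = DEFAULT_SIGMOID_SLOPE) -> float:
    """Score a genome on the XOR truth table: fitness = 4 − Σ(target − out)²."""
    if g.n_inputs != 2 or g.n_outputs != 1:
        raise ValueError("XOR fitness requires a 2-input, 1-output genome")
    p = build_phenotype(g, slope=slope)
    X = np.array([c.inputs for c in XOR_CASES])
    outputs = activate_batch(p, X)[:, 0]
    return xor_fitness_from_outputs(outputs)


def xor_evaluator(slope: float = DEFAULT_SIGMOID_SLOPE):
    """Fitness callback over genomes for the evolution loop."""
    def _eval(g: Genome) -> float:
        return xor_fitness(g, slope=slope)
    return _eval


def default_xor_config(seed: int = 0, **overrides):
    """Benchmark conditions: population 150, threshold 3.9 of max 4, cap 300."""
    from .evolve import EvolutionConfig
    kwargs = dict(n_inputs=2, n_outputs=1, population_size=150,
                  max_generations=300, fitness_threshold=3.9, seed=seed)
    kwargs.update(overrides)
    return EvolutionConfig(**kwargs)


def xor_experiment(n_runs: int = 20, seed: int = 0, **config_overrides):
    """Repeated seeded XOR runs; the standard feasibility check.

    Returns (summary DataFrame with one row per run, list of per-run
    histories). Per-run seeds are derived from ``seed`` through numpy's
    seed-sequence splitting, so the whole experiment is reproducible from
    one integer.
    """
    import pandas as pd

    from .evolve import evolve_until

    run_seeds = [int(s) & 0x7FFFFFFF
                 for s in np.random.SeedSequence(seed).generate_state(n_runs)]
    evaluate = xor_evaluator()
    rows, histories = [], []
    for i, run_seed in enumerate(run_seeds):
        result = evolve_until(default_xor_config(run_seed, **config_overrides),
                              evaluate)
        rows.append({"run": i, "seed": run_seed, "solved": result.solved,
                     "generations": result.generations,
                     "best_fitness": result.best_fitness})
        histories.append(result.history)
    return pd.DataFrame(rows), histories
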