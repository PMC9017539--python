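"""Node-based genome encoding for an evolvable neural network.

A genome is a set of node genes plus a list of connection genes. Every
connection gene carries an *innovation number*, a historical marker assigned
when the connection first appears anywhere in the population. Innovation
numbers let homologous genes line up during crossover and make the
compatibility distance (used for speciation) a cheap alignment problem
instead of a graph-isomorphism one.

Networks are feed-forward by default; a config flag allows recurrent
connections for callers that evaluate them with their own semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "NodeType",
    "NodeGene",
    "ConnectionGene",
    "Genome",
    "InnovationRegistry",
    "CompatibilityCoefficients",
    "minimal_genome",
    "mutate_add_connection",
    "mutate_add_node",
    "mutate_weights",
    "crossover",
    "compatibility_distance",
]


class NodeType(str, Enum):
    INPUT = "input"
    HIDDEN = "hidden"
    OUTPUT = "output"
    BIAS = "bias"


@dataclass(frozen=True)
class NodeGene:
    """A neuron: identity plus role. Input/bias/output nodes are permanent."""

    node_id: int
    node_type: NodeType


@dataclass
class ConnectionGene:
    """A weighted directed edge with its historical marker."""

    in_node: int
    out_node: int
    weight: float
    enabled: bool
    innovation: int

    def copy(self) -> "ConnectionGene":
        return ConnectionGene(self.in_node, self.out_node, self.weight,
                              self.enabled, self.innovation)


@dataclass
class Genome:
    """The evolving individual: nodes, connections, and its fitness slots."""

    nodes: dict[int, NodeGene] = field(default_factory=dict)
    # keyed by innovation number; iteration order is insertion order, which
    # tracks the historical order of appearance
    connections: dict[int, ConnectionGene] = field(default_factory=dict)
    raw_fitness: float | None = None
    adjusted_fitness: float | None = None

    # -- structure queries -------------------------------------------------
    def node_ids(self, node_type: NodeType | None = None) -> list[int]:
        if node_type is None:
            return sorted(self.nodes)
        return sorted(nid for nid, n in self.nodes.items() if n.node_type == node_type)

    @property
    def n_inputs(self) -> int:
        return sum(1 for n in self.nodes.values() if n.node_type == NodeType.INPUT)

    @property
    def n_outputs(self) -> int:
        return sum(1 for n in self.nodes.values() if n.node_type == NodeType.OUTPUT)

    def connected_pairs(self) -> set[tuple[int, int]]:
        """All (in, out) pairs present, enabled or not."""
        return {(c.in_node, c.out_node) for c in self.connections.values()}

    def enabled_connections(self) -> list[ConnectionGene]:
        return [c for c in self.connections.values() if c.enabled]

    def max_innovation(self) -> int:
        return max(self.connections) if self.connections else -1

    def copy(self) -> "Genome":
        g = Genome(nodes=dict(self.nodes),
                   connections={i: c.copy() for i, c in self.connections.items()},
                   raw_fitness=self.raw_fitness,
                   adjusted_fitness=self.adjusted_fitness)
        return g

    def validate(self) -> None:
        """Raise ValueError if the genome breaks a structural invariant."""
        for c in self.connections.values():
            if c.in_node not in self.nodes or c.out_node not in self.nodes:
                raise ValueError(
                    f"connection {c.innovation} references missing node "
                    f"({c.in_node} -> {c.out_node})")
        pairs = [(c.in_node, c.out_node) for c in self.connections.values() if c.enabled]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate enabled connection pair")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "nodes": [[n.node_id, n.node_type.value] for n in
                      sorted(self.nodes.values(), key=lambda n: n.node_id)],
            "connections": [[c.in_node, c.out_node, c.weight, c.enabled, c.innovation]
                            for c in self.connections.values()],
            "raw_fitness": self.raw_fitness,
            "adjusted_fitness": self.adjusted_fitness,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        payload = json.loads(text)
        g = cls()
        for nid, ntype in payload["nodes"]:
            g.nodes[nid] = NodeGene(nid, NodeType(ntype))
        for in_n, out_n, w, enabled, innov in payload["connections"]:
            g.connections[innov] = ConnectionGene(in_n, out_n, float(w),
                                                  bool(enabled), innov)
        g.raw_fitness = payload.get("raw_fitness")
        g.adjusted_fitness = payload.get("adjusted_fitness")
        return g


class InnovationRegistry:
    """Assigns historical markers, de-duplicated within a generation.

    The same structural innovation (same new connection, or same split of an
    existing connection) requested twice in one generation receives the same
    innovation number(s) and, for splits, the same new node id. ``reset()``
    is called once per generation; the global counters persist.
    """

    def __init__(self, next_innovation: int = 0, next_node_id: int = 0) -> None:
        self.next_innovation = next_innovation
        self.next_node_id = next_node_id
        self._seen_connections: dict[tuple[int, int], int] = {}
        self._seen_splits: dict[int, tuple[int, int, int]] = {}

    def connection_innovation(self, in_node: int, out_node: int) -> int:
        key = (in_node, out_node)
        if key not in self._seen_connections:
            self._seen_connections[key] = self.next_innovation
            self.next_innovation += 1
        return self._seen_connections[key]

    def split_connection(self, innovation: int, in_node: int, out_node: int
                         ) -> tuple[int, int, int]:
        """Return (new_node_id, innovation in->new, innovation new->out)."""
        if innovation not in self._seen_splits:
            node_id = self.next_node_id
            self.next_node_id += 1
            i1 = self.connection_innovation(in_node, node_id)
            i2 = self.connection_innovation(node_id, out_node)
            self._seen_splits[innovation] = (node_id, i1, i2)
        return self._seen_splits[innovation]

    def register_node_id(self, node_id: int) -> None:
        self.next_node_id = max(self.next_node_id, node_id + 1)

    def reset(self) -> None:
        """Forget this generation's innovations; keep the global counters."""
        self._seen_connections.clear()
        self._seen_splits.clear()


@dataclass
class CompatibilityCoefficients:
    """Weights of the compatibility distance δ = c1·E/N + c2·D/N + c3·W̄."""

    c1: float = 1.0
    c2: float = 1.0
    c3: float = 0.4
    # genomes smaller than this use N = 1 (no size normalization)
    N_threshold: int = 20

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("compatibility coefficients must be non-negative")


# default weight conventions, overridable per call
WEIGHT_INIT_LOW = -1.0
WEIGHT_INIT_HIGH = 1.0
WEIGHT_CLAMP = 8.0


def _random_weight(rng: np.random.Generator,
                   low: float = WEIGHT_INIT_LOW,
                   high: float = WEIGHT_INIT_HIGH) -> float:
    return float(rng.uniform(low, high))


def minimal_genome(n_inputs: int, n_outputs: int, registry: InnovationRegistry,
                   rng: np.random.Generator) -> Genome:
    """Build the minimal fully-connected starting topology.

    Inputs and a dedicated always-1 bias node are each connected to every
    output; there are no hidden nodes. Evolution only ever adds structure.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("n_inputs and n_outputs must be >= 1")
    g = Genome()
    input_ids = list(range(n_inputs))
    bias_id = n_inputs
    output_ids = list(range(n_inputs + 1, n_inputs + 1 + n_outputs))
    for nid in input_ids:
        g.nodes[nid] = NodeGene(nid, NodeType.INPUT)
    g.nodes[bias_id] = NodeGene(bias_id, NodeType.BIAS)
    for nid in output_ids:
        g.nodes[nid] = NodeGene(nid, NodeType.OUTPUT)
    registry.register_node_id(output_ids[-1])
    for src in input_ids + [bias_id]:
        for dst in output_ids:
            innov = registry.connection_innovation(src, dst)
            g.connections[innov] = ConnectionGene(src, dst, _random_weight(rng),
                                                  True, innov)
    return g


def _creates_cycle(pairs: Iterable[tuple[int, int]], candidate: tuple[int, int]) -> bool:
    """Would adding `candidate` to the directed edge set `pairs` close a cycle?"""
    src, dst = candidate
    if src == dst:
        return True
    # DFS from dst through existing edges; a path back to src means a cycle
    adjacency: dict[int, list[int]] = {}
    for a, b in pairs:
        adjacency.setdefault(a, []).append(b)
    stack, seen = [dst], set()
    while stack:
        node = stack.pop()
        if node == src:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adjacency.get(node, ()))
    return False


def mutate_add_connection(g: Genome, registry: InnovationRegistry,
                          rng: np.random.Generator, *,
                          feed_forward: bool = True,
                          weight_low: float = WEIGHT_INIT_LOW,
                          weight_high: float = WEIGHT_INIT_HIGH) -> Genome:
    """Add one new connection between a previously unlinked admissible pair.

    Saturated genomes (no admissible pair) are returned unchanged. Sources
    may be any non-output node in feed-forward mode; sinks are hidden or
    output nodes; cycles are rejected in feed-forward mode.
    """
    existing = g.connected_pairs()
    sources = [nid for nid, n in g.nodes.items()
               if n.node_type != NodeType.OUTPUT or not feed_forward]
    sinks = [nid for nid, n in g.nodes.items()
             if n.node_type in (NodeType.HIDDEN, NodeType.OUTPUT)]
    enabled_pairs = [(c.in_node, c.out_node) for c in g.enabled_connections()]
    candidates = []
    for src in sources:
        for dst in sinks:
            if src == dst or (src, dst) in existing:
                continue
            if feed_forward and _creates_cycle(enabled_pairs, (src, dst)):
                continue
            candidates.append((src, dst))
    if not candidates:
        return g
    candidates.sort()
    src, dst = candidates[rng.integers(len(candidates))]
    innov = registry.connection_innovation(src, dst)
    g.connections[innov] = ConnectionGene(src, dst,
                                          _random_weight(rng, weight_low, weight_high),
                                          True, innov)
    return g


def mutate_add_node(g: Genome, registry: InnovationRegistry,
                    rng: np.random.Generator) -> Genome:
    """Split a random enabled connection with a new hidden node.

    The old connection is disabled; the incoming new connection gets weight
    1.0 and the outgoing one inherits the old weight, which minimizes the
    functional disruption of the split. No-op when nothing is enabled.
    """
    enabled = sorted(g.enabled_connections(), key=lambda c: c.innovation)
    if not enabled:
        return g
    conn = enabled[rng.integers(len(enabled))]
    conn.enabled = False
    node_id, innov_in, innov_out = registry.split_connection(
        conn.innovation, conn.in_node, conn.out_node)
    g.nodes[node_id] = NodeGene(node_id, NodeType.HIDDEN)
    g.connections[innov_in] = ConnectionGene(conn.in_node, node_id, 1.0, True, innov_in)
    g.connections[innov_out] = ConnectionGene(node_id, conn.out_node, conn.weight,
                                              True, innov_out)
    return g


def mutate_weights(g: Genome, p_perturb: float, sigma: float, p_reset: float,
                   rng: np.random.Generator, *,
                   clamp: float = WEIGHT_CLAMP,
                   weight_low: float = WEIGHT_INIT_LOW,
                   weight_high: float = WEIGHT_INIT_HIGH) -> Genome:
    """Perturb or reset every connection weight independently.

    Each weight is reset to a fresh random value with probability ``p_reset``,
    otherwise perturbed by Gaussian noise of scale ``sigma`` with probability
    ``p_perturb``. Weights are clamped to ±``clamp``.
    """
    if not (0 <= p_perturb <= 1 and 0 <= p_reset <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    for conn in g.connections.values():
        u = rng.random()
        if u < p_reset:
            conn.weight = _random_weight(rng, weight_low, weight_high)
        elif u < p_reset + p_perturb:
            conn.weight += float(rng.normal(0.0, sigma))
        conn.weight = float(np.clip(conn.weight, -clamp, clamp))
    return g


def crossover(parent_a: Genome, parent_b: Genome, rng: np.random.Generator, *,
              p_disable_inherit: float = 0.75,
              feed_forward: bool = True) -> Genome:
    """Recombine two genomes by lining up genes on innovation numbers.

    Matching genes are inherited from either parent at random; disjoint and
    excess genes come from the fitter parent (per-gene random at an exact
    fitness tie). A gene disabled in either parent stays disabled in the
    child with probability ``p_disable_inherit``.
    """
    if parent_a.raw_fitness is None or parent_b.raw_fitness is None:
        raise ValueError("both parents must have raw_fitness set before crossover")

    tie = parent_a.raw_fitness == parent_b.raw_fitness
    if tie:
        fitter, other = parent_a, parent_b
    elif parent_a.raw_fitness > parent_b.raw_fitness:
        fitter, other = parent_a, parent_b
    else:
        fitter, other = parent_b, parent_a

    child = Genome()
    matching = sorted(set(fitter.connections) & set(other.connections))
    for innov in matching:
        source = fitter if rng.random() < 0.5 else other
        gene = source.connections[innov].copy()
        en_f = fitter.connections[innov].enabled
        en_o = other.connections[innov].enabled
        if en_f != en_o:
            # disabled in exactly one parent: disabled in the child with the
            # configured probability, otherwise re-enabled
            gene.enabled = not (rng.random() < p_disable_inherit)
        else:
            gene.enabled = en_f
        child.connections[innov] = gene

    def _try_add(gene: ConnectionGene) -> None:
        pairs = [(c.in_node, c.out_node) for c in child.connections.values()]
        pair = (gene.in_node, gene.out_node)
        if pair in pairs:
            return
        if feed_forward and gene.enabled and _creates_cycle(
                [(a, b) for (a, b), c in
                 zip(pairs, child.connections.values()) if c.enabled], pair):
            return
        child.connections[gene.innovation] = gene.copy()

    if tie:
        # a non-matching gene lives in exactly one parent; at an exact tie
        # each one is inherited from its owner with probability 1/2
        nonmatching = sorted((set(fitter.connections) | set(other.connections))
                             - set(matching))
        for innov in nonmatching:
            if rng.random() < 0.5:
                owner = parent_a if innov in parent_a.connections else parent_b
                _try_add(owner.connections[innov])
    else:
        for innov in sorted(set(fitter.connections) - set(matching)):
            _try_add(fitter.connections[innov])

    # nodes: all structural i/o nodes from the fitter parent, plus every
    # endpoint referenced by an inherited gene
    for nid, node in fitter.nodes.items():
        if node.node_type != NodeType.HIDDEN:
            child.nodes[nid] = node
    for gene in child.connections.values():
        for nid in (gene.in_node, gene.out_node):
            if nid not in child.nodes:
                child.nodes[nid] = (fitter.nodes.get(nid) or other.nodes[nid])
    return child


def _align(a: Genome, b: Genome) -> tuple[list[int], int, int]:
    """Return (matching innovations, n_disjoint, n_excess) for a pair."""
    innovs_a, innovs_b = set(a.connections), set(b.connections)
    matching = sorted(innovs_a & innovs_b)
    max_a, max_b = a.max_innovation(), b.max_innovation()
    cutoff = min(max_a, max_b)
    nonmatching = (innovs_a | innovs_b) - set(matching)
    excess = sum(1 for i in nonmatching if i > cutoff)
    disjoint = len(nonmatching) - excess
    return matching, disjoint, excess


def compatibility_distance(a: Genome, b: Genome,
                           coeff: CompatibilityCoefficients | None = None) -> float:
    """δ = c1·E/N + c2·D/N + c3·W̄ over innovation-aligned connection genes.

    E counts genes beyond the other genome's maximum innovation, D the
    non-matching genes within range, W̄ the mean absolute weight difference
    of matching genes (0 when none match). N is the connection count of the
    larger genome, forced to 1 below ``coeff.N_threshold``.
    """
    coeff = coeff or CompatibilityCoefficients()
    matching, disjoint, excess = _align(a, b)
    if matching:
        w_bar = float(np.mean([abs(a.connections[i].weight - b.connections[i].weight)
                               for i in matching]))
    else:
        w_bar = 0.0
    n = max(len(a.connections), len(b.connections))
    if n < coeff.N_threshold:
        n = 1
    if n == 0:
        n = 1
    return coeff.c1 * excess / n + coeff.c2 * disjoint / n + coeff.c3 * w_bar
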