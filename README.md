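# swimneat

Neuroevolution with adaptive genetic-operator rates, applied to
swim-stroke monitoring from a waist-worn 6-axis inertial sensor.

## The problem

Wearable swim monitoring asks two questions of a tri-axial
accelerometer + gyroscope stream: *which stroke is being swum*, and *how
well* — is the rhythm stable, are the left and right sides balanced, is
the swimmer tiring? Cameras answer these at high cost and with privacy
problems; a single waist sensor answers them from signal shape alone.
`swimneat` provides the full chain: a seeded synthetic-signal generator
(no public recordings exist for this sensor placement), sliding-window
time-domain features, transparent rule-based stroke recognition,
roll-angle analytics, and a topology-evolving neural-network classifier
driven by an adaptive genetic algorithm.

## The core algorithm

Networks are evolved NEAT-style: a genome is a set of node genes and
connection genes, each connection carrying an innovation number (a
historical marker) so homologous genes align during crossover. Structure
grows from a minimal input–output topology via add-connection and
add-node mutations; genomes are partitioned into species by the
compatibility distance

    δ = c1·E/N + c2·D/N + c3·W̄

(E excess genes, D disjoint genes, W̄ mean matched-weight difference, N
the larger genome's gene count, N := 1 for small genomes), and species
share fitness — each member's fitness is divided by the species size —
so new structure is protected while it optimizes.

The twist is the operator schedule. Instead of fixed crossover and
mutation probabilities, both follow an inverse-cosine response to the
population's convergence ratio r = f_ave/f_max:

    pc = max(pc_floor, (2/π)·arccos(r)/k1)
    pm = max(pm_floor, (2/π)·arccos(r)/k2)

A diverse population (r « 1) explores with aggressive crossover and
mutation; a converging one (r → 1) is refined gently. Rank-based fitness
assignment (linear, mean 1; or nonlinear/geometric, sum n) is available
to cap the reproductive advantage of outliers.

The loop is validated on the XOR truth table — unsolvable without a
hidden node — with fitness `4 − Σ(target − output)²`, a stopping
threshold of 3.9 and a 300-generation cap.

## Worked example

```sh
python examples/xor_evolution.py
```

prints (seed 7):

```
solved: True after 105 generations
best fitness: 3.9990 (4.0 = perfect, stop at 3.9)
best genome: 6 nodes, 7 enabled connections
  (0.0, 0.0) -> 0.000 (target 0.0)
  (0.0, 1.0) -> 0.989 (target 1.0)
  (1.0, 0.0) -> 0.977 (target 1.0)
  (1.0, 1.0) -> 0.018 (target 0.0)
```

The evolved 6-node network answers all four XOR cases nearly exactly;
the history shows the operator rates pc/pm falling as the population
converges. The other examples cover the signal generator
(`simulate_strokes.py`), feature extraction (`extract_features.py`),
roll-angle analytics (`swim_metrics.py` — e.g. a 0.2 left/right
amplitude imbalance raises the measured angle asymmetry from 0.08° to
6.8°) and stroke classification (`stroke_classification.py` — the rule
cascade labels every clean synthetic signal correctly; the evolved
classifier reaches ~0.95 held-out accuracy on four strokes).

A thin CLI wraps the same functions:

```sh
swimneat simulate --stroke freestyle --duration 60 --out signal.csv
swimneat featurize signal.csv --out features.csv
swimneat metrics signal.csv --out metrics_out
swimneat xor --n-runs 20 --seed 0 --out xor_out
```

Every run writes a JSON manifest sufficient to reproduce its outputs.

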