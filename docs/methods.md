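# Methods

## The evolutionary model

`swimneat` evolves both the weights and the topology of feed-forward
neural networks. A genome holds node genes (input, bias, hidden, output)
and connection genes `(in, out, weight, enabled, innovation)`. The
innovation number is a historical marker handed out by a registry the
first time a structural innovation appears; within one generation the
same innovation (the same new connection, or the same split of an
existing connection) always receives the same number, and the registry's
per-generation memory is cleared afterwards while the global counters
persist. Markers turn crossover into an alignment problem: matching
genes (equal innovation) are inherited from either parent at random,
disjoint and excess genes from the fitter parent (per-gene random at an
exact tie, with a feed-forward cycle guard), and weights are inherited,
never blended.

Structural mutation takes two forms. *Add connection* links a previously
unlinked admissible pair (no duplicate pairs, no cycles in feed-forward
mode; saturation is a no-op). *Add node* splits a random enabled
connection: the old gene is disabled, the incoming replacement gets
weight 1.0 and the outgoing one inherits the old weight, which minimizes
the functional disruption of the split. Weight mutation perturbs every
connection independently (Gaussian, scale `sigma = 0.5`, probability
0.8) or resets it to Uniform(−1, 1) (probability 0.1), clamped to ±8.
These weight-mutation constants and the initial-weight range are
package conventions; the paper-of-record behaviour being emulated fixes
only the operators themselves.

Networks are evaluated in topological order with a steepened logistic
activation `1/(1 + e^(−4.9x))` (slope 4.9, the standard choice at XOR
scale; configurable). Bias is a dedicated always-1 input node. A node
with no incoming enabled connection rests at 0; a node whose inputs sum
to zero outputs 0.5, which is why the all-zero-weight XOR network scores
exactly 3.0 (= 4 − 4·0.25). Recurrent connections are disallowed by
default; a config flag removes the acyclicity guard for callers that
supply their own recurrent semantics.

## The adaptive genetic algorithm

**Operator schedule.** With convergence ratio `r = clamp(f_ave/f_max, 0, 1)`
(taken as 1 when `f_max = 0`),

    pc = clamp((2/π)·arccos(r) / k1, pc_floor, 1)
    pm = clamp((2/π)·arccos(r^e) / k2, pm_floor, 1)

Defaults: `k1 = 1`, `k2 = 2`, `pc_floor = 0.05`, `pm_floor = 0.01`,
exponent `e = 1`. Both rates are non-increasing in r: a scattered
population explores, a converged one is refined. The floors keep
evolution from freezing entirely.

**Fitness assignment.** Raw fitness comes from the task callback. An
optional rank transform replaces it: linear ranking
`F(Pos) = 2 − sp + 2(sp − 1)(Pos − 1)/(n − 1)` (mean exactly 1,
`1 < sp ≤ 2`), or nonlinear ranking `F(Pos) = n·X^(Pos−1)/Σ X^(i−1)`
where X is the admissible real root of
`(sp − n)X^(n−1) + sp·X^(n−2) + … + sp = 0` (sum exactly n). The root is
found with `numpy.roots`; if no usable real root exists (e.g. `sp = n`,
where the leading coefficient vanishes) a configuration error advises
linear mode. A minimization objective can be folded to fitness with
`max(C_max − f(x), 0)`.

**Speciation and sharing.** Genomes join the first species (in stable
id order) whose representative — a random member of the species'
previous generation — lies within `delta_t` of them, else found a new
species. Member fitness is divided by species size, and offspring slots
are allocated proportionally to each species' summed adjusted fitness
with largest-remainder rounding, so counts always sum exactly to the
population size. Species stale for more than 15 generations are removed
(the species holding the global best is immune).

**Loop order per generation**: evaluate → update rates from population
statistics → speciate → stagnation bookkeeping → allocate → reproduce
(per species: elites copied for species of ≥5 members; otherwise
crossover with probability pc else cloning; structural mutations at
`0.3·pm` (add connection) and `0.1·pm` (add node); weight mutation
always) → registry reset. All randomness flows from one
`numpy.random.default_rng(seed)`; runs are bit-reproducible.

Three design choices came out of observing the loop fail and are part of
the package's design:

* **`delta_t = 2.0`.** Small genomes (< 20 genes) use N = 1, so an
  add-node child differs from its parent by δ ≈ 2 + 0.4·W̄. At the
  common threshold of 3.0 such a child stays in the parent species,
  sharing never protects it, and truncation selection deletes fresh
  structure before it can be optimized — runs plateau. At 2.0 a single
  add-node mutation founds a new species immediately.
* **Champion preservation.** The best genome ever seen is re-inserted
  unchanged each generation. Without it the incumbent best was
  occasionally lost to sharing/stagnation churn and populations could
  collapse into the degenerate all-outputs-0.5 state, where the
  convergence ratio hits 1 and the schedule freezes the operators.
* **Refocusing.** After 20 generations without any improvement of the
  population best, only the top two species reproduce until the plateau
  breaks (their staleness is reset). This concentrates search when
  diversity has stopped paying.

On the XOR benchmark (population 150, threshold 3.9, cap 300) this
configuration solves ≈95% of seeded runs with a median of roughly
60–90 generations.

## Feature extraction

Windows are fixed-length (default 2 s at the signal's sampling rate)
with configurable overlap (default 50%); trailing partial windows are
dropped. Per channel: mean, population variance (divide by n),
moment-based skewness and excess kurtosis, first quartile and quartile
difference Q3 − Q1 (linear interpolation between order statistics), and
the peak-to-valley distance |argmax − argmin| in samples (first
occurrence under ties; 0 for a constant channel). Per configured channel
pair (default: the three acceleration pairs and the three gyro pairs):
Pearson correlation. The peak-to-peak distance is the global
sample-index separation between the maxima of consecutive windows; the
first window, which has no predecessor, records a sentinel equal to the
window length and is flagged in a `p2p_sentinel` column. A zero-variance
channel reports skewness, kurtosis and its correlations as 0 and is
flagged as degenerate. All statistics are O(n) per window; only
time-domain features are computed — frequency and wavelet features cost
at least O(n log n) and are out of scope by design.

## The synthetic generator

No public recordings exist for a waist-worn 6-axis sensor with X along
the body's central axis, Y left-right, Z up-down, so all validation uses
seeded synthetic signals. Deterministic per-channel waveforms at the
stroke frequency encode the qualitative stroke signatures: backstroke is
the only stroke with negative mean Z-acceleration (baseline −1.0 G0 vs
+0.6 to +1.0 for the others); backstroke and freestyle derive a large
Y-gyro from the body-roll trajectory (half-sine roll per half-cycle,
default target 45°, giving ≈ 140–425 °/s peak across intensities);
butterfly and breaststroke instead carry large X-gyro (300 °/s) and
Z-acceleration amplitudes (5.0 / 4.0 G0), with butterfly's X-gyro a
two-lobed pulse (two significant maxima per cycle) and breaststroke's a
single sinusoid. Intensity maps to stroke frequency 0.5 / 1.0 / 1.5 Hz
and X-acceleration scale 1 / 1.5 / 2 (low / medium / high). The
"large amplitude" ratios are free parameters with these documented
defaults; only the qualitative orderings are contractual.

The roll profile supports two impairments: `asymmetry` a scales the left
roll target by (1 + a) and the right by (1 − a); `fatigue_drift` d grows
the per-cycle target jitter linearly with time from 0 to a fractional
standard deviation of d on the last cycle. Noise is i.i.d. Gaussian per
channel (0.15 G0 / 8 °/s). Parameter sets whose *nominal* waveform
leaves the hardware envelope (|acc| ≤ 15 G0, |gyro| ≤ 1500 °/s,
frequency < 2 Hz) are rejected; clipping is applied only to noise tails.
Sessions concatenate labelled segments with a short moving-average
smoothing (±0.2 s) across boundaries, preserving total length exactly.

What the generator does *not* emulate: sensor bias and drift, turns and
wall push-offs, depth/pressure effects, inter-swimmer variability, or
any biomechanical body model. Passing tests on these signals shows the
pipeline recovers known generating parameters under the stated
signatures and noise; it says nothing about robustness to real-water
artifacts.

## Swim analytics

The roll angle is the cumulative trapezoidal integral of the Y-gyro
minus a centred moving average (default 5 s), which removes integration
drift and gyro bias at the cost of attenuating very slow asymmetries.
Zero crossings are detected with a Schmitt trigger whose hysteresis band
is 5% of the angle's interquartile range, then interpolated to
sub-sample precision; alternating half-cycles give TL and TR (mean
durations of left/right half-cycles; incomplete edge half-cycles are
discarded, and fewer than two crossings yields NaN markers). The fatigue
index is the sliding variance (default 10 s horizon) of the
per-half-cycle peak angle; asymmetry is summarized as
|mean left peak − mean |right trough|| and |TL − TR|. Session means of
TL/TR are reported; the per-cycle table is also emitted.

Rule-based stroke recognition is a fixed cascade: mean Z-acc below
−0.3 G0 → backstroke; else 95th-percentile |Y-gyro| ≥ 100 °/s →
freestyle; else large X-gyro (≥ 150 °/s) with large Z-acc amplitude
(≥ 2 G0) → butterfly if the X-gyro shows ≥ 1.5 significant local maxima
per cycle (peak prominence ≥ 30% of amplitude), breaststroke otherwise;
anything else is labelled `unknown`, never silently guessed.

The evolved-network classifier standardizes a labelled feature table
(z-score per column from the training split), evolves a network with one
output per class (argmax decision, fitness = training accuracy) and
reports a held-out confusion table from a stratified 25% split. Default
budget: population 96, cap 120 generations, stop at 0.97 training
accuracy. On the default 4-class synthetic tables (200 windows/class) it
reaches ≈ 0.95–0.98 held-out accuracy in about a minute per seed.

## Numerical choices and degenerate inputs

* Topological order via Kahn's algorithm with sorted tie-breaks —
  deterministic; cycles raise an error naming the nodes.
* Sigmoid exponent clipped at ±60 to avoid overflow.
* Crossover at an exact fitness tie inherits each non-matching gene from
  its owner with probability 1/2; a gene disabled in exactly one parent
  is disabled in the child with probability 0.75 (configurable), one
  disabled in both stays disabled.
* Allocation ties in largest-remainder rounding break by species id.
* Problem sizes used by the shipped checks — 20 XOR runs, 100 twelve-
  second sessions, 60 s spectra, 200 windows/class over 5 seeds — were
  chosen so the whole validation runs on a laptop in minutes while
  keeping every Monte-Carlo margin comfortable.

## Known limitations

* Population-level operator rates only; per-pair adaptive rates (using
  the fitter parent's fitness) are not implemented.
* Feed-forward phenotypes only; the recurrent flag disables validation
  but supplies no time-stepped semantics.
* The rule cascade's thresholds are tuned to the generator's documented
  amplitude conventions; real recordings would need re-calibration.
* TL/TR assume a single dominant roll frequency; mixed-stroke windows
  blur the crossings.
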