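"""Two routes to stroke recognition: rules and an evolved network.

The rule cascade reads the axis signatures directly (Z-acc sign, Y-gyro /
X-gyro amplitudes, X-gyro cycle shape). The evolved-network classifier
instead learns from windowed time-domain features: one output per stroke,
argmax decision, fitness = training accuracy.
"""

from swimneat.evolve import EvolutionConfig
from swimneat.swimmetrics import (
    classify_stroke_neat, classify_stroke_rules, stroke_feature_table)
from swimneat.synth import STROKES, StrokeParams, generate_stroke

print("rule cascade on clean signals:")
for stroke in STROKES:
    sig = generate_stroke(StrokeParams(stroke), 20.0, 50.0, seed=8)
    print(f"  {stroke:13s} -> {classify_stroke_rules(sig)}")

print("\nevolved-network classifier (50 windows/class to keep this quick):")
table = stroke_feature_table(n_windows_per_class=50, seed=1)
config = EvolutionConfig(population_size=64, max_generations=40,
                         fitness_threshold=0.97, seed=1)
clf = classify_stroke_neat(table, config)
print(f"held-out accuracy: {clf.holdout_accuracy:.3f} "
      f"after {clf.evolution.generations} generations")
print(clf.confusion.to_string())
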