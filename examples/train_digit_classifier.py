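"""Train a single-layer physical neural network to tell '0' from '1'.

The 8x8 digit pixels fill a 64-line data band at [15, 15.5] Hz; 64
trainable control amplitudes fill [20, 20.5] Hz.  The visual cortex's
second-order response multiplies every data line with every control line,
and the power split of the [35, 36] Hz intermodulation band across two
segments is read as the class probability.  A genetic algorithm learns the
control amplitudes against the simulator.
"""

import numpy as np

from ssvep_bci import (
    CortexModel,
    GAConfig,
    PNNLayer,
    plan_bands,
    predict_proba,
    train_alpha_ga,
)
from ssvep_bci.fixtures import FixtureSpec, make_digits

model = CortexModel().noiseless()
plan = plan_bands(64, 64, f_a=15.0, f_b=20.0, bandwidth=0.5)
print(f"sum band: [{plan.sum_band.start}, {plan.sum_band.stop}] Hz, "
      f"{plan.n_sum_lines} intermodulation lines, record period {1/plan.delta_f:.0f} s")

images, labels = make_digits(
    FixtureSpec("digits8x8", n_samples=12, classes=(0, 1), noise_sd=0.03, seed=5)
)
x = images.reshape(len(images), -1)

layer = PNNLayer(band_plan=plan, n_classes=2)
ga = GAConfig(population=32, generations=60, seed=1)
result = train_alpha_ga(x, labels, layer, model, ga)
print(f"GA fitness (mean log-probability): start {result.fitness_trace[0]:.3f}, "
      f"end {result.best_fitness:.3f}")

trained = layer.with_alpha(result.alpha)
probs = np.array([predict_proba(xi, trained, model) for xi in x])
accuracy = np.mean(np.argmax(probs, axis=1) == labels)
print(f"training accuracy: {accuracy:.2f}")
for cls in (0, 1):
    mean_probs = probs[labels == cls].mean(axis=0)
    print(f"digit '{cls}': mean probability vector {np.round(mean_probs, 3)}")
print("each digit's own class receives the larger share of intermodulation power.")
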