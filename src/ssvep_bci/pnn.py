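"""SSVEP physical neural network.

The visual cortex itself is the mixing layer of the network: the data comb
``X`` (band a) and a trainable control comb ``alpha`` (band b) flicker
simultaneously, the second-order neural response multiplies every data line
with every control line, and the resulting intermodulation (sum-frequency)
band is the network output.  The digital readout divides the sum band into
as many contiguous segments as there are classes and takes the power
fraction per segment — after max-normalization, so classification never
depends on overall intensity — as the class probability.

The control amplitudes are the network weights.  They are trained against
the simulator with a genetic algorithm (tournament selection, uniform
crossover, per-gene Gaussian mutation, elitism), and layers can be stacked
by re-encoding one layer's sum-band output, rigidly translated in
frequency, as the next layer's data comb together with fresh control
parameters.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cortex import (
    CortexModel,
    chi2_profile,
    sfg_lines_noisy,
    sfg_spectrum_analytic,
    simulate_eeg,
)
from .decode import NPSD, compute_npsd
from .fdm import BandPlan, FrequencyComb, normalize_balanced, synthesize_waveform

__all__ = [
    "PNNLayer",
    "GAConfig",
    "TrainResult",
    "encode_pnn_input",
    "quantize_features",
    "classify",
    "calibrate_segment_edges",
    "layer_output_npsd",
    "predict_proba",
    "predict_proba_two_layer",
    "train_alpha_ga",
    "train_two_layer",
    "stack_layer",
    "attention_gain",
]


@dataclass(frozen=True)
class PNNLayer:
    """One physical layer: band plan, control amplitudes and readout.

    ``segment_edges`` partition the nominal sum band into ``n_classes``
    contiguous intervals; by default the partition is equal-width.  The
    optional quadratic readout squares the normalized spectrum before the
    segment powers are taken.
    """

    band_plan: BandPlan
    n_classes: int
    alpha: np.ndarray | None = None
    readout: str = "linear"
    segment_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.readout not in ("linear", "quadratic"):
            raise ValueError("readout must be 'linear' or 'quadratic'")
        if self.alpha is not None:
            alpha = np.asarray(self.alpha, dtype=float)
            if alpha.shape != (self.band_plan.n_control,):
                raise ValueError(
                    f"alpha must have length {self.band_plan.n_control}, got {alpha.shape}"
                )
            if (alpha < 0).any() or (alpha > 1).any():
                raise ValueError("alpha values must lie in [0, 1]")
            object.__setattr__(self, "alpha", alpha)
        band = self.band_plan.sum_band
        if self.segment_edges is None:
            edges = np.linspace(band.start, band.stop, self.n_classes + 1)
        else:
            edges = np.asarray(self.segment_edges, dtype=float)
        if edges.shape != (self.n_classes + 1,) or (np.diff(edges) <= 0).any():
            raise ValueError("segment_edges must be increasing with n_classes+1 entries")
        if abs(edges[0] - band.start) > 1e-9 or abs(edges[-1] - band.stop) > 1e-9:
            raise ValueError("segment_edges must span the nominal sum band exactly")
        object.__setattr__(self, "segment_edges", edges)

    def with_alpha(self, alpha: np.ndarray) -> "PNNLayer":
        return dataclasses.replace(self, alpha=np.asarray(alpha, dtype=float))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (all configurable, defaults sane)."""

    population: int = 32
    generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    fitness: str = "cross_entropy"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fitness not in ("cross_entropy", "accuracy", "mean_prob"):
            raise ValueError("fitness must be 'cross_entropy', 'accuracy' or 'mean_prob'")
        if not (1 <= self.tournament_size <= self.population):
            raise ValueError("tournament_size must lie in [1, population]")
        if not (0 <= self.elitism < self.population):
            raise ValueError("elitism must lie in [0, population)")


@dataclass(frozen=True)
class TrainResult:
    """Best genome(s) found by the GA plus the per-generation fitness trace."""

    alpha: np.ndarray
    alpha2: np.ndarray | None
    fitness_trace: np.ndarray
    best_fitness: float


def encode_pnn_input(x_values: np.ndarray, layer: PNNLayer) -> FrequencyComb:
    """Combine data and control amplitudes into one drive comb.

    Both vectors are balance-normalized (unit sum of squares each, so the
    combined comb carries total squared amplitude 2), the data lines fill
    band a, the control lines band b, and the gap between the bands is
    zero-padded on the shared line grid.
    """
    plan = layer.band_plan
    x_values = np.asarray(x_values, dtype=float)
    if x_values.shape != (plan.n_image,):
        raise ValueError(f"expected {plan.n_image} data values, got {x_values.shape}")
    if layer.alpha is None:
        raise ValueError("layer has no control amplitudes set")
    x_bal, a_bal = normalize_balanced(x_values, layer.alpha)
    d = plan.delta_f
    offset = (plan.control_band.start - plan.image_band.start) / d
    if abs(offset - round(offset)) > 1e-6:
        raise ValueError("band offset is not an integer number of line spacings")
    offset = int(round(offset))
    amps = np.zeros(offset + plan.n_control)
    amps[: plan.n_image] = x_bal
    amps[offset :] = a_bal
    return FrequencyComb(f0=plan.image_band.start, delta_f=d, amplitudes=amps, label="pnn input")


def quantize_features(
    values: np.ndarray, lo: float, hi: float, bits: int = 2
) -> np.ndarray:
    """Uniformly quantize features and expand them into on/off amplitudes.

    Each feature is quantized to ``2**bits`` levels over [lo, hi] (values
    outside are clipped with a warning) and written out in binary, most
    significant bit first; e.g. 5 features at 2-bit depth become 10 on/off
    frequency components.
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    if bits < 1:
        raise ValueError("bits must be >= 1")
    v = np.asarray(values, dtype=float)
    if (v < lo).any() or (v > hi).any():
        warnings.warn("values outside [lo, hi] were clipped", stacklevel=2)
        v = np.clip(v, lo, hi)
    n_levels = 2**bits
    levels = np.minimum((v - lo) / (hi - lo) * n_levels, n_levels - 1).astype(int)
    shifts = np.arange(bits - 1, -1, -1)
    out = (levels[..., None] >> shifts) & 1
    return out.reshape(*v.shape[:-1], v.shape[-1] * bits).astype(float)


def classify(npsd: NPSD, layer: PNNLayer) -> np.ndarray:
    """Read class probabilities from the intermodulation band.

    Restricts the NPSD to the sum band, renormalizes the maximum to 1,
    applies the optional quadratic readout, and returns the power fraction
    in each of the ``n_classes`` segments.
    """
    band = layer.band_plan.sum_band
    sub = npsd.band(band.start, band.stop)
    power = sub.power
    if layer.readout == "quadratic":
        power = power**2
    seg = np.digitize(sub.freqs, layer.segment_edges[1:-1])
    probs = np.array([power[seg == k].sum() for k in range(layer.n_classes)])
    total = probs.sum()
    if total <= 0:
        warnings.warn("zero total sum-band power; returning uniform probabilities", stacklevel=2)
        return np.full(layer.n_classes, 1.0 / layer.n_classes)
    return probs / total


def calibrate_segment_edges(
    plan: BandPlan,
    model: CortexModel,
    n_classes: int,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Segment edges that equalize the power of a reference input.

    The intermodulation profile of two combs is triangular (the number of
    line pairs summing to each frequency peaks at the band center), so an
    equal-width partition structurally favors the middle class.  This
    helper places the interior edges so the chi2-weighted power of a
    ``reference`` data comb (flat by default) splits evenly across the
    ``n_classes`` segments — i.e. a featureless input yields near-uniform
    probabilities.  Edges are snapped to midpoints between line positions.
    """
    freqs = plan.sum_frequencies()
    if reference is None:
        reference = np.ones(plan.n_image)
    ref_x = np.asarray(reference, dtype=float)
    ref_x = ref_x / np.sqrt(np.sum(ref_x**2))
    flat_alpha = np.ones(plan.n_control) / np.sqrt(plan.n_control)
    profile = (chi2_profile(freqs, model) * np.convolve(ref_x, flat_alpha)) ** 2
    cum = np.concatenate([[0.0], np.cumsum(profile)]) / profile.sum()
    band = plan.sum_band
    bounds = np.concatenate([[band.start], (freqs[:-1] + freqs[1:]) / 2.0, [band.stop]])
    interior = [bounds[np.argmin(np.abs(cum - k / n_classes))] for k in range(1, n_classes)]
    edges = np.array([band.start, *interior, band.stop])
    if (np.diff(edges) <= 0).any():
        raise ValueError("reference profile too degenerate to calibrate segment edges")
    return edges


def _x_comb(plan: BandPlan, values: np.ndarray) -> FrequencyComb:
    return FrequencyComb(plan.image_band.start, plan.delta_f, values)


def _alpha_comb(plan: BandPlan, values: np.ndarray) -> FrequencyComb:
    return FrequencyComb(plan.control_band.start, plan.delta_f, values)


def layer_output_npsd(
    x_values: np.ndarray,
    layer: PNNLayer,
    model: CortexModel,
    sim: str = "analytic",
    seed: int | None = None,
    n_records: int = 1,
    sample_rate: float = 1000.0,
) -> NPSD:
    """Sum-band NPSD a layer produces for one input sample.

    ``sim='analytic'`` evaluates the second-order line response directly on
    the sum grid (with the statistically matched line-level noise model when
    the cortex model has noise); ``sim='time_domain'`` synthesizes the drive
    waveform, runs the full simulator for ``n_records`` periods and takes
    the averaged periodogram.  Both return the sum-band restriction, ready
    for :func:`classify`.
    """
    plan = layer.band_plan
    if layer.alpha is None:
        raise ValueError("layer has no control amplitudes set")
    if sim == "analytic":
        x_bal, a_bal = normalize_balanced(np.asarray(x_values, float), layer.alpha)
        X = _x_comb(plan, x_bal)
        A = _alpha_comb(plan, a_bal)
        if model.has_noise:
            freqs, power = sfg_lines_noisy(
                X,
                A,
                model,
                record_length=1.0 / plan.delta_f,
                n_records=n_records,
                seed=seed,
                sample_rate=sample_rate,
            )
        else:
            freqs, w = sfg_spectrum_analytic(X, A, model)
            power = w**2
        return NPSD(freqs=freqs, power=power, resolution=plan.delta_f)
    if sim == "time_domain":
        comb = encode_pnn_input(x_values, layer)
        wave = synthesize_waveform(comb, sample_rate=sample_rate, n_periods=n_records)
        eeg = simulate_eeg(wave, model, seed=seed)
        npsd = compute_npsd(eeg, record_length=comb.period)
        return npsd.band(plan.sum_band.start, plan.sum_band.stop)
    raise ValueError("sim must be 'analytic' or 'time_domain'")


def predict_proba(
    x_values: np.ndarray,
    layer: PNNLayer,
    model: CortexModel,
    sim: str = "analytic",
    seed: int | None = None,
    n_records: int = 1,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Class probabilities of a single-layer network for one sample."""
    npsd = layer_output_npsd(x_values, layer, model, sim, seed, n_records, sample_rate)
    return classify(npsd, layer)


def _stacked_values(prev_npsd: NPSD, prev_layer: PNNLayer, next_layer: PNNLayer) -> np.ndarray:
    """Sum-band line powers of the previous layer, padded to the next band."""
    prev_plan = prev_layer.band_plan
    next_plan = next_layer.band_plan
    n_lines = prev_plan.n_sum_lines
    if n_lines > next_plan.n_image:
        raise ValueError(
            f"{n_lines} output lines exceed the next band capacity of {next_plan.n_image} lines"
        )
    values = np.empty(n_lines)
    for k, f in enumerate(prev_plan.sum_frequencies()):
        idx = int(np.searchsorted(prev_npsd.freqs, f))
        candidates = [i for i in (idx - 1, idx, idx + 1) if 0 <= i < prev_npsd.freqs.size]
        best = min(candidates, key=lambda i: abs(prev_npsd.freqs[i] - f))
        if abs(prev_npsd.freqs[best] - f) > 1e-6 * prev_npsd.resolution:
            raise ValueError(f"sum frequency {f:g} Hz does not lie on the NPSD grid")
        values[k] = prev_npsd.power[best]
    return np.concatenate([values, np.zeros(next_plan.n_image - n_lines)])


def stack_layer(prev_npsd: NPSD, prev_layer: PNNLayer, next_layer: PNNLayer) -> FrequencyComb:
    """Re-encode one layer's output as the next layer's drive comb.

    The previous layer's sum-band line powers are rigidly translated into
    the next layer's data band (relative values preserved; the line spacing
    carries over and unused capacity is zero-padded), balance-normalized and
    combined with the next layer's control comb.
    """
    return encode_pnn_input(_stacked_values(prev_npsd, prev_layer, next_layer), next_layer)


def predict_proba_two_layer(
    x_values: np.ndarray,
    layer1: PNNLayer,
    layer2: PNNLayer,
    model: CortexModel,
    sim: str = "analytic",
    seed: int | None = None,
    n_records: int = 1,
    sample_rate: float = 1000.0,
    stack: str = "readout",
) -> np.ndarray:
    """Class probabilities of a two-layer (connected-brain) network.

    ``stack`` selects what the first layer hands to the second:

    * ``"readout"`` (default) — the first layer's class probabilities
      (its segment powers) are re-encoded as the second layer's data comb.
      The second mixing then acts as a trainable quadratic sharpening of
      the first readout, which is what lifts the correct-class
      probabilities of the stacked network.
    * ``"lines"`` — the raw sum-band line powers are rigidly translated
      into the second layer's data band (:func:`stack_layer`).
    """
    if stack not in ("readout", "lines"):
        raise ValueError("stack must be 'readout' or 'lines'")
    rng = np.random.default_rng(seed)
    seed1, seed2 = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    if sim == "time_domain":
        comb1 = encode_pnn_input(x_values, layer1)
        wave1 = synthesize_waveform(comb1, sample_rate=sample_rate, n_periods=n_records)
        npsd1 = compute_npsd(simulate_eeg(wave1, model, seed=seed1), record_length=comb1.period)
        if stack == "readout":
            band = layer1.band_plan.sum_band
            values2 = classify(npsd1.band(band.start, band.stop), layer1)
            comb2 = encode_pnn_input(values2, layer2)
        else:
            comb2 = stack_layer(npsd1, layer1, layer2)
        wave2 = synthesize_waveform(comb2, sample_rate=sample_rate, n_periods=n_records)
        npsd2 = compute_npsd(simulate_eeg(wave2, model, seed=seed2), record_length=comb2.period)
        band2 = layer2.band_plan.sum_band
        return classify(npsd2.band(band2.start, band2.stop), layer2)
    npsd1 = layer_output_npsd(x_values, layer1, model, sim, seed1, n_records, sample_rate)
    if stack == "readout":
        values2 = classify(npsd1, layer1)
    else:
        values2 = _stacked_values(npsd1, layer1, layer2)
    npsd2 = layer_output_npsd(values2, layer2, model, sim, seed2, n_records, sample_rate)
    return classify(npsd2, layer2)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def _ga_maximize(eval_fn, n_genes: int, ga: GAConfig, initial: np.ndarray | None = None):
    """Generic GA over genomes in [0, 1]^n_genes; returns (best, trace).

    Tournament selection, uniform crossover, per-gene Gaussian mutation
    clipped to [0, 1], elitism.  ``initial`` rows (if given) seed part of
    the first population (warm start).  `eval_fn` must be deterministic for
    the elitism trace to be monotone; training therefore evaluates every
    genome against a fixed set of noise realizations (common random
    numbers).
    """
    rng = np.random.default_rng(ga.seed)
    pop = rng.uniform(0.0, 1.0, (ga.population, n_genes))
    if initial is not None:
        initial = np.atleast_2d(np.asarray(initial, dtype=float))
        pop[: min(len(initial), ga.population)] = initial[: ga.population]
    fit = np.array([eval_fn(g) for g in pop])
    trace = []
    for _ in range(ga.generations):
        order = np.argsort(fit)[::-1]
        pop, fit = pop[order], fit[order]
        trace.append(fit[0])
        children = [pop[i].copy() for i in range(ga.elitism)]
        while len(children) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]].copy())
            a, b = parents
            if rng.random() < ga.crossover_rate:
                mask = rng.random(n_genes) < 0.5
                a[mask], b[mask] = b[mask].copy(), a[mask].copy()
            for child in (a, b):
                m = rng.random(n_genes) < ga.mutation_rate
                child[m] = np.clip(child[m] + rng.normal(0.0, ga.mutation_sd, m.sum()), 0.0, 1.0)
                if len(children) < ga.population:
                    children.append(child)
        pop = np.array(children)
        fit = np.array(
            [fit[i] if i < ga.elitism else eval_fn(pop[i]) for i in range(ga.population)]
        )
    best = int(np.argmax(fit))
    trace.append(fit[best])
    return pop[best], np.array(trace)


def _fitness_from_probs(probs: np.ndarray, labels: np.ndarray, kind: str) -> float:
    correct = probs[np.arange(labels.size), labels]
    if kind == "accuracy":
        return float(np.mean(np.argmax(probs, axis=1) == labels))
    if kind == "mean_prob":
        return float(np.mean(correct))
    # negative cross-entropy, maximized; floored so a single impossible
    # sample cannot dominate the population ranking
    return float(np.mean(np.log(np.clip(correct, 1e-3, None))))


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain fewer than 2 classes")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range for the layer's class count")
    return labels


def train_alpha_ga(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    layer: PNNLayer,
    model: CortexModel,
    ga: GAConfig,
    sim: str = "analytic",
    n_records: int = 1,
    sample_rate: float = 1000.0,
) -> TrainResult:
    """Learn the control amplitudes of a single layer with the GA.

    Every candidate genome is pushed through the simulator for every
    training sample; fitness is the mean log-probability of the true class
    (or accuracy).  Noise realizations are frozen per sample at the start of
    training, so fitness is deterministic and the elite trace is monotone.
    Fully reproducible from ``ga.seed``.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    labels = _check_labels(train_labels, layer.n_classes)
    seeds = np.random.default_rng(ga.seed + 1).integers(0, 2**31 - 1, train_x.shape[0])

    def evaluate(genome: np.ndarray) -> float:
        cand = layer.with_alpha(genome)
        try:
            probs = np.array(
                [
                    predict_proba(x, cand, model, sim, int(s), n_records, sample_rate)
                    for x, s in zip(train_x, seeds)
                ]
            )
        except ValueError:
            return -np.inf
        return _fitness_from_probs(probs, labels, ga.fitness)

    best, trace = _ga_maximize(evaluate, layer.band_plan.n_control, ga)
    return TrainResult(alpha=best, alpha2=None, fitness_trace=trace, best_fitness=float(trace[-1]))


def train_two_layer(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    layer1: PNNLayer,
    layer2: PNNLayer,
    model: CortexModel,
    ga: GAConfig,
    sim: str = "analytic",
    n_records: int = 1,
    sample_rate: float = 1000.0,
    stack: str = "readout",
    warm_start: np.ndarray | None = None,
) -> TrainResult:
    """Jointly learn both layers' control amplitudes (concatenated genome).

    ``warm_start`` (optionally a trained single-layer alpha) seeds part of
    the initial population for the first-layer genes, the usual way to
    retrain a stacked network starting from its single-layer solution.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    labels = _check_labels(train_labels, layer2.n_classes)
    p1 = layer1.band_plan.n_control
    p2 = layer2.band_plan.n_control
    rng = np.random.default_rng(ga.seed + 1)
    seeds = rng.integers(0, 2**31 - 1, train_x.shape[0])

    initial = None
    if warm_start is not None:
        n_warm = max(1, ga.population // 4)
        initial = rng.uniform(0.0, 1.0, (n_warm, p1 + p2))
        initial[:, :p1] = np.asarray(warm_start, dtype=float)

    def evaluate(genome: np.ndarray) -> float:
        l1 = layer1.with_alpha(genome[:p1])
        l2 = layer2.with_alpha(genome[p1:])
        try:
            probs = np.array(
                [
                    predict_proba_two_layer(
                        x, l1, l2, model, sim, int(s), n_records, sample_rate, stack
                    )
                    for x, s in zip(train_x, seeds)
                ]
            )
        except ValueError:
            return -np.inf
        return _fitness_from_probs(probs, labels, ga.fitness)

    best, trace = _ga_maximize(evaluate, p1 + p2, ga, initial=initial)
    return TrainResult(
        alpha=best[:p1], alpha2=best[p1:], fitness_trace=trace, best_fitness=float(trace[-1])
    )


def attention_gain(model: CortexModel, gain: float) -> CortexModel:
    """Scale the second-order response by an attention factor in (0, 1].

    Disrupted attention weakens the intermodulation response; ``gain=1``
    (full focus) returns the model unchanged, smaller gains multiply
    ``chi2_scale`` (and hence sum-band power, quadratically) down.
    """
    if not (0.0 < gain <= 1.0):
        raise ValueError("gain must lie in (0, 1]")
    if gain == 1.0:
        return model
    return dataclasses.replace(model, chi2_scale=model.chi2_scale * gain)
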