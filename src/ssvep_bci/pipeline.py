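"""End-to-end experiment runner.

Wires the stages together — encode, simulate, decode, train, classify —
behind a single serializable configuration, so a run is reproducible from
the config plus its seed alone.  Three named experiments cover the
pipeline:

* ``image`` — transmit a binary digit image through the simulated cortex
  and reconstruct it from the NPSD (SSIM, raw and mutual-information bit
  rates).
* ``pnn`` — train a single-layer physical neural network to separate two
  digit classes.
* ``two_layer`` — train single- and two-layer networks on the three-class
  tabular task and compare their correct-class probabilities.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .cortex import CortexModel, simulate_eeg
from .decode import bitrate, compute_npsd, mi_bitrate, reconstruct_image, ssim
from .fdm import build_comb, flatten_image, plan_bands, synthesize_waveform
from .fixtures import FixtureSpec, make_digits, make_iris_like
from .pnn import (
    GAConfig,
    PNNLayer,
    calibrate_segment_edges,
    predict_proba,
    predict_proba_two_layer,
    quantize_features,
    train_alpha_ga,
    train_two_layer,
)

__all__ = ["ExperimentConfig", "run_experiment", "make_two_layer_network"]

logger = logging.getLogger("ssvep_bci")

KINDS = ("image", "pnn", "two_layer")


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully serializable experiment description.

    ``params`` holds stage-specific knobs (all have defaults), ``model``
    overrides :class:`CortexModel` fields, ``outdir`` (optional) receives
    ``report.json`` and stage artifacts.
    """

    kind: str
    seed: int = 0
    outdir: str | None = None
    model: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        CortexModel(**self.model)  # validate overrides before any stage runs
        unknown = set(self.params) - set(_DEFAULTS[self.kind])
        if unknown:
            raise ValueError(f"unknown params for kind {self.kind!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def cortex_model(self) -> CortexModel:
        return CortexModel(**self.model)

    def param(self, name: str):
        return self.params.get(name, _DEFAULTS[self.kind][name])


_DEFAULTS: dict[str, dict] = {
    "image": {
        "digit": 7,
        "size": 14,
        "f0": 12.0,
        "bandwidth": 12.0,
        "sample_rate": 996.0,
        "n_periods": 4,
    },
    "pnn": {
        "classes": (0, 1),
        "n_train": 12,
        "f_a": 15.0,
        "f_b": 20.0,
        "bandwidth": 0.5,
        "population": 16,
        "generations": 15,
        "sim": "analytic",
    },
    "two_layer": {
        "n_train": 45,
        "n_test": 30,
        "separation": 1.0,
        "noise_sd": 0.1,
        "population": 32,
        "generations": 40,
        "sim": "analytic",
    },
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one named experiment; returns (and optionally writes) the report."""
    t_start = time.perf_counter()
    logger.info("stage=%s seed=%d starting", config.kind, config.seed)
    stage = {"image": _run_image, "pnn": _run_pnn, "two_layer": _run_two_layer}[config.kind]
    report = {"kind": config.kind, "seed": config.seed, **stage(config)}
    report["duration_s"] = round(time.perf_counter() - t_start, 3)
    logger.info("stage=%s seed=%d done in %.2fs", config.kind, config.seed, report["duration_s"])
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_report(outdir / "report.json", report)
    return report


def _run_image(config: ExperimentConfig) -> dict:
    model = config.cortex_model()
    size = config.param("size")
    spec = FixtureSpec(kind=f"digits{size}x{size}", n_samples=1, classes=(config.param("digit"),), seed=config.seed)
    image = make_digits(spec)[0][0]
    values = flatten_image(image)
    # unit total power per comb: the simulation convention for all tasks, so
    # one noise calibration covers image transfer and classification alike
    values = values / np.sqrt(np.sum(values**2))
    comb = build_comb(values, config.param("f0"), config.param("bandwidth"))
    fs, n_periods = config.param("sample_rate"), config.param("n_periods")
    stimulus = synthesize_waveform(comb, sample_rate=fs, n_periods=n_periods)
    eeg = simulate_eeg(stimulus, model, seed=config.seed)
    npsd = compute_npsd(eeg, record_length=comb.period)
    recon = reconstruct_image(npsd, comb, (size, size))
    illumination = n_periods * comb.period
    report = {
        "ssim": ssim(recon, image),
        "raw_bits_per_s": bitrate(image.size, 1, comb.period),
        "mi_bits_per_s": mi_bitrate(recon, image, illumination),
        "period_s": comb.period,
        "illumination_s": illumination,
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.save_image(outdir / "truth.png", image)
        _io.save_image(outdir / "reconstruction.png", recon)
        _io.npsd_to_csv(outdir / "npsd.csv", npsd)
    return report


def _run_pnn(config: ExperimentConfig) -> dict:
    model = config.cortex_model()
    classes = tuple(config.param("classes"))
    spec = FixtureSpec(kind="digits8x8", n_samples=config.param("n_train"), classes=classes, seed=config.seed)
    images, raw_labels = make_digits(spec)
    labels = np.searchsorted(np.array(classes), raw_labels)
    x = images.reshape(len(images), -1)
    plan = plan_bands(x.shape[1], x.shape[1], config.param("f_a"), config.param("f_b"), config.param("bandwidth"))
    layer = PNNLayer(band_plan=plan, n_classes=len(classes))
    ga = GAConfig(
        population=config.param("population"),
        generations=config.param("generations"),
        seed=config.seed,
    )
    result = train_alpha_ga(x, labels, layer, model, ga, sim=config.param("sim"))
    trained = layer.with_alpha(result.alpha)
    eval_seeds = np.random.default_rng(config.seed + 1).integers(0, 2**31 - 1, len(x))
    probs = np.array(
        [
            predict_proba(xi, trained, model, config.param("sim"), int(s))
            for xi, s in zip(x, eval_seeds)
        ]
    )
    report = {
        "classes": list(classes),
        "train_accuracy": float(np.mean(np.argmax(probs, axis=1) == labels)),
        "mean_correct_prob": float(np.mean(probs[np.arange(labels.size), labels])),
        "fitness_trace": result.fitness_trace.tolist(),
        "probabilities": probs.tolist(),
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "alpha.csv", result.alpha, delimiter=",", header="alpha", comments="")
    return report


def make_two_layer_network(model, n_classes: int = 3, n_inputs: int = 10) -> tuple[PNNLayer, PNNLayer]:
    """Band plans and layers of the stacked classification network.

    Layer 1 mixes the ``n_inputs`` on/off data lines ([15, 15.5] Hz) with as
    many control lines ([20, 20.5] Hz).  Layer 2 re-encodes layer 1's
    ``n_classes`` readout probabilities on a narrow comb and mixes them with
    fresh control lines; its quadratic readout sharpens the probability
    vector.  Segment edges of both layers are calibrated so a featureless
    input yields near-uniform probabilities.
    """
    plan1 = plan_bands(n_inputs, n_inputs, 15.0, 20.0, 0.5)
    width2 = 0.05 * n_classes  # keep the 0.05 Hz line spacing of layer 1
    plan2 = plan_bands(n_classes, n_classes, 15.0, 20.0, width2)
    layer1 = PNNLayer(
        band_plan=plan1,
        n_classes=n_classes,
        segment_edges=calibrate_segment_edges(plan1, model, n_classes),
    )
    layer2 = PNNLayer(
        band_plan=plan2,
        n_classes=n_classes,
        readout="quadratic",
        segment_edges=calibrate_segment_edges(plan2, model, n_classes),
    )
    return layer1, layer2


def _run_two_layer(config: ExperimentConfig) -> dict:
    model = config.cortex_model()
    n_train, n_test = config.param("n_train"), config.param("n_test")
    features, labels = make_iris_like(
        n_samples=n_train + n_test,
        separation=config.param("separation"),
        noise_sd=config.param("noise_sd"),
        seed=config.seed,
    )
    x = quantize_features(features, 0.0, 1.0, bits=2)
    layer1, layer2 = make_two_layer_network(model)
    ga = GAConfig(
        population=config.param("population"),
        generations=config.param("generations"),
        seed=config.seed,
        fitness="mean_prob",
    )
    sim = config.param("sim")
    r1 = train_alpha_ga(x[:n_train], labels[:n_train], layer1, model, ga, sim=sim)
    r2 = train_two_layer(
        x[:n_train], labels[:n_train], layer1, layer2, model, ga, sim=sim, warm_start=r1.alpha
    )
    one = layer1.with_alpha(r1.alpha)
    l1, l2 = layer1.with_alpha(r2.alpha), layer2.with_alpha(r2.alpha2)
    eval_seeds = np.random.default_rng(config.seed + 2).integers(0, 2**31 - 1, n_test)
    xs, ys = x[n_train:], labels[n_train:]
    probs1 = np.array(
        [predict_proba(xi, one, model, sim, int(s)) for xi, s in zip(xs, eval_seeds)]
    )
    probs2 = np.array(
        [predict_proba_two_layer(xi, l1, l2, model, sim, int(s)) for xi, s in zip(xs, eval_seeds)]
    )
    idx = np.arange(ys.size)
    return {
        "one_layer": {
            "mean_correct_prob": float(np.mean(probs1[idx, ys])),
            "accuracy": float(np.mean(np.argmax(probs1, axis=1) == ys)),
            "probabilities": probs1.tolist(),
        },
        "two_layer": {
            "mean_correct_prob": float(np.mean(probs2[idx, ys])),
            "accuracy": float(np.mean(np.argmax(probs2, axis=1) == ys)),
            "probabilities": probs2.tolist(),
        },
    }
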