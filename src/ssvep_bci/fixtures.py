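"""Deterministic synthetic inputs for the whole pipeline.

Nothing here is downloaded: handwritten-digit-like images come from stroke
templates, the three-class tabular task from Gaussian clusters in the unit
cube, and EEG records from the cortex simulator.  Every generator is
bitwise-reproducible under a fixed seed, and every output is a valid input
to the encoding/decoding/classification modules.

These generators emulate the *shape* of the real datasets (binary digit
images, a small 3-class flower-measurement table), not their exact
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cortex import CortexModel, simulate_eeg
from .fdm import FrequencyComb, Waveform, synthesize_waveform

__all__ = ["FixtureSpec", "digit_template", "make_digits", "make_iris_like", "make_eeg_record"]


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate and under which seed.

    ``kind`` is one of ``digits8x8``, ``digits14x14``, ``iris_like``.
    ``noise_sd`` is the pixel-flip probability for binary digits and the
    Gaussian feature spread for the tabular task.
    """

    kind: str
    n_samples: int = 10
    classes: tuple = (0, 1)
    noise_sd: float = 0.0
    seed: int = 0
    jitter: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("digits8x8", "digits14x14", "iris_like"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def digit_template(digit: int, size: int) -> np.ndarray:
    """Binary stroke template of a digit on a size x size canvas.

    Supported digits: 0 (ring), 1 (bar with serifs), 7 (top bar plus
    diagonal).  Values are {0, 1}.
    """
    if size < 7:
        raise ValueError("size must be >= 7")
    img = np.zeros((size, size))
    lo, hi = 1, size - 2  # 1-pixel margin
    if digit == 0:
        img[lo, lo + 1 : hi] = 1
        img[hi, lo + 1 : hi] = 1
        img[lo + 1 : hi, lo] = 1
        img[lo + 1 : hi, hi] = 1
    elif digit == 1:
        mid = size // 2
        img[lo:hi + 1, mid] = 1
        img[lo + 1, mid - 1] = 1  # flag
        img[hi, mid - 2 : mid + 3] = 1  # base serif
    elif digit == 7:
        img[lo, lo:hi + 1] = 1
        for r in range(lo + 1, hi + 1):
            c = hi - (r - lo) * (hi - lo) // (hi - lo + 2)
            img[r, max(lo, c)] = 1
    else:
        raise ValueError(f"unsupported digit class {digit}; templates exist for 0, 1, 7")
    return img


def make_digits(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate binary digit images with jitter and optional pixel flips.

    Returns ``(images, labels)`` with images of shape ``(n, size, size)``.
    Each sample is its class template, optionally shifted by up to
    ``jitter`` pixels per axis, then each pixel is flipped independently
    with probability ``noise_sd``.
    """
    if spec.kind not in ("digits8x8", "digits14x14"):
        raise ValueError("spec.kind must be digits8x8 or digits14x14")
    size = 8 if spec.kind == "digits8x8" else 14
    templates = {c: digit_template(c, size) for c in spec.classes}
    rng = np.random.default_rng(spec.seed)
    images = np.empty((spec.n_samples, size, size))
    labels = np.empty(spec.n_samples, dtype=int)
    for i in range(spec.n_samples):
        cls = spec.classes[i % len(spec.classes)]
        img = templates[cls]
        if spec.jitter > 0:
            j = spec.jitter
            img = np.roll(img, shift=(rng.integers(-j, j + 1), rng.integers(-j, j + 1)), axis=(0, 1))
        if spec.noise_sd > 0:
            flips = rng.random(img.shape) < spec.noise_sd
            img = np.abs(img - flips)
        images[i] = img
        labels[i] = cls
    return images, labels


# class centroid patterns in the unit cube; classes 1 and 2 overlap more than
# class 0 does with either, mirroring the classic flower-measurement task
_IRIS_PATTERNS = np.array(
    [
        [0.8, 0.2, 0.2, 0.8, 0.5],
        [0.2, 0.8, 0.5, 0.2, 0.5],
        [0.2, 0.8, 0.8, 0.2, 0.2],
    ]
)


def make_iris_like(
    n_samples: int = 150,
    n_features: int = 5,
    separation: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Three Gaussian class clusters in the unit cube.

    ``separation`` scales the distance between class centroids (0 collapses
    them onto a single point, so classification degrades to chance);
    ``noise_sd`` is the per-feature spread.  Features are clipped to [0, 1]
    so they can be quantized and frequency-encoded directly.  Returns
    ``(features, labels)`` with ``n_features`` in {4, 5}.
    """
    if n_features not in (4, 5):
        raise ValueError("n_features must be 4 or 5")
    rng = np.random.default_rng(seed)
    centroids = 0.5 + separation * (_IRIS_PATTERNS[:, :n_features] - 0.5)
    labels = np.arange(n_samples) % 3
    features = centroids[labels] + rng.normal(0.0, noise_sd, (n_samples, n_features))
    return np.clip(features, 0.0, 1.0), labels


def make_eeg_record(
    comb: FrequencyComb,
    model: CortexModel,
    n_periods: int = 1,
    seed: int | None = None,
    sample_rate: float = 1000.0,
) -> Waveform:
    """Synthesize a comb's drive waveform and simulate the evoked EEG."""
    stimulus = synthesize_waveform(comb, sample_rate=sample_rate, n_periods=n_periods)
    return simulate_eeg(stimulus, model, seed=seed)
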