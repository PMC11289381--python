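"""Frequency-division-multiplexed stimulus encoding.

An image (or any parameter vector) is encoded by assigning each value an
amplitude ``A_m`` on an equally spaced set of flicker frequencies
``f_m = f0 + m * delta_f``; the LED drive waveform is the superposition

    x(t) = sum_m A_m * cos(2 pi f_m t)

which repeats with period ``T = 1/delta_f``.  Band planning guarantees that
the second-order products of two narrow input bands (harmonics at twice each
band, the sum band, the difference band) stay spectrally separated, so the
intermodulation response can be isolated in the EEG spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrequencyComb",
    "Waveform",
    "Band",
    "BandPlan",
    "BandOverlapError",
    "flatten_image",
    "build_comb",
    "synthesize_waveform",
    "plan_bands",
    "normalize_balanced",
]

DEFAULT_SAMPLE_RATE = 1000.0


@dataclass(frozen=True)
class FrequencyComb:
    """Equally spaced frequencies with per-line amplitudes.

    Line ``m`` sits at ``f0 + m * delta_f`` with amplitude ``amplitudes[m]``.
    The comb repeats in time with fundamental period ``T = 1/delta_f``.
    """

    f0: float
    delta_f: float
    amplitudes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if amps.ndim != 1 or amps.size == 0:
            raise ValueError("amplitudes must be a non-empty 1-D vector")
        if not np.isfinite(amps).all() or (amps < 0).any():
            raise ValueError("amplitudes must be finite and non-negative")
        if not (self.f0 > 0):
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if not (self.delta_f > 0):
            raise ValueError(f"delta_f must be positive, got {self.delta_f}")

    @property
    def n_lines(self) -> int:
        return int(self.amplitudes.size)

    @property
    def frequencies(self) -> np.ndarray:
        return self.f0 + np.arange(self.n_lines) * self.delta_f

    @property
    def max_frequency(self) -> float:
        return self.f0 + (self.n_lines - 1) * self.delta_f

    @property
    def period(self) -> float:
        """Fundamental period T = 1/delta_f in seconds."""
        return 1.0 / self.delta_f

    def with_amplitudes(self, amplitudes: np.ndarray) -> "FrequencyComb":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=float))


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled real time series (stimulus or simulated EEG)."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class Band:
    """Closed frequency interval [start, stop] with a name."""

    name: str
    start: float
    stop: float

    def __post_init__(self) -> None:
        if not (self.stop > self.start):
            raise ValueError(f"band {self.name}: stop must exceed start")

    @property
    def width(self) -> float:
        return self.stop - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.stop)

    def overlaps(self, other: "Band") -> bool:
        # open-interval intersection: shared endpoints do not count
        return self.start < other.stop and other.start < self.stop


class BandOverlapError(ValueError):
    """Raised when two intervals of a band plan intersect."""

    def __init__(self, a: Band, b: Band):
        self.bands = (a, b)
        super().__init__(
            f"bands overlap: {a.name} [{a.start:g}, {a.stop:g}] Hz and "
            f"{b.name} [{b.start:g}, {b.stop:g}] Hz"
        )


@dataclass(frozen=True)
class BandPlan:
    """Two narrow input bands and their second-order product bands.

    ``image_band`` holds the data comb (M lines), ``control_band`` the
    control comb (P lines).  The derived intervals are the second harmonics
    of each band, the sum band (intermodulation between the two bands) and
    the difference band.  Validity requires the control band to satisfy
    ``center_a + width < center_b < 2*center_a - width`` and the five
    intervals {image, control, 2*image, 2*control, sum} to be pairwise
    disjoint; the difference band is reported but discarded by the decoder.
    """

    image_band: Band
    control_band: Band
    n_image: int
    n_control: int
    harmonic_image: Band = field(init=False)
    harmonic_control: Band = field(init=False)
    sum_band: Band = field(init=False)
    difference_band: Band = field(init=False)

    def __post_init__(self) -> None:
        a, b = self.image_band, self.control_band
        if self.n_image < 1 or self.n_control < 1:
            raise ValueError("band line counts must be >= 1")
        object.__setattr__(
            self, "harmonic_image", Band("second harmonic of image band", 2 * a.start, 2 * a.stop)
        )
        object.__setattr__(
            self,
            "harmonic_control",
            Band("second harmonic of control band", 2 * b.start, 2 * b.stop),
        )
        object.__setattr__(
            self, "sum_band", Band("sum (intermodulation) band", a.start + b.start, a.stop + b.stop)
        )
        object.__setattr__(
            self, "difference_band", Band("difference band", b.start - a.stop, b.stop - a.start)
        )
        self.validate()

    def validate(self) -> None:
        a, b = self.image_band, self.control_band
        if abs(a.width - b.width) > 1e-12 * max(a.width, b.width):
            raise ValueError("image and control bands must share the same width")
        dw = a.width
        # narrowband contract: center_a + dw < center_b < 2*center_a - dw
        if not (a.center + dw < b.center < 2 * a.center - dw):
            raise ValueError(
                "control band violates the narrowband contract "
                f"center_a + width < center_b < 2*center_a - width "
                f"({a.center:g} + {dw:g} < {b.center:g} < {2 * a.center - dw:g})"
            )
        bands = [a, b, self.harmonic_image, self.harmonic_control, self.sum_band]
        for i, x in enumerate(bands):
            for y in bands[i + 1 :]:
                if x.overlaps(y):
                    raise BandOverlapError(x, y)

    @property
    def bands(self) -> tuple[Band, ...]:
        return (
            self.image_band,
            self.control_band,
            self.harmonic_image,
            self.harmonic_control,
            self.sum_band,
            self.difference_band,
        )

    @property
    def delta_f(self) -> float:
        """Line spacing shared by both combs (width / line count)."""
        da = self.image_band.width / self.n_image
        db = self.control_band.width / self.n_control
        if abs(da - db) > 1e-12 * da:
            raise ValueError("image and control combs must share the same line spacing")
        return da

    @property
    def n_sum_lines(self) -> int:
        """Distinct sum frequencies of two equally spaced combs."""
        return self.n_image + self.n_control - 1

    def sum_frequencies(self) -> np.ndarray:
        """Discrete sum-frequency grid {f_m + f_n} of the two combs."""
        d = self.delta_f
        f_start = self.image_band.start + self.control_band.start
        return f_start + np.arange(self.n_sum_lines) * d


def flatten_image(image: np.ndarray) -> np.ndarray:
    """Flatten a 2-D grayscale image into a row-major amplitude vector.

    The decoder assigns the same pixel order, so the choice of ordering is
    immaterial as long as it is fixed; row-major is used throughout.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D matrix")
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ValueError("pixel values must lie in [0, 1]")
    return image.reshape(-1).copy()


def build_comb(values: np.ndarray, f0: float, bandwidth: float, label: str = "") -> FrequencyComb:
    """Attach an amplitude vector to a comb of ``len(values)`` lines.

    The spacing is ``bandwidth / len(values)``, so a 196-value image spread
    over 12 Hz repeats every 196/12 ~= 16.3 s, and over 1 Hz every 196 s.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not (bandwidth > 0):
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if not (f0 > 0):
        raise ValueError(f"f0 must be positive, got {f0}")
    return FrequencyComb(f0=f0, delta_f=bandwidth / values.size, amplitudes=values, label=label)


def synthesize_waveform(
    comb: FrequencyComb,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    n_periods: int = 1,
    renormalize: bool = False,
) -> Waveform:
    """Synthesize the time-domain drive waveform of a comb.

    ``x(t) = sum_m A_m cos(2 pi f_m t)`` over ``n_periods`` fundamental
    periods.  With ``renormalize`` the samples are affinely mapped to
    [0, 1], the convention used when exporting LED intensities so the mean
    light level is comparable across experiments; simulations keep the raw
    zero-mean superposition.

    The period must resolve to an integer number of samples
    (``sample_rate / delta_f`` integral) so every comb line falls on an
    exact DFT bin of a one-period record.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if sample_rate <= 2 * comb.max_frequency:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates Nyquist for top comb "
            f"frequency {comb.max_frequency} Hz"
        )
    samples_per_period = sample_rate * comb.period
    if abs(samples_per_period - round(samples_per_period)) > 1e-6:
        raise ValueError(
            f"comb period {comb.period:g} s is not an integer number of samples at "
            f"{sample_rate:g} Hz; choose delta_f commensurate with the sample rate"
        )
    n = int(round(samples_per_period)) * n_periods
    t = np.arange(n) / sample_rate
    # one outer product per line set; fine for combs of a few hundred lines
    x = np.cos(2 * np.pi * np.outer(comb.frequencies, t)).T @ comb.amplitudes
    if renormalize:
        lo, hi = x.min(), x.max()
        x = (x - lo) / (hi - lo) if hi > lo else np.full_like(x, 0.5)
    return Waveform(samples=x, sample_rate=sample_rate)


def plan_bands(M: int, P: int, f_a: float, f_b: float, bandwidth: float) -> BandPlan:
    """Build and validate a two-band frequency plan.

    ``M`` lines start at ``f_a`` and ``P`` lines at ``f_b``, each band
    ``bandwidth`` wide.  Raises :class:`BandOverlapError` (naming the two
    clashing intervals) or ``ValueError`` when the narrowband contract or
    pairwise disjointness fails.
    """
    for name, v in (("M", M), ("P", P), ("f_a", f_a), ("f_b", f_b), ("bandwidth", bandwidth)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")
    return BandPlan(
        image_band=Band("image band", f_a, f_a + bandwidth),
        control_band=Band("control band", f_b, f_b + bandwidth),
        n_image=int(M),
        n_control=int(P),
    )


def normalize_balanced(
    x_values: np.ndarray, alpha_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each vector to unit sum of squares.

    Balancing the total power between the data and control combs keeps the
    two bands comparable in the recorded spectrum.
    """

    def _unit(v: np.ndarray, name: str) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        norm = float(np.sqrt(np.sum(v**2)))
        if norm == 0.0:
            raise ValueError(f"{name} vector is all-zero and cannot be balanced")
        return v / norm

    return _unit(x_values, "x"), _unit(alpha_values, "alpha")
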