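"""Phenomenological nonlinear visual-cortex simulator.

The steady-state visual evoked potential is modelled, in the style of
nonlinear optics, as a sum of susceptibility-weighted powers of the light
stimulus: the spectrum of the simulated EEG is

    y~(w) = sum_{n=1..N} chi~(n)(w) * FT[x^n](w)

so a flicker spectrum confined to narrow bands produces first-order lines at
the stimulus frequencies plus second-order lines at all pairwise sums and
differences (harmonics and intermodulation).  The second-order
susceptibility follows a universal decaying-exponential profile
``chi2_scale * exp(-f / chi2_decay)``.

On top of the deterministic response the simulator adds the features of a
resting EEG spectrum needed to emulate recorded data: an input-referred
perturbative white noise xi (which mixes with the stimulus through the
quadratic term), a 1/f-like colored background, a Gaussian alpha-rhythm bump
near 10 Hz, and a white output noise floor.  With the stimulus off, the
spectrum therefore shows only the alpha peak, as a blindfolded recording
does.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .fdm import Band, BandPlan, FrequencyComb, Waveform

__all__ = [
    "CortexModel",
    "chi2_profile",
    "simulate_eeg",
    "sfg_spectrum_analytic",
    "sfg_lines_noisy",
    "band_plan_from_combs",
]


@dataclass(frozen=True)
class CortexModel:
    """Parameters of the phenomenological nonlinear SSVEP response.

    Amplitude units are arbitrary (EEG gain is unknown); what matters are
    the ratios between stimulus lines, second-order products and noise.
    Defaults are calibrated so that, for balanced unit-power combs, the
    first-order lines stand ~2 orders of magnitude above the background,
    the intermodulation lines are clearly visible but much weaker than the
    first-order lines, and a stimulus-free record is dominated by the alpha
    peak — the qualitative regime of recorded spectra.

    Parameters
    ----------
    chi1:
        First-order gain (flat).  A tabulated profile can be supplied via
        ``chi1_table`` as ``(freqs_hz, values)`` and is linearly
        interpolated.
    chi2_scale, chi2_decay:
        Second-order susceptibility ``chi2_scale * exp(-f / chi2_decay)``;
        ``chi2_decay`` in Hz (``numpy.inf`` gives a flat profile).  The
        decaying exponential is universal across users; its absolute scale
        is a free parameter, set so the intermodulation band of balanced
        two-band combs stands well clear of the background (the contrast
        recorded intermodulation spectra display) while remaining much
        weaker than the first-order lines.
    max_order:
        Highest power of the stimulus included (default 2: harmonics and
        pairwise intermodulation only).  Orders >= 3 reuse the second-order
        profile.
    gain_sigma:
        Overall input gain sigma applied to the stimulus (LED intensity
        amplification); second-order products scale as sigma**2.
    noise_white_sd:
        Standard deviation per sample of the input-referred white noise xi
        added to the stimulus before the nonlinearity.
    background_scale, background_slope, background_knee:
        Colored output noise with amplitude envelope
        ``background_scale / (f + knee)**(slope/2)`` — a 1/f**slope power
        spectrum flattened below ``knee`` Hz, as resting EEG spectra are.
    alpha_center, alpha_height, alpha_width:
        Gaussian alpha-rhythm bump (Hz, amplitude, Hz).
    output_white_sd:
        White measurement-noise floor added to the output samples.
    seed:
        Default RNG seed for noise realizations; ``simulate_eeg`` may
        override it.
    """

    chi1: float = 1.0
    chi1_table: tuple | None = None
    chi2_scale: float = 3.0
    chi2_decay: float = 10.0
    max_order: int = 2
    gain_sigma: float = 1.0
    noise_white_sd: float = 0.01
    background_scale: float = 0.15
    background_slope: float = 1.0
    background_knee: float = 1.0
    alpha_center: float = 10.0
    alpha_height: float = 0.8
    alpha_width: float = 1.0
    output_white_sd: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chi2_scale < 0:
            raise ValueError("chi2_scale must be >= 0")
        if not (self.chi2_decay > 0):
            raise ValueError("chi2_decay must be > 0")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        for name in ("noise_white_sd", "background_scale", "alpha_height", "output_white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- susceptibilities ------------------------------------------------

    def chi_order(self, n: int, f: np.ndarray) -> np.ndarray:
        """nth-order susceptibility evaluated on frequencies ``f`` (Hz)."""
        f = np.asarray(f, dtype=float)
        if n == 1:
            if self.chi1_table is not None:
                xp, yp = self.chi1_table
                return np.interp(f, np.asarray(xp, float), np.asarray(yp, float))
            return np.full_like(f, self.chi1)
        return chi2_profile(f, self)

    def noise_envelope(self, f: np.ndarray) -> np.ndarray:
        """Amplitude envelope of the colored output noise (background + alpha)."""
        f = np.asarray(f, dtype=float)
        bg = self.background_scale / (f + self.background_knee) ** (self.background_slope / 2.0)
        alpha = self.alpha_height * np.exp(
            -((f - self.alpha_center) ** 2) / (2.0 * self.alpha_width**2)
        )
        return bg + alpha

    @property
    def has_noise(self) -> bool:
        return (
            self.noise_white_sd > 0
            or self.background_scale > 0
            or self.alpha_height > 0
            or self.output_white_sd > 0
        )

    def noiseless(self) -> "CortexModel":
        """Copy of the model with every noise source switched off."""
        return dataclasses.replace(
            self,
            noise_white_sd=0.0,
            background_scale=0.0,
            alpha_height=0.0,
            output_white_sd=0.0,
        )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["chi1_table"] is not None:
            xp, yp = d["chi1_table"]
            d["chi1_table"] = [list(map(float, xp)), list(map(float, yp))]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CortexModel":
        d = dict(d)
        if d.get("chi1_table") is not None:
            xp, yp = d["chi1_table"]
            d["chi1_table"] = (np.asarray(xp, float), np.asarray(yp, float))
        return cls(**d)


def chi2_profile(f, model: CortexModel):
    """Second-order susceptibility ``chi2_scale * exp(-f / chi2_decay)``.

    ``f`` in Hz, scalar or array; negative frequencies are rejected.
    """
    f_arr = np.asarray(f, dtype=float)
    if (f_arr < 0).any():
        raise ValueError("frequency must be non-negative")
    out = model.chi2_scale * np.exp(-f_arr / model.chi2_decay)
    return float(out) if np.isscalar(f) else out


def _stimulus_max_frequency(samples: np.ndarray, sample_rate: float) -> float:
    """Highest frequency with non-negligible stimulus power.

    The threshold (1e-6 of the strongest line) tolerates float32 storage
    noise in stimuli that went through a WAV file.
    """
    spec = np.abs(rfft(samples))
    top = spec.max()
    if top == 0:
        return 0.0
    freqs = rfftfreq(samples.size, 1.0 / sample_rate)
    significant = np.nonzero(spec > 1e-6 * top)[0]
    return float(freqs[significant[-1]]) if significant.size else 0.0


def simulate_eeg(stimulus: Waveform, model: CortexModel, seed: int | None = None) -> Waveform:
    """Simulate an EEG record evoked by a flicker stimulus.

    Applies the susceptibility-weighted harmonic expansion order by order
    (``irfft(chi_n(f) * rfft((sigma*x + xi)^n))``), then adds the colored
    background, the alpha bump and the white output floor.  Deterministic
    for a fixed seed (``seed`` argument, falling back to ``model.seed``).
    """
    if not np.isfinite(stimulus.samples).all():
        raise ValueError("stimulus contains non-finite samples")
    fs = stimulus.sample_rate
    n = stimulus.n_samples
    f_max = _stimulus_max_frequency(stimulus.samples, fs)
    if model.max_order * f_max >= fs / 2:
        raise ValueError(
            f"order-{model.max_order} products of the {f_max:g} Hz stimulus exceed the "
            f"Nyquist frequency {fs / 2:g} Hz"
        )

    rng = np.random.default_rng(model.seed if seed is None else seed)
    x = model.gain_sigma * stimulus.samples
    if model.noise_white_sd > 0:
        x = x + rng.normal(0.0, model.noise_white_sd, n)

    freqs = rfftfreq(n, 1.0 / fs)
    y = np.zeros(n)
    for order in range(1, model.max_order + 1):
        y += irfft(model.chi_order(order, freqs) * rfft(x**order), n)

    if model.background_scale > 0 or model.alpha_height > 0:
        env = model.noise_envelope(freqs)
        g = rng.normal(0.0, np.sqrt(0.5), freqs.size) + 1j * rng.normal(
            0.0, np.sqrt(0.5), freqs.size
        )
        g[0] = g[0].real * np.sqrt(2)
        if n % 2 == 0:
            g[-1] = g[-1].real * np.sqrt(2)
        # scaling makes the expected one-sided periodogram equal env(f)^2
        y += irfft(g * env * np.sqrt(fs * n / 2.0), n)
    if model.output_white_sd > 0:
        y += rng.normal(0.0, model.output_white_sd, n)

    return Waveform(samples=y, sample_rate=fs, t0=stimulus.t0)


def band_plan_from_combs(X: FrequencyComb, alpha: FrequencyComb) -> BandPlan:
    """Band plan implied by a data comb and a control comb.

    Requires the two combs to share their line spacing (so their pairwise
    sums fall on a single grid) and validates the narrowband contract and
    disjointness of all product bands.
    """
    if abs(X.delta_f - alpha.delta_f) > 1e-12 * X.delta_f:
        raise ValueError("data and control combs must share the same line spacing")
    return BandPlan(
        image_band=Band("image band", X.f0, X.f0 + X.n_lines * X.delta_f),
        control_band=Band("control band", alpha.f0, alpha.f0 + alpha.n_lines * alpha.delta_f),
        n_image=X.n_lines,
        n_control=alpha.n_lines,
    )


def sfg_spectrum_analytic(
    X: FrequencyComb, alpha: FrequencyComb, model: CortexModel
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free sum-frequency-generation line spectrum.

    Returns ``(freqs, weights)`` with one entry per distinct sum frequency
    ``f_m + f_n`` (data line m, control line n) and weight

        (pi/2) * chi2(f) * sum_{m+n=k} A_m B_n

    i.e. the second-order cross spectrum ``(pi/2) chi2 [X * alpha]`` with
    difference-frequency and self-harmonic terms excluded.  The pi/2 scale
    follows the continuous-transform convention in which a unit cosine
    carries spectral weight pi at its line; the time-domain cross term
    ``2 x_X x_alpha`` has cosine amplitude ``chi2 * sum A_m B_n``, i.e.
    ``2/pi`` times these weights.
    """
    plan = band_plan_from_combs(X, alpha)  # raises on overlap
    freqs = plan.sum_frequencies()
    conv = np.convolve(X.amplitudes, alpha.amplitudes)
    weights = (np.pi / 2.0) * chi2_profile(freqs, model) * conv
    return freqs, weights


def sfg_lines_noisy(
    X: FrequencyComb,
    alpha: FrequencyComb,
    model: CortexModel,
    record_length: float | None = None,
    n_records: int = 1,
    seed: int | None = None,
    sample_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy sum-band line powers, simulated directly on the line grid.

    A fast statistical equivalent of running :func:`simulate_eeg` and
    reading the periodogram on the sum band, used inside training loops.
    Per record, the input-referred noise perturbs the line amplitudes
    (``X' = sigma X + xi``, ``alpha' = sigma alpha + xi``), the cross
    convolution is weighted by ``(pi/2) chi2``, and the colored background
    adds a complex Gaussian to each bin with the variance a periodogram of
    length ``record_length`` would show; powers are averaged over
    ``n_records`` segments.

    Returns ``(freqs, power)`` in squared-amplitude units (the classifier
    renormalizes, so only ratios matter).  Noise-free this reduces exactly
    to ``sfg_spectrum_analytic``.
    """
    plan = band_plan_from_combs(X, alpha)
    freqs = plan.sum_frequencies()
    T = record_length if record_length is not None else 1.0 / plan.delta_f
    if T <= 0:
        raise ValueError("record_length must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    chi2 = chi2_profile(freqs, model)
    sigma = model.gain_sigma

    if not model.has_noise:
        amp = (np.pi / 2.0) * chi2 * (sigma**2) * np.convolve(X.amplitudes, alpha.amplitudes)
        return freqs, amp**2

    # per-line equivalent of white input noise of sd s per sample:
    # a single DFT bin of a length-T record sees cosine amplitude 2s/sqrt(fs*T)
    xi_line_sd = 2.0 * model.noise_white_sd / np.sqrt(sample_rate * T)
    # colored background: complex bin noise with per-component sd env/sqrt(T)
    # (so the expected bin power matches the env(f)^2 periodogram level)
    bg_sd = model.noise_envelope(freqs) / np.sqrt(T)
    white_sd = model.output_white_sd * np.sqrt(2.0 / (sample_rate * T))

    # per-component (Re/Im) sd of the additive bin noise, expressed in the
    # same (pi/2)-scaled amplitude units as `amp`
    comp_sd = (np.pi / 2.0) * np.sqrt(bg_sd**2 + white_sd**2)
    power = np.zeros(freqs.size)
    for _ in range(n_records):
        a = sigma * X.amplitudes + rng.normal(0.0, xi_line_sd, X.n_lines)
        b = sigma * alpha.amplitudes + rng.normal(0.0, xi_line_sd, alpha.n_lines)
        amp = (np.pi / 2.0) * chi2 * np.convolve(a, b)
        re = amp + rng.normal(0.0, 1.0, freqs.size) * comp_sd
        im = rng.normal(0.0, 1.0, freqs.size) * comp_sd
        power += re**2 + im**2
    return freqs, power / n_records
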