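"""Spectral decoding of SSVEP records.

The decoder side of the BCI: estimate a normalized power spectral density
(NPSD) from an EEG record, read the encoded amplitudes back off the comb
bins, and score reconstructions (SSIM, raw and mutual-information bit
rates).

The record length is chosen as an integer number of comb periods so every
encoded frequency falls on an exact DFT bin of the rectangular-window
periodogram (zero leakage); longer recordings are split into one-period
segments whose periodograms are averaged before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .fdm import FrequencyComb, Waveform

__all__ = ["NPSD", "compute_npsd", "reconstruct_image", "ssim", "bitrate", "mi_bitrate"]


@dataclass(frozen=True)
class NPSD:
    """One-sided power spectral density normalized to unit maximum."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0 or freqs.shape != power.shape:
            raise ValueError("freqs and power must be matching non-empty 1-D arrays")
        if (np.diff(freqs) <= 0).any():
            raise ValueError("freqs must be strictly increasing")
        if (power < 0).any():
            raise ValueError("power must be non-negative")
        top = power.max()
        if top > 0:
            power = power / top
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if not (self.resolution > 0):
            raise ValueError("resolution must be positive")

    def band(self, f_start: float, f_stop: float) -> "NPSD":
        """Restriction to [f_start, f_stop], renormalized to unit maximum."""
        mask = (self.freqs >= f_start - 1e-9) & (self.freqs <= f_stop + 1e-9)
        if not mask.any():
            raise ValueError(f"no NPSD bins inside [{f_start:g}, {f_stop:g}] Hz")
        return NPSD(self.freqs[mask], self.power[mask], self.resolution)

    def argmax_frequency(self) -> float:
        return float(self.freqs[int(np.argmax(self.power))])


def compute_npsd(eeg: Waveform, record_length: float | None = None) -> NPSD:
    """Periodogram-based NPSD of an EEG record.

    ``record_length`` (s) sets the frequency resolution ``1/record_length``;
    when the record is longer, consecutive disjoint segments of that length
    are averaged (Welch with a rectangular window) before normalization.
    The zero-frequency bin is discarded: the spectra of interest start at
    the first positive bin and the DC offset carries no stimulus
    information.
    """
    fs = eeg.sample_rate
    if record_length is None:
        record_length = eeg.duration
    n_rec = int(round(record_length * fs))
    if abs(n_rec - record_length * fs) > 1e-6:
        raise ValueError(
            f"record_length {record_length:g} s is not an integer number of samples "
            f"at {fs:g} Hz"
        )
    if n_rec < 2:
        raise ValueError("record_length too short")
    if n_rec > eeg.n_samples:
        raise ValueError(
            f"record of {eeg.duration:g} s is shorter than requested length {record_length:g} s"
        )
    freqs, psd = welch(
        eeg.samples,
        fs=fs,
        window="boxcar",
        nperseg=n_rec,
        noverlap=0,
        detrend=False,
        scaling="density",
        average="mean",
    )
    return NPSD(freqs=freqs[1:], power=psd[1:], resolution=fs / n_rec)


def _bin_index(npsd: NPSD, f: float) -> int:
    idx = int(round(f / npsd.resolution)) - 1  # DC bin was dropped
    if idx < 0 or idx >= npsd.freqs.size or abs(npsd.freqs[idx] - f) > 1e-6 * npsd.resolution:
        raise ValueError(f"frequency {f:g} Hz does not lie on the NPSD grid")
    return idx


def reconstruct_image(
    npsd: NPSD,
    comb: FrequencyComb,
    shape: tuple[int, int],
    permutation: np.ndarray | None = None,
) -> np.ndarray:
    """Reconstruct a transmitted image from an NPSD.

    Pixel ``m`` is the NPSD power at comb line ``m``, rescaled by the
    maximum over the comb's own bins (gray tone ``x / x_max``), and the
    vector is reshaped row-major.  If a ``permutation`` was used at encoding
    (line ``j`` carried pixel ``permutation[j]``), declaring the same
    permutation here undoes it.
    """
    rows, cols = shape
    if rows * cols != comb.n_lines:
        raise ValueError(f"shape {shape} does not match comb with {comb.n_lines} lines")
    line_values = np.array([npsd.power[_bin_index(npsd, f)] for f in comb.frequencies])
    top = line_values.max()
    if top > 0:
        line_values = line_values / top
    pixels = np.empty(comb.n_lines)
    if permutation is not None:
        permutation = np.asarray(permutation, dtype=int)
        if sorted(permutation.tolist()) != list(range(comb.n_lines)):
            raise ValueError("permutation must be a permutation of the pixel indices")
        pixels[permutation] = line_values
    else:
        pixels = line_values
    return pixels.reshape(rows, cols)


def ssim(image: np.ndarray, reference: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity index, single global window.

    Standard constants K1 = 0.01, K2 = 0.03 with dynamic range L =
    ``data_range``; sample (ddof = 1) variances and covariance.  Returns a
    score in [-1, 1], 1 for identical images.
    """
    a = np.asarray(image, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("images must contain at least 2 pixels")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    cov = ((a - mu_a) * (b - mu_b)).sum() / (a.size - 1)
    return float(
        ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
        / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
    )


def bitrate(n_pixels: int, bit_depth: float, illumination_time: float) -> float:
    """Raw transmission rate: ``n_pixels * bit_depth / illumination_time``.

    E.g. a 196-pixel 1-bit image over a 16.3 s illumination carries
    ~12 bits/s.
    """
    if illumination_time <= 0:
        raise ValueError("illumination_time must be positive")
    if n_pixels <= 0 or bit_depth <= 0:
        raise ValueError("n_pixels and bit_depth must be positive")
    return n_pixels * bit_depth / illumination_time


def mi_bitrate(
    reconstructed: np.ndarray,
    truth: np.ndarray,
    illumination_time: float,
    threshold: float = 0.5,
) -> float:
    """Mutual-information bit rate of a binary image transmission.

    Thresholds the reconstruction and the ground truth at ``threshold``,
    estimates the pixelwise binary channel ``I(B_hat; B)`` from the 2x2
    confusion matrix, and scales by pixels per second.  A simplified
    plug-in estimator: it accounts for wrongly reconstructed pixels (a
    perfect reconstruction yields the truth's pixel entropy, an independent
    one tends to zero) but ignores spatial correlations.
    """
    if illumination_time <= 0:
        raise ValueError("illumination_time must be positive")
    rec = np.asarray(reconstructed, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if rec.shape != tru.shape:
        raise ValueError(f"shape mismatch: {rec.shape} vs {tru.shape}")
    b_rec = (rec.reshape(-1) >= threshold).astype(int)
    b_tru = (tru.reshape(-1) >= threshold).astype(int)
    n = b_rec.size
    joint = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            joint[i, j] = np.sum((b_tru == i) & (b_rec == j)) / n
    p_tru = joint.sum(axis=1)
    p_rec = joint.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log2(joint[i, j] / (p_tru[i] * p_rec[j]))
    return n * mi / illumination_time
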