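"""File I/O: images, WAV waveforms, comb/NPSD CSV, model YAML, reports.

The on-disk formats mirror the signal chain of the physical experiment:
stimuli and EEG records travel as mono WAV (the EEG arrives through an
audio port), combs and spectra as plain CSV, model and experiment
parameters as YAML, and results as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.io import wavfile

from .cortex import CortexModel
from .decode import NPSD
from .fdm import FrequencyComb, Waveform

__all__ = [
    "load_image",
    "save_image",
    "write_wav",
    "read_wav",
    "comb_to_csv",
    "comb_from_csv",
    "npsd_to_csv",
    "eeg_to_csv",
    "eeg_from_csv",
    "model_to_yaml",
    "model_from_yaml",
    "write_report",
]


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image (PGM/PNG/...) mapped linearly to [0, 1]."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=float) / 255.0


def save_image(path, matrix: np.ndarray) -> None:
    """Write a [0, 1] matrix as an 8-bit grayscale image."""
    m = np.clip(np.asarray(matrix, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(m * 255).astype(np.uint8), mode="L").save(path)


def write_wav(path, waveform: Waveform) -> None:
    """Write a waveform as mono 32-bit float WAV (sample rate in the header)."""
    wavfile.write(path, int(round(waveform.sample_rate)), waveform.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        samples = data.astype(float) / np.iinfo(data.dtype).max
    else:
        samples = data.astype(float)
    return Waveform(samples=samples, sample_rate=float(rate))


def comb_to_csv(path, comb: FrequencyComb) -> None:
    """Serialize a comb as (index, frequency_hz, amplitude) rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "frequency_hz", "amplitude"])
        for i, (f, a) in enumerate(zip(comb.frequencies, comb.amplitudes)):
            writer.writerow([i, repr(float(f)), repr(float(a))])


def comb_from_csv(path, label: str = "") -> FrequencyComb:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    freqs, amps = rows[:, 1], rows[:, 2]
    if freqs.size == 1:
        raise ValueError("cannot infer line spacing from a single-line comb CSV")
    spacings = np.diff(freqs)
    if np.ptp(spacings) > 1e-9 * spacings[0]:
        raise ValueError("comb CSV frequencies are not equally spaced")
    return FrequencyComb(f0=float(freqs[0]), delta_f=float(spacings.mean()), amplitudes=amps, label=label)


def npsd_to_csv(path, npsd: NPSD) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency_hz", "power"])
        for f, p in zip(npsd.freqs, npsd.power):
            writer.writerow([repr(float(f)), repr(float(p))])


def eeg_to_csv(path, waveform: Waveform) -> None:
    """Write a time series as (time_s, value) rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(waveform.times, waveform.samples):
            writer.writerow([repr(float(t)), repr(float(v))])


def eeg_from_csv(path) -> Waveform:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t, v = rows[:, 0], rows[:, 1]
    if t.size < 2:
        raise ValueError("EEG CSV must contain at least 2 samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * dt[0]:
        raise ValueError("EEG CSV is not uniformly sampled")
    return Waveform(samples=v, sample_rate=1.0 / float(dt.mean()), t0=float(t[0]))


def model_to_yaml(path, model: CortexModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def model_from_yaml(path) -> CortexModel:
    with open(path) as fh:
        return CortexModel.from_dict(yaml.safe_load(fh) or {})


def write_report(path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
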