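"""Shared audio primitives: waveform container, ramps, level utilities, WAV I/O.

All synthesis in this package works on dimensionless full-scale samples
(|x| <= 1); dB SPL presentation levels are carried as metadata only, since
free-field calibration is outside the scope of a simulation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 44_100


@dataclass
class Waveform:
    """Sampled audio with its sample rate and nominal presentation level.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless full-scale samples, |x| <= 1 after synthesis.
    sample_rate : int
        Sampling rate in Hz.
    nominal_level_db_spl : float
        Intended free-field presentation level (metadata only).
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    nominal_level_db_spl: float = 70.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, gain: float) -> "Waveform":
        return replace(self, samples=self.samples * gain)


def raised_cosine_ramp(samples: np.ndarray, sample_rate: int, ramp_ms: float) -> np.ndarray:
    """Apply raised-cosine on/off ramps of ``ramp_ms`` to both ends (copy)."""
    n_ramp = int(round(ramp_ms * 1e-3 * sample_rate))
    out = np.array(samples, dtype=np.float64)
    if n_ramp == 0:
        return out
    if 2 * n_ramp > out.size:
        raise ValueError("ramps longer than the waveform")
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return out


def linear_ramp(samples: np.ndarray, sample_rate: int, ramp_ms: float) -> np.ndarray:
    """Apply linear rise/fall ramps of ``ramp_ms`` to both ends (copy)."""
    n_ramp = int(round(ramp_ms * 1e-3 * sample_rate))
    out = np.array(samples, dtype=np.float64)
    if n_ramp == 0:
        return out
    if 2 * n_ramp > out.size:
        raise ValueError("ramps longer than the waveform")
    ramp = np.arange(n_ramp) / n_ramp
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return out


def peak_normalize(samples: np.ndarray, peak: float = 0.9) -> np.ndarray:
    """Scale so that max |x| equals ``peak`` (identically for every stimulus,
    so class membership is never decodable from peak amplitude)."""
    m = np.max(np.abs(samples))
    if m == 0:
        return np.array(samples, dtype=np.float64)
    return np.asarray(samples, dtype=np.float64) * (peak / m)


def rms_equalize(waveforms: list[Waveform], target_rms: float = 0.05) -> list[Waveform]:
    """Return copies scaled to a common RMS level."""
    out = []
    for w in waveforms:
        r = w.rms()
        if r == 0:
            raise ValueError("cannot RMS-equalize a silent waveform")
        out.append(w.scaled(target_rms / r))
    return out


def db_to_gain(db: float) -> float:
    return float(10.0 ** (db / 20.0))


def write_wav(path, waveform: Waveform) -> None:
    """Write 16-bit PCM RIFF WAV."""
    x = np.clip(waveform.samples, -1.0, 1.0)
    wavfile.write(path, waveform.sample_rate, np.round(x * 32767.0).astype(np.int16))


def read_wav(path) -> Waveform:
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return Waveform(samples=data, sample_rate=int(sr))
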