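"""Minimal WAV I/O helpers (mono float arrays <-> RIFF PCM files)."""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write a mono float waveform in [-1, 1] as 16-bit PCM."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("expected a mono (1-D) waveform")
    if not np.all(np.isfinite(samples)):
        raise ValueError("waveform contains non-finite samples")
    pcm = np.clip(np.round(samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(sample_rate), pcm)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a RIFF WAV (PCM 16/24/32-bit or float) as mono float in [-1, 1]."""
    sample_rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:  # scipy promotes 24-bit PCM to int32
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return samples, int(sample_rate)
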