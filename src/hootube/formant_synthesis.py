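"""Cascade (Klatt-style) source-filter formant synthesis.

A periodic glottal source — an impulse train at f0, optionally shaped by
a -12 dB/octave spectral-tilt filter — is passed through a cascade of
second-order digital resonators, one per formant.  Each resonator uses
the standard Klatt difference equation with unity gain at DC, so the
cascade shapes the source spectrum into formant peaks at the requested
frequencies and bandwidths.

Defaults mirror the hoo-synthesis conditions: f0 held at 100 Hz
(vowel quality degrades at higher pitch) and a 2 s duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

DEFAULT_BANDWIDTHS = (60.0, 90.0)  # B1, B2; 120 Hz for every higher formant
PADDING_FORMANTS = (2500.0, 3500.0)  # optional upper formants, off by default


def default_bandwidths(n: int) -> tuple[float, ...]:
    """Klatt-style cascade defaults: 60, 90, then 120 Hz."""
    return tuple(
        DEFAULT_BANDWIDTHS[k] if k < len(DEFAULT_BANDWIDTHS) else 120.0
        for k in range(n)
    )


@dataclass(frozen=True)
class SynthesisSpec:
    """Target of one vowel synthesis.

    ``formants`` must be strictly increasing and below Nyquist.
    ``bandwidths`` defaults to (60, 90, 120, ...) Hz.  ``seed`` feeds any
    stochastic component (none in the default deterministic source) so a
    fixed spec always renders bit-identical audio.
    """

    formants: tuple[float, ...]
    bandwidths: tuple[float, ...] | None = None
    f0: float = 100.0
    duration: float = 2.0
    sample_rate: int = 16_000
    seed: int = 0
    spectral_tilt: bool = True
    pad_formants: bool = False

    def __post_init__(self) -> None:
        formants = tuple(float(f) for f in self.formants)
        if len(formants) < 2:
            raise ValueError("at least two formants are required")
        if any(b <= a for a, b in zip(formants, formants[1:])):
            raise ValueError("formants must be strictly increasing")
        if formants[-1] >= self.sample_rate / 2:
            raise ValueError(
                f"formant {formants[-1]} Hz is at or above Nyquist "
                f"({self.sample_rate / 2} Hz)"
            )
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        object.__setattr__(self, "formants", formants)
        if self.bandwidths is None:
            n = len(formants) + (len(PADDING_FORMANTS) if self.pad_formants else 0)
            object.__setattr__(self, "bandwidths", default_bandwidths(n))
        else:
            bw = tuple(float(b) for b in self.bandwidths)
            n_needed = len(formants) + (len(PADDING_FORMANTS) if self.pad_formants else 0)
            if len(bw) != n_needed:
                raise ValueError("one bandwidth per formant is required")
            if any(b <= 0 for b in bw):
                raise ValueError("bandwidths must be positive")
            object.__setattr__(self, "bandwidths", bw)

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sample_rate)


def _impulse_train(n_samples: int, f0: float, sample_rate: int) -> np.ndarray:
    """Unit impulses at integer sample indices nearest each glottal pulse."""
    source = np.zeros(n_samples)
    period = sample_rate / f0
    idx = np.round(np.arange(0, n_samples, period)).astype(int)
    source[idx[idx < n_samples]] = 1.0
    return source


def resonator_coefficients(
    frequency: float, bandwidth: float, sample_rate: int
) -> tuple[np.ndarray, np.ndarray]:
    """Klatt second-order resonator (b, a) with unity gain at DC."""
    t = 1.0 / sample_rate
    c = -np.exp(-2.0 * np.pi * bandwidth * t)
    b_coef = 2.0 * np.exp(-np.pi * bandwidth * t) * np.cos(2.0 * np.pi * frequency * t)
    a_gain = 1.0 - b_coef - c
    return np.array([a_gain]), np.array([1.0, -b_coef, -c])


def synthesize_vowel(spec: SynthesisSpec) -> np.ndarray:
    """Render a formant dispersion as a mono waveform, peak |x| = 0.9."""
    x = _impulse_train(spec.n_samples, spec.f0, spec.sample_rate)
    if spec.spectral_tilt:
        # Two one-pole lowpasses give approximately -12 dB/octave above
        # the corner, emulating glottal-flow spectral slope.
        a_lp = np.exp(-2.0 * np.pi * 100.0 / spec.sample_rate)
        for _ in range(2):
            x = lfilter([1.0 - a_lp], [1.0, -a_lp], x)
    formants = spec.formants + (PADDING_FORMANTS if spec.pad_formants else ())
    for f, bw in zip(formants, spec.bandwidths):
        b, a = resonator_coefficients(f, bw, spec.sample_rate)
        x = lfilter(b, a, x)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return x
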