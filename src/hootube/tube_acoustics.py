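"""Transmission-line acoustics of concatenated cylindrical tubes.

The vocal tract is represented as an area function discretised into
cylindrical segments, glottis first, lips last.  Each segment is a
two-port acoustic transmission line; cascading the per-segment chain
(ABCD) matrices yields the volume-velocity transfer function from an
ideal glottal flow source to the lip opening.  Resonance peaks of the
magnitude response are the formants.

The glottis is treated as an ideal volume-velocity source (infinite
source impedance, i.e. a rigid termination seen from inside the tract);
the lips default to a zero-pressure open end, with an optional
piston-in-baffle radiation inertance.  A small distributed loss factor
regularises the otherwise lossless resonance peaks to finite height
without moving them: the complex propagation constant is
``gamma = k * (damping + 1j)`` so the loss is per unit length and the
transfer function is exactly invariant under subdividing a segment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks


class NumericalDegeneracyError(ArithmeticError):
    """Raised when the transfer function evaluates to a non-finite value."""

    def __init__(self, frequency_hz: float):
        self.frequency_hz = frequency_hz
        super().__init__(
            f"non-finite transfer-function value at {frequency_hz:.3f} Hz"
        )


class PeakCountError(ValueError):
    """Raised when fewer resonance peaks qualify than were requested."""

    def __init__(self, found: int, requested: int):
        self.found = found
        self.requested = requested
        super().__init__(
            f"{found} qualifying peak(s) found, {requested} requested"
        )


@dataclass(frozen=True)
class TubeSegment:
    """One cylindrical element of the area function.

    Parameters
    ----------
    length : float
        Segment length in centimetres, > 0.
    area : float
        Cross-sectional area in square centimetres, > 0.
    """

    length: float
    area: float

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ValueError(f"segment length must be > 0, got {self.length}")
        if not (self.area > 0):
            raise ValueError(f"segment area must be > 0, got {self.area}")


@dataclass(frozen=True)
class TubeSequence:
    """Ordered area function: index 0 at the glottis, last at the lips."""

    segments: tuple[TubeSegment, ...]

    def __init__(self, segments: Iterable[TubeSegment]):
        segments = tuple(segments)
        if not segments:
            raise ValueError("a tube sequence needs at least one segment")
        object.__setattr__(self, "segments", segments)

    @property
    def total_length(self) -> float:
        """Total glottis-to-lips length in centimetres."""
        return float(sum(s.length for s in self.segments))

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class AcousticConstants:
    """Physical constants of the medium and the loss/termination model.

    ``speed_of_sound`` defaults to 35,000 cm/s (approximately 20 degrees C,
    rounded); the textbook 20 degrees C value 34,300 cm/s can be selected via
    config.  ``damping_fraction`` is the dimensionless distributed loss
    factor (imaginary part of the propagation constant relative to the
    real wavenumber).  ``radiation_load`` switches the lip termination
    from a zero-pressure open end to a first-order piston-in-baffle
    inertance.
    """

    speed_of_sound: float = 35_000.0
    air_density: float = 0.00114
    damping_fraction: float = 0.005
    radiation_load: bool = False

    def __post_init__(self) -> None:
        if not (self.speed_of_sound > 0):
            raise ValueError("speed_of_sound must be > 0")
        if not (0.0 <= self.damping_fraction <= 0.1):
            raise ValueError("damping_fraction must lie in [0, 0.1]")
        if not (self.air_density > 0):
            raise ValueError("air_density must be > 0")


@dataclass(frozen=True)
class TransferFunction:
    """Magnitude response of a tube sequence on a strictly increasing grid."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequency and magnitude arrays must be 1-D and equal length")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(m)):
            raise ValueError("magnitude array contains non-finite values")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude_db", m)

    def to_csv(self, path) -> None:
        """Write a two-column CSV (frequency_hz, magnitude_db) with header."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frequency_hz", "magnitude_db"])
            for f, m in zip(self.frequencies, self.magnitude_db):
                writer.writerow([f"{f:.6g}", f"{m:.6f}"])


@dataclass(frozen=True)
class FormantEstimate:
    """Formant frequencies in Hz with their provenance.

    ``provenance`` is one of ``simulated`` (tube model), ``synthesized``
    (known synthesis target) or ``audio`` (estimated from a waveform).
    ``f2`` may be None only for a partial estimate, which must carry a
    flag explaining the shortfall.
    """

    f1: float
    f2: float | None
    higher: tuple[float, ...] = ()
    provenance: str = "simulated"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        freqs = self.all_formants
        if any(f <= 0 for f in freqs):
            raise ValueError("formants must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError(f"formants must be strictly increasing, got {freqs}")
        if self.f2 is None and not self.flags:
            raise ValueError("a partial estimate (no F2) must carry a flag")
        if self.provenance not in ("simulated", "synthesized", "audio"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def all_formants(self) -> tuple[float, ...]:
        out = (self.f1,) if self.f2 is None else (self.f1, self.f2)
        return out + tuple(self.higher)


def uniform_tube_resonances(length: float, speed_of_sound: float, n: int) -> list[float]:
    """Quarter-wavelength resonances of a closed-open uniform tube.

    Returns ``[(2k - 1) * c / (4 L) for k = 1..n]`` in Hz — the analytic
    oracle for a one-segment tract with a rigid glottis end and an open
    lip end.
    """
    if not (length > 0):
        raise ValueError("length must be > 0")
    if not (speed_of_sound > 0):
        raise ValueError("speed_of_sound must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return [(2 * k - 1) * speed_of_sound / (4.0 * length) for k in range(1, n + 1)]


def _chain_matrix_elements(
    tubes: TubeSequence,
    omega: np.ndarray,
    constants: AcousticConstants,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cascade the per-segment chain matrices over a frequency grid.

    Returns the four elements (A, B, C, D) of the product matrix that maps
    (pressure, volume velocity) at the lips to the same pair at the glottis.
    Matrices are multiplied glottis-to-lips so the product M satisfies
    ``[p_g, U_g]^T = M [p_lip, U_lip]^T``.
    """
    c = constants.speed_of_sound
    rho = constants.air_density
    # gamma = alpha + j k with alpha = damping * k: loss per unit length.
    k = omega / c
    gamma = k * (constants.damping_fraction + 1j)

    A = np.ones_like(omega, dtype=complex)
    B = np.zeros_like(A)
    C = np.zeros_like(A)
    D = np.ones_like(A)
    for seg in tubes.segments:
        zc = rho * c / seg.area
        gl = gamma * seg.length
        ch, sh = np.cosh(gl), np.sinh(gl)
        a, b = ch, zc * sh
        cc, d = sh / zc, ch
        A, B, C, D = (A * a + B * cc, A * b + B * d,
                      C * a + D * cc, C * b + D * d)
    return A, B, C, D


def _radiation_impedance(
    area: float, omega: np.ndarray, constants: AcousticConstants
) -> np.ndarray:
    """First-order piston-in-an-infinite-baffle load: inertance only.

    Z_rad = j * omega * 8 * rho / (3 * pi^2 * a) with piston radius
    a = sqrt(area / pi).
    """
    a = np.sqrt(area / np.pi)
    inertance = 8.0 * constants.air_density / (3.0 * np.pi**2 * a)
    return 1j * omega * inertance


def transfer_function(
    tubes: TubeSequence,
    constants: AcousticConstants = AcousticConstants(),
    f_min: float = 50.0,
    f_max: float = 5000.0,
    f_step: float = 1.0,
) -> TransferFunction:
    """Volume-velocity transfer magnitude (lips over glottis) in dB.

    The glottal source is an ideal volume-velocity source; with lip
    pressure termination ``p_lip = Z_rad * U_lip`` the transfer ratio is
    ``U_lip / U_g = 1 / (C * Z_rad + D)`` in terms of the cascade chain
    matrix.  The returned magnitude is normalised to 0 dB at ``f_min``.
    """
    if f_min < 1.0:
        raise ValueError("f_min must be >= 1 Hz")
    if f_max <= f_min:
        raise ValueError("f_max must exceed f_min")
    if f_step <= 0:
        raise ValueError("f_step must be > 0")

    freqs = np.arange(f_min, f_max + 0.5 * f_step, f_step)
    omega = 2.0 * np.pi * freqs
    _, _, C, D = _chain_matrix_elements(tubes, omega, constants)

    if constants.radiation_load:
        z_rad = _radiation_impedance(tubes.segments[-1].area, omega, constants)
        denom = C * z_rad + D
    else:
        denom = D

    with np.errstate(divide="ignore"):
        mag = np.abs(1.0 / denom)
    bad = ~np.isfinite(mag)
    if np.any(bad):
        raise NumericalDegeneracyError(float(freqs[np.argmax(bad)]))
    mag_db = 20.0 * np.log10(mag)
    mag_db = mag_db - mag_db[0]
    return TransferFunction(frequencies=freqs, magnitude_db=mag_db)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through the three points around i."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + delta * step)


def find_formants(
    tf: TransferFunction,
    n_formants: int = 2,
    min_prominence_db: float = 3.0,
    provenance: str = "simulated",
) -> FormantEstimate:
    """Lowest ``n_formants`` prominent peaks of a transfer function.

    Peaks must exceed ``min_prominence_db`` of prominence; each is refined
    by parabolic interpolation over the three surrounding grid points.
    """
    if n_formants < 1:
        raise ValueError("n_formants must be >= 1")
    idx, _ = find_peaks(tf.magnitude_db, prominence=min_prominence_db)
    if len(idx) < n_formants:
        raise PeakCountError(found=len(idx), requested=n_formants)
    picked = idx[:n_formants]
    freqs = [_parabolic_refine(tf.frequencies, tf.magnitude_db, i) for i in picked]
    if n_formants == 1:
        return FormantEstimate(
            f1=freqs[0], f2=None, provenance=provenance,
            flags=("single_formant_requested",),
        )
    return FormantEstimate(
        f1=freqs[0], f2=freqs[1], higher=tuple(freqs[2:]), provenance=provenance
    )
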