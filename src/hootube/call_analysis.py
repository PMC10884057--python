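"""Formant and pitch estimation for vocalization segments.

Linear predictive coding is notoriously unreliable for calls whose
fundamental frequency approaches the first formant (it locks onto
harmonic partials instead of resonances), so the default estimator here
works on the harmonic structure directly: the long-term average spectrum
is sampled at multiples of the estimated f0, an envelope is drawn
through those harmonic amplitudes, and formants are read off its most
prominent maxima.  When no pitch can be found, a cepstrally smoothed
envelope is used instead.  No code path fits LPC poles.

Because harmonics sample the envelope only every f0 Hz, formant accuracy
is intrinsically limited by the harmonic spacing — fine at f0 = 100 Hz,
coarser at the f0 ~ 300 Hz typical of hoos, where f0 often overlaps F1
(such estimates carry an explicit ``f0_coincident_f1`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, get_window, welch

from hootube.tube_acoustics import FormantEstimate

MIN_SEGMENT_S = 0.05


class NoPitchError(ValueError):
    """Raised when a segment has no detectable periodicity."""


@dataclass(frozen=True)
class CallSegment:
    """A mono snippet of one call."""

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    airflow: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if len(samples) < MIN_SEGMENT_S * self.sample_rate:
            raise ValueError(f"segment shorter than {MIN_SEGMENT_S} s")
        if self.airflow not in ("egressive", "ingressive", "unknown"):
            raise ValueError(f"unknown airflow {self.airflow!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class SpectralEnvelope:
    """Smoothed spectral envelope with the f0 it was sampled at."""

    frequencies: np.ndarray
    level_db: np.ndarray
    f0_estimate: float | None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.level_db, dtype=float)
        if f.shape != m.shape:
            raise ValueError("frequency and level arrays must have equal length")
        if self.f0_estimate is not None and self.f0_estimate <= 0:
            raise ValueError("f0_estimate must be positive when present")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "level_db", m)


def estimate_f0(
    segment: CallSegment,
    f0_min: float = 60.0,
    f0_max: float = 600.0,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.5,
) -> float:
    """Median framewise autocorrelation pitch, in Hz.

    Frames whose normalised autocorrelation peak falls below
    ``voicing_threshold`` are treated as unvoiced; if fewer than a
    quarter of frames (or two frames) are voiced, the segment is deemed
    aperiodic and :class:`NoPitchError` is raised.
    """
    sr = segment.sample_rate
    n_frame = int(round(frame_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    lag_min = int(np.floor(sr / f0_max))
    lag_max = int(np.ceil(sr / f0_min))
    if lag_max >= n_frame:
        raise ValueError("frame too short for the requested f0_min")

    x = segment.samples
    window = get_window("hann", n_frame)
    f0s = []
    n_frames = 0
    for start in range(0, len(x) - n_frame + 1, hop):
        frame = x[start : start + n_frame]
        frame = (frame - frame.mean()) * window
        n_frames += 1
        r0 = float(np.dot(frame, frame))
        if r0 <= 0:
            continue
        # autocorrelation via FFT, normalised by the zero-lag energy
        n_fft = int(2 ** np.ceil(np.log2(2 * n_frame)))
        spectrum = np.fft.rfft(frame, n_fft)
        ac = np.fft.irfft(spectrum * np.conj(spectrum))[: lag_max + 2] / r0
        search = ac[lag_min : lag_max + 1]
        i = int(np.argmax(search)) + lag_min
        if ac[i] < voicing_threshold:
            continue
        # parabolic lag refinement
        if 0 < i < len(ac) - 1:
            denom = ac[i - 1] - 2 * ac[i] + ac[i + 1]
            lag = i + (0.5 * (ac[i - 1] - ac[i + 1]) / denom if denom != 0 else 0.0)
        else:
            lag = float(i)
        f0s.append(sr / lag)
    if n_frames == 0:
        raise ValueError("segment yielded no analysis frames")
    if len(f0s) < max(2, n_frames // 4):
        raise NoPitchError(
            f"only {len(f0s)}/{n_frames} frames voiced; segment appears aperiodic"
        )
    return float(np.median(f0s))


def long_term_spectrum(
    segment: CallSegment, frame_s: float = 0.025, hop_s: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Welch long-term average spectrum in dB (Hann frames, averaged)."""
    sr = segment.sample_rate
    n_frame = min(int(round(frame_s * sr)), len(segment.samples))
    n_overlap = n_frame - min(int(round(hop_s * sr)), n_frame - 1)
    freqs, psd = welch(
        segment.samples, fs=sr, window="hann", nperseg=n_frame,
        noverlap=n_overlap, nfft=max(4096, n_frame), detrend=False,
    )
    level_db = 10.0 * np.log10(psd + 1e-30)
    return freqs, level_db


def _harmonic_levels(
    freqs: np.ndarray, level_db: np.ndarray, f0: float, f_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectrum level at each harmonic of f0 (local max within +/- 0.25 f0).

    Also returns the local noise floor, measured as the median level in
    the inter-harmonic band around each harmonic, so callers can reject
    harmonics buried in broadband noise.  The floor is only meaningful
    when the harmonic spacing comfortably exceeds the spectral
    resolution (roughly f0 > 4 / frame length); callers gate on that.
    """
    harmonics = []
    levels = []
    floors = []
    k = 1
    while k * f0 <= f_max:
        lo = np.searchsorted(freqs, k * f0 - 0.25 * f0)
        hi = np.searchsorted(freqs, k * f0 + 0.25 * f0)
        gap_lo = np.searchsorted(freqs, k * f0 + 0.3 * f0)
        gap_hi = np.searchsorted(freqs, k * f0 + 0.7 * f0)
        if hi > lo:
            harmonics.append(k * f0)
            levels.append(float(np.max(level_db[lo:hi])))
            if gap_hi > gap_lo:
                floors.append(float(np.median(level_db[gap_lo:gap_hi])))
            else:
                floors.append(-np.inf)
        k += 1
    return np.asarray(harmonics), np.asarray(levels), np.asarray(floors)


def _cepstral_envelope(
    freqs: np.ndarray, level_db: np.ndarray, smoothing_hz: float = 300.0
) -> np.ndarray:
    """Low-quefrency liftered version of a log spectrum."""
    n = len(level_db)
    # mirror to make the log-spectrum even before transforming, so the
    # "cepstrum" is real and liftering is a plain truncation
    sym = np.concatenate([level_db, level_db[-2:0:-1]])
    cep = np.fft.rfft(sym)
    cutoff = max(1, int(round((freqs[-1] - freqs[0]) / smoothing_hz)))
    cep[cutoff + 1 :] = 0.0
    return np.fft.irfft(cep, len(sym))[:n]


def spectral_envelope(
    segment: CallSegment, f_max: float = 4000.0
) -> SpectralEnvelope:
    """Envelope through harmonic amplitudes (or cepstral fallback)."""
    freqs, level_db = long_term_spectrum(segment)
    f_max = min(f_max, 0.95 * segment.sample_rate / 2)
    try:
        f0 = estimate_f0(segment)
    except NoPitchError:
        keep = freqs <= f_max
        env = _cepstral_envelope(freqs, level_db)
        return SpectralEnvelope(freqs[keep], env[keep], None)
    hf, hl, floor = _harmonic_levels(freqs, level_db, f0, f_max)
    if f0 >= 4.0 / 0.025:  # floor meaningless below this (resolution limit)
        usable = hl >= floor + NOISE_MARGIN_DB
        if usable.sum() >= 2:
            hf, hl = hf[usable], hl[usable]
    if len(hf) < 2:
        keep = freqs <= f_max
        return SpectralEnvelope(freqs[keep], level_db[keep], f0)
    interp = PchipInterpolator(hf, hl)
    grid = np.arange(hf[0], hf[-1], 1.0)
    return SpectralEnvelope(grid, interp(grid), f0)


SOURCE_TILT_CORNER_HZ = 100.0  # assumed glottal-flow lowpass corner
ASSUMED_BANDWIDTHS = (60.0, 90.0)  # resonator bandwidths for model matching
HARMONIC_FLOOR_DB = 65.0  # harmonics further below the loudest are ignored
NOISE_MARGIN_DB = 6.0  # a harmonic must clear the local noise floor by this
MODEL_FIT_F_MAX = 2500.0  # harmonics above this do not constrain the fit


def _resonator_db(frequency: float, bandwidth: float, omega: np.ndarray) -> np.ndarray:
    """Magnitude (dB) of a unity-DC-gain second-order resonator."""
    c = -np.exp(-2.0 * np.pi * bandwidth / _MODEL_SR)
    b = 2.0 * np.exp(-np.pi * bandwidth / _MODEL_SR) * np.cos(
        2.0 * np.pi * frequency / _MODEL_SR
    )
    gain = 1.0 - b - c
    z = np.exp(-1j * omega)
    return 20.0 * np.log10(np.abs(gain / (1.0 - b * z - c * z * z)) + 1e-12)


_MODEL_SR = 16_000.0  # reference rate for the analysis model (scale-free in Hz)


def _source_tilt_db(omega: np.ndarray) -> np.ndarray:
    """Assumed source slope: two one-pole lowpasses (~ -12 dB/octave)."""
    a = np.exp(-2.0 * np.pi * SOURCE_TILT_CORNER_HZ / _MODEL_SR)
    z = np.exp(-1j * omega)
    return 40.0 * np.log10(np.abs((1.0 - a) / (1.0 - a * z)) + 1e-12)


def _two_formant_misfit(
    f1: float, f2: float, hf: np.ndarray, hl: np.ndarray,
    bandwidths: tuple[float, float],
) -> float:
    """Offset-free squared misfit of the source+resonator model in dB."""
    omega = 2.0 * np.pi * hf / _MODEL_SR
    model = (
        _source_tilt_db(omega)
        + _resonator_db(f1, bandwidths[0], omega)
        + _resonator_db(f2, bandwidths[1], omega)
    )
    resid = hl - model
    resid = resid - resid.mean()
    return float(np.dot(resid, resid))


def _scan_minima(
    grid: np.ndarray, values: np.ndarray, n_best: int = 3
) -> list[float]:
    """Locations of the lowest local minima of a sampled 1-D function."""
    minima = [
        i for i in range(len(values))
        if (i == 0 or values[i] <= values[i - 1])
        and (i == len(values) - 1 or values[i] <= values[i + 1])
    ]
    minima.sort(key=lambda i: values[i])
    return [float(grid[i]) for i in minima[:n_best]]


def _refine_1d(fun, x0: float, lo: float, hi: float, step: float = 4.0) -> float:
    """Nested grid descent of ``fun`` around x0 within [lo, hi]."""
    x = float(np.clip(x0, lo, hi))
    while step >= 0.25:
        grid = np.clip(np.arange(x - 4 * step, x + 4 * step + 1e-9, step), lo, hi)
        x = float(grid[np.argmin([fun(v) for v in grid])])
        step /= 4.0
    return x


def _fit_two_formants(
    hf: np.ndarray, hl: np.ndarray, f0: float,
    f1_init: float | None, f2_init: float | None,
    bandwidths: tuple[float, float] = ASSUMED_BANDWIDTHS,
) -> tuple[float, float]:
    """Best (F1, F2) matching the harmonic amplitudes.

    An automated stand-in for corroborating visual estimates with an
    additive synthesizer matched for f0: the assumed source-tilt plus
    two-resonator spectrum is fitted to the observed harmonic levels
    (free overall gain) by multi-start coordinate descent, so formants
    lying between harmonics are still recovered.
    """
    # F2 may sit somewhat above the last harmonic that clears the noise
    lo1, hi2 = 60.0, float(hf[-1]) + 0.7 * f0
    min_gap = 150.0

    def misfit(f1, f2):
        return _two_formant_misfit(f1, f2, hf, hl, bandwidths)

    if f2_init is None or f1_init is None:
        # coarse joint scan when the envelope supplied no usable start
        best = (np.inf, 300.0, 900.0)
        for f1 in np.arange(100.0, 1000.0, 25.0):
            for f2 in np.arange(max(f1 + min_gap, 400.0), min(hi2, 2300.0), 25.0):
                s = misfit(f1, f2)
                if s < best[0]:
                    best = (s, f1, f2)
        f1_init, f2_init = best[1], best[2]

    lo2 = max(400.0, lo1 + min_gap)

    def scan_starts(fun, lo, hi, extra):
        grid = np.arange(lo, hi, 2.0)
        starts = _scan_minima(grid, np.array([fun(v) for v in grid]), n_best=4)
        starts.append(float(np.clip(extra, lo, hi - 1e-9)))
        return starts

    # multi-start: local minima of the full F1 scan at the initial F2,
    # each paired with the local minima of the full F2 scan at that F1
    best = (np.inf, f1_init, f2_init)
    for s1 in scan_starts(lambda v: misfit(v, f2_init), lo1, f2_init - min_gap, f1_init):
        for s2 in scan_starts(lambda v: misfit(s1, v), max(lo2, s1 + min_gap), hi2, f2_init)[:2]:
            f1, f2 = s1, s2
            for _ in range(2):
                f1 = _refine_1d(lambda v: misfit(v, f2), f1, lo1, f2 - min_gap)
                f2 = _refine_1d(lambda v: misfit(f1, v), f2, f1 + min_gap, hi2)
            score = misfit(f1, f2)
            if score < best[0]:
                best = (score, f1, f2)
    return best[1], best[2]


def estimate_formants(
    segment: CallSegment,
    n_formants: int = 2,
    f_max: float = 4000.0,
    min_prominence_db: float = 2.0,
    refine: bool = True,
) -> FormantEstimate:
    """Formants from harmonic-envelope peaks (never LPC).

    The long-term spectrum is sampled at multiples of the estimated f0;
    local maxima of the tilt-corrected harmonic-amplitude sequence,
    refined by parabolic interpolation, are the formant candidates, and
    the ``n_formants`` most prominent are returned in ascending
    frequency.  For the default two-formant case the candidates are then
    polished by matching a source-tilt + two-resonator spectrum to the
    raw harmonic levels (``refine=True``), which resolves formants lying
    between harmonics — the binding limit when f0 is high.  A first
    formant within a third of a harmonic spacing of f0 is flagged
    ``f0_coincident_f1`` (common in hoos, where f0 overlaps F1).  Fewer
    qualifying peaks than requested yields a partial estimate flagged
    ``partial``; aperiodic input falls back to peaks of a cepstrally
    smoothed envelope, flagged ``cepstral_envelope``.
    """
    if n_formants < 1:
        raise ValueError("n_formants must be >= 1")
    freqs, level_db = long_term_spectrum(segment)
    f_max = min(f_max, 0.95 * segment.sample_rate / 2)
    flags: list[str] = []
    try:
        f0 = estimate_f0(segment)
    except NoPitchError:
        flags.append("cepstral_envelope")
        keep = freqs <= f_max
        env = _cepstral_envelope(freqs[keep], level_db[keep])
        idx, props = find_peaks(env, prominence=min_prominence_db)
        order = np.argsort(props["prominences"])[::-1][:n_formants]
        cand = np.sort(freqs[keep][idx[np.sort(order)]])
        return _package(cand.tolist(), n_formants, flags)

    flags.append("harmonic_envelope")
    hf, hl, floor = _harmonic_levels(freqs, level_db, f0, f_max)
    if len(hf) == 0:
        raise ValueError("no harmonics below f_max")
    if f0 < 4.0 / 0.025:  # harmonic gaps unresolved at this frame length
        floor = np.full_like(floor, -np.inf)
    # adaptive noise margin: prefer a 6 dB clearance over the local noise
    # floor, relaxing to 2 dB before giving up on a third harmonic (the
    # minimum needed to constrain a two-formant fit)
    usable = np.zeros_like(hl, dtype=bool)
    for margin in (NOISE_MARGIN_DB, 4.0, 2.0):
        usable = (hl >= hl.max() - HARMONIC_FLOOR_DB) & (hl >= floor + margin)
        if int(usable.sum()) >= 3:
            break
    hf, hl = hf[usable], hl[usable]
    tilt_corrected = hl + 12.0 * np.log2(hf / hf[0])

    # sentinel below the first harmonic so an envelope maximum sitting on
    # h1 (f0 overlapping F1) still registers as a peak
    levels = np.concatenate([[tilt_corrected.min() - 40.0], tilt_corrected])
    idx, props = find_peaks(levels, prominence=min_prominence_db)
    order = np.argsort(props["prominences"])[::-1][:n_formants]
    cand = []
    for i in np.sort(idx[np.sort(order)]):
        k = i - 1  # index into hf/hl (sentinel offset)
        if 0 < k < len(hf) - 1:
            y0, y1, y2 = tilt_corrected[k - 1 : k + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            cand.append(float(hf[k] + delta * f0))
        else:
            cand.append(float(hf[k]))
    cand.sort()
    if not cand:
        # degenerate envelope (e.g. a single usable harmonic): report the
        # strongest harmonic rather than nothing
        cand = [float(hf[int(np.argmax(tilt_corrected))])]

    fit_mask = hf <= MODEL_FIT_F_MAX
    if refine and n_formants == 2 and int(fit_mask.sum()) >= 3:
        f1_init = cand[0] if cand else None
        f2_init = cand[1] if len(cand) > 1 else None
        f1, f2 = _fit_two_formants(hf[fit_mask], hl[fit_mask], f0, f1_init, f2_init)
        flags.append("model_refined")
        cand = [f1, f2]
    if cand and abs(cand[0] - f0) <= f0 / 3.0:
        flags.append("f0_coincident_f1")
    return _package(cand, n_formants, flags)


def _package(cand: list[float], n_formants: int, flags: list[str]) -> FormantEstimate:
    if len(cand) < n_formants:
        flags.append("partial")
    if not cand:
        raise ValueError("no spectral peaks found")
    f1 = cand[0]
    f2 = cand[1] if len(cand) > 1 else None
    higher = tuple(cand[2:])
    return FormantEstimate(
        f1=f1, f2=f2, higher=higher, provenance="audio", flags=tuple(flags)
    )
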