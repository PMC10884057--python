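# Methods

## The question the package addresses

Chimpanzee *hoo* calls sound strikingly like the human close back
rounded vowel /u/, yet chimpanzee oral anatomy (simian shelf, short
pharynx, flat tongue) almost certainly precludes the lingual gesture
humans use for /u/. `hootube` asks the purely acoustic question: can a
tract that is essentially a uniform tube — extended by fleshy lip
protrusion, narrowed at the lip opening, and preceded by a crude in-line
air-sac cavity — produce an F1–F2 dispersion in the /u/ / hoo region?
The package simulates such tracts, sweeps their free parameters,
compares the predicted dispersions with published reference formants,
synthesizes the winning dispersions as audible vowels, and closes the
loop with a formant estimator and a synthetic call corpus so the whole
chain is testable without any field recordings.

## Tube acoustics (`tube_acoustics`)

The vocal tract is an area function discretized into cylindrical
segments, glottis first.  Each segment of length `l` and area `A` is a
lossy transmission line with characteristic impedance `Zc = rho*c/A` and
chain (ABCD) matrix

    [ cosh(g l)        Zc sinh(g l) ]
    [ sinh(g l)/Zc     cosh(g l)    ]

with propagation constant `g = k*(d + 1j)`, `k = omega/c`.  Cascading
the matrices glottis-to-lips and terminating with an ideal
volume-velocity source at the glottis and zero pressure at the lips
gives the volume-velocity transfer ratio `U_lip/U_glottis = 1/D` (or
`1/(C*Z_rad + D)` when the optional piston-in-baffle radiation
inertance is enabled).  Formants are the prominent peaks of
`20*log10 |H|`, refined by parabolic interpolation.

Numerical choices:

- **Speed of sound** defaults to 35 000 cm/s (a rounded room-temperature
  value); the textbook 20 °C figure of 34 300 cm/s is selectable in
  config.  Both give the quarter-wave series `F_n = (2n-1) c / 4L` for a
  uniform closed–open tube, the analytic oracle used throughout the
  tests.
- **Loss model.** Real tract losses (yielding walls, viscosity, heat
  conduction) mainly broaden resonances; peak *frequencies* are
  insensitive to small damping.  We therefore use a single dimensionless
  distributed loss factor `d` (default 0.005) rather than a physical
  wall circuit.  Loss per unit length (as opposed to a lumped per-segment
  resistance) makes the transfer function exactly invariant under
  subdividing a segment, which is also the property the tests assert.
  With `d = 0.005` peak positions shift by O(d²) ≈ 0.01 Hz.
- **Terminations.** An ideal flow source and an open (zero-pressure)
  lip end keep the lossless model identical to the textbook closed–open
  resonator, so every prediction can be checked analytically.  The
  radiation load is off by default for the same reason.
- **Grid.** 50–5000 Hz at 1 Hz steps; peak prominence threshold 3 dB
  (rejects ripple without suppressing genuine resonances); parabolic
  refinement gives sub-Hz resolution.  Invariance tests use a 0.5 Hz
  tolerance on peak frequencies.

Out of scope by design: time-domain (Kelly–Lochbaum) simulation,
side-branch air-sac topology, soft-wall shunt elements, nonlinear
source–tract interaction.

## The five-segment chimpanzee simulacrum (`chimp_tract`)

Glottis to lips: optional narrow constriction (0.125 cm ×
0.125 cm²) → air-sac cavity (length 1–2 cm, area 1–30 cm²) → main tract
(18 cm × 1 cm², the published adult-male VTL estimate rounded) → lip
protrusion (0.2–3.8 cm, bore = tract bore) → lip opening (0.2 cm long,
area 0.2–1 cm²).  A sac area of 1 cm² equals the tract bore, i.e. "no
sac".  Interpretations that the source description leaves open, each
made explicit and configurable:

- The narrow constriction "of 0.125 cm" is read as both length and
  area 0.125 (cm / cm²), and can be disabled entirely.
- The protrusion segment inherits the 1 cm² tract bore (the lip-opening
  area is a separate parameter).
- Lip-protrusion step is 0.2 cm (19 values); a finer 0.1 cm reading
  exists in the literature but the coarser published table is taken as
  authoritative.

The default grid is 19 × 3 × 30 × 5 = 8550 configurations.  The sweep
is purely deterministic; rows are emitted with protrusion varying
slowest and lip area fastest, so output CSVs are diffable.  A
configuration whose peak-picking fails is kept as a flagged row rather
than aborting the sweep.  On one CPU the full sweep takes well under a
minute.

Because the original wall-loss constants are unpublished, the exact
published point clouds are not bit-reproducible; the acceptance surface
is peak-frequency-level behaviour: F1 non-increasing in protrusion
length, F2 non-increasing in sac area (both hold in *every* grid slice),
and a nonzero fraction of configurations inside the /u/ / hoo region.

## Vowel-space comparison (`vowel_space`)

Reference formants (means ± SD, Hz): human /u/ for adult males
(307.36/50.01, 875.97/155.46), adult females (377.86/46.76,
960.57/171.46) and children (432.37/87.48, 1193.33/274.61) from the
classic Peterson–Barney survey, and chimpanzee hoos.  Two slightly
different published chimpanzee means exist (374.44/67.02 vs
358.75/56.93 for F1, same F2 896.25/133.04); both are preserved
verbatim as separate fixtures — neither is "corrected" — and the
358.75-variant is the default target.

"Overlap" is operationalized as both formants within one SD of the
reference means (the source figures are visual only, so some numeric
rule had to be chosen).  "Closest fit" defaults to Euclidean distance
in Hz; a per-SD-normalized metric is provided because the two axes have
very unequal spread, and with it the best-fitting configuration lands
within one SD on both axes.  Ties break toward the shorter tract, then
enumeration order.

## Formant synthesis (`formant_synthesis`)

Classic cascade (Klatt-style) source-filter synthesis: an impulse train
at f0 (default 100 Hz, where vowel quality is clearest), shaped by two
one-pole lowpasses approximating a −12 dB/octave glottal slope, passed
through one second-order unity-DC-gain resonator per formant.
Bandwidths default to 60, 90, then 120 Hz — typical cascade values, as
none are published for this use.  Output is 2 s at 16 kHz by default,
peak-normalized to 0.9, and bit-deterministic for a fixed spec.
Optional padding formants at 2500/3500 Hz are off by default.  The full
Klatt-80 parameter set (nasality, aspiration, source switching) is out
of scope.

## Formant estimation (`call_analysis`)

LPC is deliberately not used anywhere: with the high f0 of primate
calls it notoriously locks onto harmonics instead of resonances.  The
default estimator instead works from the harmonic structure:

1. f0 by framewise normalized autocorrelation (40 ms Hann frames,
   10 ms hop, 60–600 Hz search, 0.5 voicing threshold, median over
   voiced frames).  Aperiodic input raises a no-pitch signal.
2. Long-term average spectrum (Welch, 25 ms Hann, 10 ms hop).
3. Harmonic amplitudes at multiples of f0 (local maximum within
   ±0.25 f0).  Each harmonic must clear the local inter-harmonic noise
   floor by an adaptive margin (6 dB, relaxing to 2 dB before giving up
   on a third harmonic); the floor test is skipped when f0 is below the
   spectral resolution limit (~160 Hz at 25 ms frames) because the
   harmonic gaps are then unresolved.
4. Candidate formants from local maxima of the +12 dB/oct
   tilt-corrected harmonic sequence (a low sentinel lets a maximum on
   the first harmonic register), refined by parabolic interpolation.
5. For the two-formant default, a model-matching refinement: the
   assumed source tilt plus two resonators (bandwidths 60/90 Hz) is
   fitted to the raw harmonic levels with a free gain by multi-start
   coordinate descent.  This is the checkable analogue of corroborating
   visual estimates with an additive synthesizer matched for f0, and it
   is what resolves formants lying *between* harmonics — the binding
   limitation at f0 ≈ 300 Hz, where plain envelope peak-picking cannot
   beat the ±half-spacing quantization.

An F1 estimate within a third of a harmonic spacing of f0 carries an
`f0_coincident_f1` flag (in real hoos f0 often overlaps F1).  Unvoiced
input falls back to peaks of a cepstrally smoothed envelope
(`cepstral_envelope` flag); too few qualifying peaks yield a partial,
flagged estimate rather than an invented number.

Known limitations: the refinement assumes the synthesis-style source
slope and formant bandwidths, so its accuracy on real recordings with
very different voice qualities will be worse than on the synthetic
corpus; mirror-image solutions around the first harmonic occasionally
survive (visible as a heavy error tail at f0 ≈ 300 Hz, roughly 10% of
calls), which is why corpus-level accuracy is judged by medians and
means rather than maxima.

## Synthetic corpus (`synthetic_data`)

The generator emulates the statistical structure of the original call
sample, not its waveforms: 8 calls from 3 individuals by default;
durations Normal(0.61, 0.31) s truncated at 0.1 s; F1 ~
Normal(358.75, 56.93) Hz and F2 ~ Normal(896.25, 133.04) Hz with
rejection until F1 + 50 < F2; f0 per individual (shared
Normal(300, 30) Hz offset plus 10 Hz per-call jitter) — 300 Hz is this
package's choice, made so f0 sits in the F1 region as in real hoos,
since no chimpanzee f0 statistics are printed; a 50 ms raised-cosine
onset/offset ramp; white noise at 25 dB SNR.  Output is bit-reproducible
from the seed.

What passing tests on this corpus do *not* show: robustness to field
recording conditions (reverberation, wind, overlapping callers,
ingressive phases, amplitude modulation within a call) or to glottal
sources unlike the synthetic one.  The corpus shares its resonator
family with the estimator's refinement model, so corpus accuracy is an
upper bound on real-data accuracy.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script use the study-scale problem
sizes directly: the full 8550-configuration sweep, 100 randomized
vowels per f0 condition for the synthesis→analysis round trip, and a
200-call corpus for blind parameter recovery.  The complete suite runs
in about two minutes on one CPU.
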