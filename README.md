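# hootube

Tube-model vocal-tract acoustics for chimpanzee *hoo* calls.

Chimpanzee hoos sound like the human close back rounded vowel /u/, but
chimpanzees almost certainly cannot make the human lingual gesture for
/u/.  `hootube` explores the acoustic alternative: a vocal tract that is
essentially an unconfigured uniform tube — preceded by a crude in-line
laryngeal air-sac cavity and extended by protruded, narrowed lips — and
asks which such configurations place the first two formants in the
/u/ / hoo region.  It is aimed at bioacousticians and phoneticians who
want a small, fully testable simulation-and-analysis chain for primate
call acoustics.

## What it computes

The tract is an area function of cylindrical segments.  Each segment is
a transmission line with characteristic impedance `Zc = ρc/A`; chaining
the per-segment ABCD matrices with an ideal glottal flow source and an
open lip end gives the volume-velocity transfer function `H(f)`, whose
peaks are the formants.  A lossless closed–open uniform tube obeys the
quarter-wave series

    F_n = (2n − 1) · c / (4 L),   n = 1, 2, …

which serves as the analytic oracle for every invariance test.

On top of that core the package provides, one module each:

- `tube_acoustics` — transfer functions and formant peak-picking for
  arbitrary tube sequences;
- `chimp_tract` — the five-segment chimpanzee simulacrum
  (constriction → air sac → 18 cm × 1 cm² tract → lip protrusion → lip
  opening) and its deterministic 8550-configuration parameter sweep;
- `vowel_space` — comparison of swept F1–F2 dispersions against
  reference formants for human /u/ (male/female/child) and chimpanzee
  hoos, with nearest-fit and within-one-SD overlap reports;
- `formant_synthesis` — cascade (Klatt-style) synthesis of a formant
  dispersion as an audible vowel;
- `call_analysis` — f0 and formant estimation from audio via harmonic
  envelopes and resonator-model matching (deliberately no LPC, which
  mistakes harmonics for formants at high f0);
- `synthetic_data` — a seeded generator of hoo-like call corpora with
  the published sample statistics and known ground truth.

## Worked example

Sweep the full parameter grid, find the configuration closest to the
chimpanzee hoo means, and synthesize + re-analyze that dispersion:

```sh
$ hootube sweep --out sweep.csv
8550 configurations (8550 ok) -> sweep.csv

$ hootube fit --sweep sweep.csv --ref chimp_hoo_methods --metric per_sd_normalized
reference: chimp_hoo_methods
best F1 = 326.97 Hz, F2 = 994.60 Hz (distance 0.93, metric per_sd_normalized)
within one SD: F1 True, F2 True
  protrusion_length_cm = 3.8
  sac_length_cm = 2
  sac_area_cm2 = 2
  lip_area_cm2 = 0.2
  total_length_cm = 24.125

$ hootube synth --f1 358.75 --f2 896.25 --dur 2 --out u_chimp.wav
32000 samples at 16000 Hz -> u_chimp.wav

$ hootube analyze --in u_chimp.wav
f0 = 100.42 Hz
F1 = 360.75 Hz, F2 = 899.00 Hz
flags: harmonic_envelope, model_refined
```

Reading the numbers: the best-fitting tract needs maximal lip
protrusion (3.8 cm), a narrow lip opening (0.2 cm²) and a small air-sac
cavity, and its predicted formants land within one standard deviation
of the observed hoo means (F1 358.75 ± 56.93 Hz, F2 896.25 ± 133.04 Hz)
on both axes — a /u/-like dispersion from a tract with no human-style
tongue gesture.  The synthesized vowel re-measures within ~0.5% of its
targets, confirming the synthesis/analysis chain is self-consistent.

A synthetic corpus with ground truth (8 calls, 3 individuals by
default):

```sh
$ hootube simulate --seed 1 --out corpus_demo
8 calls -> corpus_demo (ground truth: corpus_demo/ground_truth.csv)
```

The same functionality is available as a library:

```python
from hootube import ParamGrid, run_sweep, nearest_configuration, REFERENCES

sweep = run_sweep(ParamGrid())
fit = nearest_configuration(sweep, REFERENCES["chimp_hoo_methods"])
print(fit.best_f1, fit.best_f2, fit.best_params)
```

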