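# bcgvf

Ventricular-fibrillation (VF) detection from single-channel
ballistocardiography (BCG)-like recordings sampled at 125 Hz.

The package implements the full detection pipeline as reusable modules,
exercised end-to-end on a bundled synthetic cohort simulator (no real
recordings ship with it):

| module            | role |
|-------------------|------|
| `bcgvf.synth`     | annotated multi-subject synthetic cohorts: sinus-rhythm beat trains, aperiodic fibrillatory oscillation, motion artifacts, respiration baseline, 3 s ventilator pulses, noise |
| `bcgvf.wavelets`  | Daubechies-6 undecimated filter bank with exact additive reconstruction (details d1–d7 + smooth) |
| `bcgvf.preprocess`| detail reconstruction (d3–d7), leaky LMS ventilator-noise cancellation (64 taps, α=1, μ=1e-8), segmentation into labeled 7 s / 875-sample windows (class-dependent stride: SR 7 s, MA 3 s, VF 1 s) |
| `bcgvf.transform` | weighted second decomposition, full-lag autocorrelation (r₀=1), [1,2]-normalization + squaring, discrete Stockwell transform over 1–20 Hz, beat-length (hbl) estimation over 44–150 samples, middle-period crop |
| `bcgvf.features`  | the 22 features: slice correlation, instantaneous frequency, quantized amplitude, peak intervals, spectral density (four moments each), FWHM, range |
| `bcgvf.stats`     | Mann–Whitney U relevance, Benjamini–Yekutieli FDR adjustment, correlation clustering (average linkage), 13-feature subset selection |
| `bcgvf.classify`  | training-set undersampling, systematic 10-fold and leave-one-subject-out evaluation of LR/RF with the six confusion-matrix metrics |
| `bcgvf.cli`       | `bcgvf` command-line front end with cached end-to-end runs |

## CLI

```sh
# one cached end-to-end run: simulate -> preprocess -> extract -> analyze -> evaluate
bcgvf run-all --subjects 6 --seed 1 --out runs/demo

# or stage by stage
bcgvf simulate --subjects 4 --seed 1 --out data/ --mix sr,vf,ma --ventilator
bcgvf preprocess --in data/ --out segments.csv
bcgvf extract --segments segments.csv --out features.csv
bcgvf analyze --features features.csv --out analysis
bcgvf train-eval --features features.csv --model rf --paradigm loso \
    --repeats 10 --seed 1 --feature-mode paper --out report.json
```

Every pipeline output is named with the resolved config hash and seed;
rerunning with the same config reuses cached stage outputs.

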