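# hft — hierarchical frequency tagging toolbox

Tools for building and analysing two-frequency "hierarchical" tagging
experiments in vision: a slow cyclic scrambling of image content (1.3 Hz)
superimposed with a fast global contrast modulation (10 Hz), plus the
spectral machinery to read out both tags — and their intermodulation
products — from multichannel EEG.

The package covers the full loop:

* **`hft.meyer`** — orthogonal Meyer wavelet transform for periodic
  images, evaluated exactly in the frequency domain (unitary to machine
  precision at all six dyadic levels, which the scrambler depends on).
* **`hft.swift`** — cyclic local-contour scrambling: each wavelet-domain
  (horizontal, vertical, diagonal) coefficient triplet rotates along a
  random norm-preserving circular path, destroying and restoring image
  semantics once per cycle while pinning luminance, contrast and the
  spatial-frequency envelope.
* **`hft.trial`** — 50 s trial assembly: 65 cycles of a face and a house
  image in pseudo-random order (the category proportion sets the trial's
  *certainty*), 50/50 blending with cross-category noise cycles, and the
  10 Hz sinusoidal contrast gain.
* **`hft.sim`** — synthetic 64-channel EEG forward model: f1/f2 sources
  with realistic topographies, a multiplicative interaction that creates
  intermodulation (IM) components at `n1*f1 + n2*f2`, certainty-dependent
  amplitudes, and 1/f background noise. Includes an artifact injector
  for testing the quality-control path.
* **`hft.spectrum`** — preprocessing (resample to 500 Hz, 0.6 Hz
  high-pass, average reference), trial FFT amplitude spectra at 0.02 Hz
  resolution, the 20-neighbour-bin SNR statistic, IM enumeration and
  group-level one-sample t-tests with Benjamini-Hochberg FDR.
* **`hft.quality`** — noisy-sample rules (±80 µV, 40 µV steps, ±6 SD),
  noisy-cycle flagging (> 2 % of samples) and mean-replacement,
  participant exclusion (counting accuracy r < 0.9, > 10 % noisy
  cycles) and the within-participant ±2.5 SD trial exclusion.
* **`hft.certainty`** — ten 5-percentage-point certainty bins, linear
  mixed-effects models of log2(SNR) over the 30-electrode posterior ROI
  at three nesting levels with likelihood-ratio tests, certainty-slope
  contrasts between frequency categories, and Fisher r-to-z comparison
  of scalp-map correlations.

## Command line

```bash
hft generate-cycle --image face01.png --frames 92 --seed 7 --out cycleF.npz
hft assemble-trial --face cycleF.npz --house cycleH.npz --p-dominant 0.8 --out trial.npz
hft simulate --participants 5 --trials 56 --seed 1 --out sims/
hft analyze --in sims/ --out snr.csv
hft stats --snr snr.csv --out results/
```

`simulate` writes one NPZ per trial plus a `session.csv` with the
behavioural records; `analyze` produces the tidy per-trial, per-channel
SNR table; `stats` runs the certainty LME battery on it.

## Notes

* Scrambling cycles are deterministic given a seed: the same seed
  reproduces a frame stack bit for bit.
* The forward model's interaction term multiplies the two *unit* source
  waveforms scaled by a certainty-dependent gain, so IM amplitude grows
  with certainty while the f2 amplitude falls — the qualitative pattern
  the statistics recover.
* `hft.spectrum.snr_at` refuses off-grid frequencies rather than
  interpolating; design frequencies land exactly on the 0.02 Hz grid
  for 50 s windows.
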