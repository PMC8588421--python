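# pcgsnr

Automated quality assessment of phonocardiographic (PCG) recordings
through the signal-to-noise ratio, and determination of the minimum SNR
that keeps heart-valve closure latency estimates within a chosen
uncertainty.

## Who this is for

Phonocardiography at the patient's domicile — e.g., day-to-day follow-up
of people prone to acute heart failure — stands or falls with signal
quality: a naive user cannot judge whether a recording is good enough
for clinical interpretation. `pcgsnr` implements a simple, per-heartbeat
quality metric and the sensitivity analysis that turns it into an
actionable accept/reject threshold for a concrete downstream
measurement: the latencies from the ECG R-peak to the four heart-sound
components (the mitral and tricuspid components of S1, the aortic and
pulmonary components of S2), which index the electromechanical coupling
of the ventricles and the closure timing of the heart valves.

## The metric and the method

For every heartbeat (cycles delimited by ECG R-peaks) and separately for
the first and second heart sounds,

```
SNR = 20 log10( A_S / (4 σ_N) )   [dB]
```

where `A_S` is the peak-to-peak amplitude of the heart sound of interest
and `4 σ_N` is the amplitude of the 95% band of the noise, whose
standard deviation is estimated in the 70–85% span of the cardiac cycle,
where no heart sound is expected. The recording-level SNR is the median
over beats. The Gaussian noise model behind the `4 σ` band is checked
per beat with a chi-square goodness-of-fit test.

To find the minimum acceptable SNR, a recording is repeatedly corrupted
with white Gaussian noise of standard deviation

```
σ_i = σ_0 sqrt(10^(0.1 i / 10) − 1)
```

so the measured SNR drops by 0.1 dB per step `i`. At each step both SNRs
and the four latencies are re-estimated; the loop stops when the
measured SNR stops decreasing in two consecutive iterations. Ten such
runs are resampled on a common 0.1 dB grid and their pointwise median
forms the sensitivity curve of latency vs SNR. Scanning that curve in
decreasing SNR order, the minimum acceptable SNR is the first point
whose latency *significantly* differs from the high-SNR reference:
a Wald–Wolfowitz runs test (α = 0.05) detects a trend in the trailing
deviations *and* the deviation exceeds the acceptable band — ±1 ms
(the acquisition resolution) or ±ε% of the population reference latency
for ε ∈ {2.5, …, 20}. Per-subject thresholds aggregate to the
population worst case (maximum).

Everything is testable without any data download: a bundled generator
synthesizes paired PCG+ECG cohorts with known ground truth (per-beat
component latencies, noise level, amplitudes) that emulate the
population statistics of healthy resting adults.

## Worked example

```
$ pcgsnr simulate --n-subjects 1 --duration 60 --fs 2000 --snr-range 20,20 --seed 42 --out-dir demo
wrote 1 recordings to demo
$ pcgsnr snr --in demo/subj01_pcg.wav --ecg demo/subj01_ecg.wav --out demo/snr.csv
S1 20.5 dB, S2 16.9 dB over 60 beats -> demo/snr.csv
$ pcgsnr latency --in demo/subj01_pcg.wav --ecg demo/subj01_ecg.wav --out demo/latencies.csv
aggregate latencies (ms): M=44.1 T=77.2 A=368.3 P=392.1 -> demo/latencies.csv
```

The simulated subject was calibrated to a 20 dB initial S1 SNR: the
measured value (20.5 dB, median over 60 beats, the peak-to-peak
amplitude slightly inflated by noise) confirms the calibration, and the
S2 SNR is lower because the second sound is quieter. The aggregate
latencies recover the generator's population medians (44, 77, 368,
392 ms) to within a fraction of a millisecond. The per-beat table holds
`beat_index, a_s1, a_s2, sigma_n, snr_s1_db, snr_s2_db`:

```
beat_index,a_s1,a_s2,sigma_n,snr_s1_db,snr_s2_db
0,1.6307395696640015,1.1066653430461884,0.036468541880194556,20.96812437614277,17.600758378681537
```

Downstream, `pcgsnr sensitivity` produces the median latency-vs-SNR
curve for a recording, `pcgsnr threshold` turns a directory of curves
into the per-uncertainty population threshold table, and
`pcgsnr validate` measures how often those thresholds hold on a held-out
set of recordings.

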