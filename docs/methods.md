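# Methods

This note documents the models, estimators and numerical choices behind
`pcgsnr`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the known limitations.

## Signal model

A recorded phonocardiogram is modeled as `x(t) = s(t) + n(t) + n_i(t)`:
the acoustic signal emitted by the heart, the noise superimposed at
recording time, and (during the sensitivity analysis) artificially
injected noise. `n(t)` is treated as zero-mean white Gaussian noise;
the per-beat chi-square check (below) verifies this assumption on the
segments where it is actually used. All timing is referenced to the
R-peaks of a simultaneously recorded ECG; the method is therefore
unusable on PCG-only recordings, and the readers refuse them explicitly.

## Synthetic cohort generator

The generator emulates 10-minute paired recordings from healthy resting
adults; every downstream stage is developed and tested against its
ground truth. What it emulates, and how:

* **Heart-rate process.** Per-subject rate drawn from N(60, 4) bpm
  (clipped to 40–100), per-beat RR jitter of 20 ms. This produces
  distinct, unambiguous cycles; it does not model respiratory sinus
  arrhythmia or ectopy.
* **Heart sounds.** Each component is a Gaussian-windowed cosine —
  S1 components at 50 Hz over 50 ms, S2 components at 80 Hz over 40 ms,
  amplitudes 1.0/0.8 (mitral/tricuspid) and 0.6/0.45 (aortic/pulmonary)
  so S1 is louder than S2. Any smooth transient with a well-defined
  peak-to-peak amplitude would do; this one makes the clean amplitude
  `A_S` analytically controllable and the envelope peak (the latency
  fiducial) exactly the envelope center.
* **Latency population.** Component latencies are specified by median
  and quartiles (defaults 44/38–60, 77/69–96, 368/353–393,
  392/377–432 ms for mitral, tricuspid, aortic, pulmonary) and sampled
  through a split-normal quantile function, which matches all three
  configured quantiles exactly. One standard-normal score is shared by
  a subject's four components — modelling the common electromechanical
  scaling across valves and guaranteeing the orderings
  mitral < tricuspid and aortic < pulmonary. Cohorts use a stratified
  (midpoint-quantile, shuffled) sample of that score, a latin-hypercube
  style variance reduction that makes even a 25-subject cohort
  representative of the configured medians while preserving convergence
  of all cohort statistics as n grows. Per-beat latency jitter is
  Gaussian with sd 1 ms, which makes averaging over beats meaningful.
* **Noise calibration.** The recording noise sd `σ0` is set so that the
  recording-level S1 SNR per the definition below hits the configured
  target; cohort targets are spread evenly over 7–25 dB by default.
  A requested `σ0 = 0` is rejected: the SNR is undefined without noise.
* **ECG.** Gaussian QRS spikes (sd 6 ms, amplitude 1) plus a
  same-polarity T-wave (amplitude 0.25, 280 ms after R) over a small
  noise floor (sd 0.02), so both ECG admissibility filters pass by
  construction unless a fixture deliberately violates them.
* **Sampling rate.** Default 2 kHz; latencies are reported at 1 ms
  resolution, mirroring typical acquisition systems. The rate is a free
  parameter (≥ 1 kHz).

Fixing the seed fixes every waveform sample. What the generator does
*not* emulate — murmurs, friction/ambient artifacts, respiration-
modulated split dynamics, pathological morphologies, electrode motion —
bounds what passing tests show: they validate the *pipeline logic and
statistics*, not robustness to real-world artifact classes.

## Segmentation

R-peaks are detected with a polarity-robust threshold at half the
maximum deflection and a 200 ms refractory period. Cycles run R-to-R;
the last partial cycle is discarded (its noise window would be
undefined). Cycles shorter than 300 ms or longer than 2 s are excluded
as artifacts. Within each cycle of length L: S1 window
[R + 10 ms, R + 200 ms) (clipped to the start of the S2 window on short
cycles), S2 window [0.25 L, 0.55 L), noise window [0.70 L, 0.85 L).
The sound windows are config-overridable; the defaults are safe for
40–120 bpm and keep the noise window clear of both sounds.

## SNR metric

Per beat and per sound, `SNR = 20 log10(A_S / (4 σ_N))` with `A_S` the
peak-to-peak amplitude in the sound's window of the **raw** signal and
`σ_N` the sample sd (mean removed) in the noise window; `4 σ_N` is the
95% band of Gaussian noise. A zero `σ_N` flags the beat as SNR-
undefined. The recording-level aggregate is the **median** of per-beat
values — the aggregation is a design choice; the median is robust to
occasional artifact beats — kept at full precision internally and
rounded to integer dB only for reporting.

Noise normality is checked per beat with a chi-square goodness-of-fit
test against a normal with moments estimated from the segment. Binning
uses Sturges' count with *equiprobable* bins under the fitted normal
(every expected count is n/k, so no merging step is needed) and
df = k − 3. With estimated moments the statistic is only approximately
chi-square (Chernoff–Lehmann); on clean Gaussian segments of ~300
samples the empirical non-rejection rate at α = 0.05 sits at ~0.95,
which the acceptance suite verifies.

## Latency estimation

The component detector is a deliberately transparent stand-in with the
interface sized so a more elaborate algorithm can be dropped in. Steps:
zero-phase 4th-order Butterworth band-pass 20–250 Hz; envelope as the
magnitude of the analytic signal smoothed over 10 ms; within each sound
window the two most prominent envelope peaks at least 10 ms apart
(prominence ≥ 10% of the window maximum), earlier = mitral/aortic,
later = tricuspid/pulmonary. Latency is measured from the R-peak to the
envelope **peak** (not onset — onset detection is noise-fragile, and any
consistent fiducial supports the sensitivity analysis), rounded to 1 ms.
A window whose envelope maximum is below 2.5× its median is treated as
holding no sound (pure-noise envelope ratios sit near 2; genuine
transients above 3 even at 5 dB), yielding per-beat missing values.
Splits below 10 ms merge into one peak and the pair is reported missing
for that beat. The per-recording estimate is the mean over beats with
defined values, with contributing-beat counts reported.

## Degradation and sensitivity curves

Injected noise at step i has sd `σ_i = σ0 sqrt(10^(0.1 i / 10) − 1)`,
with `σ0` the average noise-window sd of the original recording. Noise
is re-drawn independently each step and added to the *original* signal,
never cumulatively, so the total noise sd is `σ0·10^(0.005 i)` and the
expected measured SNR is the initial value minus 0.1·i dB. The loop
stops when either sound's recording SNR fails to decrease in two
consecutive iterations (conservative: stop at the first sign of
breakdown; past that point the measured SNR is dominated by the noise
contribution to the peak-to-peak amplitude and saturates), with a
safety cap of 400 steps.

The measured slope is slightly shallower than 0.1 dB/step (typically
0.09–0.095 in the acceptance run) because the peak-to-peak amplitude in
the sound window itself grows with the injected noise — a property of
the metric, not an implementation artifact.

Ten runs per recording are linearly interpolated onto a descending
0.1 dB grid restricted to the SNR range covered by every run (no
extrapolation), separately per component, with the S1 SNR as the axis of
the S1-component curves and the S2 SNR for the S2 components; the
pointwise median across runs is the subject's sensitivity curve. Run
curves are retained for audit.

## Minimum acceptable SNR

Scanning the median curve in decreasing SNR order, the threshold is the
first grid point where both hold:

1. **Trend** — a Wald–Wolfowitz runs test at α = 0.05 on the signs of
   the deviations from the reference (the curve value at the highest SNR
   grid point) over the trailing 20 grid points (2 dB) ending at the
   candidate. The p-value is the exact conditional two-sided mid-p
   (mid-p keeps the empirical size of the discrete test at the nominal
   α; the acceptance suite measures 5% ± 1% on i.i.d. signs at n = 40).
   A trend requires the runs count *below* expectation — clustered
   signs; alternation is not a trend. Zero deviations are dropped; an
   all-zero or shorter-than-10 window carries no trend; a single-sign
   window of ≥ 10 points is maximal clustering and counts as a trend
   candidate.
2. **Deviation** — the candidate's |latency − reference| exceeds the
   band half-width: 1 ms in absolute mode (strictly greater, matching a
   1 ms resolution), or ε% of the population reference latency (the
   cohort median) in percentage mode.

If never satisfied the result is "N/A" (empty CSV cell, JSON null).
Per-subject thresholds aggregate to the population worst case (maximum
over subjects, N/A excluded but counted). In the threshold-vs-ε table a
subject whose curve never leaves the band contributes the minimum SNR
its curve reached, so every cell is defined; band nesting makes each
column non-increasing in ε.

## Validation stage

External recordings are admitted when (1) the median R-peak amplitude is
at least 3× the ECG noise 95% band — ECG noise measured in the same
70–85% cycle windows, for consistency with the SNR convention — and
(2) the R-wave and T-wave (dominant deflection 150–400 ms post R,
majority-voted over beats) share polarity, and (3) both sounds' initial
SNR strictly exceeds 14 dB. Each admitted recording is degraded to the
population threshold for every (component, ε); it satisfies level ε when
all four latencies stay within ε% of its own high-SNR reference. At
ε = 0 the band is the CI95 of the per-beat latency mean
(±1.96 sd/√n_beats), which accounts for short validation records with
few beats. Recordings whose curves stop above a threshold SNR are
reported as not evaluable and excluded from the denominator.

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale versions of
the study conditions: 30–60 s records (60-s, 25-subject cohort at 25 dB
for latency recovery; a 600-s single recording for the noise-model
check; 50 steps × 100 realizations for the SNR schedule), chosen so the
statistics under test are well resolved while the full suite completes
in well under a minute of compute per module. Grid arithmetic keeps SNR
grid points exact multiples of 0.1 dB via integer indices; interpolation
is linear; all sample indices are 0-based half-open; reported times are
ms.

## Known limitations

* The latency estimator is a documented stand-in, not a reimplementation
  of a clinical-grade detector; its 10 ms split resolution and
  envelope-peak fiducial are part of the package contract.
* The R-peak detector assumes a dominant QRS deflection; tall T-waves
  (> ~50% of R) or heavy ECG noise can defeat the fixed 50% threshold.
* Population thresholds derived from the bundled synthetic cohorts
  characterize the pipeline, not any clinical population: real
  recordings carry artifact classes the generator does not model.
* The stochastic stop condition can truncate degradation runs early on
  short recordings, where the per-step SNR measurement noise is
  comparable to the 0.1 dB decrement; long recordings (the 10-minute
  default) make spurious stops rare.
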