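"""Calibrated noise-injection degradation and sensitivity curves.

A recording is iteratively corrupted with fresh zero-mean white Gaussian
noise whose standard deviation at step ``i`` is

    sigma_i = sigma0 * sqrt(10**(0.01 * i) - 1)

where ``sigma0`` is the average standard deviation of the noise in the
original recording (measured in the 70–85% windows of its cycles).  The
corrupted signal is ``x = s + n + n_i``: the injected noise is re-drawn
independently at each step and added to the *original* recording, never
cumulatively, so the total noise sd is ``sigma0 * 10**(0.005 i)`` and the
measured SNR decreases by 0.1 dB per step in expectation.

At every step the recording-level SNR of both sounds and the aggregated
latencies are recomputed on the corrupted signal.  The loop stops when
the measured SNR fails to decrease in two consecutive iterations — past
that point the SNR computation itself has broken down (at high noise the
peak-to-peak amplitude inside the sound window is dominated by noise and
the measured SNR saturates).

The test is repeated over several runs; each run's latency-vs-SNR curve
is resampled onto a common descending grid at 0.1 dB resolution and the
pointwise median over the runs forms the sensitivity curve for the
recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .latency import AggregatedLatencies, COMPONENT_FIELDS, estimate_recording_latencies
from .segmentation import BeatSegmentation, segment_recording
from .simulate import Recording
from .snr import compute_recording_snr, estimate_noise_sigma

__all__ = [
    "DegradationStep",
    "RunCurve",
    "SensitivityCurve",
    "DisjointRangeError",
    "noise_sigma_for_step",
    "inject_noise",
    "measure_sigma0",
    "stop_index",
    "run_degradation",
    "summarize_runs",
    "sensitivity_curve",
]

#: which sound's SNR forms the x-axis of each latency's curve
SOUND_OF_COMPONENT = {
    "mitral": "s1", "tricuspid": "s1", "aortic": "s2", "pulmonary": "s2",
}


class DisjointRangeError(ValueError):
    """The runs share no common SNR range to resample on."""


@dataclass
class DegradationStep:
    i: int
    sigma_i: float
    snr_s1_db: float
    snr_s2_db: float
    latencies: AggregatedLatencies


@dataclass
class RunCurve:
    """One degradation run: step 0 is the uncorrupted reference."""

    steps: list[DegradationStep]
    sigma0: float

    def snr(self, sound: str) -> np.ndarray:
        return np.array([getattr(s, f"snr_{sound}_db") for s in self.steps])

    def latency(self, component: str) -> np.ndarray:
        attr = COMPONENT_FIELDS[component]
        return np.array([getattr(s.latencies, attr) for s in self.steps])


@dataclass
class SensitivityCurve:
    """Median latency vs SNR on a 0.1 dB grid, per component.

    ``components`` maps each component name to ``(grid_db, latency_ms)``
    with the grid strictly descending in 0.1 dB steps.  The individual
    run curves are retained for audit.
    """

    components: dict[str, tuple[np.ndarray, np.ndarray]]
    n_runs: int
    run_curves: list[RunCurve]

    def min_snr_reached(self, component: str) -> float:
        return float(self.components[component][0][-1])


def noise_sigma_for_step(sigma0: float, i: int) -> float:
    """Injected-noise sd producing an expected SNR drop of 0.1*i dB."""
    if not sigma0 > 0:
        raise ValueError("sigma0 must be positive")
    if i <= 0:
        raise ValueError("step index must be >= 1")
    return sigma0 * math.sqrt(10.0 ** (0.01 * i) - 1.0)


def inject_noise(recording: Recording, sigma_i: float,
                 rng: np.random.Generator) -> Recording:
    """Add fresh i.i.d. Gaussian noise of sd ``sigma_i`` to the PCG.

    The ECG is untouched; segmentation therefore remains valid.
    """
    if sigma_i < 0:
        raise ValueError("sigma_i must be >= 0")
    pcg = recording.pcg if sigma_i == 0 else \
        recording.pcg + rng.normal(0.0, sigma_i, len(recording.pcg))
    return Recording(pcg=pcg, ecg=recording.ecg, fs_hz=recording.fs_hz,
                     ground_truth=recording.ground_truth,
                     label=recording.label)


def measure_sigma0(pcg: np.ndarray, segmentation: BeatSegmentation) -> float:
    """Average noise sd over the beats' 70–85% windows."""
    sigmas = np.array([estimate_noise_sigma(pcg, w)
                       for w in segmentation.noise_windows])
    sigmas = sigmas[np.isfinite(sigmas)]
    if len(sigmas) == 0:
        raise ValueError("no usable noise window")
    return float(sigmas.mean())


def stop_index(values, patience: int = 2) -> int | None:
    """Index at which ``values`` failed to decrease ``patience`` times in
    a row, or None if it never does.  Monitoring the measured SNR with
    ``patience=2`` implements the loop's stop condition."""
    count = 0
    for j in range(1, len(values)):
        count = count + 1 if values[j] >= values[j - 1] else 0
        if count >= patience:
            return j
    return None


def run_degradation(
    recording: Recording,
    rng: np.random.Generator,
    segmentation: BeatSegmentation | None = None,
    *,
    max_steps: int = 400,
    patience: int = 2,
) -> RunCurve:
    """One degradation run: corrupt, re-measure, stop on SNR breakdown.

    The stop condition is evaluated on both sounds: the loop ends as soon
    as *either* sound's recording-level SNR fails to decrease in
    ``patience`` consecutive iterations (conservative — stops at the
    first sign of breakdown), or at the ``max_steps`` safety cap.
    """
    seg = segmentation or segment_recording(recording)
    sigma0 = measure_sigma0(recording.pcg, seg)

    def measure(pcg, i, sigma_i):
        rs = compute_recording_snr(pcg, seg)
        agg, _ = estimate_recording_latencies(pcg, seg)
        return DegradationStep(i, sigma_i, rs.snr_s1_db, rs.snr_s2_db, agg)

    steps = [measure(recording.pcg, 0, 0.0)]
    count_s1 = count_s2 = 0
    for i in range(1, max_steps + 1):
        sigma_i = noise_sigma_for_step(sigma0, i)
        corrupted = recording.pcg + rng.normal(0.0, sigma_i, len(recording.pcg))
        step = measure(corrupted, i, sigma_i)
        prev = steps[-1]
        count_s1 = count_s1 + 1 if step.snr_s1_db >= prev.snr_s1_db else 0
        count_s2 = count_s2 + 1 if step.snr_s2_db >= prev.snr_s2_db else 0
        steps.append(step)
        if count_s1 >= patience or count_s2 >= patience:
            break
    return RunCurve(steps=steps, sigma0=sigma0)


def _resample_run(run: RunCurve, component: str, grid: np.ndarray) -> np.ndarray:
    x = run.snr(SOUND_OF_COMPONENT[component])
    y = run.latency(component)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    order = np.argsort(x)
    # np.interp needs ascending x; the grid is descending, so flip twice
    return np.interp(grid[::-1], x[order], y[order])[::-1]


def summarize_runs(runs: list[RunCurve], grid_step_db: float = 0.1) -> SensitivityCurve:
    """Pointwise median over runs on a common descending 0.1 dB grid.

    Each run is linearly interpolated at the grid points; the grid is
    restricted, per component, to the SNR range covered by every run so
    no run is ever extrapolated.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to summarize")
    components: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for comp in COMPONENT_FIELDS:
        lo = -np.inf
        hi = np.inf
        for run in runs:
            x = run.snr(SOUND_OF_COMPONENT[comp])
            y = run.latency(comp)
            x = x[np.isfinite(x) & np.isfinite(y)]
            if len(x) < 2:
                raise ValueError(
                    f"a run has fewer than 2 valid points for {comp}")
            lo, hi = max(lo, x.min()), min(hi, x.max())
        k_hi = math.floor(round(hi / grid_step_db, 6))
        k_lo = math.ceil(round(lo / grid_step_db, 6))
        if k_hi < k_lo:
            raise DisjointRangeError(
                f"runs share no common SNR range for {comp}")
        grid = np.arange(k_hi, k_lo - 1, -1) * grid_step_db
        stack = np.vstack([_resample_run(r, comp, grid) for r in runs])
        components[comp] = (grid, np.median(stack, axis=0))
    return SensitivityCurve(components=components, n_runs=len(runs),
                            run_curves=list(runs))


def sensitivity_curve(
    recording: Recording,
    n_runs: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    segmentation: BeatSegmentation | None = None,
    *,
    max_steps: int = 400,
) -> SensitivityCurve:
    """Run the degradation ``n_runs`` times and summarize as the median."""
    if rng is None:
        rng = np.random.default_rng(seed)
    seg = segmentation or segment_recording(recording)
    runs = [run_degradation(recording, child, seg, max_steps=max_steps)
            for child in rng.spawn(n_runs)]
    return summarize_runs(runs)
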