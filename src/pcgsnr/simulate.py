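"""Synthetic paired PCG+ECG recordings with ground truth.

Every downstream stage of the pipeline (segmentation, SNR, latency
estimation, degradation, thresholds) is exercised on recordings produced
here, so the generator emulates the statistical structure of resting
recordings from healthy adults:

* a regular heart-rate process with mild RR variability, giving distinct
  cardiac cycles delimited by unambiguous ECG R-peaks;
* four-component heart sounds — the mitral (M) and tricuspid (T)
  components of S1, the aortic (A) and pulmonary (P) components of S2 —
  placed at per-beat latencies drawn around per-subject values, which are
  in turn drawn from a configurable population distribution specified by
  its median and quartiles;
* zero-mean white Gaussian recording noise, whose standard deviation
  ``sigma0`` is calibrated so that the recording-level S1 SNR
  (``20*log10(A_S1 / (4*sigma0))``) matches a configured target.

The ground truth (true per-beat latencies, ``sigma0``, clean peak-to-peak
amplitudes, R-peak sample indices) is attached to each recording so tests
can compare estimates against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtri

__all__ = [
    "ComponentSpec",
    "LatencyPopulation",
    "CohortConfig",
    "GroundTruth",
    "Recording",
    "InvalidSpecError",
    "NoiseFloorError",
    "DEFAULT_COMPONENTS",
    "DEFAULT_LATENCY_POPULATION",
    "COMPONENT_NAMES",
    "synthesize_component",
    "generate_recording",
    "generate_cohort",
]

COMPONENT_NAMES = ("mitral", "tricuspid", "aortic", "pulmonary")

#: standard normal 75th percentile, used to convert quartiles to scales
_Z75 = 0.6744897501960817


class InvalidSpecError(ValueError):
    """Raised for physically meaningless component specifications."""


class NoiseFloorError(ValueError):
    """Raised when a requested noise level leaves the SNR undefined."""


@dataclass(frozen=True)
class ComponentSpec:
    """Morphology and timing of one heart-sound component.

    The component is synthesized as a Gaussian-windowed cosine: a burst at
    ``center_freq_hz`` under a Gaussian envelope whose +/-3 sigma support
    spans ``duration_ms``, with peak amplitude ``amplitude`` at the
    envelope center.  ``latency_ms`` is the time from the R-peak to the
    envelope peak and is applied at placement time, not in the waveform.
    """

    name: str
    latency_ms: float
    amplitude: float
    center_freq_hz: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise InvalidSpecError(f"unknown component name {self.name!r}")
        if not self.latency_ms > 0:
            raise InvalidSpecError("latency_ms must be positive")
        if not self.duration_ms > 0:
            raise InvalidSpecError("duration_ms must be positive")
        if not self.center_freq_hz > 0:
            raise InvalidSpecError("center_freq_hz must be positive")
        if self.amplitude < 0:
            raise InvalidSpecError("amplitude must be non-negative")


# S1 components around 50 Hz and S2 components around 80 Hz, S1 louder
# than S2; durations chosen so that neighbouring components (33 ms and
# 24 ms median splits) remain resolvable as separate envelope peaks.
DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("mitral", 44.0, 1.00, 50.0, 50.0),
    ComponentSpec("tricuspid", 77.0, 0.80, 50.0, 50.0),
    ComponentSpec("aortic", 368.0, 0.60, 80.0, 40.0),
    ComponentSpec("pulmonary", 392.0, 0.45, 80.0, 40.0),
)


@dataclass(frozen=True)
class LatencyPopulation:
    """Population distribution of one latency, given as median/quartiles.

    Subjects are drawn from a split-normal distribution whose median and
    quartiles match the three configured values exactly: the left/right
    scales are ``(median-q25)/z75`` and ``(q75-median)/z75``.
    """

    median_ms: float
    q25_ms: float
    q75_ms: float

    def __post_init__(self) -> None:
        if not (self.q25_ms <= self.median_ms <= self.q75_ms):
            raise InvalidSpecError("quartiles must bracket the median")

    @property
    def scale_low_ms(self) -> float:
        return (self.median_ms - self.q25_ms) / _Z75

    @property
    def scale_high_ms(self) -> float:
        return (self.q75_ms - self.median_ms) / _Z75

    def value_at_z(self, z: float) -> float:
        """Latency at standard-normal score ``z`` (split-normal quantile)."""
        scale = self.scale_high_ms if z >= 0 else self.scale_low_ms
        return self.median_ms + z * scale


#: population medians and quartiles (ms) of the four R-to-component
#: latencies in healthy adults, used as generator defaults
DEFAULT_LATENCY_POPULATION: dict[str, LatencyPopulation] = {
    "mitral": LatencyPopulation(44.0, 38.0, 60.0),
    "tricuspid": LatencyPopulation(77.0, 69.0, 96.0),
    "aortic": LatencyPopulation(368.0, 353.0, 393.0),
    "pulmonary": LatencyPopulation(392.0, 377.0, 432.0),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the acquisition protocol the pipeline targets:
    10-minute paired recordings from 25 healthy resting volunteers, with
    initial S1 SNRs spread over 7–25 dB.
    """

    n_subjects: int = 25
    record_duration_s: float = 600.0
    fs_hz: float = 2000.0
    heart_rate_bpm_mean: float = 60.0
    heart_rate_bpm_sd: float = 4.0
    latency_population: dict[str, LatencyPopulation] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_POPULATION)
    )
    target_snr_db_range: tuple[float, float] = (7.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs_hz < 1000:
            raise ValueError("fs_hz must be >= 1000 Hz")
        lo, hi = self.target_snr_db_range
        if lo > hi:
            raise ValueError("target SNR range lower bound must be <= upper bound")
        missing = set(COMPONENT_NAMES) - set(self.latency_population)
        if missing:
            raise ValueError(f"latency_population missing components: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Construction-time truth attached to a synthetic recording."""

    beat_latencies_ms: dict[str, np.ndarray]
    subject_latencies_ms: dict[str, float]
    sigma0: float
    s1_p2p: float
    s2_p2p: float
    r_peak_indices: np.ndarray
    target_snr_db: float | None = None


@dataclass
class Recording:
    """A paired single-channel PCG + ECG recording at a common rate."""

    pcg: np.ndarray
    ecg: np.ndarray
    fs_hz: float
    ground_truth: GroundTruth | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.pcg = np.asarray(self.pcg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.pcg.shape != self.ecg.shape:
            raise ValueError("pcg and ecg must have equal length")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.pcg) / self.fs_hz


def synthesize_component(spec: ComponentSpec, fs_hz: float) -> np.ndarray:
    """Synthesize one component transient of finite support.

    Returns an odd-length waveform: a cosine at ``spec.center_freq_hz``
    under a Gaussian envelope (sd = duration/6, support +/-3 sd), peak
    amplitude ``spec.amplitude`` at the central sample.  Latency plays no
    role here; it is applied when the transient is placed in a beat.
    """
    if not fs_hz > 0:
        raise InvalidSpecError("fs_hz must be positive")
    sigma_s = spec.duration_ms / 6000.0  # envelope sd, seconds
    half = int(round(3 * sigma_s * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    envelope = np.exp(-0.5 * (t / sigma_s) ** 2)
    return spec.amplitude * envelope * np.cos(2 * np.pi * spec.center_freq_hz * t)


def _place(signal: np.ndarray, wave: np.ndarray, center: int) -> None:
    """Add ``wave`` (odd length, centered) into ``signal`` at ``center``."""
    half = len(wave) // 2
    lo, hi = center - half, center + half + 1
    wlo = max(0, -lo)
    whi = len(wave) - max(0, hi - len(signal))
    lo, hi = max(lo, 0), min(hi, len(signal))
    if lo < hi:
        signal[lo:hi] += wave[wlo:whi]


def _clean_p2p(pcg: np.ndarray, r_idx: np.ndarray, fs: float,
               s1: bool) -> float:
    """Median per-beat peak-to-peak amplitude of S1 or S2 in the clean PCG."""
    amps = []
    for k in range(len(r_idx) - 1):
        start, end = r_idx[k], r_idx[k + 1]
        rr = end - start
        if s1:
            lo = start + int(round(0.010 * fs))
            hi = start + int(round(0.200 * fs))
        else:
            lo = start + int(round(0.25 * rr))
            hi = start + int(round(0.55 * rr))
        hi = min(hi, end)
        if hi > lo:
            amps.append(np.ptp(pcg[lo:hi]))
    if not amps:
        raise ValueError("recording too short to hold one full cardiac cycle")
    return float(np.median(amps))


def generate_recording(
    duration_s: float,
    fs_hz: float,
    heart_rate_bpm: float = 60.0,
    target_snr_db: float | None = 20.0,
    component_specs: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS,
    *,
    sigma0: float | None = None,
    latency_jitter_ms: float = 1.0,
    rr_jitter_ms: float = 20.0,
    ecg_noise_sd: float = 0.02,
    qrs_amplitude: float = 1.0,
    t_wave_amplitude: float = 0.25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label: str = "synthetic",
) -> Recording:
    """Generate one paired PCG+ECG recording with ground truth.

    The ECG holds a Gaussian QRS-like spike train (amplitude
    ``qrs_amplitude``, far above its noise floor) plus a same-polarity
    T-wave deflection 280 ms after each R.  The PCG holds, per full cycle,
    the four components at per-beat true latencies (spec values plus
    Gaussian jitter of sd ``latency_jitter_ms``), plus zero-mean white
    Gaussian noise.

    The noise sd is either given directly (``sigma0``) or calibrated from
    ``target_snr_db`` so that the recording-level S1 SNR, measured as
    ``20*log10(A_S1 / (4*sigma0))`` with ``A_S1`` the median clean
    peak-to-peak S1 amplitude, equals the target.

    Raises
    ------
    NoiseFloorError
        If the requested noise sd is zero or not finite (the SNR is
        undefined at ``sigma_N = 0``; a strictly positive noise floor is
        required).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = [s.name for s in component_specs]
    if sorted(names) != sorted(set(names)):
        raise InvalidSpecError("duplicate component names")
    n = int(round(duration_s * fs_hz))
    if n < fs_hz:
        raise ValueError("duration_s must be at least 1 s")

    # --- heart-rate process: R times with mild RR variability ----------
    rr_base = 60.0 / heart_rate_bpm
    r_times = [0.5]
    while True:
        rr = rr_base + rng.normal(0.0, rr_jitter_ms / 1000.0)
        rr = max(rr, 0.5 * rr_base)
        t_next = r_times[-1] + rr
        if t_next > duration_s - 0.1:
            break
        r_times.append(t_next)
    r_idx = np.asarray(np.round(np.asarray(r_times) * fs_hz), dtype=int)
    r_idx = r_idx[r_idx < n]

    # --- ECG: QRS spikes + same-polarity T-waves + small noise ---------
    ecg = rng.normal(0.0, ecg_noise_sd, n)
    t_axis = np.arange(n) / fs_hz
    qrs_sd, t_sd = 0.006, 0.040  # seconds
    for r in r_idx:
        tc = r / fs_hz
        lo = max(0, int((tc - 5 * qrs_sd) * fs_hz))
        hi = min(n, int((tc + 5 * qrs_sd) * fs_hz) + 1)
        ecg[lo:hi] += qrs_amplitude * np.exp(
            -0.5 * ((t_axis[lo:hi] - tc) / qrs_sd) ** 2)
        tw = tc + 0.280
        lo = max(0, int((tw - 4 * t_sd) * fs_hz))
        hi = min(n, int((tw + 4 * t_sd) * fs_hz) + 1)
        ecg[lo:hi] += t_wave_amplitude * np.exp(
            -0.5 * ((t_axis[lo:hi] - tw) / t_sd) ** 2)

    # --- PCG: components per full cycle + Gaussian noise ---------------
    clean = np.zeros(n)
    waves = {s.name: synthesize_component(s, fs_hz) for s in component_specs}
    beat_lat: dict[str, list[float]] = {s.name: [] for s in component_specs}
    for k in range(len(r_idx) - 1):  # last partial cycle carries no beat
        for s in component_specs:
            lat = s.latency_ms + rng.normal(0.0, latency_jitter_ms)
            center = r_idx[k] + int(round(lat / 1000.0 * fs_hz))
            _place(clean, waves[s.name], center)
            beat_lat[s.name].append((center - r_idx[k]) * 1000.0 / fs_hz)

    a_s1 = _clean_p2p(clean, r_idx, fs_hz, s1=True)
    a_s2 = _clean_p2p(clean, r_idx, fs_hz, s1=False)
    if sigma0 is None:
        if target_snr_db is None:
            raise ValueError("either sigma0 or target_snr_db is required")
        sigma0 = a_s1 / (4.0 * 10.0 ** (target_snr_db / 20.0))
    if not (np.isfinite(sigma0) and sigma0 > 0):
        raise NoiseFloorError(
            "noise sd must be finite and > 0: the SNR is undefined at sigma_N = 0")
    pcg = clean + rng.normal(0.0, sigma0, n)

    truth = GroundTruth(
        beat_latencies_ms={k: np.asarray(v) for k, v in beat_lat.items()},
        subject_latencies_ms={s.name: s.latency_ms for s in component_specs},
        sigma0=float(sigma0),
        s1_p2p=a_s1,
        s2_p2p=a_s2,
        r_peak_indices=r_idx,
        target_snr_db=target_snr_db,
    )
    return Recording(pcg=pcg, ecg=ecg, fs_hz=fs_hz, ground_truth=truth, label=label)


def _stratified_midpoints(n: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled midpoint quantiles (j-0.5)/n — a representative sample."""
    q = (np.arange(n) + 0.5) / n
    return rng.permutation(q)


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate a cohort of recordings per ``config``.

    Per-subject latencies are drawn from the configured population via a
    stratified (midpoint-quantile, shuffled) sample of a single shared
    standard-normal score, mapped through each component's split-normal
    quantile function.  Sharing one score across components models the
    common electromechanical scaling across a subject's four latencies
    and guarantees the physiologic orderings (mitral before tricuspid,
    aortic before pulmonary); the stratification makes small cohorts
    representative of the configured quantiles while cohort statistics
    still converge to the population values as ``n_subjects`` grows.
    Initial target SNRs are likewise spread evenly over
    ``target_snr_db_range``.  Fixing ``config.seed`` fixes every sample.
    """
    rng = np.random.default_rng(config.seed)
    nsub = config.n_subjects
    z = ndtri(_stratified_midpoints(nsub, rng))
    lo, hi = config.target_snr_db_range
    snr = lo + _stratified_midpoints(nsub, rng) * (hi - lo)
    hr = np.clip(
        rng.normal(config.heart_rate_bpm_mean, config.heart_rate_bpm_sd, nsub),
        40.0, 100.0)

    base = {s.name: s for s in DEFAULT_COMPONENTS}
    cohort = []
    for j in range(nsub):
        specs = tuple(
            replace(base[name], latency_ms=config.latency_population[name].value_at_z(z[j]))
            for name in COMPONENT_NAMES
        )
        cohort.append(generate_recording(
            duration_s=config.record_duration_s,
            fs_hz=config.fs_hz,
            heart_rate_bpm=float(hr[j]),
            target_snr_db=float(snr[j]),
            component_specs=specs,
            rng=rng,
            label=f"subj{j + 1:02d}",
        ))
    return cohort
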