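"""External-validation stage: ECG admissibility filters and sensitivity.

Recordings from an external database are admitted only when their ECG
supports reliable R-peak referencing:

1. the R-peak amplitude is at least three times the amplitude of the ECG
   noise 95% band (4 sigma, measured in the 70–85% cycle windows);
2. the R-wave has the same polarity as the T-wave (dominant deflection
   150–400 ms after R).

Additionally, only recordings whose initial SNR (both sounds) exceeds
14 dB before corruption are used.  Each admitted recording is then
degraded down to the population minimum acceptable SNR for every
(component, uncertainty) pair; the validation sensitivity at an
uncertainty level is the fraction of admitted recordings whose latency
estimates all stay within the band of their own high-SNR reference.
For the zero-uncertainty column the band is the 95% confidence interval
of the latency estimate (mean +/- 1.96 sd/sqrt(n_beats)) rather than
1 ms, which accounts for short validation records with few beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degradation import SensitivityCurve, sensitivity_curve
from .latency import COMPONENT_FIELDS, estimate_recording_latencies
from .segmentation import BeatSegmentation, UnsegmentableEcgError, segment_recording
from .simulate import Recording
from .snr import compute_recording_snr, estimate_noise_sigma

__all__ = [
    "EcgQualityVerdict",
    "ValidationReport",
    "ecg_quality_filter",
    "select_validation_recordings",
    "compute_validation_sensitivity",
]


@dataclass
class EcgQualityVerdict:
    r_amplitude_ratio: float
    polarity_match: bool
    passed: bool
    reasons: list[str] = field(default_factory=list)


def ecg_quality_filter(
    recording: Recording,
    segmentation: BeatSegmentation | None = None,
    min_ratio: float = 3.0,
) -> EcgQualityVerdict:
    """Check the two ECG admissibility criteria.

    The noise 95% band is ``4 sigma`` with sigma measured in the same
    70–85% cycle windows used for the PCG (consistency with the SNR
    noise convention).  The R amplitude is the median baseline-corrected
    ECG value at the detected R-peaks; criterion 1 passes when the
    amplitude-to-band ratio is at least ``min_ratio`` ("at least three
    times", boundary included).  T polarity is the sign of the largest
    deflection 150–400 ms after R, majority-voted over beats.
    """
    reasons: list[str] = []
    try:
        seg = segmentation or segment_recording(recording)
    except UnsegmentableEcgError as exc:
        return EcgQualityVerdict(float("nan"), False, False,
                                 [f"unsegmentable ECG: {exc}"])
    ecg = np.asarray(recording.ecg, dtype=float)
    fs = recording.fs_hz
    baseline = float(np.median(ecg))
    d = ecg - baseline

    sigmas = np.array([estimate_noise_sigma(ecg, w) for w in seg.noise_windows])
    sigmas = sigmas[np.isfinite(sigmas)]
    if len(sigmas) == 0:
        return EcgQualityVerdict(float("nan"), False, False,
                                 ["no usable ECG noise window"])
    band = 4.0 * float(np.median(sigmas))

    r_vals = d[seg.r_peaks]
    r_sign = 1.0 if np.median(r_vals) >= 0 else -1.0
    r_amp = float(np.median(np.abs(r_vals)))
    ratio = r_amp / band if band > 0 else float("inf")
    if ratio < min_ratio:
        reasons.append(
            f"R amplitude only {ratio:.2f}x the noise 95% band (need >= {min_ratio})")

    t_signs = []
    lo_off, hi_off = int(round(0.150 * fs)), int(round(0.400 * fs))
    for start, end in seg.cycles:
        lo, hi = start + lo_off, min(start + hi_off, end)
        if hi <= lo:
            continue
        w = d[lo:hi]
        t_signs.append(np.sign(w[np.argmax(np.abs(w))]))
    polarity = bool(t_signs) and float(np.median(t_signs)) * r_sign > 0
    if not polarity:
        reasons.append("T-wave polarity differs from R-wave polarity")

    return EcgQualityVerdict(ratio, polarity, not reasons, reasons)


def select_validation_recordings(
    recordings: list[Recording],
    min_initial_snr_db: float = 14.0,
) -> tuple[list[Recording], list[dict]]:
    """Admit recordings passing the ECG filter with initial SNR above
    ``min_initial_snr_db`` (strictly) for both sounds.

    Returns the admitted list and a per-recording report of verdicts.
    """
    admitted, report = [], []
    for rec in recordings:
        entry: dict[str, object] = {"label": rec.label}
        verdict = ecg_quality_filter(rec)
        entry["ecg_pass"] = verdict.passed
        entry["ecg_reasons"] = list(verdict.reasons)
        ok = verdict.passed
        if verdict.passed:
            seg = segment_recording(rec)
            rs = compute_recording_snr(rec.pcg, seg)
            entry["snr_s1_db"] = rs.snr_s1_db
            entry["snr_s2_db"] = rs.snr_s2_db
            if not (rs.snr_s1_db > min_initial_snr_db
                    and rs.snr_s2_db > min_initial_snr_db):
                ok = False
                entry["ecg_reasons"] = entry["ecg_reasons"] + [
                    f"initial SNR not above {min_initial_snr_db} dB"]
        entry["admitted"] = ok
        report.append(entry)
        if ok:
            admitted.append(rec)
    return admitted, report


@dataclass
class ValidationReport:
    """Per-uncertainty sensitivity of the population thresholds."""

    sensitivity: dict[float, float]
    n_admitted: int
    n_satisfying: dict[float, int]
    n_not_evaluable: dict[float, int]
    ci95_for_zero: bool = True


def _latency_at(curve: SensitivityCurve, comp: str, snr_db: float):
    grid, lat = curve.components[comp]
    if snr_db > grid[0] + 1e-9 or snr_db < grid[-1] - 1e-9:
        return None  # curve does not reach this SNR
    j = int(np.argmin(np.abs(grid - snr_db)))
    return float(lat[j])


def compute_validation_sensitivity(
    admitted: list[Recording],
    population_thresholds: dict[float, dict[str, float]],
    eps_list,
    *,
    curve_provider=None,
    n_runs: int = 10,
    seed: int | None = None,
    max_steps: int = 400,
) -> ValidationReport:
    """Fraction of admitted recordings staying in band at the population
    minimum acceptable SNR.

    ``population_thresholds`` maps eps -> component -> SNR threshold
    (dB).  A recording satisfies level eps when, for all four
    components, its median-curve latency at the population threshold
    stays within eps% of its own high-SNR reference (for eps = 0: within
    the CI95 of its per-beat latency estimate at the original SNR).
    Recordings whose curves do not reach a threshold SNR are counted as
    not evaluable at that level and are excluded from the denominator.

    ``curve_provider(recording) -> SensitivityCurve`` may be supplied to
    reuse precomputed curves; by default curves are built by running the
    degradation here.
    """
    rng = np.random.default_rng(seed)
    if curve_provider is None:
        def curve_provider(rec, _rng=rng):
            return sensitivity_curve(rec, n_runs=n_runs, rng=_rng,
                                     max_steps=max_steps)

    sensitivity: dict[float, float] = {}
    n_sat: dict[float, int] = {}
    n_ne: dict[float, int] = {}
    if len(eps_list) == 0:
        return ValidationReport({}, len(admitted), {}, {})

    prepared = []
    for rec in admitted:
        seg = segment_recording(rec)
        agg, per_beat = estimate_recording_latencies(rec.pcg, seg)
        ci95 = {}
        for comp, attr in COMPONENT_FIELDS.items():
            vals = np.array([ls.value(comp) for ls in per_beat])
            vals = vals[np.isfinite(vals)]
            ci95[comp] = (1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
                          if len(vals) > 1 else float("inf"))
        prepared.append((rec, curve_provider(rec), ci95))

    for eps in eps_list:
        sat = ne = evaluable = 0
        for rec, curve, ci95 in prepared:
            ok = True
            reachable = True
            for comp in COMPONENT_FIELDS:
                thr = population_thresholds[eps][comp]
                val = _latency_at(curve, comp, thr)
                if val is None:
                    reachable = False
                    break
                grid, lat = curve.components[comp]
                ref = float(lat[np.argmax(np.isfinite(lat))])
                half = ci95[comp] if eps == 0 else eps / 100.0 * abs(ref)
                if abs(val - ref) > half:
                    ok = False
            if not reachable:
                ne += 1
                continue
            evaluable += 1
            sat += ok
        n_sat[eps] = sat
        n_ne[eps] = ne
        sensitivity[eps] = sat / evaluable if evaluable else float("nan")
    return ValidationReport(sensitivity, len(admitted), n_sat, n_ne)
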