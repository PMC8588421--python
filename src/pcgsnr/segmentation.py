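"""ECG-referenced segmentation of the PCG into cardiac cycles.

The R-peaks of the simultaneous ECG delimit the cycles.  Within each
R-to-R cycle three half-open sample windows are laid out:

* the S1 search window, ``[R + 10 ms, R + 200 ms)``;
* the S2 search window, ``[start + 0.25 L, start + 0.55 L)``;
* the noise window, ``[start + 0.70 L, start + 0.85 L)`` — the span of
  the cycle where no heart sound is expected, used to estimate the noise
  statistics.

``L`` is the cycle length in samples.  Cycles shorter than 300 ms or
longer than 2 s are flagged and excluded as artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "BeatSegmentation",
    "UnsegmentableEcgError",
    "detect_r_peaks",
    "segment_cycles",
    "segment_recording",
]


class UnsegmentableEcgError(ValueError):
    """The ECG offers no usable R-peaks."""


@dataclass(frozen=True)
class SegmentationConfig:
    s1_window_ms: tuple[float, float] = (10.0, 200.0)
    s2_window_frac: tuple[float, float] = (0.25, 0.55)
    noise_window_frac: tuple[float, float] = (0.70, 0.85)
    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0
    refractory_ms: float = 200.0


@dataclass
class BeatSegmentation:
    """Per-cycle boundaries and search windows, all 0-based half-open."""

    r_peaks: np.ndarray
    cycles: list[tuple[int, int]]
    s1_windows: list[tuple[int, int]]
    s2_windows: list[tuple[int, int]]
    noise_windows: list[tuple[int, int]]
    fs_hz: float
    excluded: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.cycles)


def detect_r_peaks(
    ecg: np.ndarray,
    fs_hz: float,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Detect R-peak sample indices in the ECG.

    Polarity-robust: if the dominant deflection is negative the signal is
    flipped before thresholding at half the maximum deflection.  A
    refractory period of ``refractory_ms`` is enforced through the peak
    distance constraint.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs_hz:
        raise ValueError("ECG must be at least 2 s long")
    x = ecg - np.median(ecg)
    if -x.min() > x.max():  # inverted lead
        x = -x
    height = 0.5 * x.max()
    if not height > 0:
        raise UnsegmentableEcgError("flat ECG: no R-peaks found")
    distance = max(1, int(round(refractory_ms / 1000.0 * fs_hz)))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    if len(peaks) == 0:
        raise UnsegmentableEcgError("no R-peaks found")
    return peaks


def segment_cycles(
    r_peaks: np.ndarray,
    fs_hz: float,
    config: SegmentationConfig | None = None,
) -> BeatSegmentation:
    """Build cycles and per-cycle windows from consecutive R-peak pairs.

    The last partial cycle (after the final R-peak) is discarded — its
    end, and therefore its noise window, is undefined.  With fewer than
    two R-peaks the segmentation holds zero cycles.
    """
    cfg = config or SegmentationConfig()
    r_peaks = np.asarray(r_peaks, dtype=int)
    cycles, s1w, s2w, noisew, excluded = [], [], [], [], []
    for start, end in zip(r_peaks[:-1], r_peaks[1:]):
        start, end = int(start), int(end)
        length = end - start
        rr_ms = length * 1000.0 / fs_hz
        if rr_ms < cfg.rr_min_ms or rr_ms > cfg.rr_max_ms:
            reason = f"RR {rr_ms:.0f} ms outside [{cfg.rr_min_ms:.0f}, {cfg.rr_max_ms:.0f}] ms"
            logger.info("cycle [%d, %d) excluded: %s", start, end, reason)
            excluded.append((start, end, reason))
            continue
        cycles.append((start, end))
        s1_lo = start + int(round(cfg.s1_window_ms[0] / 1000.0 * fs_hz))
        s1_hi = min(end, start + int(round(cfg.s1_window_ms[1] / 1000.0 * fs_hz)))
        # keep the S1 search strictly before the S2 search on short cycles
        s1_hi = min(s1_hi, start + int(round(cfg.s2_window_frac[0] * length)))
        s1w.append((s1_lo, s1_hi))
        s2w.append((start + int(round(cfg.s2_window_frac[0] * length)),
                    start + int(round(cfg.s2_window_frac[1] * length))))
        noisew.append((start + int(round(cfg.noise_window_frac[0] * length)),
                       start + int(round(cfg.noise_window_frac[1] * length))))
    return BeatSegmentation(
        r_peaks=r_peaks, cycles=cycles, s1_windows=s1w, s2_windows=s2w,
        noise_windows=noisew, fs_hz=fs_hz, excluded=excluded)


def segment_recording(recording, config: SegmentationConfig | None = None) -> BeatSegmentation:
    """Detect R-peaks on the ECG channel and segment the recording."""
    cfg = config or SegmentationConfig()
    r = detect_r_peaks(recording.ecg, recording.fs_hz, cfg.refractory_ms)
    return segment_cycles(r, recording.fs_hz, cfg)
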