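"""Per-beat SNR quality metric for the first and second heart sounds.

The quality of a PCG recording is scored from the raw (unfiltered)
signal, per heartbeat and separately for S1 and S2:

    SNR = 20 * log10( A_S / (4 * sigma_N) )   [dB]

where ``A_S`` is the peak-to-peak amplitude of the heart sound of
interest within its search window and ``4 * sigma_N`` is the amplitude
of the 95% band of the noise, whose standard deviation ``sigma_N`` is
estimated in the 70–85% span of the same cycle where no heart sound is
expected.  The recording-level value is the median of the per-beat
values, which is robust to occasional artifact beats.

The Gaussian noise model behind the ``4 sigma`` band is checked with a
per-beat chi-square goodness-of-fit test against a normal distribution
with moments estimated from the noise segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import chi2

__all__ = [
    "BeatSNR",
    "RecordingSNR",
    "NoBeatsError",
    "estimate_noise_sigma",
    "compute_beat_snr",
    "compute_recording_snr",
    "test_noise_normality",
]


class NoBeatsError(ValueError):
    """No retained beat was available to compute a recording-level SNR."""


@dataclass
class BeatSNR:
    beat_index: int
    a_s1: float
    a_s2: float
    sigma_n: float
    snr_s1_db: float
    snr_s2_db: float
    valid: bool


@dataclass
class RecordingSNR:
    beats: list[BeatSNR]
    snr_s1_db: float
    snr_s2_db: float
    n_beats: int


def estimate_noise_sigma(pcg: np.ndarray, window: tuple[int, int]) -> float:
    """Sample standard deviation (mean removed) of the PCG in ``window``.

    Returns NaN for windows shorter than 10 samples, which flags the beat
    for exclusion.
    """
    lo, hi = window
    if hi - lo < 10:
        return float("nan")
    seg = np.asarray(pcg[lo:hi], dtype=float)
    return float(seg.std(ddof=1))


def _snr_db(a_s: float, sigma_n: float) -> float:
    if not (sigma_n > 0 and np.isfinite(sigma_n)):
        return float("nan")
    return 20.0 * math.log10(a_s / (4.0 * sigma_n))


def compute_beat_snr(pcg: np.ndarray, segmentation, beat_index: int) -> BeatSNR:
    """SNR of one retained beat, separately for S1 and S2.

    ``A_S`` is max minus min of the raw PCG within the sound's window.
    A zero (or undefined) ``sigma_N`` leaves both SNRs NaN and marks the
    beat invalid: the SNR is undefined without noise.
    """
    pcg = np.asarray(pcg, dtype=float)
    sigma = estimate_noise_sigma(pcg, segmentation.noise_windows[beat_index])
    lo, hi = segmentation.s1_windows[beat_index]
    a1 = float(np.ptp(pcg[lo:hi])) if hi > lo else float("nan")
    lo, hi = segmentation.s2_windows[beat_index]
    a2 = float(np.ptp(pcg[lo:hi])) if hi > lo else float("nan")
    s1 = _snr_db(a1, sigma) if np.isfinite(a1) else float("nan")
    s2 = _snr_db(a2, sigma) if np.isfinite(a2) else float("nan")
    valid = np.isfinite(s1) and np.isfinite(s2)
    return BeatSNR(beat_index, a1, a2, sigma, s1, s2, valid)


def compute_recording_snr(pcg: np.ndarray, segmentation) -> RecordingSNR:
    """Median per-beat SNR over all retained beats, per sound.

    Full precision is kept here; rounding to integer dB happens only at
    reporting time.
    """
    beats = [compute_beat_snr(pcg, segmentation, i)
             for i in range(segmentation.n_beats)]
    s1 = np.array([b.snr_s1_db for b in beats])
    s2 = np.array([b.snr_s2_db for b in beats])
    ok = np.isfinite(s1) & np.isfinite(s2)
    if not ok.any():
        raise NoBeatsError("no retained beat with a defined SNR")
    return RecordingSNR(
        beats=beats,
        snr_s1_db=float(np.median(s1[ok])),
        snr_s2_db=float(np.median(s2[ok])),
        n_beats=int(ok.sum()),
    )


def test_noise_normality(
    pcg: np.ndarray,
    segmentation,
    alpha: float = 0.05,
    min_beats: int = 20,
) -> float:
    """Fraction of noise windows compatible with a Gaussian noise model.

    Each beat's 70–85% noise segment is tested with a chi-square
    goodness-of-fit test against a normal distribution with mean and sd
    estimated from the segment itself.  Binning follows Sturges' rule
    with equiprobable bins under the fitted normal, so every expected
    count equals ``n / k``; the degrees of freedom are reduced by the two
    estimated parameters (df = k - 3).  Returns the fraction of tested
    beats where the null is *not* rejected at ``alpha``; segments too
    short to give at least five expected counts per bin are skipped and
    counted out.
    """
    pcg = np.asarray(pcg, dtype=float)
    if segmentation.n_beats < min_beats:
        raise ValueError(f"need at least {min_beats} beats, got {segmentation.n_beats}")
    tested = 0
    kept = 0
    for lo, hi in segmentation.noise_windows:
        seg = pcg[lo:hi]
        n = len(seg)
        k = int(math.ceil(math.log2(n) + 1)) if n > 1 else 0
        k = min(k, n // 5)
        if k < 4:
            continue  # too short for a meaningful test
        mu, sd = seg.mean(), seg.std(ddof=1)
        if not sd > 0:
            continue
        edges = mu + sd * ndtri(np.arange(1, k) / k)
        obs = np.histogram(seg, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
        expected = n / k
        stat = float(((obs - expected) ** 2 / expected).sum())
        p = float(chi2.sf(stat, df=k - 3))
        tested += 1
        if p >= alpha:
            kept += 1
    if tested == 0:
        raise ValueError("no noise segment long enough to test")
    return kept / tested


# not a pytest test, despite the statistical-test naming
test_noise_normality.__test__ = False
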