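"""Minimum acceptable SNR determination from sensitivity curves.

Scanning a median latency-vs-SNR curve in decreasing SNR order, the
minimum acceptable SNR is the SNR of the first latency measurement that
*significantly* differs from the reference (the latency at the highest
SNR grid point).  "Significantly different" requires both:

1. presence of a trend — a Wald–Wolfowitz runs test (alpha = 0.05) on
   the signs of the trailing deviations detects clustering (fewer runs
   than expected under randomness);
2. a deviation beyond the acceptable band — either more than 1 ms from
   the reference (absolute mode, matching a 1 ms acquisition
   resolution), or more than eps% of a population reference latency
   (percentage mode), for eps in {2.5, 5, ..., 20}.

If the conditions are never met, the threshold is not available (N/A).
Population tables aggregate per-subject thresholds by the worst case
(the maximum over subjects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .latency import COMPONENT_FIELDS

__all__ = [
    "UncertaintyBand",
    "TrendResult",
    "ThresholdResult",
    "DEFAULT_EPSILONS",
    "uncertainty_bounds",
    "runs_test_pvalue",
    "runs_test_trend",
    "find_min_acceptable_snr",
    "population_worst_case",
    "threshold_vs_uncertainty",
    "per_subject_threshold_table",
]

DEFAULT_EPSILONS = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)


@dataclass(frozen=True)
class UncertaintyBand:
    """Acceptable uncertainty band around a reference latency.

    In percentage mode the bounds are ``rs_ref * (1 +/- eps/100)``; in
    absolute mode they are ``rs_ref +/- 1 ms``.  During a curve scan the
    band's *half-width* is what matters: a point deviates when it lies
    more than the half-width away from the curve's own reference.
    """

    rs_ref_ms: float
    epsilon_pct: float | None = None
    absolute: bool = False

    @property
    def half_width_ms(self) -> float:
        if self.absolute:
            return 1.0
        return self.epsilon_pct / 100.0 * self.rs_ref_ms

    @property
    def lower_ms(self) -> float:
        return self.rs_ref_ms - self.half_width_ms

    @property
    def upper_ms(self) -> float:
        return self.rs_ref_ms + self.half_width_ms


def uncertainty_bounds(rs_ref_ms: float, epsilon_pct: float | None = None,
                       absolute_1ms: bool = False) -> UncertaintyBand:
    if not rs_ref_ms > 0:
        raise ValueError("rs_ref_ms must be positive")
    if absolute_1ms:
        return UncertaintyBand(rs_ref_ms, absolute=True)
    if epsilon_pct is None:
        raise ValueError("epsilon_pct required unless absolute_1ms")
    if epsilon_pct < 0:
        raise ValueError("epsilon_pct must be >= 0")
    return UncertaintyBand(rs_ref_ms, epsilon_pct=epsilon_pct)


# ---------------------------------------------------------------------
# Wald–Wolfowitz runs test, exact conditional distribution
# ---------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@lru_cache(maxsize=4096)
def _runs_pmf(n1: int, n2: int) -> np.ndarray:
    """pmf[r] = P(R = r) for runs of two kinds with n1, n2 elements."""
    n = n1 + n2
    pmf = np.zeros(n + 1)
    denom = _log_comb(np.array(n), np.array(n1))
    for r in range(2, n + 1):
        k = r // 2
        if r % 2 == 0:
            if k <= n1 and k <= n2:
                pmf[r] = 2 * math.exp(
                    _log_comb(np.array(n1 - 1), np.array(k - 1))
                    + _log_comb(np.array(n2 - 1), np.array(k - 1)) - denom)
        else:
            # r = 2k+1: either k+1 runs of the first kind and k of the
            # second, or vice versa
            total = 0.0
            for a, b in ((k + 1, k), (k, k + 1)):
                if 1 <= a <= n1 and 1 <= b <= n2:
                    total += math.exp(
                        _log_comb(np.array(n1 - 1), np.array(a - 1))
                        + _log_comb(np.array(n2 - 1), np.array(b - 1)) - denom)
            pmf[r] = total
    return pmf


def runs_test_pvalue(n1: int, n2: int, runs: int) -> float:
    """Two-sided exact mid-p value of the runs count given ``n1``, ``n2``.

    The mid-p convention (half weight on the observed runs count) is the
    standard remedy for the conservatism of discrete tests; it keeps the
    empirical size of the test close to the nominal alpha.
    """
    if n1 == 0 or n2 == 0:
        return float("nan")
    pmf = _runs_pmf(n1, n2)
    point = pmf[runs]
    lower = pmf[: runs + 1].sum() - 0.5 * point
    upper = pmf[runs:].sum() - 0.5 * point
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class TrendResult:
    trend: bool
    p_value: float
    runs: int
    n_pos: int
    n_neg: int


def runs_test_trend(deviations, alpha: float = 0.05,
                    min_length: int = 10) -> TrendResult:
    """Trend detection on a sequence of signed latency deviations.

    The test is applied to the sign sequence of the deviations about the
    reference (zeros dropped).  A trend is flagged when the two-sided
    exact runs-test p-value is below ``alpha`` *and* the runs count lies
    below its expectation (clustered signs — the alternation side is not
    a trend).  Degenerate cases follow fixed conventions: an all-zero or
    too-short sequence carries no trend; a single-sign sequence of at
    least ``min_length`` elements is maximal clustering and counts as a
    trend candidate (p reported as 0).
    """
    signs = np.sign(np.asarray(deviations, dtype=float))
    signs = signs[np.isfinite(signs) & (signs != 0)]
    n = len(signs)
    if n == 0:
        return TrendResult(False, 1.0, 0, 0, 0)
    n_pos = int((signs > 0).sum())
    n_neg = n - n_pos
    runs = 1 + int(np.count_nonzero(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        return TrendResult(n >= min_length, 0.0, runs, n_pos, n_neg)
    if n < min_length:
        return TrendResult(False, float("nan"), runs, n_pos, n_neg)
    p = runs_test_pvalue(n_pos, n_neg, runs)
    expected = 1.0 + 2.0 * n_pos * n_neg / n
    return TrendResult(p < alpha and runs < expected, p, runs, n_pos, n_neg)


# ---------------------------------------------------------------------
# Curve scan
# ---------------------------------------------------------------------

@dataclass
class ThresholdResult:
    component: str
    band: UncertaintyBand
    snr_db: float | None  # None = N/A (condition never met)
    trigger: tuple[float, float] | None = None  # (snr_db, latency_ms)
    n_skipped: int = 0

    @property
    def available(self) -> bool:
        return self.snr_db is not None


def find_min_acceptable_snr(
    grid_db: np.ndarray,
    latency_ms: np.ndarray,
    band: UncertaintyBand,
    alpha: float = 0.05,
    *,
    trend_window: int = 20,
    component: str = "",
) -> ThresholdResult:
    """Scan a median curve in decreasing SNR order for the breakdown point.

    ``grid_db`` must be descending.  The reference is the latency at the
    highest-SNR grid point.  At each candidate the runs test is applied
    to the trailing ``trend_window`` deviations (candidate included); the
    first candidate where a trend is present *and* the candidate's
    deviation exceeds the band half-width is the minimum acceptable SNR.
    Grid points with missing latency are skipped and counted.
    """
    grid_db = np.asarray(grid_db, dtype=float)
    latency_ms = np.asarray(latency_ms, dtype=float)
    if len(grid_db) != len(latency_ms):
        raise ValueError("grid and latency lengths differ")
    if len(grid_db) > 1 and grid_db[0] < grid_db[-1]:
        raise ValueError("grid_db must be in decreasing SNR order")
    finite = np.isfinite(latency_ms)
    if not finite.any():
        raise ValueError("curve holds no finite latency")
    ref = latency_ms[np.argmax(finite)]
    dev = latency_ms - ref
    n_skipped = int((~finite).sum())
    for j in range(len(grid_db)):
        if not finite[j]:
            continue
        if not abs(dev[j]) > band.half_width_ms:
            continue
        window = dev[max(0, j - trend_window + 1): j + 1]
        if runs_test_trend(window[np.isfinite(window)], alpha).trend:
            return ThresholdResult(component, band, float(grid_db[j]),
                                   (float(grid_db[j]), float(latency_ms[j])),
                                   n_skipped)
    return ThresholdResult(component, band, None, None, n_skipped)


def population_worst_case(results: list[ThresholdResult]) -> tuple[float | None, int]:
    """Worst-case (maximum) threshold over subjects; N/A excluded.

    Returns ``(value_or_None, n_not_available)``.
    """
    values = [r.snr_db for r in results if r.available]
    n_na = sum(1 for r in results if not r.available)
    if not values:
        return None, n_na
    return max(values), n_na


def per_subject_threshold_table(
    curves: dict[str, "SensitivityCurve"],
    initial_snrs: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject minimum acceptable SNR at the 1-ms uncertainty.

    ``curves`` maps subject labels to their median sensitivity curves;
    ``initial_snrs`` optionally maps labels to (S1, S2) initial SNRs in
    dB, reported rounded to integer dB.  The last row holds the
    population worst case per component.  Missing thresholds are NaN
    (serialized as "N/A"/empty by the writers).
    """
    rows = []
    per_comp: dict[str, list[ThresholdResult]] = {c: [] for c in COMPONENT_FIELDS}
    for label, curve in curves.items():
        row: dict[str, object] = {"subject": label}
        if initial_snrs and label in initial_snrs:
            s1, s2 = initial_snrs[label]
            row["snr_s1_db"] = round(s1)
            row["snr_s2_db"] = round(s2)
        for comp in COMPONENT_FIELDS:
            grid, lat = curve.components[comp]
            ref = lat[np.argmax(np.isfinite(lat))]
            band = uncertainty_bounds(ref, absolute_1ms=True)
            res = find_min_acceptable_snr(grid, lat, band, alpha, component=comp)
            per_comp[comp].append(res)
            row[comp] = res.snr_db if res.available else np.nan
        rows.append(row)
    worst: dict[str, object] = {"subject": "worst case"}
    for comp in COMPONENT_FIELDS:
        value, _ = population_worst_case(per_comp[comp])
        worst[comp] = value if value is not None else np.nan
    rows.append(worst)
    return pd.DataFrame(rows)


def threshold_vs_uncertainty(
    curves: dict[str, "SensitivityCurve"],
    refs: dict[str, float],
    eps_list=DEFAULT_EPSILONS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Population worst-case minimum SNR per uncertainty level.

    ``refs`` holds the population reference latency per component (the
    cohort medians).  For a subject whose curve never leaves the band at
    some eps, the minimum SNR reached by that subject's curve stands in
    as its minimum acceptable value, so every cell is defined.  Rows are
    eps levels, columns components; values are non-increasing down each
    column as eps grows (band nesting).
    """
    records = []
    for eps in eps_list:
        row: dict[str, object] = {"epsilon_pct": eps}
        for comp in COMPONENT_FIELDS:
            values = []
            band = uncertainty_bounds(refs[comp], epsilon_pct=eps)
            for curve in curves.values():
                grid, lat = curve.components[comp]
                res = find_min_acceptable_snr(grid, lat, band, alpha,
                                              component=comp)
                values.append(res.snr_db if res.available
                              else curve.min_snr_reached(comp))
            row[comp] = max(values)
        records.append(row)
    return pd.DataFrame(records)
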