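import numpy as np
import pytest

from pcgsnr.degradation import SensitivityCurve
from pcgsnr.simulate import Recording, generate_recording
from pcgsnr.validation import (
    compute_validation_sensitivity,
    ecg_quality_filter,
    select_validation_recordings,
)

COMPS = ("mitral", "tricuspid", "aortic", "pulmonary")
REF = {"mitral": 44.0, "tricuspid": 77.0, "aortic": 368.0, "pulmonary": 392.0}


def _rec_with_ratio(target_ratio, seed=21):
    """Synthetic recording whose ECG R-to-noise-band ratio is ~target.

    Extra noise is added only inside the 70-85% cycle windows where the
    filter measures the noise band, so R-peak detection and the T-wave
    polarity vote are untouched.
    """
    from pcgsnr.segmentation import segment_recording
    from pcgsnr.snr import estimate_noise_sigma

    rec = generate_recording(20.0, 2000.0, 60.0, target_snr_db=20.0, seed=seed)
    seg = segment_recording(rec)
    base = ecg_quality_filter(rec, seg)
    sigma0 = float(np.median([estimate_noise_sigma(rec.ecg, w)
                              for w in seg.noise_windows]))
    sigma_target = sigma0 * base.r_amplitude_ratio / target_ratio
    extra = np.sqrt(sigma_target ** 2 - sigma0 ** 2)
    ecg = rec.ecg.copy()
    rng = np.random.default_rng(seed + 1)
    for lo, hi in seg.noise_windows:
        ecg[lo:hi] += rng.normal(0.0, extra, hi - lo)
    return Recording(rec.pcg, ecg, rec.fs_hz, label=rec.label)


class TestEcgQualityFilter:
    def test_default_synthetic_ecg_passes(self, rec20):
        verdict = ecg_quality_filter(rec20)
        assert verdict.passed and verdict.polarity_match
        assert verdict.r_amplitude_ratio > 3.0

    def test_ratio_just_above_boundary_passes(self):
        rec = _rec_with_ratio(3.3)
        verdict = ecg_quality_filter(rec)
        assert verdict.r_amplitude_ratio >= 3.0 and verdict.passed

    def test_ratio_below_boundary_fails_with_reason(self):
        rec = _rec_with_ratio(2.5)
        verdict = ecg_quality_filter(rec)
        assert verdict.r_amplitude_ratio < 3.0
        assert not verdict.passed
        assert any("noise 95% band" in r for r in verdict.reasons)

    def test_inverted_t_wave_fails_polarity(self):
        rec = generate_recording(20.0, 2000.0, 60.0, target_snr_db=20.0,
                                 seed=5, t_wave_amplitude=-0.25)
        verdict = ecg_quality_filter(rec)
        assert not verdict.polarity_match and not verdict.passed

    def test_unsegmentable_ecg_fails_with_reason(self):
        rec = Recording(np.random.default_rng(0).normal(0, 1, 8000),
                        np.zeros(8000), 2000.0)
        verdict = ecg_quality_filter(rec)
        assert not verdict.passed
        assert any("unsegmentable" in r for r in verdict.reasons)


class TestSelection:
    def test_snr_must_exceed_14_db_strictly(self):
        # ~12 dB recording: ECG fine, PCG too noisy -> excluded
        low = generate_recording(20.0, 2000.0, 60.0, target_snr_db=12.0, seed=31)
        high = generate_recording(20.0, 2000.0, 60.0, target_snr_db=22.0, seed=32)
        admitted, report = select_validation_recordings([low, high])
        assert admitted == [high]
        assert [r["admitted"] for r in report] == [False, True]
        assert any("14" in reason for reason in report[0]["ecg_reasons"])

    def test_all_failing_yields_empty_list(self):
        low = generate_recording(20.0, 2000.0, 60.0, target_snr_db=5.0, seed=33)
        admitted, report = select_validation_recordings([low])
        assert admitted == [] and len(report) == 1


def _flat_curve(ref_shift=0.0, lo=6.0, hi=20.0):
    grid = np.arange(int(hi * 10), int(lo * 10) - 1, -1) / 10
    comps = {c: (grid, np.full_like(grid, REF[c] + ref_shift)) for c in COMPS}
    return SensitivityCurve(components=comps, n_runs=1, run_curves=[])


def _deviating_curve(dev_pct, below_db=12.0):
    grid = np.arange(200, 59, -1) / 10
    comps = {}
    for c in COMPS:
        lat = np.full_like(grid, REF[c])
        lat[grid < below_db] = REF[c] * (1 + dev_pct / 100.0)
        comps[c] = (grid, lat)
    return SensitivityCurve(components=comps, n_runs=1, run_curves=[])


class TestValidationSensitivity:
    THRESHOLDS = {eps: {c: 10.0 for c in COMPS} for eps in (2.5, 5.0, 10.0)}

    def _admitted(self, n):
        return [generate_recording(15.0, 2000.0, 60.0, target_snr_db=20.0, seed=40 + i)
                for i in range(n)]

    def test_zero_estimator_noise_gives_sensitivity_one(self):
        recs = self._admitted(3)
        report = compute_validation_sensitivity(
            recs, self.THRESHOLDS, [2.5, 5.0],
            curve_provider=lambda rec: _flat_curve())
        assert report.sensitivity == {2.5: 1.0, 5.0: 1.0}

    def test_constructed_nine_of_ten_in_band(self):
        recs = self._admitted(10)
        curves = [_deviating_curve(7.0)] + [_flat_curve() for _ in range(9)]
        it = iter(curves)
        report = compute_validation_sensitivity(
            recs, self.THRESHOLDS, [5.0], curve_provider=lambda rec: next(it))
        assert report.sensitivity[5.0] == pytest.approx(0.9)

    def test_sensitivity_non_decreasing_in_epsilon(self):
        recs = self._admitted(4)
        curves = [_deviating_curve(3.0), _deviating_curve(7.0),
                  _flat_curve(), _flat_curve()]
        it = iter(curves)
        report = compute_validation_sensitivity(
            recs, self.THRESHOLDS, [2.5, 5.0, 10.0],
            curve_provider=lambda rec: next(it))
        vals = [report.sensitivity[e] for e in (2.5, 5.0, 10.0)]
        assert vals == sorted(vals)

    def test_unreachable_threshold_counted_not_evaluable(self):
        recs = self._admitted(2)
        curves = [_flat_curve(lo=12.0), _flat_curve()]  # first stops at 12 dB
        it = iter(curves)
        report = compute_validation_sensitivity(
            recs, self.THRESHOLDS, [5.0], curve_provider=lambda rec: next(it))
        assert report.n_not_evaluable[5.0] == 1
        assert report.sensitivity[5.0] == pytest.approx(1.0)

    def test_empty_eps_list_gives_empty_report(self):
        report = compute_validation_sensitivity([], {}, [])
        assert report.sensitivity == {} and report.n_admitted == 0
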