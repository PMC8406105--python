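"""Preprocessing pipeline: resampling, smoothing, delay, beats, filters."""

import numpy as np
import pytest
from dataclasses import replace

from openapco.preprocessing import (
    FilterReport,
    FilterThresholds,
    SmoothingParams,
    build_samples,
    co_to_sv,
    detect_beats,
    estimate_delay,
    lowess_smooth,
    quality_filter,
    resample_waveform,
    segment_waveform,
    shift_pac,
    split_on_gaps,
)
from openapco.synthetic import (
    SimConfig,
    emulate_apco,
    emulate_hr,
    emulate_pac,
    generate_case,
    inject_artifact,
)
from openapco.types import (
    Demographics,
    Device,
    PressureWaveform,
    Quantity,
    Sample,
    Sex,
    TrendSeries,
)


def lowess_oracle(y, x, frac):
    """Tri-cube weighted local-linear smoother, straight from the definition."""
    n = len(x)
    r = max(int(np.ceil(frac * n)), 2)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:r]
        dmax = d[idx].max()
        w = np.clip(1 - (d[idx] / dmax) ** 3, 0, 1) ** 3 if dmax > 0 else np.ones(r)
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        xm = (w * xw).sum() / sw
        ym = (w * yw).sum() / sw
        sxx = (w * (xw - xm) ** 2).sum()
        out[i] = ym + ((w * (xw - xm) * (yw - ym)).sum() / sxx) * (x[i] - xm) \
            if sxx > 1e-12 else ym
    return out


class TestResample:
    def test_constant_preserved(self):
        w = PressureWaveform(np.full(5000, 80.0), fs=500.0)
        out = resample_waveform(w, 100.0)
        assert len(out.values) == 1000
        assert np.allclose(out.values, 80.0, atol=1e-6)

    def test_sinusoid_amplitude_preserved(self):
        # 1-Hz content is far below the 50-Hz output Nyquist
        t = np.arange(5000) / 500.0
        w = PressureWaveform(90 + 10 * np.sin(2 * np.pi * 1.0 * t), fs=500.0)
        out = resample_waveform(w, 100.0)
        # FFT oracle: amplitude of the 1-Hz line on the interior
        interior = out.values[100:-100] - np.mean(out.values[100:-100])
        amp = np.ptp(interior) / 2
        assert abs(amp - 10.0) / 10.0 < 0.01

    def test_mains_noise_attenuated(self):
        rng = np.random.default_rng(0)
        t = np.arange(50000) / 500.0
        clean = 90 + 10 * np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + 5 * np.sin(2 * np.pi * 60.0 * t)
        out = resample_waveform(PressureWaveform(noisy, 500.0), 100.0)
        # FFT oracle on the output: 60 Hz aliases to 40 Hz at fs=100
        spec = np.abs(np.fft.rfft(out.values - out.values.mean()))
        freqs = np.fft.rfftfreq(len(out.values), 1 / 100.0)
        band = spec[(freqs > 39) & (freqs < 41)].max()
        line1hz = spec[(freqs > 0.9) & (freqs < 1.1)].max()
        input_ratio = 5.0 / 10.0
        output_ratio = band / line1hz
        assert 20 * np.log10(input_ratio / output_ratio) > 20  # > 20 dB down

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            resample_waveform(PressureWaveform(np.array([80.0]), 500.0), 100.0)


class TestSegment:
    @pytest.mark.parametrize(
        "dur_s,expected_starts",
        [(60.0, [0.0, 20.0, 40.0]), (19.99, []), (45.0, [0.0, 20.0])],
    )
    def test_window_count(self, dur_s, expected_starts):
        w = PressureWaveform(np.zeros(int(dur_s * 100)), fs=100.0)
        segs = segment_waveform(w)
        assert [t for t, _ in segs] == expected_starts
        assert all(len(s) == 2000 for _, s in segs)

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            segment_waveform(PressureWaveform(np.zeros(10000), fs=500.0))


class TestCoToSv:
    @pytest.mark.parametrize("co,hr,sv", [(5.0, 50.0, 100.0), (4.8, 80.0, 60.0)])
    def test_arithmetic(self, co, hr, sv):
        assert co_to_sv(co, hr) == pytest.approx(sv)

    def test_zero_hr_rejected(self):
        with pytest.raises(ValueError):
            co_to_sv(5.0, 0.0)


class TestSplitOnGaps:
    def _trend(self, times):
        return TrendSeries(np.asarray(times, float), np.zeros(len(times)),
                           Quantity.SV_ML, Device.APCO)

    def test_no_gap_one_chunk(self):
        chunks = split_on_gaps(self._trend(np.arange(0, 100, 2)))
        assert len(chunks) == 1

    def test_single_and_double_gaps(self):
        t1 = np.r_[np.arange(0, 100, 2), np.arange(400, 500, 2)]
        assert len(split_on_gaps(self._trend(t1))) == 2
        t2 = np.r_[np.arange(0, 100, 2), np.arange(350, 450, 2), np.arange(700, 800, 2)]
        assert len(split_on_gaps(self._trend(t2))) == 3

    def test_concatenation_is_identity(self):
        t = np.r_[np.arange(0, 100, 2), np.arange(400, 500, 2)]
        chunks = split_on_gaps(self._trend(t))
        assert np.array_equal(np.concatenate([c.times for c in chunks]), t)


class TestLowess:
    def test_linear_series_is_fixed_point(self):
        t = np.arange(0, 600, 2.0)
        tr = TrendSeries(t, 50 + 0.05 * t, Quantity.SV_ML, Device.APCO)
        out = lowess_smooth(tr, SmoothingParams(lam=0.03))
        assert np.max(np.abs(out.values - tr.values)) < 1e-9

    def test_matches_tricube_oracle_and_reduces_variance(self):
        rng = np.random.default_rng(3)
        t = np.arange(1000) * 2.0
        y = 70 + rng.normal(0, 5, 1000)
        tr = TrendSeries(t, y, Quantity.SV_ML, Device.APCO)
        out = lowess_smooth(tr, SmoothingParams(lam=0.03))
        oracle = lowess_oracle(y, t, 0.03)
        assert np.max(np.abs(out.values - oracle)) < 1e-6
        assert np.var(out.values) < np.var(y)

    def test_chunks_smoothed_independently(self):
        rng = np.random.default_rng(4)
        t = np.r_[np.arange(0, 200, 2.0), np.arange(500, 700, 2.0)]
        y = 70 + rng.normal(0, 5, len(t))
        tr = TrendSeries(t, y, Quantity.SV_ML, Device.APCO)
        whole = lowess_smooth(tr, SmoothingParams(lam=0.10))
        parts = [
            lowess_smooth(c, SmoothingParams(lam=0.10))
            for c in split_on_gaps(tr, 200.0)
        ]
        assert len(parts) == 2
        assert np.array_equal(
            whole.values, np.concatenate([p.values for p in parts])
        )

    def test_short_chunk_passes_through(self):
        tr = TrendSeries([0.0, 2.0], [70.0, 75.0], Quantity.SV_ML, Device.APCO)
        out = lowess_smooth(tr)
        assert np.array_equal(out.values, tr.values)

    def test_non_sv_quantity_rejected(self):
        tr = TrendSeries([0.0, 2.0, 4.0], [5, 5, 5], Quantity.CO_LMIN, Device.PAC)
        with pytest.raises(ValueError):
            lowess_smooth(tr)


class TestDelay:
    def _sv(self, times, values, device=Device.PAC):
        return TrendSeries(times, values, Quantity.SV_ML, device)

    def test_identity_gives_zero_lag(self):
        t = np.arange(0, 600, 2.0)
        v = 70 + 10 * np.sin(t / 60)
        tr = self._sv(t, v)
        assert estimate_delay(tr, tr, np.arange(0, 240, 2.0)) == 0.0

    def test_recovers_exact_delay(self):
        t = np.arange(0, 1200, 2.0)
        v = 70 + 10 * np.sin(t / 60) + 5 * np.sin(t / 17)
        ref = self._sv(t, v)
        delayed = self._sv(t + 120.0, v)
        assert estimate_delay(delayed, ref, np.arange(0, 240, 2.0)) == 120.0

    def test_noisy_recovery_within_4s(self):
        # Monte-Carlo against the known 120-s injected delay
        t = np.arange(0, 3600, 2.0)
        lags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = 70 + 10 * np.sin(t / 60) + 5 * np.sin(t / 23)
            ref = self._sv(t, v)
            noisy = self._sv(t + 120.0, v + rng.normal(0, 2.0, len(t)))
            lags.append(estimate_delay(noisy, ref, np.arange(0, 240, 2.0)))
        assert abs(np.median(lags) - 120.0) <= 4.0

    def test_empty_grid_rejected(self):
        tr = self._sv(np.arange(0, 10, 2.0), np.zeros(5))
        with pytest.raises(ValueError):
            estimate_delay(tr, tr, [])


class TestShiftPac:
    def _sv(self, times, values):
        return TrendSeries(times, values, Quantity.SV_ML, Device.PAC)

    def test_zero_delay_identity(self):
        tr = self._sv(np.arange(0, 10, 2.0), np.arange(5.0))
        out = shift_pac(tr, 0.0)
        assert np.array_equal(out.times, tr.times)
        assert np.array_equal(out.values, tr.values)

    def test_point_mapping_and_dropping(self):
        tr = self._sv(np.array([100.0, 400.0]), np.array([60.0, 65.0]))
        out = shift_pac(tr, 120.0)
        assert np.array_equal(out.times, [280.0])
        assert np.array_equal(out.values, [65.0])

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            shift_pac(self._sv(np.array([0.0]), np.array([70.0])), -5.0)


class TestDetectBeats:
    def test_regular_train_beat_count_and_intervals(self):
        rec, gt = generate_case(SimConfig(duration_s=30.0, noise_sd=0.5, seed=5))
        w100 = resample_waveform(rec.waveform, 100.0)
        ann = detect_beats(w100.values[:2000])
        true_beats = np.sum(gt.beat_onsets < 20.0)
        assert abs(ann.n_beats - true_beats) <= 1
        assert abs(np.mean(ann.intervals) - 0.8) < 0.01

    def test_flatline_has_no_beats(self):
        ann = detect_beats(np.full(2000, 80.0))
        assert ann.n_beats == 0

    def test_premature_beats_flagged(self):
        rec, gt = generate_case(SimConfig(duration_s=60.0, seed=6))
        rec2, _ = inject_artifact(rec, gt, "vpb_burst", (20.0, 40.0))
        w100 = resample_waveform(rec2.waveform, 100.0)
        seg = w100.values[2000:4000]  # the corrupted window
        ann = detect_beats(seg)
        assert np.mean(ann.vpb_flags) > 0.3

    def test_pulse_pressure_matches_simulated_sv(self):
        cfg = SimConfig(duration_s=30.0, noise_sd=0.5, seed=7)
        rec, gt = generate_case(cfg)
        w100 = resample_waveform(rec.waveform, 100.0)
        ann = detect_beats(w100.values[:2000])
        expected_pp = cfg.sv_to_pp_gain * cfg.sv_base
        assert abs(np.mean(ann.pulse_pressures) - expected_pp) < 3 * cfg.noise_sd


def _mk_sample(segment, sv=70.0):
    return Sample(
        segment=segment,
        target_sv=sv,
        demographics=Demographics(60, Sex.MALE, 165, 65),
        source=Device.APCO,
        t_start=0.0,
        case_id="c",
    )


@pytest.fixture(scope="module")
def clean_segment():
    rec, _ = generate_case(SimConfig(duration_s=30.0, seed=8))
    return resample_waveform(rec.waveform, 100.0).values[:2000]


class TestQualityFilter:
    def test_clean_segment_kept(self, clean_segment):
        s = _mk_sample(clean_segment, 70.0)
        keep, reason = quality_filter(s, detect_beats(clean_segment))
        assert keep and reason is None

    def test_low_pressure_rejected(self, clean_segment):
        seg = clean_segment.copy()
        seg[100] = 20.0  # a single out-of-range pressure sample suffices
        s = _mk_sample(seg)
        keep, reason = quality_filter(s, detect_beats(seg))
        assert not keep and reason == "pressure_range"

    @pytest.mark.parametrize("sv", [210.0, 15.0])
    def test_sv_out_of_range_rejected(self, clean_segment, sv):
        s = _mk_sample(clean_segment, sv)
        keep, reason = quality_filter(s, detect_beats(clean_segment))
        assert not keep and reason == "sv_range"

    def test_low_pulse_pressure_rejected(self, clean_segment):
        mid = np.median(clean_segment)
        seg = mid + 0.2 * (clean_segment - mid)  # compress to ~7 mmHg
        s = _mk_sample(seg)
        keep, reason = quality_filter(s, detect_beats(seg))
        assert not keep and reason == "pulse_pressure"

    def test_missing_data_rejected(self, clean_segment):
        seg = clean_segment.copy()
        seg[5] = np.nan
        s = _mk_sample(seg)
        keep, reason = quality_filter(s, detect_beats(seg))
        assert not keep and reason == "missing_data"


class TestBuildSamples:
    def test_clean_apco_case_keeps_everything(self, apco_samples):
        samples, report, gt = apco_samples
        assert report.n_in == 30
        assert report.n_kept == 30 == len(samples)
        assert report.n_rejected == 0

    def test_artifact_segments_rejected_with_reason(self):
        rec, gt = generate_case(SimConfig(duration_s=600.0, seed=15))
        rec = replace(rec, trends=[emulate_apco(gt, fluct_sd=8.0, seed=16)])
        rec, gt = inject_artifact(rec, gt, "hypotension_clip", (100.0, 130.0))
        samples, report = build_samples(rec, Device.APCO)
        assert set(gt.corrupted) == {5, 6}
        assert report.rejections["pressure_range"] == 2
        kept_idx = {int(s.t_start // 20) for s in samples}
        assert kept_idx.isdisjoint(gt.corrupted)

    def test_pac_requires_hr_channel(self):
        rec, gt = generate_case(SimConfig(duration_s=120.0, seed=17))
        rec = replace(rec, trends=[emulate_pac(gt)])
        with pytest.raises(ValueError, match="heart-rate"):
            build_samples(rec, Device.PAC)

    def test_pac_targets_track_true_sv(self, pac_samples):
        samples, report, gt = pac_samples
        assert report.n_kept == len(samples) > 0
        errs = [abs(s.target_sv - 70.0) for s in samples]
        assert np.mean(errs) < 2.0  # device smoothing bounds the residual

    def test_deterministic(self):
        rec, gt = generate_case(SimConfig(duration_s=200.0, seed=18))
        rec = replace(rec, trends=[emulate_apco(gt, fluct_sd=8.0, seed=19)])
        s1, _ = build_samples(rec, Device.APCO)
        s2, _ = build_samples(rec, Device.APCO)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.segment, b.segment)
            assert a.target_sv == b.target_sv


class TestFilterReportConservation:
    def test_counts_conserved_across_random_corpora(self):
        from openapco.synthetic import generate_corpus

        recs, gts = generate_corpus(6, role_mix=(0.5, 0.5), seed=21,
                                    artifact_rate=0.8)
        for rec in recs:
            role = Device.APCO if rec.get_trend(Device.APCO, Quantity.SV_ML) else Device.PAC
            _, report = build_samples(rec, role)
            assert report.n_in == report.n_kept + report.n_rejected
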