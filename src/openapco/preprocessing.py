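"""Waveform-to-sample preprocessing.

Turns a :class:`~openapco.types.CaseRecord` into quality-controlled training
samples in four steps:

1. convert pulmonary-artery-catheter (PAC) cardiac output to stroke volume
   (SV = 1000 * CO / HR, mL per beat);
2. smooth the fluctuating arterial-pressure-based (APCO) SV trend with
   LOWESS (span fraction lambda, applied independently per recording chunk
   when the trend has gaps longer than 200 s);
3. shift PAC values 2 minutes earlier to undo the monitor's trend-mode lag
   (the lag itself is recoverable with :func:`estimate_delay`);
4. reject unsuitable 20-s segments: pressure outside 25-250 mmHg, target SV
   outside 20-200 mL, heart rate outside 30-180 beats/min, mean pulse
   pressure under 20 mmHg, or frequent (>50%) ventricular premature beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .types import (
    SEGMENT_FS,
    SEGMENT_LENGTH,
    SEGMENT_SECONDS,
    CaseRecord,
    Device,
    PressureWaveform,
    Quantity,
    Sample,
    TrendSeries,
)

__all__ = [
    "BeatAnnotation",
    "FilterReport",
    "SmoothingParams",
    "FilterThresholds",
    "resample_waveform",
    "segment_waveform",
    "co_to_sv",
    "split_on_gaps",
    "lowess_smooth",
    "estimate_delay",
    "shift_pac",
    "detect_beats",
    "quality_filter",
    "build_samples",
]

REJECTION_REASONS = (
    "pressure_range",
    "sv_range",
    "hr_range",
    "pulse_pressure",
    "vpb_frequent",
    "missing_data",
)


@dataclass
class BeatAnnotation:
    """Per-beat annotation of one pressure segment."""

    beat_onsets: np.ndarray  # diastolic onset indices
    systolic_peaks: np.ndarray  # indices
    systolic_values: np.ndarray  # mmHg
    diastolic_mins: np.ndarray  # indices
    diastolic_values: np.ndarray  # mmHg
    pulse_pressures: np.ndarray  # mmHg per beat
    intervals: np.ndarray  # s per beat (peak-to-peak, one fewer than beats)
    vpb_flags: np.ndarray  # bool per beat

    @property
    def n_beats(self) -> int:
        return len(self.systolic_peaks)

    def mean_hr(self) -> float:
        """Segment heart rate from mean peak-to-peak interval (beats/min)."""
        if len(self.intervals) == 0:
            return float("nan")
        return 60.0 / float(np.mean(self.intervals))


@dataclass
class FilterReport:
    """Bookkeeping of segment rejection; conserves n_in = n_kept + rejected."""

    n_in: int = 0
    n_kept: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECTION_REASONS}
    )

    def add(self, reason: str | None) -> None:
        self.n_in += 1
        if reason is None:
            self.n_kept += 1
        else:
            if reason not in self.rejections:
                raise KeyError(f"unknown rejection reason {reason!r}")
            self.rejections[reason] += 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())

    def check_conservation(self) -> None:
        if self.n_in != self.n_kept + self.n_rejected:
            raise AssertionError("filter report does not conserve counts")


@dataclass
class SmoothingParams:
    """LOWESS span fraction and the gap length that splits a trend."""

    lam: float = 0.03
    max_gap_s: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.lam <= 1:
            raise ValueError("smoothing fraction must be in (0, 1]")


@dataclass
class FilterThresholds:
    """Quality-filter thresholds (defaults are the clinical rejection rules)."""

    pressure_min: float = 25.0  # mmHg
    pressure_max: float = 250.0
    sv_min: float = 20.0  # mL
    sv_max: float = 200.0
    hr_min: float = 30.0  # beats/min
    hr_max: float = 180.0
    pulse_pressure_min: float = 20.0  # mmHg
    vpb_fraction_max: float = 0.5
    # beat flagged as ventricular premature when BOTH fall below these
    # fractions of the segment's 90th-percentile interval / pulse pressure
    vpb_interval_frac: float = 0.75
    vpb_pp_frac: float = 0.75


# ---------------------------------------------------------------------------
# step 0: resampling and slicing


def resample_waveform(w: PressureWaveform, fs_out: float) -> PressureWaveform:
    """Resample a pressure waveform to ``fs_out`` with anti-alias filtering.

    Uses polyphase resampling, so content above the output Nyquist is
    attenuated before decimation. Duration is preserved to within one
    output sample.
    """
    if fs_out <= 0:
        raise ValueError("output rate must be positive")
    if len(w.values) < 2:
        raise ValueError("waveform too short to resample")
    if fs_out == w.fs:
        return PressureWaveform(w.values.copy(), w.fs, w.t0)
    from fractions import Fraction

    frac = Fraction(fs_out / w.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(w.values, up, down, padtype="line")
    return PressureWaveform(out, fs_out, w.t0)


def segment_waveform(
    w: PressureWaveform, seg_len_s: float = SEGMENT_SECONDS
) -> list[tuple[float, np.ndarray]]:
    """Slice a 100-Hz waveform into consecutive non-overlapping windows.

    Returns ``(t_start, segment)`` pairs; a trailing partial window is
    discarded.
    """
    if w.fs != SEGMENT_FS:
        raise ValueError(f"expected a {SEGMENT_FS:.0f}-Hz waveform, got {w.fs} Hz")
    n = int(round(seg_len_s * w.fs))
    out = []
    for start in range(0, len(w.values) - n + 1, n):
        out.append((w.t0 + start / w.fs, w.values[start : start + n]))
    return out


# ---------------------------------------------------------------------------
# step 1: CO -> SV


def co_to_sv(co: float | np.ndarray, hr: float | np.ndarray) -> float | np.ndarray:
    """Convert cardiac output (L/min) to stroke volume (mL) via SV = CO/HR."""
    hr_arr = np.asarray(hr, dtype=float)
    if np.any(hr_arr <= 0):
        raise ValueError("heart rate must be positive to convert CO to SV")
    out = 1000.0 * np.asarray(co, dtype=float) / hr_arr
    return float(out) if np.isscalar(co) or np.ndim(co) == 0 else out


# ---------------------------------------------------------------------------
# step 2: gap splitting + LOWESS smoothing


def split_on_gaps(t: TrendSeries, max_gap_s: float = 200.0) -> list[TrendSeries]:
    """Split a trend wherever successive timestamps differ by > ``max_gap_s``."""
    if len(t) == 0:
        return [t]
    cut = np.flatnonzero(np.diff(t.times) > max_gap_s) + 1
    chunks = []
    for lo, hi in zip(np.r_[0, cut], np.r_[cut, len(t)]):
        chunks.append(
            TrendSeries(t.times[lo:hi], t.values[lo:hi], t.quantity, t.device)
        )
    return chunks


def lowess_smooth(t: TrendSeries, p: SmoothingParams | None = None) -> TrendSeries:
    """LOWESS-smooth a stroke-volume trend, independently per gap-split chunk.

    Classic locally weighted scatterplot smoothing: a degree-1 weighted fit
    with tri-cube weights over the nearest fraction ``lam`` of points
    (minimum 2), no robustness iterations. Chunks shorter than 3 points pass
    through unsmoothed. Output timestamps equal input timestamps.
    """
    p = p or SmoothingParams()
    if t.quantity is not Quantity.SV_ML:
        raise ValueError("lowess_smooth expects a stroke-volume trend")
    out_vals = []
    for chunk in split_on_gaps(t, p.max_gap_s):
        n = len(chunk)
        if n < 3:
            out_vals.append(chunk.values.copy())
            continue
        frac = max(p.lam, 2.0 / n)
        sm = _sm_lowess(
            chunk.values, chunk.times, frac=frac, it=0, return_sorted=False
        )
        out_vals.append(np.asarray(sm, dtype=float))
    return TrendSeries(t.times.copy(), np.concatenate(out_vals), t.quantity, t.device)


# ---------------------------------------------------------------------------
# step 3: PAC delay


def estimate_delay(
    trend: TrendSeries,
    reference: TrendSeries,
    lag_grid: np.ndarray | list[float],
    match_tol_s: float = 1.0,
) -> float:
    """Grid-search the lag by which ``trend`` trails ``reference``.

    For each candidate lag the trend is shifted earlier by that amount and
    compared with the reference over nearest-neighbour-matched timestamps
    (within ``match_tol_s``); the lag minimising the mean absolute
    difference wins, ties broken toward the smaller lag. Lags with no
    overlapping support are excluded; if none overlap an error is raised.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    if lag_grid.size == 0:
        raise ValueError("lag grid is empty")
    best_lag, best_mad = None, np.inf
    for lag in np.sort(lag_grid):
        t_shift = trend.times - lag
        idx = np.searchsorted(reference.times, t_shift)
        idx = np.clip(idx, 1, len(reference.times) - 1) if len(reference) > 1 else None
        if idx is None:
            raise ValueError("reference series too short")
        left = reference.times[idx - 1]
        right = reference.times[idx]
        use_left = (t_shift - left) <= (right - t_shift)
        nearest = np.where(use_left, idx - 1, idx)
        dist = np.abs(reference.times[nearest] - t_shift)
        ok = dist <= match_tol_s
        if not np.any(ok):
            continue
        mad = float(np.mean(np.abs(trend.values[ok] - reference.values[nearest[ok]])))
        if mad < best_mad - 1e-12:
            best_mad, best_lag = mad, float(lag)
    if best_lag is None:
        raise ValueError("no candidate lag had overlapping support")
    return best_lag


def shift_pac(
    t: TrendSeries, delay_s: float = 120.0, case_start: float = 0.0
) -> TrendSeries:
    """Shift a PAC trend ``delay_s`` earlier; points before case start drop."""
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    times = t.times - delay_s
    keep = times >= case_start
    return TrendSeries(times[keep], t.values[keep].copy(), t.quantity, t.device)


# ---------------------------------------------------------------------------
# step 4: beat detection + quality filtering


def detect_beats(
    segment: np.ndarray,
    fs: float = SEGMENT_FS,
    thresholds: FilterThresholds | None = None,
) -> BeatAnnotation:
    """Detect beats in one pressure segment and annotate their morphology.

    Threshold-free local-maxima detection: the segment is band-passed to
    0.5-10 Hz, maxima above the 60th percentile of the filtered signal with
    a 0.33-s refractory period (heart rate <= 180) mark candidate beats,
    and the raw-signal systolic peak / preceding diastolic minimum are then
    located per beat. A beat is flagged as a ventricular premature beat
    when both its peak-to-peak interval and its pulse pressure fall below
    0.75x the segment's 90th-percentile values — premature beats are early
    and under-filled, so both shrink together.
    """
    th = thresholds or FilterThresholds()
    segment = np.asarray(segment, dtype=float)
    empty = BeatAnnotation(*[np.array([]) for _ in range(7)], np.array([], dtype=bool))
    if len(segment) < fs or not np.all(np.isfinite(segment)):
        return empty
    sos = scipy.signal.butter(2, [0.5, 10.0], btype="bandpass", fs=fs, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, segment)
    if np.ptp(filt) < 1e-6:  # flatline
        return empty
    height = np.percentile(filt, 60)
    # prominence floor rejects baseline-noise maxima during long diastoles
    prominence = 0.25 * (np.percentile(filt, 98) - np.percentile(filt, 2))
    refractory = int(round(0.33 * fs))
    peaks, _ = scipy.signal.find_peaks(
        filt, height=height, distance=refractory, prominence=prominence
    )
    if len(peaks) < 2:
        return empty

    # refine: raw systolic peak near each filtered peak, diastolic minimum
    # in the stretch between the previous peak and this one
    half = int(round(0.15 * fs))
    sys_idx = np.empty(len(peaks), dtype=int)
    for i, pk in enumerate(peaks):
        lo, hi = max(0, pk - half), min(len(segment), pk + half + 1)
        sys_idx[i] = lo + int(np.argmax(segment[lo:hi]))
    dia_idx = np.empty(len(peaks), dtype=int)
    for i, pk in enumerate(sys_idx):
        lo = sys_idx[i - 1] if i > 0 else max(0, pk - int(round(1.5 * fs)))
        if lo >= pk:
            lo = max(0, pk - 1)
        dia_idx[i] = lo + int(np.argmin(segment[lo:pk])) if pk > lo else lo

    sys_val = segment[sys_idx]
    dia_val = segment[dia_idx]
    pp = sys_val - dia_val
    intervals = np.diff(sys_idx) / fs

    # VPB flags: interval of beat i = interval ending at beat i (first beat
    # inherits the following interval so every beat gets one)
    beat_int = np.r_[intervals[:1], intervals] if len(intervals) else np.array([])
    if len(beat_int):
        ref_int = np.percentile(beat_int, 90)
        ref_pp = np.percentile(pp, 90)
        vpb = (beat_int < th.vpb_interval_frac * ref_int) & (
            pp < th.vpb_pp_frac * ref_pp
        )
    else:
        vpb = np.zeros(len(sys_idx), dtype=bool)

    return BeatAnnotation(
        beat_onsets=dia_idx,
        systolic_peaks=sys_idx,
        systolic_values=sys_val,
        diastolic_mins=dia_idx,
        diastolic_values=dia_val,
        pulse_pressures=pp,
        intervals=intervals,
        vpb_flags=vpb,
    )


def quality_filter(
    s: Sample,
    b: BeatAnnotation,
    thresholds: FilterThresholds | None = None,
) -> tuple[bool, str | None]:
    """Decide whether a sample is usable; report the first failing rule.

    Rule order: missing pressure data, pressure range (per raw sample),
    target-SV range, heart-rate range (segment mean from beat intervals;
    fewer than 2 beats also fails here), mean pulse pressure, frequent
    ventricular premature beats.
    """
    th = thresholds or FilterThresholds()
    seg = s.segment
    if not np.all(np.isfinite(seg)) or not np.isfinite(s.target_sv):
        return False, "missing_data"
    if np.any(seg < th.pressure_min) or np.any(seg > th.pressure_max):
        return False, "pressure_range"
    if s.target_sv < th.sv_min or s.target_sv > th.sv_max:
        return False, "sv_range"
    hr = b.mean_hr()
    if not np.isfinite(hr) or hr < th.hr_min or hr > th.hr_max:
        return False, "hr_range"
    if float(np.mean(b.pulse_pressures)) < th.pulse_pressure_min:
        return False, "pulse_pressure"
    if float(np.mean(b.vpb_flags)) > th.vpb_fraction_max:
        return False, "vpb_frequent"
    return True, None


# ---------------------------------------------------------------------------
# full pipeline


def _target_trend(
    rec: CaseRecord,
    role: Device,
    p: SmoothingParams,
    pac_delay_s: float,
) -> TrendSeries:
    """Build the per-role stroke-volume target trend."""
    role = Device(role)
    if role is Device.APCO:
        sv = rec.get_trend(Device.APCO, Quantity.SV_ML)
        if sv is None:
            raise ValueError(f"case {rec.case_id}: APCO stroke-volume trend missing")
        return lowess_smooth(sv, p)
    if role is Device.PAC:
        co = rec.get_trend(Device.PAC, Quantity.CO_LMIN)
        hr = rec.get_trend(Device.MONITOR, Quantity.HR_BPM)
        if co is None:
            raise ValueError(f"case {rec.case_id}: PAC cardiac-output trend missing")
        if hr is None:
            raise ValueError(f"case {rec.case_id}: heart-rate trend missing")
        # nearest HR (within 2 s of cadence) for each CO tick
        idx = np.clip(np.searchsorted(hr.times, co.times), 1, max(len(hr) - 1, 1))
        left, right = hr.times[idx - 1], hr.times[np.minimum(idx, len(hr) - 1)]
        nearest = np.where(
            (co.times - left) <= (right - co.times), idx - 1, np.minimum(idx, len(hr) - 1)
        )
        sv_vals = co_to_sv(co.values, hr.values[nearest])
        sv = TrendSeries(co.times.copy(), sv_vals, Quantity.SV_ML, Device.PAC)
        return shift_pac(sv, pac_delay_s, case_start=rec.waveform.t0)
    raise ValueError(f"unsupported role {role}")


def build_samples(
    rec: CaseRecord,
    role: Device | str,
    p: SmoothingParams | None = None,
    thresholds: FilterThresholds | None = None,
    pac_delay_s: float = 120.0,
    seg_len_s: float = SEGMENT_SECONDS,
    target_tol_s: float = 2.0,
) -> tuple[list[Sample], FilterReport]:
    """Run the full preprocessing pipeline on one case.

    resample -> slice into 20-s segments -> build the role's target trend
    (APCO: gap-split + LOWESS; PAC: CO->SV conversion + 2-min shift) ->
    pair each segment with the trend value nearest its end (within
    ``target_tol_s``) -> beat detection -> quality filter. The report
    accounts for every candidate segment.
    """
    role = Device(role)
    p = p or SmoothingParams()
    th = thresholds or FilterThresholds()
    target = _target_trend(rec, role, p, pac_delay_s)

    w100 = resample_waveform(rec.waveform, SEGMENT_FS)
    report = FilterReport()
    kept: list[Sample] = []
    for t_start, seg in segment_waveform(w100, seg_len_s):
        t_end = t_start + seg_len_s
        if len(target) == 0:
            report.add("missing_data")
            continue
        j = int(np.argmin(np.abs(target.times - t_end)))
        if abs(target.times[j] - t_end) > target_tol_s:
            report.add("missing_data")
            continue
        sample = Sample(
            segment=seg.copy(),
            target_sv=float(target.values[j]),
            demographics=rec.demographics,
            source=role,
            t_start=float(t_start),
            case_id=rec.case_id,
        )
        ann = detect_beats(seg, SEGMENT_FS, th)
        keep, reason = quality_filter(sample, ann, th)
        report.add(reason)
        if keep:
            kept.append(sample)
    report.check_conservation()
    return kept, report
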