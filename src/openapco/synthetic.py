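"""Synthetic hemodynamic case generator with exact ground truth.

Builds pulsatile arterial pressure waveforms beat by beat: each beat is a
diastolic baseline plus a smooth unimodal systolic bump and a delayed
dicrotic bump (two windowed raised cosines), with the beat's pulse pressure
set to ``sv_to_pp_gain`` times its true stroke volume. This makes the
SV <-> waveform-morphology link exact and invertible, which is what the
test suite needs; physiological realism (Windkessel dynamics, reflected
waves) is deliberately out of scope.

The generator also emulates the two monitoring channels the preprocessing
pipeline is built around: a noisy APCO-like SV trend (large fluctuations
that LOWESS smoothing should remove) and a smoothed, time-delayed PAC-like
CO trend (the trend-mode lag that the 2-minute shift undoes), plus artifact
injection where each artifact kind is constructed to trip exactly one
quality filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    SEGMENT_SECONDS,
    CaseRecord,
    Demographics,
    Device,
    PressureWaveform,
    Quantity,
    Sample,
    Sex,
    SurgeryType,
    TrendSeries,
)

__all__ = [
    "PulseShape",
    "SimConfig",
    "GroundTruth",
    "generate_case",
    "emulate_apco",
    "emulate_pac",
    "inject_artifact",
    "generate_corpus",
    "CorpusConfig",
]

ARTIFACT_KINDS = ("hypotension_clip", "flatline", "low_pp", "vpb_burst", "sv_outlier")

#: quality-filter rejection reason that each artifact kind is built to trip
ARTIFACT_REASON = {
    "hypotension_clip": "pressure_range",
    "flatline": "hr_range",
    "low_pp": "pulse_pressure",
    "vpb_burst": "vpb_frequent",
    "sv_outlier": "sv_range",
}


@dataclass
class PulseShape:
    """Morphology of one synthetic beat."""

    systolic_width_s: float = 0.30
    dicrotic_amp_frac: float = 0.12
    # kept inside the beat detector's 0.33-s refractory period so the
    # dicrotic wave is never mistaken for a separate beat
    dicrotic_delay_s: float = 0.30
    dicrotic_width_s: float = 0.16


@dataclass
class SimConfig:
    """Study conditions for one synthetic case.

    Defaults describe a stable adult intraoperative recording: 10 minutes,
    heart rate wandering around 75 beats/min, stroke volume around 70 mL,
    mean pressure near 90 mmHg, 0.5 mmHg of pulse pressure per mL of stroke
    volume (SV 70 -> pulse pressure 35 mmHg) and 1 mmHg of additive
    measurement noise.
    """

    duration_s: float = 600.0
    hr_base: float = 75.0  # beats/min
    hr_walk_sd: float = 0.0  # per-beat random-walk step, beats/min
    sv_base: float = 70.0  # mL
    sv_walk_sd: float = 0.0  # per-beat random-walk step, mL
    map_baseline: float = 90.0  # mmHg
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    sv_to_pp_gain: float = 0.5  # mmHg per mL
    sv_clip: tuple[float, float] = (30.0, 150.0)  # random-walk bounds, mL
    noise_sd: float = 1.0  # mmHg
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 20 < self.hr_base < 220:
            raise ValueError("heart rate outside plausible range (20, 220)")
        if not 10 < self.sv_base < 250:
            raise ValueError("stroke volume outside plausible range (10, 250)")


@dataclass
class GroundTruth:
    """Exact per-beat truth plus corruption bookkeeping for one case."""

    beat_onsets: np.ndarray  # s
    beat_sv: np.ndarray  # mL, per beat
    beat_hr: np.ndarray  # beats/min, per beat
    segment_sv: np.ndarray  # mL, mean true SV per 20-s segment
    corrupted: dict[int, str] = field(default_factory=dict)  # segment -> artifact kind
    config: SimConfig | None = None

    def segment_index(self, t: float) -> int:
        return int(t // SEGMENT_SECONDS)

    def sv_at(self, times: np.ndarray) -> np.ndarray:
        """True SV of the beat containing each query time."""
        idx = np.clip(
            np.searchsorted(self.beat_onsets, times, side="right") - 1,
            0,
            len(self.beat_sv) - 1,
        )
        return self.beat_sv[idx]

    def hr_at(self, times: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.beat_onsets, times, side="right") - 1,
            0,
            len(self.beat_hr) - 1,
        )
        return self.beat_hr[idx]


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth unimodal bump on [center - width/2, center + width/2], peak 1."""
    x = (t - center) / width
    out = np.zeros_like(t)
    mask = np.abs(x) < 0.5
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * math.pi * x[mask]))
    return out


def _beat_waveform(
    t_rel: np.ndarray, pp: float, dia: float, shape: PulseShape, interval: float
) -> np.ndarray:
    """Pressure of one beat sampled at times ``t_rel`` from its onset."""
    w_sys = min(shape.systolic_width_s, 0.8 * interval)
    sys_center = 0.5 * w_sys
    bump = _raised_cosine(t_rel, sys_center, w_sys)
    dic_center = min(shape.dicrotic_delay_s, 0.7 * interval)
    bump = bump + shape.dicrotic_amp_frac * _raised_cosine(
        t_rel, dic_center, min(shape.dicrotic_width_s, 0.4 * interval)
    )
    # normalise so the systolic peak equals exactly dia + pp
    return dia + pp * bump / max(bump.max(), 1.0)


def generate_case(
    cfg: SimConfig, case_id: str = "sim", demographics: Demographics | None = None
) -> tuple[CaseRecord, GroundTruth]:
    """Synthesise one case: waveform built beat by beat, truth recorded.

    Deterministic given ``cfg.seed``. Beat schedule and per-beat SV use one
    random stream, additive noise another, so two seeds differing only in
    noise keep the same beat schedule only if the walk SDs are zero.
    """
    rng_traj = np.random.default_rng(cfg.seed)
    rng_noise = np.random.default_rng(cfg.seed + 1_000_003)

    onsets, svs, hrs = [], [], []
    t, hr, sv = 0.0, cfg.hr_base, cfg.sv_base
    while t < cfg.duration_s:
        onsets.append(t)
        svs.append(sv)
        hrs.append(hr)
        t += 60.0 / hr
        hr = float(np.clip(hr + cfg.hr_walk_sd * rng_traj.standard_normal(), 30, 180))
        sv = float(np.clip(sv + cfg.sv_walk_sd * rng_traj.standard_normal(), *cfg.sv_clip))
    onsets_a = np.array(onsets)
    svs_a = np.array(svs)
    hrs_a = np.array(hrs)

    n = int(round(cfg.duration_s * cfg.fs))
    times = np.arange(n) / cfg.fs
    values = np.empty(n)
    bounds = np.r_[onsets_a, cfg.duration_s]
    for i in range(len(onsets_a)):
        lo = int(np.ceil(bounds[i] * cfg.fs))
        hi = min(int(np.ceil(bounds[i + 1] * cfg.fs)), n)
        if hi <= lo:
            continue
        pp = cfg.sv_to_pp_gain * svs_a[i]
        dia = cfg.map_baseline - pp / 3.0  # MAP ~ diastolic + PP/3
        interval = bounds[i + 1] - bounds[i]
        values[lo:hi] = _beat_waveform(
            times[lo:hi] - bounds[i], pp, dia, cfg.pulse_shape, interval
        )
    values += cfg.noise_sd * rng_noise.standard_normal(n)

    n_seg = int(cfg.duration_s // SEGMENT_SECONDS)
    seg_sv = np.empty(n_seg)
    for k in range(n_seg):
        in_seg = (onsets_a >= k * SEGMENT_SECONDS) & (
            onsets_a < (k + 1) * SEGMENT_SECONDS
        )
        seg_sv[k] = svs_a[in_seg].mean() if in_seg.any() else np.nan

    demo = demographics or Demographics(age=60, sex=Sex.MALE, height=165, weight=65)
    rec = CaseRecord(
        case_id=case_id,
        waveform=PressureWaveform(values, cfg.fs, 0.0),
        trends=[],
        demographics=demo,
        surgery_type=SurgeryType.SYNTHETIC,
    )
    gt = GroundTruth(
        beat_onsets=onsets_a,
        beat_sv=svs_a,
        beat_hr=hrs_a,
        segment_sv=seg_sv,
        config=cfg,
    )
    return rec, gt


def emulate_apco(
    gt: GroundTruth,
    fluct_sd: float = 8.0,
    seed: int = 0,
    gain: float = 1.0,
    offset: float = 0.0,
) -> TrendSeries:
    """APCO-device-like SV trend: truth plus i.i.d. fluctuation at 2-s ticks.

    ``gain``/``offset`` apply a systematic device discrepancy
    (reported = gain * true + offset) used to give transfer-learning
    experiments a real domain shift; defaults are the identity.
    """
    rng = np.random.default_rng(seed)
    duration = gt.beat_onsets[-1] + 60.0 / gt.beat_hr[-1]
    ticks = np.arange(0.0, duration, 2.0)
    vals = gain * gt.sv_at(ticks) + offset + fluct_sd * rng.standard_normal(len(ticks))
    return TrendSeries(ticks, vals, Quantity.SV_ML, Device.APCO)


def emulate_pac(
    gt: GroundTruth,
    delay_s: float = 120.0,
    smooth_win_s: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TrendSeries:
    """PAC-monitor-like CO trend: smoothed, delayed, in L/min.

    CO = true SV x HR / 1000 at 2-s ticks, moving-average smoothed over
    ``smooth_win_s`` (trailing windows truncated at the start), timestamps
    shifted ``delay_s`` later — the trend-mode behaviour the preprocessing
    delay shift undoes.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    rng = np.random.default_rng(seed)
    duration = gt.beat_onsets[-1] + 60.0 / gt.beat_hr[-1]
    ticks = np.arange(0.0, duration, 2.0)
    co = gt.sv_at(ticks) * gt.hr_at(ticks) / 1000.0
    if smooth_win_s > 0:
        k = max(int(round(smooth_win_s / 2.0)), 1)
        c = np.cumsum(np.r_[0.0, co])
        sm = np.empty_like(co)
        for i in range(len(co)):
            lo = max(0, i - k + 1)
            sm[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
        co = sm
    co = co + noise_sd * rng.standard_normal(len(co))
    return TrendSeries(ticks + delay_s, co, Quantity.CO_LMIN, Device.PAC)


def emulate_hr(gt: GroundTruth) -> TrendSeries:
    """Bedside-monitor heart-rate channel at 2-s ticks (noise-free)."""
    duration = gt.beat_onsets[-1] + 60.0 / gt.beat_hr[-1]
    ticks = np.arange(0.0, duration, 2.0)
    return TrendSeries(ticks, gt.hr_at(ticks), Quantity.HR_BPM, Device.MONITOR)


def _overlapping_segments(t0: float, t1: float, duration: float) -> list[int]:
    n_seg = int(duration // SEGMENT_SECONDS)
    first = int(t0 // SEGMENT_SECONDS)
    last = int(np.ceil(t1 / SEGMENT_SECONDS)) - 1
    return [k for k in range(first, last + 1) if 0 <= k < n_seg]


def inject_artifact(
    rec: CaseRecord,
    gt: GroundTruth,
    kind: str,
    window: tuple[float, float],
    pac_delay_s: float = 120.0,
) -> tuple[CaseRecord, GroundTruth]:
    """Corrupt a time window so it trips exactly one quality filter.

    Waveform kinds: ``hypotension_clip`` (pressures scaled below 25 mmHg),
    ``flatline`` (constant 80 mmHg), ``low_pp`` (pulse pressure compressed
    under 20 mmHg), ``vpb_burst`` (two of every three beats resynthesised
    premature and under-filled). These mark every segment overlapping the
    window as corrupted, so windows aligned to 20-s segment boundaries give
    exact rejection closure.

    ``sv_outlier`` is a device-side artifact: ticks of the record's
    attached SV/CO trend whose case-time falls in ``(t0, t1]`` are set out
    of the valid 20-200 mL band (PAC device times are mapped through the
    monitor's ``pac_delay_s`` lag), marking segments whose *end* lies in
    ``(t0, t1]``. Note that for an APCO-role record the downstream LOWESS
    step blurs a label outlier into neighbouring targets, so exact closure
    holds for PAC-role records; corpus generation assigns this kind to
    PAC-role cases only.

    Returns new record/truth objects; the inputs are not modified. An empty
    window is the identity.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    t0, t1 = window
    duration = rec.waveform.duration
    if not (0 <= t0 <= t1 <= duration + 1e-9):
        raise ValueError("artifact window outside case duration")
    w = rec.waveform
    values = w.values.copy()
    trends = list(rec.trends)
    corrupted = dict(gt.corrupted)
    if t1 > t0:
        if kind == "sv_outlier":
            if not trends:
                raise ValueError("sv_outlier needs an attached device trend")
            new_trends = []
            for tr in trends:
                vals = tr.values.copy()
                if tr.quantity is Quantity.SV_ML:
                    hit = (tr.times > t0) & (tr.times <= t1)
                    vals[hit] = 250.0
                elif tr.quantity is Quantity.CO_LMIN:
                    hit = (tr.times - pac_delay_s > t0) & (tr.times - pac_delay_s <= t1)
                    vals[hit] = 25.0  # SV = 25000/HR mL, >200 for any HR < 125
                new_trends.append(TrendSeries(tr.times.copy(), vals, tr.quantity, tr.device))
            trends = new_trends
            n_seg = int(duration // SEGMENT_SECONDS)
            for k in range(n_seg):
                if t0 < (k + 1) * SEGMENT_SECONDS <= t1:
                    corrupted[k] = kind
        else:
            lo, hi = int(t0 * w.fs), int(t1 * w.fs)
            win = values[lo:hi]
            if kind == "hypotension_clip":
                base = np.median(win)
                values[lo:hi] = 15.0 + 0.1 * (win - base)  # well below 25 mmHg
            elif kind == "flatline":
                values[lo:hi] = 80.0
            elif kind == "low_pp":
                base = np.median(win)
                values[lo:hi] = base + 0.2 * (win - base)  # pulse pressure < 20
            elif kind == "vpb_burst":
                values[lo:hi] = _vpb_waveform(gt, t0, t1, w.fs, len(win))
            for k in _overlapping_segments(t0, t1, duration):
                corrupted[k] = kind
    new_rec = replace(
        rec, waveform=PressureWaveform(values, w.fs, w.t0), trends=trends
    )
    new_gt = replace(gt, corrupted=corrupted)
    return new_rec, new_gt


def _vpb_waveform(
    gt: GroundTruth, t0: float, t1: float, fs: float, n: int
) -> np.ndarray:
    """Resynthesise a window as a bigeminy-like run: 2 of 3 beats premature."""
    cfg = gt.config or SimConfig()
    hr = float(np.median(gt.hr_at(np.array([0.5 * (t0 + t1)]))))
    # floor the burst's stroke volume so the segment's *mean* pulse pressure
    # stays above the 20-mmHg filter and only the VPB rule trips
    sv = max(float(np.median(gt.sv_at(np.array([0.5 * (t0 + t1)])))), 70.0)
    base_interval = 60.0 / hr
    times = np.arange(n) / fs
    out = np.empty(n)
    t = 0.0
    i_beat = 0
    rng = np.random.default_rng((gt.config.seed if gt.config else 0) + 77)
    while t < times[-1] + base_interval:
        premature = i_beat % 3 != 0
        # a premature beat arrives early: the interval *before* it (the
        # previous beat's duration) is the short coupling interval
        next_premature = (i_beat + 1) % 3 != 0
        interval = base_interval * (0.6 if next_premature else 1.0)
        pp = cfg.sv_to_pp_gain * sv * (0.5 if premature else 1.0)
        dia = cfg.map_baseline - cfg.sv_to_pp_gain * sv / 3.0
        lo = int(np.ceil(t * fs))
        hi = min(int(np.ceil((t + interval) * fs)), n)
        if hi > lo:
            out[lo:hi] = _beat_waveform(
                times[lo:hi] - t, pp, dia, cfg.pulse_shape, interval
            )
        t += interval
        i_beat += 1
    out += cfg.noise_sd * rng.standard_normal(n)
    return out


# ---------------------------------------------------------------------------
# corpus generation


@dataclass
class CorpusConfig:
    """Ranges for sampling a corpus of synthetic cases.

    APCO-role and PAC-role cases share the waveform physics but the APCO
    device labels carry a systematic gain/offset discrepancy
    (``apco_label_gain``/``apco_label_offset``) plus larger fluctuation —
    the domain shift that pretraining-then-tuning must overcome.
    """

    duration_s: float = 600.0
    hr_range: tuple[float, float] = (55.0, 95.0)
    sv_range: tuple[float, float] = (50.0, 100.0)
    sv_walk_sd: float = 0.4  # mL per beat: intra-case drift, SD ~10 mL over 10 min
    hr_walk_sd: float = 0.05
    map_range: tuple[float, float] = (80.0, 100.0)
    noise_sd: float = 1.0
    apco_fluct_sd: float = 8.0
    apco_label_gain: float = 0.85
    apco_label_offset: float = 12.0
    pac_delay_s: float = 120.0
    pac_smooth_win_s: float = 60.0
    age_range: tuple[float, float] = (30.0, 80.0)
    height_range: tuple[float, float] = (150.0, 185.0)
    weight_range: tuple[float, float] = (45.0, 95.0)


def generate_corpus(
    n_cases: int,
    role_mix: tuple[float, float] = (0.8, 0.2),
    cfg_ranges: CorpusConfig | None = None,
    seed: int = 0,
    artifact_rate: float = 0.0,
) -> tuple[list[CaseRecord], list[GroundTruth]]:
    """Sample ``n_cases`` cases with device channels attached.

    ``role_mix`` = (fraction APCO-role, fraction PAC-role); the first
    ``round(n_cases * role_mix[0])`` cases get an APCO SV channel, the rest
    get PAC CO + monitor HR channels. With ``artifact_rate`` > 0 that
    fraction of cases receives one segment-aligned artifact (waveform kinds
    for APCO-role cases, any kind including the device-side SV outlier for
    PAC-role cases) with the corruption recorded in the ground truth.
    Deterministic given ``seed``.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    cr = cfg_ranges or CorpusConfig()
    rng = np.random.default_rng(seed)
    n_apco = int(round(n_cases * role_mix[0] / sum(role_mix)))
    records, truths = [], []
    for i in range(n_cases):
        role = Device.APCO if i < n_apco else Device.PAC
        demo = Demographics(
            age=float(rng.uniform(*cr.age_range)),
            sex=Sex.MALE if rng.random() < 0.6 else Sex.FEMALE,
            height=float(rng.uniform(*cr.height_range)),
            weight=float(rng.uniform(*cr.weight_range)),
        )
        cfg = SimConfig(
            duration_s=cr.duration_s,
            hr_base=float(rng.uniform(*cr.hr_range)),
            hr_walk_sd=cr.hr_walk_sd,
            sv_base=float(rng.uniform(*cr.sv_range)),
            sv_walk_sd=cr.sv_walk_sd,
            sv_clip=(48.0, 145.0),  # keeps pulse pressure > 24 mmHg
            map_baseline=float(rng.uniform(*cr.map_range)),
            noise_sd=cr.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, gt = generate_case(cfg, case_id=f"sim{i:04d}", demographics=demo)
        sub = int(rng.integers(0, 2**31 - 1))
        if role is Device.APCO:
            trends = [
                emulate_apco(
                    gt,
                    fluct_sd=cr.apco_fluct_sd,
                    seed=sub,
                    gain=cr.apco_label_gain,
                    offset=cr.apco_label_offset,
                )
            ]
        else:
            trends = [
                emulate_pac(
                    gt, delay_s=cr.pac_delay_s, smooth_win_s=cr.pac_smooth_win_s, seed=sub
                ),
                emulate_hr(gt),
            ]
        rec = replace(rec, trends=trends)
        if rng.random() < artifact_rate:
            kinds = (
                ("hypotension_clip", "flatline", "low_pp", "vpb_burst")
                if role is Device.APCO
                else ARTIFACT_KINDS
            )
            kind = kinds[int(rng.integers(len(kinds)))]
            n_seg = int(cr.duration_s // SEGMENT_SECONDS)
            # one or two full interior segments, aligned to boundaries
            width = int(rng.integers(1, 3))
            first = int(rng.integers(1, n_seg - width))
            window = (first * SEGMENT_SECONDS, (first + width) * SEGMENT_SECONDS)
            rec, gt = inject_artifact(rec, gt, kind, window, pac_delay_s=cr.pac_delay_s)
        records.append(rec)
        truths.append(gt)
    return records, truths
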