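"""Core domain types for arterial-pressure-based stroke volume estimation.

All times are seconds on a single per-case clock with the waveform starting
at ``t0`` (0 by convention). Slow "trend" channels (device-reported stroke
volume, cardiac output, heart rate) live on the same axis at a nominal 2-s
cadence. Missing pressure values are carried as NaN and treated as
rejectable by the downstream quality filters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Quantity",
    "Device",
    "Sex",
    "SurgeryType",
    "PressureWaveform",
    "TrendSeries",
    "Demographics",
    "CaseRecord",
    "Sample",
    "SEGMENT_SECONDS",
    "SEGMENT_FS",
    "SEGMENT_LENGTH",
]

#: Duration of one training segment (s), its sampling rate (Hz) and length.
SEGMENT_SECONDS = 20.0
SEGMENT_FS = 100.0
SEGMENT_LENGTH = 2000

#: Tolerance (s) by which trend timestamps may extend past the waveform span.
TREND_SLACK_S = 300.0


class Quantity(str, enum.Enum):
    """Physical quantity carried by a trend channel."""

    SV_ML = "sv_ml"
    CO_LMIN = "co_lmin"
    HR_BPM = "hr_bpm"


class Device(str, enum.Enum):
    """Source device role of a trend channel.

    ``apco`` — uncalibrated arterial-pressure-based monitor (FloTrac family),
    ``pac`` — pulmonary-artery-catheter thermodilution monitor,
    ``monitor`` — bedside patient monitor (heart rate).
    """

    APCO = "apco"
    PAC = "pac"
    MONITOR = "monitor"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class SurgeryType(str, enum.Enum):
    CARDIAC = "cardiac"
    LIVER_TX = "liver_tx"
    OTHER = "other"
    SYNTHETIC = "synthetic"


@dataclass
class PressureWaveform:
    """Uniformly sampled arterial pressure in mmHg."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("waveform values must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


@dataclass
class TrendSeries:
    """Timestamped slow channel at a nominal 2-s cadence (gaps allowed)."""

    times: np.ndarray
    values: np.ndarray
    quantity: Quantity
    device: Device

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.quantity = Quantity(self.quantity)
        self.device = Device(self.device)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"trend timestamps must be strictly increasing "
                f"({self.device.value}/{self.quantity.value})"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Demographics:
    """Patient characteristics used as auxiliary model input."""

    age: float
    sex: Sex
    height: float  # cm
    weight: float  # kg

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"demographic field {name!r} missing or non-finite")

    def as_vector(self) -> np.ndarray:
        """Raw numeric vector [age, sex_code, height, weight]; male=1, female=0."""
        return np.array(
            [self.age, 1.0 if self.sex is Sex.MALE else 0.0, self.height, self.weight]
        )


@dataclass
class CaseRecord:
    """One surgical case: waveform + trend channels + demographics."""

    case_id: str
    waveform: PressureWaveform
    trends: list[TrendSeries]
    demographics: Demographics
    surgery_type: SurgeryType = SurgeryType.SYNTHETIC

    def __post_init__(self) -> None:
        self.surgery_type = SurgeryType(self.surgery_type)
        seen: set[tuple[Device, Quantity]] = set()
        for tr in self.trends:
            key = (tr.device, tr.quantity)
            if key in seen:
                raise ValueError(f"duplicate trend channel {key}")
            seen.add(key)
            if len(tr) and (
                tr.times[0] < self.waveform.t0 - TREND_SLACK_S
                or tr.times[-1] > self.waveform.t_end + TREND_SLACK_S
            ):
                raise ValueError(
                    f"trend {key} timestamps fall outside the waveform span "
                    f"by more than {TREND_SLACK_S:.0f} s"
                )

    def get_trend(self, device: Device, quantity: Quantity) -> TrendSeries | None:
        for tr in self.trends:
            if tr.device is Device(device) and tr.quantity is Quantity(quantity):
                return tr
        return None


@dataclass
class Sample:
    """A 20-s, 100-Hz pressure segment paired with one target stroke volume."""

    segment: np.ndarray  # length 2000, mmHg
    target_sv: float  # mL
    demographics: Demographics
    source: Device  # APCO or PAC label provenance
    t_start: float
    case_id: str

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=float)
        self.source = Device(self.source)
        if self.segment.shape != (SEGMENT_LENGTH,):
            raise ValueError(
                f"segment must have length {SEGMENT_LENGTH}, got {self.segment.shape}"
            )
        if self.source not in (Device.APCO, Device.PAC):
            raise ValueError("sample source must be 'apco' or 'pac'")


def samples_to_arrays(samples: list[Sample]) -> dict[str, np.ndarray]:
    """Stack a sample list into parallel arrays (used by I/O and training)."""
    return {
        "segments": np.stack([s.segment for s in samples])
        if samples
        else np.empty((0, SEGMENT_LENGTH)),
        "target_sv": np.array([s.target_sv for s in samples]),
        "demographics": np.stack([s.demographics.as_vector() for s in samples])
        if samples
        else np.empty((0, 4)),
        "source": np.array([s.source.value for s in samples], dtype=object),
        "t_start": np.array([s.t_start for s in samples]),
        "case_id": np.array([s.case_id for s in samples], dtype=object),
    }
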