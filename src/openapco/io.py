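"""On-disk formats for case records and preprocessed sample sets.

A case is a *bundle*: a directory holding one delimited-text file per
channel (two columns, ``time_s,value``) plus a YAML sidecar with the case
id, demographics, units and the channel manifest. Missing values are
written as the sentinel ``NA`` and carried in memory as NaN. Sample sets —
dense ``[n, 2000]`` float arrays plus targets and labels — are stored in a
single HDF5 container.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    SEGMENT_LENGTH,
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

__all__ = ["read_case", "write_case", "read_samples", "write_samples"]

logger = logging.getLogger(__name__)

_SENTINEL = "NA"
META_NAME = "meta.yaml"


class CaseParseError(ValueError):
    """A bundle could not be parsed; the message names the offending part."""


def _write_channel(path: Path, times: np.ndarray, values: np.ndarray) -> None:
    df = pd.DataFrame({"time_s": times, "value": values})
    df.to_csv(path, index=False, na_rep=_SENTINEL, float_format="%.10g")


def _read_channel(path: Path, name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, na_values=[_SENTINEL])
    except Exception as exc:  # noqa: BLE001 - report which channel failed
        raise CaseParseError(f"channel {name!r}: unreadable file ({exc})") from exc
    if list(df.columns) != ["time_s", "value"]:
        raise CaseParseError(
            f"channel {name!r}: expected columns time_s,value, got {list(df.columns)}"
        )
    return df["time_s"].to_numpy(float), df["value"].to_numpy(float)


def write_case(rec: CaseRecord, path: str | Path) -> None:
    """Write a case bundle; readable back by :func:`read_case`.

    Trend values round-trip bit-identically at the written precision
    (10 significant digits); waveform values likewise.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    w = rec.waveform
    _write_channel(path / "waveform.csv", w.times(), w.values)
    manifest = []
    for tr in rec.trends:
        fname = f"trend_{tr.device.value}_{tr.quantity.value}.csv"
        _write_channel(path / fname, tr.times, tr.values)
        manifest.append(
            {"file": fname, "device": tr.device.value, "quantity": tr.quantity.value}
        )
    meta = {
        "case_id": rec.case_id,
        "surgery_type": rec.surgery_type.value,
        "demographics": {
            "age": float(rec.demographics.age),
            "sex": rec.demographics.sex.value,
            "height": float(rec.demographics.height),
            "weight": float(rec.demographics.weight),
        },
        "waveform": {"file": "waveform.csv", "fs": float(w.fs), "t0": float(w.t0)},
        "trends": manifest,
        "units": {"waveform": "mmHg", "sv_ml": "mL", "co_lmin": "L/min", "hr_bpm": "beats/min"},
    }
    with open(path / META_NAME, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_case(path: str | Path) -> CaseRecord:
    """Read a case bundle written by :func:`write_case`, validating it.

    Raises :class:`CaseParseError` naming the offending channel on
    malformed files, and ``ValueError`` on violated invariants (missing
    demographics, non-monotone trend timestamps, duplicate channels).
    """
    path = Path(path)
    meta_path = path / META_NAME
    if not meta_path.exists():
        raise CaseParseError(f"no {META_NAME} in {path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)

    wf_meta = meta.get("waveform")
    if not wf_meta or not (path / wf_meta["file"]).exists():
        raise CaseParseError("bundle lacks the waveform channel")
    _, wf_values = _read_channel(path / wf_meta["file"], "waveform")
    waveform = PressureWaveform(wf_values, float(wf_meta["fs"]), float(wf_meta["t0"]))

    demo_meta = meta.get("demographics") or {}
    for fieldname in ("age", "sex", "height", "weight"):
        if fieldname not in demo_meta or demo_meta[fieldname] is None:
            raise ValueError(f"demographic field {fieldname!r} absent")
    demo = Demographics(
        age=float(demo_meta["age"]),
        sex=Sex(demo_meta["sex"]),
        height=float(demo_meta["height"]),
        weight=float(demo_meta["weight"]),
    )

    trends = []
    manifest = meta.get("trends", [])
    for entry in manifest:
        times, values = _read_channel(path / entry["file"], entry["file"])
        trends.append(
            TrendSeries(times, values, Quantity(entry["quantity"]), Device(entry["device"]))
        )
    if len(trends) != len(manifest):
        logger.warning(
            "case %s: %d channels in manifest, %d read",
            meta.get("case_id"),
            len(manifest),
            len(trends),
        )
    return CaseRecord(
        case_id=str(meta["case_id"]),
        waveform=waveform,
        trends=trends,
        demographics=demo,
        surgery_type=SurgeryType(meta.get("surgery_type", "other")),
    )


# ---------------------------------------------------------------------------
# sample sets


class SampleFileError(ValueError):
    """Sample container corrupt or shape-inconsistent."""


def write_samples(samples: list[Sample], path: str | Path) -> None:
    """Write a sample set to one HDF5 container (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(samples)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["n"] = n
        f.attrs["segment_length"] = SEGMENT_LENGTH
        f.create_dataset(
            "segments",
            data=np.stack([s.segment for s in samples])
            if n
            else np.empty((0, SEGMENT_LENGTH)),
        )
        f.create_dataset("target_sv", data=np.array([s.target_sv for s in samples]))
        f.create_dataset("t_start", data=np.array([s.t_start for s in samples]))
        f.create_dataset(
            "age", data=np.array([s.demographics.age for s in samples])
        )
        f.create_dataset(
            "sex",
            data=np.array([s.demographics.sex.value for s in samples], dtype=object),
            dtype=str_dt,
        )
        f.create_dataset(
            "height", data=np.array([s.demographics.height for s in samples])
        )
        f.create_dataset(
            "weight", data=np.array([s.demographics.weight for s in samples])
        )
        f.create_dataset(
            "source",
            data=np.array([s.source.value for s in samples], dtype=object),
            dtype=str_dt,
        )
        f.create_dataset(
            "case_id",
            data=np.array([s.case_id for s in samples], dtype=object),
            dtype=str_dt,
        )


def read_samples(path: str | Path) -> list[Sample]:
    """Read a sample set written by :func:`write_samples`."""
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n"])
        seg = f["segments"][...]
        if seg.shape != (n, SEGMENT_LENGTH):
            raise SampleFileError(
                f"segment array has shape {seg.shape}, expected ({n}, {SEGMENT_LENGTH})"
            )
        fields = {
            k: f[k][...]
            for k in ("target_sv", "t_start", "age", "sex", "height", "weight", "source", "case_id")
        }
        if any(len(v) != n for v in fields.values()):
            raise SampleFileError("field lengths disagree with the declared count")
    out = []
    for i in range(n):
        out.append(
            Sample(
                segment=seg[i],
                target_sv=float(fields["target_sv"][i]),
                demographics=Demographics(
                    age=float(fields["age"][i]),
                    sex=Sex(fields["sex"][i].decode()),
                    height=float(fields["height"][i]),
                    weight=float(fields["weight"][i]),
                ),
                source=Device(fields["source"][i].decode()),
                t_start=float(fields["t_start"][i]),
                case_id=fields["case_id"][i].decode(),
            )
        )
    return out
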