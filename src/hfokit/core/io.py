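"""File readers and writers: recordings, channel tables, event catalogs.

All tabular interchange is UTF-8 CSV.  Recordings are EDF or the package's
raw-binary format (little-endian float32 block plus a JSON sidecar carrying
rate, channel ids, condition, and patient id).
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import edf as _edf
from .model import (
    MIN_RATE_HZ,
    Band,
    Category,
    ChannelInfo,
    ClassifiedEvent,
    Condition,
    Lobe,
    Montage,
    PatientOutcome,
    Recording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "read_channel_table",
    "write_channel_table",
    "read_event_catalog",
    "write_event_catalog",
    "read_outcome_table",
    "write_outcome_table",
]

_RAW_SUFFIX = ".f32"
_SIDE_SUFFIX = ".json"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDE_SUFFIX)


def write_recording(
    recording: Recording, path: str | os.PathLike, format: Optional[str] = None
) -> None:
    """Write a recording as EDF (``format='edf'``) or raw binary."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "raw-binary")
    if fmt == "edf":
        _edf.write_edf(recording, path)
    elif fmt == "raw-binary":
        recording.samples.astype("<f4").tofile(path)
        meta = {
            "rate_hz": recording.rate_hz,
            "channel_ids": list(recording.channel_ids),
            "condition": recording.condition.value,
            "patient_id": recording.patient_id,
            "n_samples": recording.n_samples,
            "start_time_s": recording.start_time_s,
        }
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | os.PathLike, format: Optional[str] = None) -> Recording:
    """Read an EDF or raw-binary recording; sample values are microvolts.

    Raises a hard error for files whose sampling rate cannot resolve the
    250-600 Hz fast-ripple band.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "raw-binary")
    if fmt == "edf":
        return _edf.read_edf(path)
    if fmt != "raw-binary":
        raise ValueError(f"unknown recording format {fmt!r}")

    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"raw-binary sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    rate = float(meta["rate_hz"])
    if rate < MIN_RATE_HZ:
        raise ValueError(
            f"sampling rate {rate:g} Hz insufficient for the 250-600 Hz band"
        )
    channel_ids = tuple(meta["channel_ids"])
    raw = np.fromfile(path, dtype="<f4")
    n_samples = int(meta["n_samples"])
    if raw.size != len(channel_ids) * n_samples:
        raise ValueError(
            f"raw-binary size mismatch: {raw.size} values for "
            f"{len(channel_ids)} channels x {n_samples} samples"
        )
    return Recording(
        samples=raw.reshape(len(channel_ids), n_samples).astype(np.float64),
        rate_hz=rate,
        channel_ids=channel_ids,
        condition=Condition(meta.get("condition", "intraop")),
        patient_id=meta.get("patient_id", ""),
        start_time_s=float(meta.get("start_time_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# channel metadata


def _parse_tristate(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "unknown", "na", "nan", "none"):
        return None
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"cannot parse tri-state value {value!r}")


def _parse_bool(value) -> bool:
    parsed = _parse_tristate(value)
    if parsed is None:
        raise ValueError(f"cannot parse boolean value {value!r}")
    return parsed


def read_channel_table(path: str | os.PathLike) -> list[ChannelInfo]:
    """Read a per-contact metadata CSV into :class:`ChannelInfo` records.

    Required columns: ``channel``, ``patient``, ``soz``, ``resected``,
    ``lobe``.  A blank ``resected`` cell means *unknown*, not ``False``.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"channel", "patient", "soz", "resected", "lobe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"channel table missing columns: {sorted(missing)}")
    dupes = df["channel"][df["channel"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate channel id(s): {sorted(set(dupes))}")

    infos = []
    for _, row in df.iterrows():
        partner = row.get("montage_partner")
        if isinstance(partner, float) or partner in (None, "", "nan"):
            partner = None
        infos.append(
            ChannelInfo(
                channel_id=row["channel"],
                patient_id=row["patient"],
                lobe=Lobe(row["lobe"]),
                soz=_parse_bool(row["soz"]),
                resected=_parse_tristate(row["resected"]),
                matched=_parse_bool(row.get("matched", "false")),
                montage_partner=partner,
            )
        )
    return infos


def write_channel_table(infos: Sequence[ChannelInfo], path: str | os.PathLike) -> None:
    rows = [
        {
            "channel": ci.channel_id,
            "patient": ci.patient_id,
            "lobe": ci.lobe.value,
            "soz": ci.soz,
            "resected": "" if ci.resected is None else ci.resected,
            "matched": ci.matched,
            "montage_partner": ci.montage_partner or "",
        }
        for ci in infos
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event catalogs

_EVENT_COLUMNS = [
    "channel",
    "band",
    "onset_s",
    "offset_s",
    "peak_envelope_z",
    "montage",
    "condition",
    "category",
    "power",
    "spectral_freq_hz",
    "duration_ms",
    "has_spike",
    "tf_island",
]


def write_event_catalog(
    events: Iterable[ClassifiedEvent], path: str | os.PathLike
) -> int:
    """Write events to CSV, one row each; returns the number of rejected rows.

    Rows with ``onset >= offset`` are excluded with a logged warning; times
    are written with sub-0.5 ms precision.
    """
    rows, rejected = [], 0
    for ev in events:
        if ev.offset_s <= ev.onset_s:
            logger.warning(
                "rejecting event on %s: offset %.4f <= onset %.4f",
                ev.channel_id,
                ev.offset_s,
                ev.onset_s,
            )
            rejected += 1
            continue
        rows.append(
            {
                "channel": ev.channel_id,
                "band": ev.band.value,
                "onset_s": repr(float(ev.onset_s)),
                "offset_s": repr(float(ev.offset_s)),
                "peak_envelope_z": repr(float(ev.peak_envelope_z)),
                "montage": ev.montage.value,
                "condition": ev.condition.value,
                "category": ev.category.value if isinstance(ev, ClassifiedEvent) else "",
                "power": repr(float(getattr(ev, "power", 0.0))),
                "spectral_freq_hz": repr(float(getattr(ev, "spectral_freq_hz", float("nan")))),
                "duration_ms": repr(float(getattr(ev, "duration_ms", float("nan")))),
                "has_spike": bool(getattr(ev, "has_spike", False)),
                "tf_island": bool(getattr(ev, "tf_island", False)),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
    return rejected


def read_event_catalog(path: str | os.PathLike) -> list[ClassifiedEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        events.append(
            ClassifiedEvent(
                channel_id=row["channel"],
                band=Band(row["band"]),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                peak_envelope_z=float(row["peak_envelope_z"]),
                montage=Montage(row["montage"]),
                condition=Condition(row["condition"]),
                category=Category(row["category"]),
                power=float(row["power"]),
                spectral_freq_hz=float(row["spectral_freq_hz"]),
                duration_ms=float(row["duration_ms"]),
                has_spike=bool(row["has_spike"]),
                tf_island=bool(row["tf_island"]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# outcomes


def read_outcome_table(path: str | os.PathLike) -> list[PatientOutcome]:
    df = pd.read_csv(path, dtype=str)
    required = {"patient", "engel_class", "postop_mri"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    return [
        PatientOutcome(
            patient_id=row["patient"],
            engel_class=row["engel_class"],
            postop_mri=_parse_bool(row["postop_mri"]),
        )
        for _, row in df.iterrows()
    ]


def write_outcome_table(
    outcomes: Sequence[PatientOutcome], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            {
                "patient": o.patient_id,
                "engel_class": o.engel_class,
                "postop_mri": o.postop_mri,
            }
            for o in outcomes
        ]
    ).to_csv(path, index=False)
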