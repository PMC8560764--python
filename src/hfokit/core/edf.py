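"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF subset this package needs: a common sampling rate for
all signals, 1-second data records, 16-bit samples.  Signal values are scaled
to/from physical units (microvolts) through the per-signal physical/digital
ranges, so a write-then-read round trip is exact up to 16-bit quantization.
"""

from __future__ import annotations

import datetime as _dt
import math
import os
import warnings

import numpy as np

from .model import MIN_RATE_HZ, Condition, Recording

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def write_edf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a :class:`Recording` as plain EDF with 1 s data records.

    The trailing partial second, if any, is zero-padded; the true sample
    count is recovered on read from the recording-id annotation.
    """
    rate = recording.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_sig = recording.n_channels
    n_samp = recording.n_samples
    n_rec = max(1, math.ceil(n_samp / spr))

    data = np.zeros((n_sig, n_rec * spr), dtype=np.float64)
    data[:, :n_samp] = recording.samples

    # symmetric per-signal physical range; quantize with the exact affine map
    # the reader reconstructs from the (<= 7 char + sign) ASCII header fields
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_strs = [f"{pm:.5g}"[:7] for pm in phys_max]
    pm_eff = np.array([float(s) for s in phys_strs])
    scale = 2.0 * pm_eff / (_DIG_MAX - _DIG_MIN)
    digital = np.clip(
        np.round((data + pm_eff[:, None]) / scale[:, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header_bytes = 256 + 256 * n_sig
    rec_id = f"condition={recording.condition.value} nsamples={n_samp}"

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(recording.patient_id or "X", 80))
        fh.write(_pad(rec_id, 80))
        fh.write(_pad(now.strftime("%d.%m.%y"), 8))
        fh.write(_pad(now.strftime("%H.%M.%S"), 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_sig), 4))

        for cid in recording.channel_ids:
            fh.write(_pad(cid, 16))
        fh.write(_pad("", 80) * n_sig)
        fh.write(_pad("uV", 8) * n_sig)
        for s in phys_strs:
            fh.write(_pad("-" + s, 8))
        for s in phys_strs:
            fh.write(_pad(s, 8))
        fh.write(_pad(str(_DIG_MIN), 8) * n_sig)
        fh.write(_pad(str(_DIG_MAX), 8) * n_sig)
        fh.write(_pad("", 80) * n_sig)
        fh.write(_pad(str(spr), 8) * n_sig)
        fh.write(_pad("", 32) * n_sig)

        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _read_fields(fh, width: int, count: int) -> list[str]:
    return [fh.read(width).decode("ascii").strip() for _ in range(count)]


def read_edf(path: str | os.PathLike) -> Recording:
    """Read a plain EDF file into a :class:`Recording` (values in uV)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        fh.read(8)  # version
        patient_id = fh.read(80).decode("ascii").strip()
        rec_id = fh.read(80).decode("ascii").strip()
        fh.read(16)  # date + time
        header_bytes = int(fh.read(8))
        fh.read(44)
        n_rec = int(fh.read(8))
        rec_dur = float(fh.read(8))
        n_sig = int(fh.read(4))
        if n_sig < 1:
            raise ValueError("EDF file declares no signals")

        labels = _read_fields(fh, 16, n_sig)
        fh.read(80 * n_sig)  # transducer
        fh.read(8 * n_sig)  # physical dimension
        phys_min = [float(v) for v in _read_fields(fh, 8, n_sig)]
        phys_max = [float(v) for v in _read_fields(fh, 8, n_sig)]
        dig_min = [int(v) for v in _read_fields(fh, 8, n_sig)]
        dig_max = [int(v) for v in _read_fields(fh, 8, n_sig)]
        fh.read(80 * n_sig)  # prefiltering
        spr = [int(v) for v in _read_fields(fh, 8, n_sig)]
        fh.read(32 * n_sig)

        if header_bytes != 256 + 256 * n_sig:
            raise ValueError("EDF header size does not match signal count")
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates are not supported")
        rate = spr[0] / rec_dur

        raw = np.frombuffer(fh.read(n_rec * n_sig * spr[0] * 2), dtype="<i2")
        if raw.size != n_rec * n_sig * spr[0]:
            raise ValueError("EDF data section truncated")
        raw = raw.reshape(n_rec, n_sig, spr[0])
        # int32 before offset arithmetic: int16 would overflow on d - dig_min
        digital = np.concatenate([raw[r] for r in range(n_rec)], axis=1).astype(np.int32)

    samples = np.empty(digital.shape, dtype=np.float64)
    for i in range(n_sig):
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        samples[i] = (digital[i] - dig_min[i]) * scale + phys_min[i]

    if rate < MIN_RATE_HZ:
        raise ValueError(
            f"sampling rate {rate:g} Hz insufficient for the 250-600 Hz band "
            f"(need >= {MIN_RATE_HZ:g} Hz)"
        )

    condition = Condition.INTRAOP
    n_samp = samples.shape[1]
    for token in rec_id.split():
        if token.startswith("condition="):
            try:
                condition = Condition(token.split("=", 1)[1])
            except ValueError:
                warnings.warn(f"unknown condition tag in EDF header: {token}")
        elif token.startswith("nsamples="):
            n_samp = min(int(token.split("=", 1)[1]), n_samp)
    samples = samples[:, :n_samp]

    return Recording(
        samples=samples,
        rate_hz=rate,
        channel_ids=tuple(labels),
        condition=condition,
        patient_id=patient_id,
    )
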