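"""Hilbert detector for high-frequency events.

Chain per channel and band: 1000th-order symmetric FIR band-pass (zero phase
after group-delay compensation), analytic-signal envelope, moving-average
smoothing, whole-series z-scoring, a skewness-defined threshold, and maximal
suprathreshold runs walked out to the half-threshold crossings.

The 80-600 Hz broad pass is the primary detection band (ripple vs fast
ripple is resolved from classifier spectral frequency); the dedicated
250-600 Hz pass adds fast-ripple sensitivity.  Candidates from the bipolar
montage and the fast-ripple pass are deduplicated against referential
broad-band candidates by interval overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as st
from scipy.ndimage import uniform_filter1d

from .core.config import DetectorConfig
from .core.model import (
    BAND_EDGES_HZ,
    Band,
    CandidateEvent,
    ChannelInfo,
    Condition,
    Montage,
    Recording,
)
from .preprocess import to_bipolar

logger = logging.getLogger(__name__)

__all__ = [
    "AnalyticEnvelope",
    "bandpass_fir",
    "analytic_envelope",
    "smooth_normalize",
    "skewness_threshold",
    "extract_events",
    "detect_channel",
    "detect_all",
]


@dataclass
class AnalyticEnvelope:
    band: Band
    a_t: np.ndarray  # instantaneous amplitude, uV
    phi_t: np.ndarray  # instantaneous phase, radians
    group_delay_samples: int = 0  # 0: delay already compensated


def design_bandpass(rate_hz: float, band: Band | str, order: int = 1000) -> np.ndarray:
    """Symmetric (linear-phase) FIR band-pass taps for the given band."""
    band = Band(band)
    lo, hi = BAND_EDGES_HZ[band]
    nyq = rate_hz / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    return sps.firwin(order + 1, [lo, hi], pass_zero=False, fs=rate_hz)


def bandpass_fir(
    signal: np.ndarray, rate_hz: float, band: Band | str, order: int = 1000
) -> np.ndarray:
    """Zero-phase band-pass: symmetric FIR with group delay compensated.

    An odd-length symmetric kernel applied with centred ('same') convolution
    has exactly zero phase, so no explicit delay shift is needed.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size <= order:
        raise ValueError(f"signal length {signal.size} must exceed filter order {order}")
    taps = design_bandpass(rate_hz, band, order)
    return sps.fftconvolve(signal, taps, mode="same")


def analytic_envelope(filtered: np.ndarray, rate_hz: float, band: Band | str = Band.BROAD_HFO) -> AnalyticEnvelope:
    """Instantaneous amplitude/phase of the analytic signal z(t) = a(t)e^(i phi(t))."""
    analytic = sps.hilbert(np.asarray(filtered, dtype=np.float64))
    return AnalyticEnvelope(
        band=Band(band),
        a_t=np.abs(analytic),
        phi_t=np.angle(analytic),
        group_delay_samples=0,
    )


def smooth_normalize(
    a_t: np.ndarray, window_ms: float, rate_hz: float
) -> np.ndarray:
    """Moving-average smoothing then whole-series z-scoring.

    Returns a series with mean 0 and SD 1; a constant envelope degenerates to
    an all-zero series with a warning.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    n_win = int(round(window_ms * rate_hz / 1000.0))
    n_win = max(1, n_win) | 1  # odd, centred window
    if n_win > a_t.size:
        raise ValueError(f"smoothing window ({n_win} samples) longer than series")
    smoothed = uniform_filter1d(np.asarray(a_t, dtype=np.float64), size=n_win, mode="reflect")
    mu = smoothed.mean()
    sd = smoothed.std()
    if sd <= 1e-12 * max(abs(mu), 1.0):
        warnings.warn("constant envelope: normalized series degenerates to zeros")
        return np.zeros_like(smoothed)
    return (smoothed - mu) / sd


def skewness_threshold(
    normalized: np.ndarray,
    base: float = 3.0,
    gain: float = 0.5,
    floor: float = 3.0,
    ceiling: float = 6.0,
) -> float:
    """Detection threshold in SD units from the skewness of the series.

    ``clamp(base + gain * max(0, skewness), floor, ceiling)`` — monotone
    non-decreasing in skewness, so burst-laden (right-skewed) channels get a
    stricter threshold.
    """
    skew = float(st.skew(np.asarray(normalized, dtype=np.float64)))
    return float(np.clip(base + gain * max(0.0, skew), floor, ceiling))


def _merge_runs(
    runs: list[tuple[int, int]], gap_samples: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def extract_events(
    normalized: np.ndarray,
    threshold: float,
    band: Band | str,
    rate_hz: float,
    config: Optional[DetectorConfig] = None,
    channel_id: str = "",
    montage: Montage = Montage.REFERENTIAL,
    condition: Condition = Condition.INTRAOP,
) -> list[CandidateEvent]:
    """Maximal suprathreshold runs -> candidate events (half-open intervals).

    Runs shorter than the band's minimum duration are discarded, then
    onset/offset are walked out to the nearest crossing of
    ``boundary_fraction * threshold``, and runs closer than the merge gap are
    merged.  (Duration gating happens on the core suprathreshold run: the
    walked-out boundary sits at half threshold, a level the smoothed envelope
    crosses so often on plain noise that gating the walked interval instead
    floods the catalog with false events.)
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    config = config or DetectorConfig()
    band = Band(band)
    z = np.asarray(normalized, dtype=np.float64)
    above = z > threshold
    if not above.any():
        return []

    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    stops = list(np.flatnonzero(~above[1:] & above[:-1]) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(z.size)

    min_ms = (
        config.min_duration_broad_ms
        if band is Band.BROAD_HFO
        else config.min_duration_fast_ms
    )
    min_samples = int(round(min_ms * rate_hz / 1000.0))
    core = [(a, b) for a, b in zip(starts, stops) if b - a >= min_samples]

    boundary = config.boundary_fraction * threshold
    below = z <= boundary
    walked = []
    for start, stop in core:
        lo = start
        while lo > 0 and not below[lo - 1]:
            lo -= 1
        hi = stop
        while hi < z.size and not below[hi]:
            hi += 1
        walked.append((lo, hi))

    gap = int(round(config.merge_gap_ms * rate_hz / 1000.0))
    merged = _merge_runs(sorted(walked), gap)

    events = []
    for lo, hi in merged:
        events.append(
            CandidateEvent(
                channel_id=channel_id,
                band=band,
                onset_s=lo / rate_hz,
                offset_s=hi / rate_hz,
                peak_envelope_z=float(z[lo:hi].max()),
                montage=montage,
                condition=condition,
            )
        )
    return events


def detect_channel(
    signal: np.ndarray,
    rate_hz: float,
    config: DetectorConfig,
    band: Band | str,
    channel_id: str = "",
    montage: Montage = Montage.REFERENTIAL,
    condition: Condition = Condition.INTRAOP,
) -> list[CandidateEvent]:
    """Run the full single-channel, single-band detection chain."""
    filtered = bandpass_fir(signal, rate_hz, band, config.filter_order)
    env = analytic_envelope(filtered, rate_hz, band)
    z = smooth_normalize(env.a_t, config.smooth_window_ms, rate_hz)
    if not z.any():
        return []
    thr = skewness_threshold(
        z,
        base=config.threshold_base,
        gain=config.threshold_gain,
        floor=config.threshold_floor,
        ceiling=config.threshold_ceiling,
    )
    return extract_events(
        z, thr, band, rate_hz, config, channel_id=channel_id, montage=montage,
        condition=condition,
    )


def _overlap_fraction(a: CandidateEvent, b: CandidateEvent) -> float:
    inter = a.overlap_s(b)
    shorter = min(a.duration_s, b.duration_s)
    return inter / shorter if shorter > 0 else 0.0


def _dedup(candidates: list[CandidateEvent], overlap: float) -> list[CandidateEvent]:
    """Greedy dedup by interval overlap within a channel.

    Priority: referential before bipolar, broad band before fast-ripple band,
    then higher envelope peak — the kept instance is the referential/broad one
    whenever montage or band duplicates collide.
    """
    def priority(ev: CandidateEvent):
        return (
            0 if ev.montage is Montage.REFERENTIAL else 1,
            0 if ev.band is Band.BROAD_HFO else 1,
            -ev.peak_envelope_z,
        )

    kept: list[CandidateEvent] = []
    for ev in sorted(candidates, key=priority):
        if any(
            k.channel_id == ev.channel_id and _overlap_fraction(ev, k) >= overlap
            for k in kept
        ):
            continue
        kept.append(ev)
    kept.sort(key=lambda e: (e.channel_id, e.onset_s))
    return kept


def detect_all(
    recording: Recording,
    channel_infos: Sequence[ChannelInfo],
    config: Optional[DetectorConfig] = None,
) -> list[CandidateEvent]:
    """Detect candidates on both montages and both bands, deduplicated.

    Bipolar-montage candidates are attributed to the source (first) contact of
    the pair.  Deterministic for fixed input and config.
    """
    config = config or DetectorConfig()
    candidates: list[CandidateEvent] = []

    for band in (Band.BROAD_HFO, Band.FAST_RIPPLE):
        for cid in recording.channel_ids:
            candidates.extend(
                detect_channel(
                    recording.get(cid),
                    recording.rate_hz,
                    config,
                    band,
                    channel_id=cid,
                    montage=Montage.REFERENTIAL,
                    condition=recording.condition,
                )
            )

    has_pairs = any(
        ci.montage_partner is not None and ci.channel_id in recording.channel_ids
        for ci in channel_infos
    )
    if config.use_bipolar and has_pairs:
        bipolar = to_bipolar(recording, channel_infos)
        for band in (Band.BROAD_HFO, Band.FAST_RIPPLE):
            for cid in bipolar.channel_ids:
                source = cid.split("-")[0]
                for ev in detect_channel(
                    bipolar.get(cid),
                    bipolar.rate_hz,
                    config,
                    band,
                    channel_id=source,
                    montage=Montage.BIPOLAR,
                    condition=recording.condition,
                ):
                    candidates.append(ev)

    return _dedup(candidates, config.dedup_overlap)
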