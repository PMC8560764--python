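"""Time-frequency review of candidate events.

Distinguishes authentic oscillatory bursts from the filter ringing that a
band-passed sharp transient produces (Gibbs phenomenon).  A Morlet scalogram
over log-spaced 32-600 Hz is thresholded at a fraction of the event-window
peak; the connected above-threshold region containing the in-band peak must
be an *island* — closed, and not extending below 80 Hz — for the event to
count as an oscillation.  Ringing from a spike instead forms a ridge that
runs continuously down into the low frequencies.

Decision table (island x coincident low-frequency spike):

=========  ======  ==============================
island     spike   category
=========  ======  ==============================
yes        no      RonO / fRonO  (by TF peak frequency)
yes        yes     RonS / fRonS
no         yes     SharpSpike
no         no      Artifact  (audit-only)
=========  ======  ==============================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import fft
from scipy import signal as sps
from scipy.ndimage import label as nd_label

from .core.config import ClassifierConfig
from .core.model import (
    RIPPLE_SPLIT_HZ,
    Band,
    CandidateEvent,
    Category,
    ClassifiedEvent,
    Recording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "tf_map",
    "detect_spike",
    "island_test",
    "classify_event",
    "classify_all",
    "screen_artifact_rate",
]

_HFO_FLOOR_HZ = 80.0


def _morlet_freqs(config: ClassifierConfig) -> np.ndarray:
    return np.geomspace(config.freq_min_hz, config.freq_max_hz, config.n_freqs)


def tf_map(
    excerpt: np.ndarray,
    rate_hz: float,
    config: Optional[ClassifierConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet scalogram: returns (power [n_freqs x n_times], freqs_hz).

    Implemented as frequency-domain filtering with Gaussian kernels of
    bandwidth f / n_cycles.  Power is normalized so that the total over the
    map approximates the signal energy (in uV^2 * samples) for inputs band-
    limited well inside the analyzed range.
    """
    config = config or ClassifierConfig()
    x = np.asarray(excerpt, dtype=np.float64)
    freqs = _morlet_freqs(config)
    sigma_f = freqs / config.n_cycles
    min_len = int(np.ceil(2 * config.n_cycles * rate_hz / freqs[0]))
    if x.size < min_len:
        raise ValueError(
            f"excerpt of {x.size} samples shorter than two wavelet lengths "
            f"({min_len}) at {freqs[0]:.0f} Hz"
        )

    n = x.size
    n_fft = int(fft.next_fast_len(2 * n))  # pad against circular wrap
    X = np.fft.fft(x, n_fft)
    nu = np.fft.fftfreq(n_fft, d=1.0 / rate_hz)
    positive = nu > 0

    # Gaussian kernels on the positive axis; log-frequency trapezoid weights
    w = np.gradient(np.log(freqs))
    power = np.empty((freqs.size, n))
    kernels = []
    tiling_grid = np.zeros(positive.sum())
    for i, (f0, sf) in enumerate(zip(freqs, sigma_f)):
        H = np.zeros(n_fft)
        H[positive] = np.exp(-0.5 * ((nu[positive] - f0) / sf) ** 2)
        kernels.append(H)
        tiling_grid += w[i] * H[positive] ** 2
    # calibrate the tiling constant at mid-band so that the summed map
    # reproduces the energy of inputs band-limited well inside the range
    mid = np.argmin(np.abs(nu[positive] - np.sqrt(freqs[0] * freqs[-1])))
    tiling = float(tiling_grid[mid])
    for i, H in enumerate(kernels):
        analytic = np.fft.ifft(X * 2.0 * H)[:n]
        power[i] = (np.abs(analytic) ** 2) / 2.0 * (w[i] / tiling)
    return power, freqs


def detect_spike(
    excerpt: np.ndarray,
    rate_hz: float,
    candidate_window: tuple[float, float],
    config: Optional[ClassifierConfig] = None,
) -> tuple[bool, Optional[tuple[float, float]]]:
    """Detect a sharp low-frequency transient coinciding with the candidate.

    The excerpt is low-passed below ``spike_lowpass_hz``; a spike is declared
    when both the robust amplitude z-score and the robust slope z-score of
    the low-passed trace exceed their thresholds within ``spike_window_ms``
    of the candidate interval.  Times in ``candidate_window`` are seconds
    relative to the excerpt start.  Returns (flag, spike interval).
    """
    config = config or ClassifierConfig()
    x = np.asarray(excerpt, dtype=np.float64)
    # band-pass rather than low-pass: ongoing delta activity would otherwise
    # inflate the robust scale and mask genuine transients
    sos = sps.butter(
        4, [4.0, config.spike_lowpass_hz], btype="bandpass", fs=rate_hz, output="sos"
    )
    low = sps.sosfiltfilt(sos, x)
    slope = np.gradient(low) * rate_hz  # uV/s

    def robust_z(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        scale = 1.4826 * mad
        if scale <= 0:
            return np.zeros_like(v)
        return (v - med) / scale

    amp_z = np.abs(robust_z(low))
    slope_z = np.abs(robust_z(slope))

    pad = config.spike_window_ms / 1000.0
    lo = max(0, int(round((candidate_window[0] - pad) * rate_hz)))
    hi = min(x.size, int(round((candidate_window[1] + pad) * rate_hz)))
    if hi <= lo:
        return False, None
    window_amp = amp_z[lo:hi]
    window_slope = slope_z[lo:hi]
    if window_amp.max() < config.spike_amp_z or window_slope.max() < config.spike_slope_z:
        return False, None

    peak = lo + int(np.argmax(window_amp))
    half = 0.5 * amp_z[peak]
    a = peak
    while a > 0 and amp_z[a - 1] > half:
        a -= 1
    b = peak
    while b < x.size - 1 and amp_z[b + 1] > half:
        b += 1
    return True, (a / rate_hz, (b + 1) / rate_hz)


def island_test(
    power: np.ndarray,
    freqs: np.ndarray,
    rate_hz: float,
    event_window: tuple[float, float],
    band: Band | str = Band.BROAD_HFO,
    contour_fraction: float = 0.5,
    secondary_floor: float = 0.05,
    max_peaks: int = 3,
) -> tuple[bool, Optional[dict]]:
    """Topographic test: does an in-band TF peak sit on a closed island?

    Thresholds the map at ``contour_fraction`` of a peak found inside the
    event time window and at/above 80 Hz; the connected component holding
    that peak must not extend below 80 Hz.  A ridge running continuously to
    the low frequencies (the ringing signature) fails.  Because a coincident
    sharp transient can out-power a genuine superimposed oscillation at the
    low in-band frequencies, up to ``max_peaks`` successive local maxima are
    examined (each at least ``secondary_floor`` of the primary peak) before
    declaring no island.  Returns ``(flag, peak_info)``.
    """
    t_lo = max(0, int(round(event_window[0] * rate_hz)))
    t_hi = min(power.shape[1], int(round(event_window[1] * rate_hz)))
    if t_hi <= t_lo:
        return False, None
    in_band = freqs >= _HFO_FLOOR_HZ
    window_cols = np.arange(t_lo, t_hi)
    sub = power[np.ix_(in_band, window_cols)]
    if sub.size == 0 or sub.max() <= 0:
        return False, None

    excluded = np.zeros_like(power, dtype=bool)
    primary_power = float(sub.max())
    first_info: Optional[dict] = None

    for _ in range(max_peaks):
        search = power.copy()
        search[~in_band, :] = -np.inf
        search[:, : t_lo] = -np.inf
        search[:, t_hi:] = -np.inf
        search[excluded] = -np.inf
        fi, ti = np.unravel_index(np.argmax(search), search.shape)
        peak_power = power[fi, ti]
        if not np.isfinite(search[fi, ti]) or peak_power < secondary_floor * primary_power:
            break

        # contour ladder: a burst blob merged with a ringing ridge at the
        # base contour can separate at a tighter one; a pure ridge stays
        # connected toward low frequencies at every contour level
        base_component = None
        for level in sorted({contour_fraction, 0.7, 0.85}):
            mask = power >= level * peak_power
            labels, _ = nd_label(mask)
            component = labels == labels[fi, ti]
            comp_freq_idx = np.flatnonzero(component.any(axis=1))
            comp_time_idx = np.flatnonzero(component.any(axis=0))
            min_freq = float(freqs[comp_freq_idx[0]])
            info = {
                "peak_freq_hz": float(freqs[fi]),
                "peak_time_s": ti / rate_hz,
                "peak_power": float(peak_power),
                "component": component,
                "min_freq_hz": min_freq,
                "time_extent_s": (
                    comp_time_idx[0] / rate_hz,
                    (comp_time_idx[-1] + 1) / rate_hz,
                ),
                "island_power": float(power[component].sum()),
            }
            if base_component is None:
                base_component = component
            if first_info is None:
                first_info = info
            if min_freq >= _HFO_FLOOR_HZ:
                return True, info
        excluded |= base_component

    return False, first_info


def _burst_duration_ms(info: dict, config: ClassifierConfig) -> float:
    """Burst duration from the island's half-power temporal extent.

    For a Gaussian-envelope burst the scalogram's half-power width is
    ``1.665 * sqrt(sigma_burst^2 + sigma_wavelet^2)``; the wavelet smear is
    deconvolved and the duration reported as the +/-3 sigma support, matching
    the planted-atom convention.
    """
    fwhm_s = info["time_extent_s"][1] - info["time_extent_s"][0]
    sigma_w = config.n_cycles / (2.0 * np.pi * info["peak_freq_hz"])
    sigma_a = fwhm_s / 1.665
    sigma_burst = np.sqrt(max(sigma_a**2 - sigma_w**2, (0.25 * sigma_a) ** 2))
    return float(6.0 * sigma_burst * 1000.0)


def classify_event(
    candidate: CandidateEvent,
    recording: Recording,
    config: Optional[ClassifierConfig] = None,
) -> ClassifiedEvent:
    """Classify one candidate; see the module decision table."""
    config = config or ClassifierConfig()
    rate = recording.rate_hz
    context = config.context_ms / 1000.0
    lo = max(0.0, candidate.onset_s - context)
    hi = min(recording.duration_s, candidate.offset_s + context)
    # keep at least two wavelet lengths at the lowest analyzed frequency,
    # shifting inward when the candidate sits at a recording edge
    min_span = 2.0 * config.n_cycles / config.freq_min_hz + 2.0 / rate
    if hi - lo < min_span:
        if lo == 0.0:
            hi = min(recording.duration_s, min_span)
        else:
            lo = max(0.0, hi - min_span)
    trace = recording.get(candidate.channel_id)
    excerpt = trace[int(round(lo * rate)) : int(round(hi * rate))]
    window = (candidate.onset_s - lo, candidate.offset_s - lo)

    power, freqs = tf_map(excerpt, rate, config)
    has_spike, spike_interval = detect_spike(excerpt, rate, window, config)
    is_island, info = island_test(
        power, freqs, rate, window, candidate.band, config.contour_fraction
    )

    if is_island and info is not None:
        spectral_freq = info["peak_freq_hz"]
        tf_power = info["island_power"]
        duration_ms = _burst_duration_ms(info, config)
        if has_spike:
            category = (
                Category.RON_S if spectral_freq < RIPPLE_SPLIT_HZ else Category.FRON_S
            )
        else:
            category = (
                Category.RON_O if spectral_freq < RIPPLE_SPLIT_HZ else Category.FRON_O
            )
    else:
        spectral_freq = info["peak_freq_hz"] if info else float("nan")
        duration_ms = candidate.duration_s * 1000.0
        if has_spike:
            category = Category.SHARP_SPIKE
            # in-band power inside the candidate window
            t_lo = int(round(window[0] * rate))
            t_hi = int(round(window[1] * rate))
            band_rows = freqs >= _HFO_FLOOR_HZ
            tf_power = float(power[np.ix_(band_rows, range(t_lo, t_hi))].sum())
            if spike_interval is not None:
                duration_ms = 1000.0 * (spike_interval[1] - spike_interval[0])
        else:
            category = Category.ARTIFACT
            tf_power = 0.0

    return ClassifiedEvent(
        channel_id=candidate.channel_id,
        band=candidate.band,
        onset_s=candidate.onset_s,
        offset_s=candidate.offset_s,
        peak_envelope_z=candidate.peak_envelope_z,
        montage=candidate.montage,
        condition=candidate.condition,
        category=category,
        power=tf_power,
        spectral_freq_hz=spectral_freq,
        duration_ms=duration_ms,
        has_spike=has_spike,
        tf_island=is_island,
    )


def classify_all(
    candidates: Sequence[CandidateEvent],
    recording: Recording,
    config: Optional[ClassifierConfig] = None,
) -> list[ClassifiedEvent]:
    return [classify_event(c, recording, config) for c in candidates]


def screen_artifact_rate(
    events: Sequence[ClassifiedEvent], cap: float = 0.05
) -> dict[str, dict]:
    """Audit per-channel Artifact fractions against a cap; never deletes.

    Returns ``{channel_id: {"artifact_fraction": ..., "n_events": ...}}`` for
    channels whose Artifact fraction exceeds ``cap``.
    """
    per_channel: dict[str, list[ClassifiedEvent]] = {}
    for ev in events:
        per_channel.setdefault(ev.channel_id, []).append(ev)
    report = {}
    for cid, evs in per_channel.items():
        n_art = sum(1 for e in evs if e.category is Category.ARTIFACT)
        frac = n_art / len(evs)
        if frac > cap:
            report[cid] = {"artifact_fraction": frac, "n_events": len(evs)}
            logger.warning(
                "channel %s: artifact fraction %.1f%% exceeds cap %.1f%%",
                cid,
                100 * frac,
                100 * cap,
            )
    return report
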