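"""Synthetic multichannel iEEG with planted, ground-truth-labeled events.

Generates 1/f background (plus delta-band slow activity for the sleep
condition), then superimposes five event families per channel at Poisson
rates, elevated on seizure-onset-zone channels:

* ``RonO`` / ``fRonO`` — Gaussian-windowed sinusoids (Gabor atoms) of
  4-12 cycles in the 80-250 / 250-600 Hz bands;
* ``SharpSpike`` — a biphasic difference-of-Gaussians transient of 30-60 ms
  with no sustained oscillation (its band-passed trace rings, which is the
  classifier's hard case);
* ``RonS`` / ``fRonS`` — a Gabor atom superimposed on such a transient.

Condition effects are applied on the natural-log scale: a log-power offset
``b`` multiplies sleep amplitudes by ``exp(b / 2)``, a log-frequency offset
``c`` multiplies sleep oscillation frequencies by ``exp(c)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core.model import Category, ChannelInfo, Condition, Lobe, PatientOutcome, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthEvent",
    "SimulationSpec",
    "CohortBundle",
    "simulate_background",
    "plant_events",
    "simulate_cohort",
    "score_detections",
    "gabor_atom",
    "biphasic_spike",
]

#: Oscillation frequency sampling ranges per category (Hz); SharpSpike has none.
_FREQ_RANGES = {
    Category.RON_O: (100.0, 220.0),
    Category.RON_S: (100.0, 220.0),
    Category.FRON_O: (270.0, 450.0),
    Category.FRON_S: (270.0, 450.0),
}

_RIPPLE_BAND = (80.0, 250.0)
_FAST_BAND = (250.0, 600.0)


@dataclass
class GroundTruthEvent:
    channel_id: str
    category: Category
    onset_s: float
    offset_s: float
    amplitude_uv: float
    osc_freq_hz: Optional[float] = None  # absent for SharpSpike

    def __post_init__(self) -> None:
        if isinstance(self.category, str):
            self.category = Category(self.category)
        if self.category is Category.SHARP_SPIKE:
            if self.osc_freq_hz is not None:
                raise ValueError("SharpSpike carries no oscillation frequency")
        else:
            lo, hi = (
                _RIPPLE_BAND
                if self.category in (Category.RON_O, Category.RON_S)
                else _FAST_BAND
            )
            if not (lo <= self.osc_freq_hz <= hi):
                raise ValueError(
                    f"{self.category.value} frequency {self.osc_freq_hz} outside "
                    f"[{lo}, {hi}]"
                )


def _default_base_rates() -> dict[str, float]:
    return {"RonO": 2.0, "RonS": 1.0, "fRonO": 1.0, "fRonS": 0.5, "SharpSpike": 1.5}


def _default_soz_multipliers() -> dict[str, float]:
    return {"RonO": 3.0, "RonS": 3.0, "fRonO": 3.0, "fRonS": 3.0, "SharpSpike": 3.0}


def _default_log_power() -> dict[str, float]:
    # sleep-minus-intraop log-power offsets; signs mirror the planted design
    return {"RonO": 1.291, "RonS": 0.97, "fRonO": 0.3, "fRonS": 1.208, "SharpSpike": 0.6}


def _default_log_freq() -> dict[str, float]:
    return {"RonO": 0.03, "RonS": 0.022, "fRonO": -0.1877, "fRonS": -0.115, "SharpSpike": 0.0}


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort; ``seed`` determines everything."""

    n_patients: int = 4
    channels_per_patient: int = 8
    soz_fraction: float = 0.25
    matched_fraction: float = 1.0
    duration_intraop_s: float = 120.0
    duration_sleep_s: float = 120.0
    rate_hz: float = 2000.0
    base_rates_per_min: dict[str, float] = field(default_factory=_default_base_rates)
    soz_multipliers: dict[str, float] = field(default_factory=_default_soz_multipliers)
    condition_log_power: dict[str, float] = field(default_factory=_default_log_power)
    condition_log_freq: dict[str, float] = field(default_factory=_default_log_freq)
    background_amplitude_uv: float = 25.0  # total background SD
    background_exponent: float = 1.0  # 1/f^alpha power exponent
    slow_amplitude_uv: float = 40.0  # 0.5-2 Hz component SD, sleep only
    event_amplitude_uv: float = 70.0  # intraop oscillation amplitude
    spike_amplitude_uv: float = 300.0
    amplitude_jitter_log_sd: float = 0.15
    n_failure_patients: int = 0  # Engel >= IIa with an unresected hot channel
    postop_mri_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.soz_fraction < 1.0:
            raise ValueError("soz_fraction must be in (0, 1)")
        for name, rate in self.base_rates_per_min.items():
            if rate < 0:
                raise ValueError(f"negative base rate for {name}")
        if self.n_failure_patients > self.n_patients:
            raise ValueError("more failure patients than patients")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# background


def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum proportional to 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    scale[0] = 0.0  # zero-mean
    out = np.fft.irfft(spec * scale, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_background(
    duration_s: float,
    rate_hz: float,
    condition: Condition | str,
    spec: SimulationSpec,
    n_channels: int | None = None,
    rng: np.random.Generator | None = None,
    channel_ids: Sequence[str] | None = None,
    patient_id: str = "SIM",
) -> Recording:
    """Pink-noise background; sleep adds a 0.5-2 Hz slow component."""
    if duration_s < 10.0:
        raise ValueError("background duration must be at least 10 s")
    condition = Condition(condition)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if channel_ids is None:
        n_channels = n_channels or spec.channels_per_patient
        channel_ids = tuple(f"CH{i + 1:02d}" for i in range(n_channels))
    n = int(round(duration_s * rate_hz))
    samples = np.empty((len(channel_ids), n))
    for i in range(len(channel_ids)):
        trace = spec.background_amplitude_uv * _pink_noise(
            n, spec.background_exponent, rng
        )
        if condition is Condition.SLEEP and spec.slow_amplitude_uv > 0:
            slow = _narrowband_noise(n, rate_hz, 0.5, 2.0, rng)
            trace = trace + spec.slow_amplitude_uv * slow
        samples[i] = trace - trace.mean()
    return Recording(
        samples=samples,
        rate_hz=rate_hz,
        channel_ids=tuple(channel_ids),
        condition=condition,
        patient_id=patient_id,
    )


def _narrowband_noise(
    n: int, rate_hz: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, white)
    sd = out.std()
    return out / sd if sd > 0 else out


# ---------------------------------------------------------------------------
# event waveforms


def gabor_atom(
    rate_hz: float, freq_hz: float, n_cycles: float, amplitude: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid; +/-3 sigma support spans ``n_cycles`` cycles."""
    sigma_s = n_cycles / (6.0 * freq_hz)
    half = int(np.ceil(3.0 * sigma_s * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    return amplitude * np.exp(-0.5 * (t / sigma_s) ** 2) * np.cos(2 * np.pi * freq_hz * t)


def biphasic_spike(rate_hz: float, width_ms: float, amplitude: float) -> np.ndarray:
    """Biphasic difference-of-Gaussians transient of total width ~``width_ms``.

    The leading lobe is sharp (sigma = width/20) so the transient carries
    genuine 80-600 Hz energy and rings when band-passed — the Gibbs confound
    the classifier must reject; the opposite lobe is the slower after-wave.
    """
    width_s = width_ms / 1000.0
    sigma1 = width_s / 20.0
    sigma2 = width_s / 5.0
    shift = width_s / 4.0
    half = int(np.ceil((shift + 3 * sigma2) * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    wave = np.exp(-0.5 * (t / sigma1) ** 2) - 0.6 * np.exp(
        -0.5 * ((t - shift) / sigma2) ** 2
    )
    return amplitude * wave / np.abs(wave).max()


def _render_event(
    category: Category,
    rate_hz: float,
    amplitude: float,
    spike_amplitude: float,
    osc_freq: Optional[float],
    n_cycles: float,
    spike_width_ms: float,
) -> np.ndarray:
    if category is Category.SHARP_SPIKE:
        return biphasic_spike(rate_hz, spike_width_ms, spike_amplitude)
    atom = gabor_atom(rate_hz, osc_freq, n_cycles, amplitude)
    if category in (Category.RON_O, Category.FRON_O):
        return atom
    spike = biphasic_spike(rate_hz, spike_width_ms, spike_amplitude)
    # superimpose the atom on the spike, centers aligned
    n = max(len(atom), len(spike))
    out = np.zeros(n)
    for w in (atom, spike):
        pad = (n - len(w)) // 2
        out[pad : pad + len(w)] += w
    return out


def plant_events(
    recording: Recording,
    spec: SimulationSpec,
    seed: int | np.random.Generator,
    soz_channels: Optional[set[str]] = None,
    rate_overrides: Optional[dict[tuple[str, str], float]] = None,
    max_attempts: int = 200,
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Superimpose Poisson-placed events; returns ground truth sorted by onset.

    ``rate_overrides`` maps ``(channel_id, category)`` to an events/min rate,
    replacing the spec's base-rate-times-SOZ-multiplier value for that cell.
    Non-overlap within a channel is enforced by rejection sampling; an
    infeasible density raises after ``max_attempts`` rejections per event.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    soz_channels = soz_channels or set()
    rate_overrides = rate_overrides or {}
    condition = recording.condition
    sleep = condition is Condition.SLEEP
    rate_hz = recording.rate_hz
    duration_min = recording.duration_s / 60.0

    samples = recording.samples.copy()
    truth: list[GroundTruthEvent] = []
    guard_s = 0.15  # minimum spacing between event supports within a channel

    for ci, channel_id in enumerate(recording.channel_ids):
        occupied: list[tuple[float, float]] = []
        for category in (
            Category.RON_O,
            Category.RON_S,
            Category.FRON_O,
            Category.FRON_S,
            Category.SHARP_SPIKE,
        ):
            lam = spec.base_rates_per_min.get(category.value, 0.0)
            if channel_id in soz_channels:
                lam *= spec.soz_multipliers.get(category.value, 1.0)
            lam = rate_overrides.get((channel_id, category.value), lam)
            if lam <= 0:
                continue
            count = rng.poisson(lam * duration_min)
            for _ in range(count):
                osc_freq: Optional[float] = None
                n_cycles = float(rng.uniform(4.0, 12.0))
                spike_width = float(rng.uniform(30.0, 60.0))
                jitter = float(np.exp(rng.normal(0.0, spec.amplitude_jitter_log_sd)))
                amp = spec.event_amplitude_uv * jitter
                spike_amp = spec.spike_amplitude_uv * jitter
                if category is not Category.SHARP_SPIKE:
                    lo, hi = _FREQ_RANGES[category]
                    osc_freq = float(rng.uniform(lo, hi))
                    if sleep:
                        osc_freq *= float(
                            np.exp(spec.condition_log_freq.get(category.value, 0.0))
                        )
                    band_lo, band_hi = (
                        _RIPPLE_BAND
                        if category in (Category.RON_O, Category.RON_S)
                        else _FAST_BAND
                    )
                    osc_freq = float(np.clip(osc_freq, band_lo + 1.0, band_hi - 1.0))
                if sleep:
                    scale = float(
                        np.exp(spec.condition_log_power.get(category.value, 0.0) / 2.0)
                    )
                    amp *= scale
                    spike_amp *= scale

                wave = _render_event(
                    category, rate_hz, amp, spike_amp, osc_freq, n_cycles, spike_width
                )
                dur_s = len(wave) / rate_hz
                placed = False
                for _attempt in range(max_attempts):
                    onset = float(rng.uniform(0.05, recording.duration_s - dur_s - 0.05))
                    lo_t, hi_t = onset - guard_s, onset + dur_s + guard_s
                    if all(hi_t <= a or lo_t >= b for a, b in occupied):
                        occupied.append((onset, onset + dur_s))
                        start = int(round(onset * rate_hz))
                        samples[ci, start : start + len(wave)] += wave
                        truth.append(
                            GroundTruthEvent(
                                channel_id=channel_id,
                                category=category,
                                onset_s=onset,
                                offset_s=onset + dur_s,
                                amplitude_uv=amp
                                if category is not Category.SHARP_SPIKE
                                else spike_amp,
                                osc_freq_hz=osc_freq,
                            )
                        )
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"could not place event on {channel_id}: density infeasible "
                        f"after {max_attempts} attempts"
                    )

    truth.sort(key=lambda ev: (ev.channel_id, ev.onset_s))
    out = Recording(
        samples=samples,
        rate_hz=rate_hz,
        channel_ids=recording.channel_ids,
        condition=condition,
        patient_id=recording.patient_id,
    )
    return out, truth


# ---------------------------------------------------------------------------
# cohort


def score_detections(
    detected: Sequence, truth: Sequence[GroundTruthEvent]
) -> dict[str, float]:
    """Recall/precision of detected intervals against planted ground truth.

    A detected event is a true positive when it overlaps a planted event on
    the same channel (half-open interval intersection > 0); a planted event
    is recalled when at least one detection overlaps it.
    """
    by_channel: dict[str, list[GroundTruthEvent]] = {}
    for g in truth:
        by_channel.setdefault(g.channel_id, []).append(g)

    recalled: set[int] = set()
    n_tp = 0
    for det in detected:
        hit = False
        for g in by_channel.get(det.channel_id, []):
            if min(det.offset_s, g.offset_s) > max(det.onset_s, g.onset_s):
                hit = True
                recalled.add(id(g))
        n_tp += hit
    precision = n_tp / len(detected) if detected else float("nan")
    recall = len(recalled) / len(truth) if truth else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_detected": len(detected),
        "n_truth": len(truth),
    }


@dataclass
class CohortBundle:
    """Everything a full analysis needs, with ground truth attached."""

    recordings: list[Recording]
    channel_infos: list[ChannelInfo]
    outcomes: list[PatientOutcome]
    ground_truth: dict[tuple[str, str], list[GroundTruthEvent]]  # (patient, condition)
    durations_s: dict[tuple[str, str], float]
    spec: SimulationSpec

    def truth_for(self, patient_id: str, condition: Condition | str) -> list[GroundTruthEvent]:
        return self.ground_truth[(patient_id, Condition(condition).value)]

    @property
    def all_truth(self) -> list[GroundTruthEvent]:
        return [ev for events in self.ground_truth.values() for ev in events]


_LOBES = (Lobe.FRONTAL, Lobe.PARIETAL, Lobe.TEMPORAL, Lobe.OCCIPITAL)


def simulate_cohort(spec: SimulationSpec) -> CohortBundle:
    """Simulate the full two-condition cohort.

    Per patient: all channels are recorded in the sleep condition, the
    matched subset also intraoperatively.  Failure patients (Engel III) get
    one high-rate SOZ channel left unresected; the fRonO rate on that channel
    is boosted so the planted failure mechanism is "top-percentile fast-ripple
    channel outside the resection".
    """
    root = np.random.SeedSequence(spec.seed)
    patient_seeds = root.spawn(spec.n_patients)

    recordings: list[Recording] = []
    channel_infos: list[ChannelInfo] = []
    outcomes: list[PatientOutcome] = []
    ground_truth: dict[tuple[str, str], list[GroundTruthEvent]] = {}
    durations: dict[tuple[str, str], float] = {}

    n_soz = max(1, int(round(spec.soz_fraction * spec.channels_per_patient)))
    n_matched = max(2, int(round(spec.matched_fraction * spec.channels_per_patient)))
    n_matched = min(n_matched, spec.channels_per_patient)

    for p in range(spec.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        patient_id = f"P{p + 1:02d}"
        channel_ids = [f"{patient_id}C{c + 1:02d}" for c in range(spec.channels_per_patient)]
        soz_idx = rng.choice(spec.channels_per_patient, size=n_soz, replace=False)
        soz_set = {channel_ids[i] for i in soz_idx}
        # matched subset always includes the SOZ sample plus random others
        others = [i for i in range(spec.channels_per_patient) if i not in set(soz_idx)]
        extra = rng.choice(
            others, size=max(0, n_matched - n_soz), replace=False
        ) if n_matched > n_soz else np.array([], dtype=int)
        matched_idx = sorted(set(soz_idx.tolist()) | set(extra.tolist()))
        matched_set = {channel_ids[i] for i in matched_idx}

        is_failure = p < spec.n_failure_patients
        has_mri = p < int(round(spec.postop_mri_fraction * spec.n_patients))
        hot_channel = channel_ids[int(soz_idx[0])]

        rate_overrides: dict[tuple[str, str], float] = {}
        if is_failure:
            # dominant unresected fast-ripple generator
            hot_rate = (
                spec.base_rates_per_min.get("fRonO", 1.0)
                * spec.soz_multipliers.get("fRonO", 1.0)
                * 4.0
            )
            rate_overrides[(hot_channel, "fRonO")] = hot_rate

        for i, cid in enumerate(channel_ids):
            in_soz = cid in soz_set
            if not has_mri:
                resected: Optional[bool] = None
            elif is_failure and cid == hot_channel:
                resected = False
            else:
                resected = in_soz  # successes: SOZ resected, rest untouched
            channel_infos.append(
                ChannelInfo(
                    channel_id=cid,
                    patient_id=patient_id,
                    lobe=_LOBES[i % len(_LOBES)],
                    soz=in_soz,
                    resected=resected,
                    matched=cid in matched_set,
                    montage_partner=None,
                )
            )

        for condition, duration in (
            (Condition.INTRAOP, spec.duration_intraop_s),
            (Condition.SLEEP, spec.duration_sleep_s),
        ):
            ids = (
                [channel_ids[i] for i in matched_idx]
                if condition is Condition.INTRAOP
                else channel_ids
            )
            background = simulate_background(
                duration,
                spec.rate_hz,
                condition,
                spec,
                rng=rng,
                channel_ids=ids,
                patient_id=patient_id,
            )
            rec, truth = plant_events(
                background, spec, rng, soz_channels=soz_set, rate_overrides=rate_overrides
            )
            recordings.append(rec)
            ground_truth[(patient_id, condition.value)] = truth
            durations[(patient_id, condition.value)] = duration

        outcomes.append(
            PatientOutcome(
                patient_id=patient_id,
                engel_class="III" if is_failure else "I",
                postop_mri=has_mri,
            )
        )

    return CohortBundle(
        recordings=recordings,
        channel_infos=channel_infos,
        outcomes=outcomes,
        ground_truth=ground_truth,
        durations_s=durations,
        spec=spec,
    )
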