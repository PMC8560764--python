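"""Shared fixtures: synthetic recordings and a session-scoped cohort pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from hfokit.classify import classify_all
from hfokit.core.config import ClassifierConfig, DetectorConfig
from hfokit.core.model import ChannelInfo, Condition
from hfokit.detect import detect_all
from hfokit.synth import SimulationSpec, plant_events, simulate_background, simulate_cohort

RATE_HZ = 2000.0


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    return SimulationSpec(seed=42)


@pytest.fixture(scope="session")
def noise_recording(default_spec):
    """60 s, 2-channel intraop background without events."""
    rng = np.random.default_rng(101)
    return simulate_background(
        60.0, RATE_HZ, Condition.INTRAOP, default_spec, n_channels=2, rng=rng
    )


@pytest.fixture(scope="session")
def planted_channel(default_spec):
    """One 10-min channel pair with default-rate planted events + truth."""
    rng = np.random.default_rng(7)
    background = simulate_background(
        600.0, RATE_HZ, Condition.INTRAOP, default_spec, n_channels=2, rng=rng
    )
    recording, truth = plant_events(
        background, default_spec, rng, soz_channels={background.channel_ids[0]}
    )
    return recording, truth


@pytest.fixture(scope="session")
def cohort():
    """Small two-condition cohort with ground truth (session-scoped)."""
    spec = SimulationSpec(
        seed=2024,
        n_patients=4,
        channels_per_patient=8,
        duration_intraop_s=90.0,
        duration_sleep_s=90.0,
        matched_fraction=0.75,
        n_failure_patients=2,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_pipeline(cohort):
    """Detection + classification over the session cohort."""
    det_cfg = DetectorConfig()
    cls_cfg = ClassifierConfig()
    candidates = []
    classified = []
    for rec in cohort.recordings:
        cands = detect_all(rec, cohort.channel_infos, det_cfg)
        candidates.extend(cands)
        classified.extend(classify_all(cands, rec, cls_cfg))
    return {
        "bundle": cohort,
        "candidates": candidates,
        "classified": classified,
    }


@pytest.fixture()
def channel_infos_pairs():
    """Six contacts forming three declared bipolar pairs."""
    infos = []
    for p in range(3):
        a, b = f"E{p}1", f"E{p}2"
        infos.append(ChannelInfo(channel_id=a, patient_id="P01", montage_partner=b))
        infos.append(ChannelInfo(channel_id=b, patient_id="P01"))
    return infos
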