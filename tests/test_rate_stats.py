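import itertools

import numpy as np
import pandas as pd
import pytest

from hfokit.core.model import (
    RATE_CATEGORIES,
    Band,
    Category,
    ChannelInfo,
    ClassifiedEvent,
    Condition,
)
from hfokit.ratestats import (
    auroc_mann_whitney,
    compare_auroc,
    compute_rates,
    condition_soz_rate_test,
    events_to_frame,
    fit_power_frequency_model,
    soz_roc,
)


def _event(channel, condition=Condition.INTRAOP, category=Category.RON_O, onset=1.0):
    return ClassifiedEvent(
        channel_id=channel, band=Band.BROAD_HFO, onset_s=onset, offset_s=onset + 0.05,
        peak_envelope_z=5.0, condition=condition, category=category,
        power=100.0, spectral_freq_hz=140.0,
    )


def _infos(n, patient="P01", soz_first=1, matched=True):
    return [
        ChannelInfo(
            channel_id=f"{patient}c{i}", patient_id=patient, soz=i < soz_first,
            matched=matched,
        )
        for i in range(n)
    ]


class TestComputeRates:
    def test_rate_arithmetic(self):
        infos = _infos(1)
        events = [_event("P01c0", onset=i * 10.0) for i in range(12)]
        rates = compute_rates(events, infos, {("P01", "intraop"): 600.0})
        row = rates[(rates["category"] == "RonO")].iloc[0]
        assert row["rate_per_min"] == pytest.approx(1.2)
        assert row["n_events"] == 12

    def test_empty_catalog_gives_zero_rows(self):
        infos = _infos(5)
        rates = compute_rates([], infos, {("P01", "intraop"): 60.0})
        assert len(rates) == 5 * len(RATE_CATEGORIES)
        assert (rates["rate_per_min"] == 0).all()

    def test_rate_times_minutes_equals_count(self, cohort_pipeline):
        bundle = cohort_pipeline["bundle"]
        rates = compute_rates(
            cohort_pipeline["classified"], bundle.channel_infos, bundle.durations_s
        )
        np.testing.assert_allclose(
            rates["rate_per_min"] * rates["minutes_analyzed"],
            rates["n_events"],
            atol=1e-9,
        )

    def test_artifact_excluded(self):
        infos = _infos(1)
        events = [_event("P01c0", category=Category.ARTIFACT)]
        rates = compute_rates(events, infos, {("P01", "intraop"): 60.0})
        assert (rates["n_events"] == 0).all()
        assert "Artifact" not in set(rates["category"])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            compute_rates([_event("ghost")], _infos(1), {("P01", "intraop"): 60.0})

    def test_unmatched_channels_absent_from_intraop(self):
        infos = _infos(2, matched=False)
        rates = compute_rates(
            [], infos, {("P01", "intraop"): 60.0, ("P01", "sleep"): 60.0}
        )
        assert set(rates["condition"]) == {"sleep"}


def _simulate_lmm_events(
    n_contacts, events_per_contact, intercept, condition_beta, soz_beta,
    re_sd=0.5, noise_sd=1.0, seed=0,
):
    """Direct simulation of per-event log-power with contact random intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_contacts):
        soz = i < n_contacts // 4
        b_i = rng.normal(0, re_sd)
        n_events = max(2, rng.poisson(events_per_contact))
        for _ in range(n_events):
            condition = rng.random() < 0.5
            log_power = (
                intercept + condition_beta * condition + soz_beta * soz + b_i
                + rng.normal(0, noise_sd)
            )
            rows.append(
                {
                    "channel_id": f"c{i}",
                    "patient_id": f"P{i // 20}",
                    "condition": "sleep" if condition else "intraop",
                    "soz": soz,
                    "category": "RonO",
                    "power": float(np.exp(log_power)),
                    "spectral_freq_hz": 140.0,
                }
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_planted_coefficients_recovered(self):
        # reference-scale planted coefficients for a ripple log-power fit
        df = _simulate_lmm_events(500, 40, 12.287, 1.291, 0.263, seed=1)
        fit = fit_power_frequency_model(df, "log_power", "RonO")
        for name, planted in (
            ("Intercept", 12.287),
            ("condition", 1.291),
            ("soz", 0.263),
        ):
            se = (fit.ci_high[name] - fit.ci_low[name]) / (2 * 1.96)
            assert abs(fit.estimates[name] - planted) < 3 * se
        assert fit.ci_low["condition"] < fit.estimates["condition"] < fit.ci_high["condition"]

    def test_null_condition_coverage(self):
        # CI covers 0 in most of 60 null replicates (nominal 95%)
        covered = 0
        for seed in range(60):
            df = _simulate_lmm_events(40, 8, 12.0, 0.0, 0.0, seed=seed)
            fit = fit_power_frequency_model(df, "log_power", "RonO")
            if fit.ci_low["condition"] <= 0.0 <= fit.ci_high["condition"]:
                covered += 1
        assert covered >= 51  # >= 85% with binomial slack at n=60

    def test_single_contact_rejected(self):
        df = _simulate_lmm_events(1, 10, 12.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="2 contacts"):
            fit_power_frequency_model(df, "log_power", "RonO")

    def test_bad_response_rejected(self):
        with pytest.raises(ValueError, match="response"):
            fit_power_frequency_model(pd.DataFrame(), "power", "RonO")

    def test_events_to_frame_joins_metadata(self, cohort_pipeline):
        bundle = cohort_pipeline["bundle"]
        df = events_to_frame(cohort_pipeline["classified"], bundle.channel_infos)
        assert {"channel_id", "condition", "soz", "power", "spectral_freq_hz"} <= set(df.columns)
        assert len(df) == len(cohort_pipeline["classified"])


def _rate_table(values, patient="P01"):
    """values: dict channel -> (intraop_rate, sleep_rate)."""
    rows = []
    for channel, (r_i, r_s) in values.items():
        for condition, r in (("intraop", r_i), ("sleep", r_s)):
            rows.append(
                {
                    "patient_id": patient,
                    "channel_id": channel,
                    "condition": condition,
                    "category": "RonO",
                    "n_events": r,
                    "minutes_analyzed": 1.0,
                    "rate_per_min": r,
                }
            )
    return pd.DataFrame(rows)


class TestConditionSozTest:
    def _null_table(self, n_contacts, seed):
        rng = np.random.default_rng(seed)
        values = {
            f"c{i}": (rng.normal(5, 1), rng.normal(5, 1)) for i in range(n_contacts)
        }
        return _rate_table(values), [
            ChannelInfo(channel_id=f"c{i}", patient_id="P01", soz=i % 2 == 0, matched=True)
            for i in range(n_contacts)
        ]

    def test_returns_three_effects(self):
        table, infos = self._null_table(20, 0)
        summary = condition_soz_rate_test(table, "RonO", infos)
        assert {"condition", "soz", "interaction"} <= set(summary.effects)
        for eff in summary.effects.values():
            assert 0.0 <= eff["p"] <= 1.0

    def test_planted_interaction_detected(self):
        # sleep-only SOZ elevation -> interaction significant in most runs
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = {}
            for i in range(40):
                soz = i % 2 == 0
                base = rng.normal(5, 0.5)
                sleep_boost = 2.0 if soz else 0.0
                values[f"c{i}"] = (base + rng.normal(0, 0.5), base + sleep_boost + rng.normal(0, 0.5))
            table = _rate_table(values)
            infos = [
                ChannelInfo(channel_id=f"c{i}", patient_id="P01", soz=i % 2 == 0, matched=True)
                for i in range(40)
            ]
            summary = condition_soz_rate_test(table, "RonO", infos)
            hits += summary.effects["interaction"]["p"] < 0.05
        assert hits >= 16  # >= 80%

    def test_single_contact_rejected(self):
        table, infos = self._null_table(1, 0)
        with pytest.raises(ValueError):
            condition_soz_rate_test(table, "RonO", infos)

    def test_unbalanced_contacts_dropped(self):
        table, infos = self._null_table(10, 3)
        table = table[~((table["channel_id"] == "c0") & (table["condition"] == "sleep"))]
        summary = condition_soz_rate_test(table, "RonO", infos)
        assert summary.n_contacts_dropped == 1
        assert summary.n_contacts_used == 9


def _brute_force_auroc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def _table_and_infos(self, scores, labels):
        infos = [
            ChannelInfo(channel_id=f"c{i}", patient_id="P01", soz=bool(l), matched=True)
            for i, l in enumerate(labels)
        ]
        rows = [
            {
                "patient_id": "P01",
                "channel_id": f"c{i}",
                "condition": "sleep",
                "category": "RonO",
                "n_events": s,
                "minutes_analyzed": 1.0,
                "rate_per_min": s,
            }
            for i, s in enumerate(scores)
        ]
        return pd.DataFrame(rows), infos

    def test_worked_example(self):
        # SOZ {3,5} vs non-SOZ {1,4}: 3 of 4 pairs concordant -> 0.75
        assert auroc_mann_whitney(
            np.array([3.0, 5.0, 1.0, 4.0]), np.array([True, True, False, False])
        ) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc_mann_whitney(
            np.array([10.0, 9.0, 1.0, 2.0]), np.array([True, True, False, False])
        ) == 1.0

    def test_all_ties_half(self):
        assert auroc_mann_whitney(
            np.ones(6), np.array([True, True, False, False, True, False])
        ) == pytest.approx(0.5)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.integers(0, 8, 30).astype(float)  # ties likely
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auroc_mann_whitney(scores, labels) == pytest.approx(
                _brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.random(50) < 0.3
        a = auroc_mann_whitney(scores, labels)
        b = auroc_mann_whitney(np.exp(5 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_soz_roc_end_to_end(self):
        rng = np.random.default_rng(2)
        labels = np.arange(40) < 10
        scores = np.where(labels, rng.normal(5, 1, 40), rng.normal(2, 1, 40))
        table, infos = self._table_and_infos(scores, labels)
        result = soz_roc(table, infos, "RonO", "sleep", n_boot=200, seed=0)
        assert 0.9 <= result.auroc <= 1.0
        assert result.auroc_ci_95[0] <= result.auroc <= result.auroc_ci_95[1]
        assert 0.0 <= result.partial_auroc <= 1.0
        # curve is monotone
        assert (np.diff(result.sensitivity) >= -1e-12).all()
        assert (np.diff(result.specificity) <= 1e-12).all()

    def test_single_class_rejected(self):
        table, infos = self._table_and_infos(np.ones(5), np.ones(5, dtype=bool))
        with pytest.raises(ValueError, match="SOZ"):
            soz_roc(table, infos, "RonO", "sleep")

    def test_compare_identical_curves(self):
        rng = np.random.default_rng(3)
        labels = np.arange(30) < 10
        scores = np.where(labels, rng.normal(4, 1, 30), rng.normal(2, 1, 30))
        table, infos = self._table_and_infos(scores, labels)
        roc = soz_roc(table, infos, "RonO", "sleep", n_boot=100, seed=0)
        result = compare_auroc(roc, roc, n_boot=200, seed=1)
        assert result["delta_auroc"] == 0.0
        assert result["p_value"] == pytest.approx(1.0)

    def test_compare_detects_planted_difference(self):
        detections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = np.arange(60) < 20
            strong = np.where(labels, rng.normal(5, 1, 60), rng.normal(2, 1, 60))
            weak = np.where(labels, rng.normal(2.6, 1, 60), rng.normal(2, 1, 60))
            ta, infos = self._table_and_infos(strong, labels)
            tb, _ = self._table_and_infos(weak, labels)
            ra = soz_roc(ta, infos, "RonO", "sleep", n_boot=50, seed=0)
            rb = soz_roc(tb, infos, "RonO", "sleep", n_boot=50, seed=0)
            res = compare_auroc(ra, rb, n_boot=400, seed=seed)
            detections += res["delta_auroc"] > 0 and res["p_value"] < 0.05
        assert detections >= 8

    def test_compare_requires_same_channels(self):
        rng = np.random.default_rng(4)
        labels = np.arange(20) < 8
        scores = rng.normal(3, 1, 20)
        ta, infos = self._table_and_infos(scores, labels)
        ra = soz_roc(ta, infos, "RonO", "sleep", n_boot=50, seed=0)
        tb, infos_b = self._table_and_infos(scores[:18], labels[:18])
        rb = soz_roc(tb, infos_b, "RonO", "sleep", n_boot=50, seed=0)
        with pytest.raises(ValueError, match="channel set"):
            compare_auroc(ra, rb)

    def test_zero_bootstrap_rejected(self):
        rng = np.random.default_rng(5)
        labels = np.arange(20) < 8
        scores = rng.normal(3, 1, 20)
        table, infos = self._table_and_infos(scores, labels)
        roc = soz_roc(table, infos, "RonO", "sleep", n_boot=50, seed=0)
        with pytest.raises(ValueError, match="n_boot"):
            compare_auroc(roc, roc, n_boot=0)
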