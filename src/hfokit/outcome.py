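"""Putative-EZ definition and patient-level outcome scoring.

The putative epileptogenic zone (EZ) per patient is the set of contacts
whose event rate strictly exceeds the 95th percentile (linear-interpolation
method) of the patient's pooled contact rates in a scope (intraoperative,
matched sleep contacts, or all sleep contacts).  A patient predicts failure
when some EZ contact lies outside the resection; the actual outcome is a
failure when the Engel class is IIa or worse.  Contingency metrics carry
Clopper-Pearson 95% CIs; degenerate 0/0 ratios are reported as 0.0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .core.model import Category, ChannelInfo, Condition, PatientOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "Scope",
    "EZDefinition",
    "PatientLabel",
    "ContingencyMetrics",
    "define_ez",
    "score_patient",
    "aggregate_metrics",
    "binomial_ci",
    "outcome_analysis",
]


class Scope(str, Enum):
    INTRAOP = "intraop"
    SLEEP_MATCHED = "sleep_matched"
    SLEEP_ALL = "sleep_all"


class PatientLabel(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    EXCLUDED = "excluded"


@dataclass
class EZDefinition:
    patient_id: str
    category: str
    scope: Scope
    threshold_rate: float
    ez_channels: frozenset[str]
    n_contacts: int


def _scope_rows(
    rates: pd.DataFrame, infos: Sequence[ChannelInfo], scope: Scope, category: str
) -> pd.DataFrame:
    matched = {ci.channel_id for ci in infos if ci.matched}
    df = rates[rates["category"] == category]
    if scope is Scope.INTRAOP:
        df = df[df["condition"] == Condition.INTRAOP.value]
        df = df[df["channel_id"].isin(matched)]
    elif scope is Scope.SLEEP_MATCHED:
        df = df[df["condition"] == Condition.SLEEP.value]
        df = df[df["channel_id"].isin(matched)]
    else:
        df = df[df["condition"] == Condition.SLEEP.value]
    return df


def define_ez(
    rates: pd.DataFrame,
    channel_infos: Sequence[ChannelInfo],
    scope: Scope | str,
    category: str | Category,
) -> dict[str, EZDefinition]:
    """95th-percentile positive regions, one :class:`EZDefinition` per patient.

    The percentile is computed by linear interpolation over the patient's
    pooled contact rates in the scope; strict exceedance selects channels.
    Fewer than 20 in-scope contacts triggers a warning; an empty scope is an
    error.
    """
    scope = Scope(scope)
    category = Category(category).value
    df = _scope_rows(rates, channel_infos, scope, category)
    if df.empty:
        raise ValueError(f"no rate rows for scope {scope.value!r}")

    out: dict[str, EZDefinition] = {}
    for patient_id, sub in df.groupby("patient_id"):
        values = sub["rate_per_min"].to_numpy(dtype=np.float64)
        if len(values) < 20:
            warnings.warn(
                f"{patient_id}: only {len(values)} contacts in scope; 95th "
                "percentile is poorly determined"
            )
        threshold = float(np.percentile(values, 95.0))
        ez = frozenset(sub.loc[sub["rate_per_min"] > threshold, "channel_id"])
        if not values.any():
            warnings.warn(f"{patient_id}: all rates zero; empty positive region")
        out[patient_id] = EZDefinition(
            patient_id=patient_id,
            category=category,
            scope=scope,
            threshold_rate=threshold,
            ez_channels=ez,
            n_contacts=len(values),
        )
    return out


def score_patient(
    ez: EZDefinition,
    channel_infos: Sequence[ChannelInfo],
    outcome: Optional[PatientOutcome],
) -> PatientLabel:
    """Cross-tabulate one patient's EZ-resection prediction against outcome.

    Positive prediction: some EZ channel unresected (empty EZ counts as a
    negative prediction).  Actual positive: Engel IIa or worse.  Patients
    without post-op imaging, without an outcome, or with an EZ channel of
    unknown resection status are excluded.
    """
    if outcome is None or not outcome.postop_mri:
        logger.info("%s: no post-op imaging/outcome, excluded", ez.patient_id)
        return PatientLabel.EXCLUDED
    resection = {
        ci.channel_id: ci.resected
        for ci in channel_infos
        if ci.patient_id == ez.patient_id
    }
    statuses = []
    for cid in ez.ez_channels:
        status = resection.get(cid)
        if status is None:
            logger.info(
                "%s: resection status of EZ channel %s unknown, excluded",
                ez.patient_id,
                cid,
            )
            return PatientLabel.EXCLUDED
        statuses.append(status)

    predicted_positive = any(status is False for status in statuses)
    actual_positive = outcome.is_failure
    if predicted_positive and actual_positive:
        return PatientLabel.TP
    if predicted_positive and not actual_positive:
        return PatientLabel.FP
    if not predicted_positive and actual_positive:
        return PatientLabel.FN
    return PatientLabel.TN


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval via beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


@dataclass
class ContingencyMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = 0.0
    specificity: float = 0.0
    ppv: float = 0.0
    npv: float = 0.0
    accuracy: float = 0.0
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "ci_95": {k: list(v) for k, v in self.ci_95.items()},
            "degenerate": self.degenerate,
            "n_excluded": self.n_excluded,
        }


def aggregate_metrics(labels: Sequence[PatientLabel | str]) -> ContingencyMetrics:
    """Contingency metrics over per-patient labels.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/N.  A 0/0 ratio is reported as 0.0
    and listed under ``degenerate``.  CIs are Clopper-Pearson at 95%.
    """
    labels = [PatientLabel(l) for l in labels]
    counted = [l for l in labels if l is not PatientLabel.EXCLUDED]
    if not counted:
        raise ValueError("all patients excluded; nothing to aggregate")
    tp = sum(1 for l in counted if l is PatientLabel.TP)
    fp = sum(1 for l in counted if l is PatientLabel.FP)
    tn = sum(1 for l in counted if l is PatientLabel.TN)
    fn = sum(1 for l in counted if l is PatientLabel.FN)

    metrics = ContingencyMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=len(labels) - len(counted)
    )

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            metrics.degenerate.append(name)
            metrics.ci_95[name] = (0.0, 0.0)
            return 0.0
        metrics.ci_95[name] = binomial_ci(num, den)
        return num / den

    metrics.sensitivity = ratio("sensitivity", tp, tp + fn)
    metrics.specificity = ratio("specificity", tn, tn + fp)
    metrics.ppv = ratio("ppv", tp, tp + fp)
    metrics.npv = ratio("npv", tn, tn + fn)
    metrics.accuracy = ratio("accuracy", tp + tn, tp + fp + tn + fn)
    return metrics


def outcome_analysis(
    rates: pd.DataFrame,
    channel_infos: Sequence[ChannelInfo],
    outcomes: Sequence[PatientOutcome],
    category: str | Category,
    scope: Scope | str,
) -> tuple[ContingencyMetrics, dict[str, PatientLabel]]:
    """End-to-end: define EZ per patient, score each, aggregate."""
    ez_by_patient = define_ez(rates, channel_infos, scope, category)
    outcome_by_patient = {o.patient_id: o for o in outcomes}
    labels = {}
    for patient_id, ez in ez_by_patient.items():
        labels[patient_id] = score_patient(
            ez, channel_infos, outcome_by_patient.get(patient_id)
        )
    return aggregate_metrics(list(labels.values())), labels
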