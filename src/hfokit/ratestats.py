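"""Per-contact event rates and group statistics.

* rate tables: events/min per contact x category x condition (Artifact
  excluded);
* linear mixed models of natural-log event power / spectral frequency with a
  random intercept per contact and condition + SOZ fixed effects;
* a mixed two-way ANOVA (within: condition, between: SOZ / lobe / anesthesia)
  on matched-contact rates;
* SOZ-classification ROC with channel-bootstrap CIs and a McClish-normalized
  partial AUROC on the specificity > 0.8 segment.

AUROC is computed as the Mann-Whitney U statistic normalized by n1*n2 with
ties counted 1/2, which equals the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy.stats import rankdata

from .core.model import (
    RATE_CATEGORIES,
    Category,
    ChannelInfo,
    ClassifiedEvent,
    Condition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rates",
    "events_to_frame",
    "MixedModelFit",
    "fit_power_frequency_model",
    "AnovaSummary",
    "condition_soz_rate_test",
    "RocResult",
    "soz_roc",
    "compare_auroc",
    "auroc_mann_whitney",
]


def compute_rates(
    events: Sequence[ClassifiedEvent],
    channel_infos: Sequence[ChannelInfo],
    durations_s: dict[tuple[str, str], float],
) -> pd.DataFrame:
    """Events/min per (patient, channel, condition, category).

    ``durations_s`` maps ``(patient_id, condition)`` to analyzed seconds.
    Channels present in a condition (all channels for sleep, matched ones for
    intraop) appear with rate 0 when they have no events; Artifact events are
    excluded.  An event referencing an unknown channel is an error.
    """
    info_by_id = {ci.channel_id: ci for ci in channel_infos}
    counts: dict[tuple[str, str, str], int] = {}
    for ev in events:
        if ev.category is Category.ARTIFACT:
            continue
        if ev.channel_id not in info_by_id:
            raise ValueError(f"event references unknown channel {ev.channel_id!r}")
        key = (ev.channel_id, ev.condition.value, ev.category.value)
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for ci in channel_infos:
        for (patient_id, condition) , dur in durations_s.items():
            if ci.patient_id != patient_id:
                continue
            if condition == Condition.INTRAOP.value and not ci.matched:
                continue  # intraop montage covers matched contacts only
            minutes = dur / 60.0
            for cat in RATE_CATEGORIES:
                n = counts.get((ci.channel_id, condition, cat.value), 0)
                rows.append(
                    {
                        "patient_id": patient_id,
                        "channel_id": ci.channel_id,
                        "condition": condition,
                        "category": cat.value,
                        "n_events": n,
                        "minutes_analyzed": minutes,
                        "rate_per_min": n / minutes,
                    }
                )
    return pd.DataFrame(rows)


def events_to_frame(
    events: Sequence[ClassifiedEvent], channel_infos: Sequence[ChannelInfo]
) -> pd.DataFrame:
    """Flatten classified events joined with channel metadata (for modeling)."""
    info_by_id = {ci.channel_id: ci for ci in channel_infos}
    rows = []
    for ev in events:
        ci = info_by_id.get(ev.channel_id)
        if ci is None:
            raise ValueError(f"event references unknown channel {ev.channel_id!r}")
        rows.append(
            {
                "channel_id": ev.channel_id,
                "patient_id": ci.patient_id,
                "condition": ev.condition.value,
                "soz": ci.soz,
                "category": ev.category.value,
                "power": ev.power,
                "spectral_freq_hz": ev.spectral_freq_hz,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MixedModelFit:
    response: str  # "log_power" or "log_frequency"
    category: str
    n_events: int
    n_contacts: int
    estimates: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    converged: bool
    singular: bool = False

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "category": self.category,
            "n_events": self.n_events,
            "n_contacts": self.n_contacts,
            "estimates": self.estimates,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_values": self.p_values,
            "random_intercept_var": self.random_intercept_var,
            "converged": self.converged,
            "singular": self.singular,
        }


def fit_power_frequency_model(
    events: pd.DataFrame,
    response: str,
    category: str | Category,
) -> MixedModelFit:
    """Linear mixed model of ln(power) or ln(frequency) per event.

    Random intercept per contact; fixed effects: condition (sleep = 1) and
    SOZ membership; maximum-likelihood estimation.  Requires at least two
    contacts with at least two events each.
    """
    if response not in ("log_power", "log_frequency"):
        raise ValueError("response must be 'log_power' or 'log_frequency'")
    category = Category(category).value
    df = events[events["category"] == category].copy()
    raw = df["power"] if response == "log_power" else df["spectral_freq_hz"]
    df = df[np.isfinite(raw) & (raw > 0)]
    counts = df.groupby("channel_id").size()
    eligible = counts[counts >= 2]
    if len(eligible) < 2:
        raise ValueError(
            "mixed model requires >= 2 contacts with >= 2 events each "
            f"(got {len(eligible)})"
        )
    df = df[df["channel_id"].isin(eligible.index)]

    y = np.log(
        df["power"].to_numpy()
        if response == "log_power"
        else df["spectral_freq_hz"].to_numpy()
    )
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "condition": (df["condition"] == Condition.SLEEP.value).astype(float),
            "soz": df["soz"].astype(float),
        }
    )
    model = sm.MixedLM(y, X, groups=df["channel_id"].to_numpy())
    singular = False
    try:
        result = model.fit(reml=False, method="lbfgs")
    except np.linalg.LinAlgError:
        result = model.fit(reml=False, method="powell")
    if not result.converged:
        logger.warning("mixed model did not fully converge; estimates returned")
    cov_re = float(np.asarray(result.cov_re).ravel()[0])
    if cov_re <= 1e-10:
        singular = True
        logger.warning("singular fit: random-intercept variance collapsed to ~0")

    names = ["Intercept", "condition", "soz"]
    ci = result.conf_int()
    return MixedModelFit(
        response=response,
        category=category,
        n_events=len(df),
        n_contacts=df["channel_id"].nunique(),
        estimates={n: float(result.params[n]) for n in names},
        ci_low={n: float(ci.loc[n, 0]) for n in names},
        ci_high={n: float(ci.loc[n, 1]) for n in names},
        p_values={n: float(result.pvalues[n]) for n in names},
        random_intercept_var=cov_re,
        converged=bool(result.converged),
        singular=singular,
    )


@dataclass
class AnovaSummary:
    category: str
    between_factor: str
    n_contacts_used: int
    n_contacts_dropped: int
    effects: dict[str, dict[str, float]]  # effect -> {F, df1, df2, p}

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "between_factor": self.between_factor,
            "n_contacts_used": self.n_contacts_used,
            "n_contacts_dropped": self.n_contacts_dropped,
            "effects": self.effects,
        }


def condition_soz_rate_test(
    rates: pd.DataFrame,
    category: str | Category,
    channel_infos: Sequence[ChannelInfo],
    between: str = "soz",
) -> AnovaSummary:
    """Two-way repeated-measures rate comparison on matched contacts.

    Within-factor: recording condition (2 levels); between-factor: SOZ by
    default, or ``lobe`` when requested.  Estimated as a mixed two-way ANOVA
    (mixed-model-equivalent decomposition); contacts missing either condition
    are dropped with a logged count.
    """
    category = Category(category).value
    info_by_id = {ci.channel_id: ci for ci in channel_infos}
    df = rates[rates["category"] == category].copy()
    if between == "soz":
        df["between"] = df["channel_id"].map(lambda c: bool(info_by_id[c].soz))
    elif between == "lobe":
        df["between"] = df["channel_id"].map(lambda c: info_by_id[c].lobe.value)
    else:
        raise ValueError(f"unsupported between-factor {between!r}")

    have_both = df.groupby("channel_id")["condition"].nunique()
    balanced = set(have_both[have_both == 2].index)
    dropped = df["channel_id"].nunique() - len(balanced)
    if dropped:
        logger.info("dropping %d contacts missing one condition", dropped)
    df = df[df["channel_id"].isin(balanced)]
    if df["channel_id"].nunique() < 2:
        raise ValueError("need at least two contacts with both conditions")
    if df["between"].nunique() < 2:
        raise ValueError("between-factor has a single level in the matched data")

    aov = pg.mixed_anova(
        data=df,
        dv="rate_per_min",
        within="condition",
        subject="channel_id",
        between="between",
        correction=False,
    )
    effects = {}
    name_map = {"between": between, "condition": "condition", "Interaction": "interaction"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for _, row in aov.iterrows():
        key = name_map.get(row["Source"], row["Source"])
        effects[key] = {
            "F": float(row["F"]),
            "df1": float(row["DF1"]),
            "df2": float(row["DF2"]),
            "p": float(row[p_col]),
        }
    return AnovaSummary(
        category=category,
        between_factor=between,
        n_contacts_used=df["channel_id"].nunique(),
        n_contacts_dropped=dropped,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# ROC


def auroc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    """Empirical ROC points sorted by increasing false-positive rate."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1] if tps[-1] else np.zeros_like(tps)]
    fpr = np.r_[0.0, fps / fps[-1] if fps[-1] else np.zeros_like(fps)]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def _partial_auroc(
    fpr: np.ndarray, tpr: np.ndarray, max_fpr: float = 0.2, mcclish: bool = True
) -> float:
    """Trapezoidal pAUC over fpr in [0, max_fpr], McClish-rescaled to [0, 1]."""
    grid = np.unique(np.clip(np.r_[fpr, 0.0, max_fpr], 0.0, max_fpr))
    interp = np.interp(grid, fpr, tpr)
    pauc = float(np.trapezoid(interp, grid))
    if not mcclish:
        return pauc
    max_area = max_fpr
    min_area = 0.5 * max_fpr**2  # chance diagonal
    return 0.5 * (1.0 + (pauc - min_area) / (max_area - min_area))


@dataclass
class RocResult:
    category: str
    condition: str
    auroc: float
    auroc_ci_95: tuple[float, float]
    partial_auroc: float
    n_bootstrap: int
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    channel_ids: tuple[str, ...] = ()
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "condition": self.condition,
            "auroc": self.auroc,
            "auroc_ci_95": list(self.auroc_ci_95),
            "partial_auroc": self.partial_auroc,
            "n_bootstrap": self.n_bootstrap,
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
        }


def soz_roc(
    rates: pd.DataFrame,
    channel_infos: Sequence[ChannelInfo],
    category: str | Category,
    condition: str | Condition,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    channel_subset: Optional[Sequence[str]] = None,
) -> RocResult:
    """ROC for classifying SOZ membership from the per-contact event rate."""
    category = Category(category).value
    condition = Condition(condition).value
    info_by_id = {ci.channel_id: ci for ci in channel_infos}
    df = rates[(rates["category"] == category) & (rates["condition"] == condition)]
    if channel_subset is not None:
        df = df[df["channel_id"].isin(set(channel_subset))]
    if df.empty:
        raise ValueError("no rate rows in the requested scope")

    channels = df["channel_id"].to_numpy()
    scores = df["rate_per_min"].to_numpy(dtype=np.float64)
    labels = np.array([info_by_id[c].soz for c in channels], dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both SOZ and non-SOZ channels are required")

    auroc = auroc_mann_whitney(scores, labels)
    fpr, tpr, thresholds = _roc_curve(scores, labels)
    pauc = _partial_auroc(fpr, tpr, max_fpr=0.2)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(scores), len(scores))
        if labels[idx].all() or not labels[idx].any():
            continue
        boots.append(auroc_mann_whitney(scores[idx], labels[idx]))
    ci = (
        tuple(np.percentile(boots, [2.5, 97.5]).tolist())
        if boots
        else (float("nan"), float("nan"))
    )

    return RocResult(
        category=category,
        condition=condition,
        auroc=auroc,
        auroc_ci_95=ci,
        partial_auroc=pauc,
        n_bootstrap=n_boot,
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        channel_ids=tuple(channels),
        scores=scores,
        labels=labels,
    )


def compare_auroc(
    roc_a: RocResult,
    roc_b: RocResult,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Paired channel-bootstrap comparison of two ROC curves.

    Both results must rest on the same channels.  Returns the observed
    difference (a minus b), its bootstrap CI, and a two-sided p-value.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if set(roc_a.channel_ids) != set(roc_b.channel_ids) or not roc_a.channel_ids:
        raise ValueError("ROC results must share an identical channel set")

    order_b = {c: i for i, c in enumerate(roc_b.channel_ids)}
    idx_b = np.array([order_b[c] for c in roc_a.channel_ids])
    scores_a, labels = roc_a.scores, roc_a.labels
    scores_b = roc_b.scores[idx_b]

    delta = roc_a.auroc - roc_b.auroc
    rng = np.random.default_rng(seed)
    deltas = []
    n = len(scores_a)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lab = labels[idx]
        if lab.all() or not lab.any():
            continue
        deltas.append(
            auroc_mann_whitney(scores_a[idx], lab)
            - auroc_mann_whitney(scores_b[idx], lab)
        )
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise RuntimeError("all bootstrap replicates degenerate")
    ci = tuple(np.percentile(deltas, [2.5, 97.5]).tolist())
    p = 2.0 * min(float(np.mean(deltas <= 0.0)), float(np.mean(deltas >= 0.0)))
    return {
        "delta_auroc": float(delta),
        "ci_95": ci,
        "p_value": min(1.0, p),
        "n_bootstrap": int(deltas.size),
    }
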