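"""Spatial reliability of per-contact rate maps across recording conditions.

The statistic is the normalized scalar product (cosine) between the two
conditions' rate vectors over matched contacts.  Its null distribution is
built by independently permuting the channel order of each vector; the
one-sided p-value uses add-one smoothing so p > 0 always.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core.model import Category, Condition

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroVectorError",
    "DegenerateNullError",
    "scalar_product",
    "permutation_reliability",
    "cohort_reliability",
    "ReliabilityResult",
]


class ZeroVectorError(ValueError):
    """Scalar product undefined: a rate vector is all zero."""


class DegenerateNullError(ValueError):
    """Permutation null degenerate: a rate vector is constant."""


def scalar_product(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Normalized scalar product dot(v1, v2) / (||v1|| * ||v2||)."""
    a = np.asarray(v1, dtype=np.float64)
    b = np.asarray(v2, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroVectorError("scalar product undefined for a zero rate vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class ReliabilityResult:
    patient_id: str
    category: str
    s_obs: float
    p_value: float
    n_perm: int
    n_channels: int
    null_mean: float
    null_p95: float

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "category": self.category,
            "s_obs": self.s_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n_channels": self.n_channels,
            "null_mean": self.null_mean,
            "null_p95": self.null_p95,
        }


def permutation_reliability(
    v1: Sequence[float],
    v2: Sequence[float],
    n_perm: int = 2000,
    seed: Optional[int] = None,
    patient_id: str = "",
    category: str = "",
) -> ReliabilityResult:
    """Channel-permutation test of the normalized scalar product.

    Each replicate independently permutes the channel order of both vectors;
    ``p = (1 + #{s_perm >= s_obs}) / (1 + n_perm)`` (one-sided: high cosine
    means reliable spatial alignment).  Deterministic under a fixed seed.
    """
    a = np.asarray(v1, dtype=np.float64)
    b = np.asarray(v2, dtype=np.float64)
    if a.size < 3:
        raise ValueError("permutation test requires vectors of length >= 3")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-value resolution is poor")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateNullError(
            "constant rate vector: permutation null is degenerate"
        )
    s_obs = scalar_product(a, b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = scalar_product(rng.permutation(a), rng.permutation(b))
    n_exceed = int(np.sum(null >= s_obs))
    p = (1.0 + n_exceed) / (1.0 + n_perm)
    return ReliabilityResult(
        patient_id=patient_id,
        category=category,
        s_obs=s_obs,
        p_value=p,
        n_perm=n_perm,
        n_channels=a.size,
        null_mean=float(null.mean()),
        null_p95=float(np.percentile(null, 95)),
    )


def cohort_reliability(
    rates: pd.DataFrame,
    categories: Optional[Sequence[str | Category]] = None,
    n_perm: int = 2000,
    seed: Optional[int] = None,
) -> list[ReliabilityResult]:
    """Per patient x category reliability over matched contacts.

    Uses contacts that carry rates in both conditions; patients with fewer
    than 3 such contacts, and degenerate (zero/constant) rate maps, are
    skipped with a log entry.
    """
    if categories is None:
        categories = sorted(rates["category"].unique())
    categories = [Category(c).value for c in categories]
    rng = np.random.default_rng(seed)

    results = []
    for (patient_id,), patient_df in rates.groupby(["patient_id"]):
        for category in categories:
            sub = patient_df[patient_df["category"] == category]
            pivot = sub.pivot_table(
                index="channel_id", columns="condition", values="rate_per_min"
            )
            needed = {Condition.INTRAOP.value, Condition.SLEEP.value}
            if not needed.issubset(pivot.columns):
                logger.info("%s/%s: missing a condition, skipped", patient_id, category)
                continue
            pivot = pivot.dropna()
            if len(pivot) < 3:
                logger.info(
                    "%s/%s: only %d matched contacts, skipped",
                    patient_id,
                    category,
                    len(pivot),
                )
                continue
            v1 = pivot[Condition.INTRAOP.value].to_numpy()
            v2 = pivot[Condition.SLEEP.value].to_numpy()
            try:
                results.append(
                    permutation_reliability(
                        v1,
                        v2,
                        n_perm=n_perm,
                        seed=rng.integers(2**31),
                        patient_id=patient_id,
                        category=category,
                    )
                )
            except (ZeroVectorError, DegenerateNullError) as exc:
                logger.info("%s/%s: %s, skipped", patient_id, category, exc)
    return results
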