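"""Individualized survival graphs from risk-nearest training patients.

For a new patient, the fitted model predicts a risk score; the patients
in the training cohort whose predicted risks are closest (absolute
difference, default the nearest 5%) are selected and their outcomes
yield a Kaplan-Meier curve — an individualized survival graph backed by
observed follow-up of risk-matched patients rather than a parametric
baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Cohort, PatientRecord
from .evaluation import KMCurve, km_estimate

__all__ = ["SurvivalGraphResult", "risk_percentile", "neighbor_km"]

DEFAULT_NEIGHBOR_FRACTION = 0.05


@dataclass(frozen=True)
class SurvivalGraphResult:
    """Risk, its percentile among training risks, and the neighbor KM curve."""

    risk: float
    percentile: float  # 0..100 among the training risks
    neighbor_ids: tuple[str, ...]
    km: KMCurve
    fraction: float


def risk_percentile(new_risk: float, train_risks) -> float:
    """100 x fraction of training risks <= the new risk."""
    train_risks = np.asarray(train_risks, dtype=float)
    if train_risks.size == 0:
        raise ValueError("train_risks must be non-empty")
    return float(100.0 * (train_risks <= new_risk).mean())


def _neighbor_count(n_train: int, fraction: float) -> int:
    # round half away from zero, floor of one neighbor
    return max(1, int(np.floor(fraction * n_train + 0.5)))


def neighbor_km(new_record: PatientRecord, results, train_cohort: Cohort,
                fraction: float = DEFAULT_NEIGHBOR_FRACTION) -> SurvivalGraphResult:
    """KM curve over the training patients with the most similar risk.

    Similarity is the absolute difference in predicted (serial-mode)
    risk; k = max(1, round(fraction * n_train)) neighbors are kept, ties
    broken by stable training order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    if len(train_cohort) == 0:
        raise ValueError("training cohort must be non-empty")
    train_risks = results.predict_cohort(train_cohort, mode="serial")
    new_risk = results.predict_risk(new_record, mode="serial")
    k = _neighbor_count(len(train_cohort), fraction)
    order = np.argsort(np.abs(train_risks - new_risk), kind="stable")
    chosen = np.sort(order[:k])  # stable original order for the outcomes
    times = train_cohort.times()[chosen]
    events = train_cohort.events()[chosen]
    return SurvivalGraphResult(
        risk=float(new_risk),
        percentile=risk_percentile(new_risk, train_risks),
        neighbor_ids=tuple(train_cohort.patient_ids[i] for i in chosen),
        km=km_estimate(times, events),
        fraction=float(fraction),
    )
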