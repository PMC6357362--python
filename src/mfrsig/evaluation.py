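"""Risk scoring, percentile stratification, Kaplan-Meier curves, log-rank tests.

A fitted signature assigns each patient the linear predictor of the
multivariate Cox model as a risk score.  Patients whose score exceeds the
75th percentile (default) of the *training* scores are called high-risk;
the same threshold is applied unchanged to the validation split, whose
log-rank p-value is the honest measure of the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .discovery import Signature
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 75.0


class SplitLabel(str, Enum):
    TRAINING = "training"
    VALIDATION = "validation"


@dataclass(frozen=True)
class RiskStratification:
    """High/low risk assignment with its log-rank comparison."""

    threshold: float
    groups: dict  # patient_id -> "high" | "low"
    logrank_statistic: float
    logrank_p: float
    split_label: SplitLabel

    @property
    def n_high(self) -> int:
        return sum(1 for g in self.groups.values() if g == "high")

    @property
    def n_low(self) -> int:
        return sum(1 for g in self.groups.values() if g == "low")


def risk_scores(signature: Signature, matrix: ProfileMatrix) -> dict[str, float]:
    """Linear predictor sum(coef_g * profile value_g) per patient."""
    missing = [g for g in signature.genes if g not in matrix.genes]
    if missing:
        raise ValueError(f"signature gene(s) missing from profile matrix: {missing}")
    cols = [matrix.genes.index(g) for g in signature.genes]
    scores = matrix.values[:, cols] @ np.asarray(signature.coefficients)
    return {p: float(s) for p, s in zip(matrix.patients, scores)}


def percentile_threshold(training_scores, percentile: float = DEFAULT_PERCENTILE) -> float:
    """Linear-interpolation percentile of the training risk scores."""
    scores = np.asarray(list(training_scores), dtype=float)
    if scores.size < 4:
        raise ValueError("need >= 4 training scores for a percentile threshold")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(scores, percentile, method="linear"))


def stratify(scores: dict, threshold: float) -> dict[str, str]:
    """Score strictly above the threshold -> high risk; else low."""
    groups = {p: ("high" if s > threshold else "low") for p, s in scores.items()}
    labels = set(groups.values())
    if len(labels) < 2 and groups:
        logger.warning("stratify: all patients fell in the %s-risk group", labels.pop())
    return groups


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one patient group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_at_risk": self.at_risk,
                "n_events": self.events,
            }
        )


def km_estimate(group, clinical) -> KMCurve:
    """Kaplan-Meier product-limit estimate over the given patient group."""
    group = set(group)
    if not group:
        raise ValueError("cannot estimate survival of an empty group")
    recs = [c for c in clinical if c.patient_id in group]
    if len(recs) != len(group):
        raise ValueError("clinical records missing for some group members")
    t = np.array([c.time for c in recs])
    e = np.array([c.event for c in recs], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
    )


def logrank_test(groups: dict, clinical) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) comparing high vs low risk."""
    by_id = {c.patient_id: c for c in clinical}
    high = [p for p, g in groups.items() if g == "high"]
    low = [p for p, g in groups.items() if g == "low"]
    if not high or not low:
        raise ValueError("log-rank test needs two non-empty groups")
    t_h = np.array([by_id[p].time for p in high])
    e_h = np.array([by_id[p].event for p in high], dtype=bool)
    t_l = np.array([by_id[p].time for p in low])
    e_l = np.array([by_id[p].event for p in low], dtype=bool)
    if e_h.sum() + e_l.sum() < 1:
        raise ValueError("log-rank test needs >= 1 observed event")
    res = _ll_logrank(t_h, t_l, event_observed_A=e_h, event_observed_B=e_l)
    return float(res.test_statistic), float(res.p_value)


def evaluate_split(
    signature: Signature,
    matrix: ProfileMatrix,
    clinical,
    threshold: float,
    split_label: SplitLabel | str,
) -> RiskStratification:
    """Score, stratify and log-rank-test one cohort split at a fixed threshold.

    If the threshold puts every patient in one risk group the comparison
    is vacuous: the stratification is reported with statistic 0 and p = 1
    (plus a warning) rather than failing the run.
    """
    scores = risk_scores(signature, matrix)
    groups = stratify(scores, threshold)
    if len(set(groups.values())) < 2:
        logger.warning("evaluate_split(%s): single risk group; log-rank test vacuous", split_label)
        stat, p = 0.0, 1.0
    else:
        stat, p = logrank_test(groups, clinical)
    return RiskStratification(
        threshold=threshold,
        groups=groups,
        logrank_statistic=stat,
        logrank_p=p,
        split_label=SplitLabel(split_label),
    )
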