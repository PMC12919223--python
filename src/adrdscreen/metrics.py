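"""Screening-test evaluation: ROC/AUC, specificity thresholds, prevalence
standardization, likelihood ratios, subgroup and horizon-decay summaries.

Discrimination metrics (AUC, sensitivity, specificity, likelihood ratios)
are prevalence-invariant, but predictive values are not, so PPV/NPV are
reported at a fixed standardization prevalence (default 10.9%, roughly one
in nine) rather than at each cohort's own case fraction — this makes
screening performance directly comparable across sites with very different
case mixes.

Threshold convention: a patient screens positive when their score exceeds
the threshold strictly (ties push toward fewer false positives, the
conservative choice), and ``threshold_at_specificity`` returns the smallest
threshold whose empirical control specificity meets the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "PrevalenceSpec",
    "MetricReport",
    "roc_auc",
    "threshold_at_specificity",
    "standardized_predictive_values",
    "ppv_from_lr",
    "standardized_accuracy",
    "percent",
    "horizon_decay",
    "evaluate_scores",
    "subgroup_report",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class PrevalenceSpec:
    """Standardization prevalence; default 10.9% (≈ 1 in 9)."""

    pi: float = 0.109

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("prevalence must lie strictly between 0 and 1")


@dataclass(frozen=True)
class MetricReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    threshold: float
    n_cases: int
    n_controls: int
    stratum: Optional[dict] = None
    ci_halfwidths: Optional[dict] = None
    suppressed_reason: Optional[str] = None


def _split_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    return scores[labels == 1], scores[labels == 0]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = Mann–Whitney pairwise concordance, ties counted one half."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_at_specificity(
    control_scores: Sequence[float], target: float = 0.95
) -> float:
    """Smallest threshold whose empirical control specificity ≥ target.

    With the strict-exceedance positivity rule (positive iff score >
    threshold), this is the ⌈target·n⌉-th smallest control score.
    """
    control_scores = np.sort(np.asarray(control_scores, dtype=float))
    n = len(control_scores)
    if n == 0:
        raise ValueError("no control scores supplied")
    if n < 20:
        warnings.warn(f"only {n} controls: the specificity threshold is unstable")
    if not 0 < target <= 1:
        raise ValueError("target specificity must lie in (0, 1]")
    if control_scores[0] == control_scores[-1]:
        warnings.warn("all control scores identical: degenerate threshold")
    m = math.ceil(target * n)
    return float(control_scores[m - 1])


def standardized_predictive_values(
    sensitivity: float, specificity: float, prev: PrevalenceSpec = PrevalenceSpec()
) -> tuple[float, float, float, float]:
    """(PPV, NPV, LR+, LR−) at the standardization prevalence.

    PPV = se·π / (se·π + (1−sp)(1−π)); NPV = sp(1−π) / ((1−se)π + sp(1−π));
    LR+ = se/(1−sp) (infinite at sp = 1); LR− = (1−se)/sp.
    """
    se, sp, pi = sensitivity, specificity, prev.pi
    for name, v in (("sensitivity", se), ("specificity", sp)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    ppv = se * pi / ppv_den if ppv_den > 0 else math.nan
    npv_den = (1 - se) * pi + sp * (1 - pi)
    npv = sp * (1 - pi) / npv_den if npv_den > 0 else math.nan
    lr_pos = se / (1 - sp) if sp < 1 else math.inf
    lr_neg = (1 - se) / sp if sp > 0 else math.inf
    return ppv, npv, lr_pos, lr_neg


def ppv_from_lr(lr_pos: float, prev: PrevalenceSpec = PrevalenceSpec()) -> float:
    """PPV implied by a positive likelihood ratio: LR⁺π / (LR⁺π + 1 − π)."""
    pi = prev.pi
    return lr_pos * pi / (lr_pos * pi + 1 - pi)


def standardized_accuracy(
    sensitivity: float, specificity: float, prev: PrevalenceSpec = PrevalenceSpec()
) -> float:
    """Accuracy at the standardization prevalence: se·π + sp·(1−π)."""
    return sensitivity * prev.pi + specificity * (1 - prev.pi)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals`` places — the cross-tabulation display unit."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def horizon_decay(auc_by_horizon: Mapping[float, float]) -> tuple[float, float]:
    """Per-year AUC decline, in percent per year.

    Returns (endpoint decline, OLS slope): the endpoint estimate is
    (AUC at the shortest horizon − AUC at the longest) / span; the OLS
    slope is the least-squares fit over all horizons, sign-flipped so a
    falling curve reports a positive decay rate.
    """
    horizons = list(auc_by_horizon)
    if len(horizons) != len(set(horizons)):
        raise ValueError("duplicate horizons")
    if len(horizons) < 2:
        raise ValueError("need at least two horizons")
    h = np.array(sorted(horizons), dtype=float)
    a = np.array([auc_by_horizon[k] for k in sorted(horizons)], dtype=float)
    span = h[-1] - h[0]
    endpoint = (a[0] - a[-1]) / span * 100.0
    slope = -np.polyfit(h, a, 1)[0] * 100.0
    return float(endpoint), float(slope)


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    prev: PrevalenceSpec = PrevalenceSpec(),
    target_specificity: float = 0.95,
    threshold: Optional[float] = None,
    stratum: Optional[dict] = None,
) -> MetricReport:
    """Full screening report at a specificity-targeted (or given) threshold."""
    case_scores, control_scores = _split_scores(np.asarray(scores), np.asarray(labels))
    if len(case_scores) == 0 or len(control_scores) == 0:
        raise ValueError("evaluation requires both cases and controls")
    if threshold is None:
        threshold = threshold_at_specificity(control_scores, target_specificity)
    se = float(np.mean(case_scores > threshold))
    sp = float(np.mean(control_scores <= threshold))
    ppv, npv, lr_pos, lr_neg = standardized_predictive_values(se, sp, prev)
    return MetricReport(
        auc=roc_auc(scores, labels),
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        accuracy=standardized_accuracy(se, sp, prev),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        threshold=float(threshold),
        n_cases=len(case_scores),
        n_controls=len(control_scores),
        stratum=stratum,
    )


def subgroup_report(
    scores: Sequence[float],
    labels: Sequence[int],
    strata: Mapping[str, Sequence],
    prev: PrevalenceSpec = PrevalenceSpec(),
    target_specificity: float = 0.95,
    min_cases: int = 10,
    min_controls: int = 10,
) -> list[MetricReport]:
    """One MetricReport per observed stratum combination.

    Strata with fewer than ``min_cases`` cases or ``min_controls`` controls
    are returned suppressed, with the reason recorded instead of metrics.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fields = list(strata)
    columns = {f: np.asarray(strata[f]) for f in fields}
    for f in fields:
        if len(columns[f]) != len(scores):
            raise ValueError(f"stratum field {f!r} misaligned with scores")
    keys = sorted(
        {tuple(columns[f][i] for f in fields) for i in range(len(scores))}
    )
    reports = []
    for key in keys:
        mask = np.ones(len(scores), dtype=bool)
        for f, val in zip(fields, key):
            mask &= columns[f] == val
        label_info = dict(zip(fields, (str(v) for v in key)))
        nc = int(np.sum(labels[mask] == 1))
        nn = int(np.sum(labels[mask] == 0))
        if nc < min_cases or nn < min_controls:
            reports.append(
                MetricReport(
                    auc=math.nan, sensitivity=math.nan, specificity=math.nan,
                    ppv=math.nan, npv=math.nan, accuracy=math.nan,
                    lr_pos=math.nan, lr_neg=math.nan, threshold=math.nan,
                    n_cases=nc, n_controls=nn, stratum=label_info,
                    suppressed_reason=f"<{min_cases} cases or <{min_controls} controls",
                )
            )
            continue
        reports.append(
            evaluate_scores(
                scores[mask], labels[mask], prev=prev,
                target_specificity=target_specificity, stratum=label_info,
            )
        )
    return reports


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> Optional[float]:
    """Percentile-bootstrap half-width of a metric, resampling patients
    stratified by label.  ``n_boot = 0`` disables and returns None."""
    if n_boot == 0:
        return None
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates (or 0 to disable)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
            ]
        )
        stats[b] = metric_fn(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float((hi - lo) / 2)
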