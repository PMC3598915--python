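"""Predictive-performance measures for survival risk scores.

Single-group analysis: Somers' rank correlation ``D_xy`` between risk score
and survival time, the hazard ratio / Wald p / explained variation ``R^2``
from a univariate Cox fit of the scores, and the time-dependent ROC curve
``ROC(t)``. Two-group comparison: the test cohort is split at the *median of
the training scores* into high- and low-risk groups and compared by a Cox
model on the group indicator and by the log-rank test; degenerate splits
(one empty group, or one group with no events) yield an NA row rather than
an exception so that batch tables render with NA entries.

Sign convention: ``D_xy`` is the rank correlation between score and
survival *time*, so a well-performing model — high score, short survival —
has a *negative* D_xy. The companion signed c-index satisfies
``D_xy = sign(c) * (2|c| - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError, UndefinedStatisticError
from .survival import (
    SurvivalOutcome,
    cox_fit,
    log_rank_test,
    outcomes_to_arrays,
)

__all__ = [
    "RocCurve",
    "TwoGroupResult",
    "PredictabilityReport",
    "somers_dxy",
    "concordance_index",
    "dxy_from_cindex",
    "single_group_metrics",
    "roc_t",
    "two_group_comparison",
    "predictability_report",
    "EVALUATION_TIME_PRESETS",
]

# ROC evaluation-time presets (months after surgery): the lung analysis is
# read at month 36; the colon analysis at the 25th/50th/75th follow-up
# percentiles, months 23/42/68.
EVALUATION_TIME_PRESETS = {"lung": (36.0,), "colon": (23.0, 42.0, 68.0)}


def _pair_counts(scores: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Vectorised usable/concordant/tied pair counts over ordered pairs
    (i, j) with T_i < T_j and delta_i = 1 (plus the symmetric case)."""
    n = len(scores)
    ti = times[:, None]
    tj = times[None, :]
    usable = (ti < tj) & (events[:, None] == 1)
    si = scores[:, None]
    sj = scores[None, :]
    concordant = usable & (si < sj)  # shorter time has lower score
    tied = usable & (si == sj)
    return int(usable.sum()), int(concordant.sum()), int(tied.sum())


def somers_dxy(scores: Sequence[float], outcomes: Sequence[SurvivalOutcome]) -> float:
    """Somers' D_xy between risk scores and censored survival times.

    Usable pairs are those whose time ordering is determinable under right
    censoring: the patient with the shorter follow-up time experienced the
    event (tied times are not usable). A usable pair is concordant when the
    shorter-lived patient has the lower score; tied scores count 1/2.
    D_xy = 2c' - 1 where c' is the concordant fraction, so D_xy is in
    [-1, 1] and negative for a good risk model.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = outcomes_to_arrays(outcomes)
    if len(scores) != len(times):
        raise InputError("scores and outcomes length mismatch")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    usable, concordant, tied = _pair_counts(scores, times, events)
    if usable == 0:
        raise UndefinedStatisticError("no usable pairs (all censored or all ties)")
    c_prime = (concordant + 0.5 * tied) / usable
    return float(2.0 * c_prime - 1.0)


def concordance_index(scores: Sequence[float], outcomes: Sequence[SurvivalOutcome]) -> float:
    """Signed concordance index companion to :func:`somers_dxy`.

    The magnitude is ``max(c', 1 - c')`` — the concordance of the better-
    oriented reading of the scores — and the sign matches D_xy, so reported
    pairs look like (c = -0.6033, D_xy = -0.2066).
    """
    dxy = somers_dxy(scores, outcomes)
    c_prime = (dxy + 1.0) / 2.0
    magnitude = max(c_prime, 1.0 - c_prime)
    return float(np.sign(dxy) * magnitude) if dxy != 0 else 0.5


def dxy_from_cindex(c: float) -> float:
    """Map a (signed) concordance index to Somers' D_xy.

    ``D = 2|c| - 1`` applied to the magnitude with the sign of ``c``
    preserved; c = 0.5 (chance) maps to 0, c = 1 to 1, c = -0.6033 to
    -0.2066.
    """
    if abs(c) > 1:
        raise InputError(f"|c| must be <= 1, got {c}")
    return float(np.sign(c) * (2.0 * abs(c) - 1.0))


@dataclass
class RocCurve:
    """Time-dependent ROC at horizon ``t``.

    Cases are patients with an observed event by ``t``; controls are
    patients still under follow-up beyond ``t``; patients censored before
    ``t`` are unclassifiable and excluded (``n_excluded``). Points are
    (FPR, TPR) pairs over all distinct score cutoffs; being simple counting
    proportions they are monotone with no negative probability mass.
    """

    t: float
    cutoffs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    n_excluded: int

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def roc_t(
    scores: Sequence[float], outcomes: Sequence[SurvivalOutcome], t: float
) -> RocCurve:
    """Time-dependent ROC curve of risk scores at horizon ``t``.

    For each cutoff c: TP = cases with score > c, FP = controls with
    score > c; TPR = TP / (TP + FN), FPR = FP / (FP + TN). AUC by the
    trapezoid rule over the stepwise curve.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = outcomes_to_arrays(outcomes)
    if len(scores) != len(times):
        raise InputError("scores and outcomes length mismatch")
    if t <= 0:
        raise InputError("evaluation time must be positive")
    case = (times <= t) & (events == 1)
    control = times > t
    excluded = (times <= t) & (events == 0)
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0 or n_controls == 0:
        raise UndefinedStatisticError(
            f"ROC({t}) undefined: {n_cases} cases, {n_controls} controls"
        )
    # descending cutoffs sweep the curve from (0,0) to (1,1); the final
    # -inf cutoff classifies everyone positive, closing the curve at (1,1)
    cuts = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    above = scores[None, :] > cuts[:, None]
    tpr = (above & case).sum(axis=1) / n_cases
    fpr = (above & control).sum(axis=1) / n_controls
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        t=float(t),
        cutoffs=cuts,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_cases=n_cases,
        n_controls=n_controls,
        n_excluded=int(excluded.sum()),
    )


@dataclass
class TwoGroupResult:
    """High-/low-risk comparison at the training-score median threshold."""

    hr: float
    cox_p: float
    logrank_p: float
    n_high: int
    n_low: int


def two_group_comparison(
    train_scores: Sequence[float],
    test_scores: Sequence[float],
    test_outcomes: Sequence[SurvivalOutcome],
) -> TwoGroupResult | None:
    """Median-threshold two-group comparison.

    The threshold is the median of the *training* scores; test patients
    with score strictly above it form the high-risk group (ties at the
    median go low-risk). Returns None — the table-level NA — when one group
    is empty or one group contains no events; never raises for degeneracy.
    """
    test_scores = np.asarray(test_scores, dtype=float)
    times, events = outcomes_to_arrays(test_outcomes)
    if len(test_scores) != len(times):
        raise InputError("scores and outcomes length mismatch")
    threshold = float(np.median(np.asarray(train_scores, dtype=float)))
    high = test_scores > threshold
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        return None
    if events[high].sum() == 0 or events[~high].sum() == 0:
        return None
    fit = cox_fit(high.astype(float)[:, None], test_outcomes, names=["high_risk"])
    if not fit.converged:
        return None
    _, logrank_p = log_rank_test(test_outcomes, high.astype(int))
    return TwoGroupResult(
        hr=float(np.exp(fit.beta[0])),
        cox_p=float(fit.wald_p[0]),
        logrank_p=float(logrank_p),
        n_high=n_high,
        n_low=n_low,
    )


def single_group_metrics(
    scores: Sequence[float], outcomes: Sequence[SurvivalOutcome]
) -> tuple[float, float, float, float]:
    """Univariate Cox fit of outcomes on the risk scores.

    Returns ``(hr, hr_p, r2, dxy)`` where hr = exp(beta), hr_p is the Wald
    p-value, and R^2 = 1 - exp(-LR/n) is the likelihood-ratio explained-
    variation measure standard Cox software prints.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.max() == scores.min():
        raise UndefinedStatisticError("constant risk scores")
    fit = cox_fit(scores[:, None], outcomes, names=["risk_score"])
    hr = float(np.exp(fit.beta[0]))
    hr_p = float(fit.wald_p[0])
    r2 = float(1.0 - np.exp(-fit.lr_statistic / fit.n))
    dxy = somers_dxy(scores, outcomes)
    return hr, hr_p, r2, dxy


@dataclass
class PredictabilityReport:
    """All performance measures of one model on one test cohort."""

    model_kind: str
    dxy: float
    hr: float
    hr_p: float
    r2: float
    twogroup: TwoGroupResult | None
    roc: list[RocCurve]

    def to_row(self) -> dict:
        row = {
            "model": self.model_kind,
            "dxy": self.dxy,
            "hr": self.hr,
            "hr_p": self.hr_p,
            "r2": self.r2,
        }
        if self.twogroup is None:
            row.update(
                twogroup_hr=np.nan, twogroup_cox_p=np.nan,
                twogroup_logrank_p=np.nan, n_high=np.nan, n_low=np.nan,
            )
        else:
            tg = self.twogroup
            row.update(
                twogroup_hr=tg.hr, twogroup_cox_p=tg.cox_p,
                twogroup_logrank_p=tg.logrank_p, n_high=tg.n_high, n_low=tg.n_low,
            )
        for rc in self.roc:
            row[f"auc_t{rc.t:g}"] = rc.auc
        return row


def predictability_report(
    model_kind: str,
    train_scores: Sequence[float],
    test_scores: Sequence[float],
    test_outcomes: Sequence[SurvivalOutcome],
    evaluation_times: Sequence[float] = (),
) -> PredictabilityReport:
    """Full single-group + two-group + ROC(t) evaluation of one score
    vector against one test cohort."""
    hr, hr_p, r2, dxy = single_group_metrics(test_scores, test_outcomes)
    twogroup = two_group_comparison(train_scores, test_scores, test_outcomes)
    roc = []
    for t in evaluation_times:
        try:
            roc.append(roc_t(test_scores, test_outcomes, t))
        except UndefinedStatisticError:
            continue
    return PredictabilityReport(
        model_kind=model_kind, dxy=dxy, hr=hr, hr_p=hr_p, r2=r2,
        twogroup=twogroup, roc=roc,
    )
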