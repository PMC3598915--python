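"""Cross-center reproducibility of survival risk predictions.

Two Pearson-correlation statistics on predicted risk scores quantify how
well models travel between centers:

* transferability ``Tran_ij = rho(beta_i^T X_j, beta_j^T X_j)`` — agreement
  between center i's model and center j's own model on center j's patients;
* consistency ``Cons_ij|k = rho(beta_i^T X_k, beta_j^T X_k)`` — agreement
  between centers i and j when both predict a target center k. When k = j
  (or i) consistency reduces exactly to transferability.

Two evaluation pathways are exposed, matching how multi-center studies use
them: :func:`crosscenter_table` fits each center's model on its *entire*
data and evaluates every transfer/consistency pair once (the four-center
lung layout: 3 transferability + 3 consistency rows per target center);
:func:`resample_signature_transfer` repeatedly splits one center into
train/test halves and compares a foreign model (*vmc*), a locally trained
model (*mcc1*) and a locally refit model borrowing the foreign gene
signature (*mcc2*) on the held-out patients, yielding the rho1/rho2/rho3
draws whose distributions summarise model and signature transferability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SurvTransferError, UndefinedStatisticError
from .metrics import PredictabilityReport, predictability_report
from .models import ModelConfig, RiskModel, apply_signature, fit_risk_model, predict_risk
from .simulate import CenterDataset

__all__ = [
    "TransferReport",
    "ResampleReport",
    "transferability",
    "consistency",
    "crosscenter_table",
    "pairwise_prediction_eval",
    "resample_signature_transfer",
]

log = logging.getLogger(__name__)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("correlation undefined for constant score vector")
    return float(np.corrcoef(a, b)[0, 1])


def transferability(model_i: RiskModel, model_j: RiskModel, data_j: CenterDataset) -> float:
    """Tran_ij: Pearson correlation on center j's patients between the
    scores predicted by center i's model and by center j's own model."""
    if model_i.kind != model_j.kind:
        raise SurvTransferError(
            f"models must share a kind (got {model_i.kind} vs {model_j.kind})"
        )
    return _pearson(predict_risk(model_i, data_j), predict_risk(model_j, data_j))


def consistency(model_i: RiskModel, model_j: RiskModel, data_k: CenterDataset) -> float:
    """Cons_ij|k: Pearson correlation between the scores centers i and j
    predict for target center k's patients; symmetric in (i, j), and equal
    to Tran_ij when k = j."""
    return transferability(model_i, model_j, data_k)


@dataclass
class TransferReport:
    """Table-6-style cross-center correlation table for one model kind.

    One row per (target center, training source): for each target, one
    transferability row per other center and one consistency row per pair
    of other centers. Failed fits leave rows with rho = NaN and a note.
    """

    model_kind: str
    rows: pd.DataFrame  # columns: target_center, training_source, row_type, rho, note

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(2, "model_kind", self.model_kind)
        return out


def crosscenter_table(
    centers: Sequence[CenterDataset],
    kind: str,
    config: ModelConfig = ModelConfig(),
) -> TransferReport:
    """Fit one model per center on its entire data, then tabulate all
    transferability and consistency correlations for every target center.
    """
    models: dict[str, RiskModel | None] = {}
    for ds in centers:
        try:
            models[ds.center_id] = fit_risk_model(kind, ds, config)
        except SurvTransferError as err:
            log.warning("fit failed for %s on %s: %s", kind, ds.center_id, err)
            models[ds.center_id] = None

    records = []
    for target in centers:
        others = [c for c in centers if c.center_id != target.center_id]
        for src in others:
            records.append(
                _corr_record(
                    target, src.center_id, "transferability",
                    models[src.center_id], models[target.center_id],
                )
            )
        for a, b in combinations(others, 2):
            records.append(
                _corr_record(
                    target, f"{a.center_id} and {b.center_id}", "consistency",
                    models[a.center_id], models[b.center_id],
                )
            )
    rows = pd.DataFrame.from_records(
        records, columns=["target_center", "training_source", "row_type", "rho", "note"]
    )
    return TransferReport(model_kind=kind, rows=rows)


def _corr_record(target, source_label, row_type, m1, m2):
    base = dict(
        target_center=target.center_id,
        training_source=source_label,
        row_type=row_type,
    )
    if m1 is None or m2 is None:
        return {**base, "rho": np.nan, "note": "fit failed"}
    try:
        rho = transferability(m1, m2, target)
    except SurvTransferError as err:
        return {**base, "rho": np.nan, "note": str(err)}
    return {**base, "rho": rho, "note": ""}


def pairwise_prediction_eval(
    centers: Sequence[CenterDataset],
    kind: str,
    config: ModelConfig = ModelConfig(),
    evaluation_times: Sequence[float] = (),
) -> pd.DataFrame:
    """Every ordered (train, test) center pair: fit on the training center,
    predict the test center, and compute the full predictability report
    (two-group split at the training-score median). Per-pair failures are
    recorded and the run continues."""
    models: dict[str, RiskModel | None] = {}
    train_scores: dict[str, np.ndarray] = {}
    for ds in centers:
        try:
            m = fit_risk_model(kind, ds, config)
            models[ds.center_id] = m
            train_scores[ds.center_id] = predict_risk(m, ds)
        except SurvTransferError as err:
            log.warning("fit failed for %s on %s: %s", kind, ds.center_id, err)
            models[ds.center_id] = None

    rows = []
    by_id = {c.center_id: c for c in centers}
    for train_id, test_id in permutations(by_id, 2):
        base = {"train_center": train_id, "test_center": test_id, "model": kind}
        model = models[train_id]
        if model is None:
            rows.append({**base, "note": "fit failed"})
            continue
        test_ds = by_id[test_id]
        try:
            scores = predict_risk(model, test_ds)
            report = predictability_report(
                kind, train_scores[train_id], scores, test_ds.outcomes, evaluation_times
            )
        except SurvTransferError as err:
            rows.append({**base, "note": str(err)})
            continue
        row = report.to_row()
        row.pop("model")
        rows.append({**base, **row, "note": ""})
    return pd.DataFrame(rows)


@dataclass
class ResampleReport:
    """rho1/rho2/rho3 draws from the resampling signature-transferability
    procedure; NaN entries mark failed repetitions (reason recorded)."""

    model_kind: str
    rho1: np.ndarray
    rho2: np.ndarray
    rho3: np.ndarray
    n_train: int
    n_test: int
    n_reps: int
    seed: int
    failures: dict[int, str] = field(default_factory=dict)

    def summary(self) -> dict:
        def stats(x: np.ndarray) -> dict:
            ok = x[np.isfinite(x)]
            return {
                "median": float(np.median(ok)),
                "q1": float(np.quantile(ok, 0.25)),
                "q3": float(np.quantile(ok, 0.75)),
                "n": int(ok.size),
            }

        return {
            "model_kind": self.model_kind,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "n_failed": len(self.failures),
            "rho1": stats(self.rho1),
            "rho2": stats(self.rho2),
            "rho3": stats(self.rho3),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": np.arange(self.n_reps),
                "rho1": self.rho1,
                "rho2": self.rho2,
                "rho3": self.rho3,
            }
        )


def resample_signature_transfer(
    center_a: CenterDataset,
    center_b: CenterDataset,
    kind: str,
    *,
    n_train: int = 55,
    n_reps: int = 1000,
    seed: int = 0,
    config: ModelConfig = ModelConfig(),
    min_success: float = 0.9,
) -> ResampleReport:
    """Signature-transferability by repeated random splitting.

    Per repetition, center_b is split without replacement into ``n_train``
    training patients and the rest as test patients; three models predict
    the test patients:

    * *vmc*  — ``kind`` fitted once on all of center_a,
    * *mcc1* — ``kind`` fitted on center_b's training split (own selection),
    * *mcc2* — center_b's training split refit with vmc's gene signature.

    rho1 = rho(vmc, mcc1) (model transferability), rho2 = rho(vmc, mcc2)
    and rho3 = rho(mcc1, mcc2) (signature transferability). For the
    clinical-only kinds A and B, mcc2 coincides with mcc1 so rho3 = 1 and
    rho1 = rho2 identically.

    Each repetition ``r`` draws its split from a generator seeded with
    ``seed + r``, so runs are reproducible and parallelisable. Failed
    repetitions (e.g. non-convergence on a small split) are recorded as NaN;
    fewer than ``min_success`` successful repetitions aborts the run.
    """
    if center_b.n <= n_train:
        raise SurvTransferError(
            f"center_b has {center_b.n} patients; need more than n_train={n_train}"
        )
    vmc = fit_risk_model(kind, center_a, config)

    rho1 = np.full(n_reps, np.nan)
    rho2 = np.full(n_reps, np.nan)
    rho3 = np.full(n_reps, np.nan)
    failures: dict[int, str] = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        perm = rng.permutation(center_b.n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        train_ds = center_b.subset(train_idx)
        test_ds = center_b.subset(test_idx)
        try:
            mcc1 = fit_risk_model(kind, train_ds, config)
            mcc2 = apply_signature(vmc, train_ds, config)
            s_vmc = predict_risk(vmc, test_ds)
            s_mcc1 = predict_risk(mcc1, test_ds)
            s_mcc2 = predict_risk(mcc2, test_ds)
            rho1[rep] = _pearson(s_vmc, s_mcc1)
            rho2[rep] = _pearson(s_vmc, s_mcc2)
            rho3[rep] = _pearson(s_mcc1, s_mcc2)
        except SurvTransferError as err:
            failures[rep] = str(err)
    n_ok = n_reps - len(failures)
    if n_ok < min_success * n_reps:
        raise SurvTransferError(
            f"only {n_ok}/{n_reps} repetitions succeeded "
            f"(minimum {min_success:.0%}); first failure: "
            f"{next(iter(failures.values()), '')}"
        )
    return ResampleReport(
        model_kind=kind,
        rho1=rho1,
        rho2=rho2,
        rho3=rho3,
        n_train=n_train,
        n_test=center_b.n - n_train,
        n_reps=n_reps,
        seed=seed,
        failures=failures,
    )
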