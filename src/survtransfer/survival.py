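"""From-scratch survival estimators.

This module implements the estimators every risk model and performance
metric in the package is built on:

* Kaplan–Meier product-limit estimator (:func:`km_estimate`),
* the k-sample log-rank test (:func:`log_rank_test`),
* Cox proportional-hazards partial-likelihood fitting with the Efron tie
  correction via Newton–Raphson (:func:`cox_fit`),
* a log-rank-split survival tree whose leaves carry incidence rates
  (events per unit person-time; :func:`survival_tree_fit`,
  :func:`tree_incidence_rate`).

Outcomes are right-censored pairs ``(T_j, delta_j)`` with ``delta_j = 1``
for an observed event and ``0`` for censoring. Risk scores throughout the
package are linear predictors ``H_j = beta^T x_j``; a larger score means a
higher predicted hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateGroupingError, DesignError, InputError, RoutingError

__all__ = [
    "SurvivalOutcome",
    "CovariateMatrix",
    "CoxFit",
    "KaplanMeier",
    "SurvivalTree",
    "TreeNode",
    "km_estimate",
    "log_rank_test",
    "cox_fit",
    "cox_linear_predictor",
    "survival_tree_fit",
    "tree_incidence_rate",
    "outcomes_to_arrays",
    "arrays_to_outcomes",
]


class SurvivalOutcome(NamedTuple):
    """Right-censored follow-up for one patient: time ``T_j > 0`` and event
    indicator ``delta_j`` (1 = event observed, 0 = censored)."""

    time: float
    event: int


def outcomes_to_arrays(outcomes: Sequence[SurvivalOutcome]) -> tuple[np.ndarray, np.ndarray]:
    """Convert a sequence of outcomes to ``(times, events)`` float/int arrays,
    validating positivity of times and the 0/1 event coding."""
    if len(outcomes) == 0:
        raise InputError("empty outcome list")
    arr = np.asarray(outcomes, dtype=float)
    times, events = arr[:, 0], arr[:, 1]
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise InputError("survival times must be positive and finite")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise InputError("event indicators must be coded 1=event, 0=censored")
    return times, events.astype(int)


def arrays_to_outcomes(times: Iterable[float], events: Iterable[int]) -> list[SurvivalOutcome]:
    return [SurvivalOutcome(float(t), int(e)) for t, e in zip(times, events)]


# ---------------------------------------------------------------------------
# Covariate matrix


@dataclass
class CovariateMatrix:
    """A patients x covariates table with encoding metadata.

    ``frame`` holds raw columns (numeric, or string labels for categorical
    covariates). ``categorical`` maps a column name to its reference level;
    :meth:`design` expands those columns to treatment-coded 0/1 indicators
    against that reference (by convention the most frequent training level).
    Ordinal covariates such as tumour stage stay numeric unless listed.
    """

    frame: pd.DataFrame
    categorical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise DesignError("covariate matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    def subset(self, columns: Sequence[str]) -> "CovariateMatrix":
        cat = {c: r for c, r in self.categorical.items() if c in columns}
        return CovariateMatrix(self.frame[list(columns)].copy(), cat)

    def design(self) -> tuple[np.ndarray, list[str]]:
        """Expand to a numeric design matrix (no intercept; the Cox partial
        likelihood is invariant to one). Returns ``(values, names)``."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        for name in self.frame.columns:
            col = self.frame[name]
            if name in self.categorical:
                ref = self.categorical[name]
                levels = sorted(set(col.astype(str)) | {ref})
                for lev in levels:
                    if lev == ref:
                        continue
                    cols.append((col.astype(str) == lev).to_numpy(float))
                    names.append(f"{name}[{lev}]")
            else:
                cols.append(col.to_numpy(float))
                names.append(name)
        if not cols:
            raise DesignError("no covariates to expand")
        return np.column_stack(cols), names


def infer_reference_levels(frame: pd.DataFrame, categorical: Sequence[str]) -> dict[str, str]:
    """Reference level per categorical column = the most frequent level
    (ties broken lexicographically for determinism)."""
    refs = {}
    for name in categorical:
        counts = frame[name].astype(str).value_counts()
        top = counts.max()
        refs[name] = sorted(counts.index[counts == top])[0]
    return refs


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KaplanMeier:
    """Product-limit estimate as a right-continuous step function; callable
    at arbitrary times, with S(0) = 1."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray     # S(t) just after each event time

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate(([1.0], self.survival))[idx]
        return s if s.ndim else float(s)


def km_estimate(outcomes: Sequence[SurvivalOutcome]) -> KaplanMeier:
    """Kaplan–Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with d_i events and n_i patients at risk (T_j >= t_i).
    """
    times, events = outcomes_to_arrays(outcomes)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n_at_risk = len(times) - np.searchsorted(times, uniq, side="left")
    d = np.array([np.sum((times == t) & (events == 1)) for t in uniq])
    surv = np.cumprod(1.0 - d / n_at_risk)
    return KaplanMeier(uniq, surv)


# ---------------------------------------------------------------------------
# Log-rank test


def log_rank_test(
    outcomes: Sequence[SurvivalOutcome], groups: Sequence[int]
) -> tuple[float, float]:
    """k-sample log-rank test (two groups in routine use).

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk-set composition;
    the statistic is (O-E)' V^{-1} (O-E) on the first k-1 groups, referred
    to a chi-square with k-1 degrees of freedom.

    Returns ``(chi_square, p_value)``. Raises
    :class:`DegenerateGroupingError` if any labelled group is empty.
    """
    times, events = outcomes_to_arrays(outcomes)
    g = np.asarray(groups)
    if len(g) != len(times):
        raise InputError("groups and outcomes length mismatch")
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise DegenerateGroupingError("log-rank test needs at least two non-empty groups")
    gi = np.searchsorted(labels, g)

    order = np.argsort(times, kind="stable")
    times, events, gi = times[order], events[order], gi[order]
    uniq = np.unique(times[events == 1])

    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for t in uniq:
        at_risk = times >= t
        n_t = at_risk.sum()
        if n_t < 2:
            continue
        n_jt = np.bincount(gi[at_risk], minlength=k).astype(float)
        ev = (times == t) & (events == 1)
        d_t = ev.sum()
        d_jt = np.bincount(gi[ev], minlength=k).astype(float)
        p = n_jt / n_t
        o_minus_e += d_jt - d_t * p
        scale = d_t * (n_t - d_t) / max(n_t - 1, 1)
        V += scale * (np.diag(p) - np.outer(p, p))
    # drop last group: the O-E vector sums to zero
    u = o_minus_e[:-1]
    Vk = V[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(Vk, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vk) @ u)
    chi2 = max(chi2, 0.0)
    p_value = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p_value


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    names: list[str] = field(default_factory=list)

    @property
    def zscores(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zscores))

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)


def _cox_prepare(X: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Sort ascending by time; censored sort after events at tied times so
    that the risk set at an event time includes same-time censored patients
    (both have T >= t; ordering only matters for bookkeeping)."""
    order = np.lexsort((1 - events, times))
    return X[order], times[order], events[order]


def _cox_loglik_terms(X, times, events, beta, ties="efron"):
    """Partial log-likelihood, score vector and observed information.

    Data must be pre-sorted by :func:`_cox_prepare`. Uses a vectorised path
    when no two events share a time (Efron == Breslow there); otherwise the
    generic Efron/Breslow accumulation over tied event groups.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guards exp overflow; PL is invariant to shifts
    w = np.exp(eta)
    wx = w[:, None] * X
    # reverse cumulative sums over the risk set {j : T_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    wxx = wx[:, :, None] * X[:, None, :]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(events == 1)
    ev_times = times[ev_idx]
    tied = len(np.unique(ev_times)) < len(ev_times)

    if not tied:
        start = np.searchsorted(times, ev_times, side="left")
        denom = S0[start]
        m = S1[start] / denom[:, None]
        loglik = float(np.sum(eta[ev_idx] - np.log(denom)))
        grad = X[ev_idx].sum(axis=0) - m.sum(axis=0)
        info = (S2[start] / denom[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", m, m
        )
        return loglik, grad, info

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(ev_times):
        D = np.flatnonzero((times == t) & (events == 1))
        d = len(D)
        s = np.searchsorted(times, t, side="left")
        wD = w[D].sum()
        wxD = wx[D].sum(axis=0)
        wxxD = wxx[D].sum(axis=0)
        loglik += float(eta[D].sum())
        grad += X[D].sum(axis=0)
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            denom = S0[s] - frac * wD
            num1 = S1[s] - frac * wxD
            num2 = S2[s] - frac * wxxD
            m = num1 / denom
            loglik -= float(np.log(denom))
            grad -= m
            info += num2 / denom - np.outer(m, m)
    return loglik, grad, info


def cox_fit(
    X: CovariateMatrix | np.ndarray,
    outcomes: Sequence[SurvivalOutcome],
    *,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    names: Sequence[str] | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by maximising the partial
    likelihood with Newton–Raphson.

    Ties among event times are handled by the Efron approximation by default
    (``ties="breslow"`` selects Breslow). Iteration starts at beta = 0 with
    step-halving whenever a full Newton step would decrease the likelihood;
    convergence is declared when the score norm drops below ``tol``.

    Raises :class:`DesignError` for a constant column or n <= p. A fit that
    exhausts ``max_iter`` or drifts toward infinite coefficients (separation)
    is returned with ``converged=False``.
    """
    if isinstance(X, CovariateMatrix):
        values, nm = X.design()
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        nm = list(names) if names is not None else [f"x{i}" for i in range(values.shape[1])]
    times, events = outcomes_to_arrays(outcomes)
    n, p = values.shape
    if len(times) != n:
        raise DesignError(f"design has {n} rows but {len(times)} outcomes")
    if n <= p:
        raise DesignError(f"need n > p (n={n}, p={p})")
    ptp = values.max(axis=0) - values.min(axis=0)
    if np.any(ptp == 0):
        bad = nm[int(np.argmax(ptp == 0))]
        raise DesignError(f"constant covariate column: {bad!r}")
    if events.sum() == 0:
        raise InputError("no events observed; partial likelihood undefined")

    # standardise columns internally: centering leaves beta unchanged,
    # scaling makes conditioning and the separation guard scale-free;
    # beta and se are transformed back to the raw scale afterwards
    center = values.mean(axis=0)
    scale = values.std(axis=0)
    Xc, t_s, e_s = _cox_prepare((values - center) / scale, times, events)

    beta = np.zeros(p)
    loglik_null, _, _ = _cox_loglik_terms(Xc, t_s, e_s, beta, ties)
    loglik = loglik_null
    converged = False
    info = np.eye(p)
    for _ in range(max_iter):
        loglik, grad, info = _cox_loglik_terms(Xc, t_s, e_s, beta, ties)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _half in range(30):
            cand = beta + step * delta
            ll_new, _, _ = _cox_loglik_terms(Xc, t_s, e_s, cand, ties)
            if ll_new >= loglik - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        if np.linalg.norm(beta) > 50:
            break  # monotone likelihood / separation
    if converged:
        loglik, _, info = _cox_loglik_terms(Xc, t_s, e_s, beta, ties)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    # a vanishing score with no curvature left is separation, not a maximum:
    # on the standardised scale a per-sd se above ~100 carries no information
    if converged and (not np.all(np.isfinite(se)) or np.any(se > 100.0)):
        converged = False
    return CoxFit(
        beta=beta / scale,
        se=se / scale,
        loglik=float(loglik),
        loglik_null=float(loglik_null),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        names=nm,
    )


def cox_linear_predictor(beta: np.ndarray, X: CovariateMatrix | np.ndarray) -> np.ndarray:
    """Risk scores ``H_j = beta^T x_j``; larger = higher predicted hazard."""
    values = X.design()[0] if isinstance(X, CovariateMatrix) else np.asarray(X, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    beta = np.asarray(beta, dtype=float)
    if values.shape[1] != beta.shape[0]:
        raise DesignError(
            f"beta has {beta.shape[0]} coefficients but design has {values.shape[1]} columns"
        )
    return values @ beta


# ---------------------------------------------------------------------------
# Survival tree


@dataclass
class TreeNode:
    """Internal node (split on a covariate) or leaf (incidence rate)."""

    # split fields (internal nodes)
    feature: str | None = None
    threshold: float | None = None          # numeric: x <= threshold goes left
    left_levels: frozenset | None = None    # categorical: level in set goes left
    right_levels: frozenset | None = None   # levels observed on the right at training
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaf fields
    incidence_rate: float = 0.0
    n: int = 0
    n_events: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class SurvivalTree:
    """Greedy binary survival tree split by the two-sample log-rank statistic.

    Leaves carry the training incidence rate: events per unit person-time
    (n_events / total follow-up time among training patients in the leaf).
    """

    root: TreeNode
    feature_names: list[str]
    categorical: dict[str, str]
    min_leaf: int
    max_depth: int

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def _leaf_from(times: np.ndarray, events: np.ndarray) -> TreeNode:
    total_time = float(times.sum())
    n_events = int(events.sum())
    rate = n_events / total_time if total_time > 0 else 0.0
    return TreeNode(incidence_rate=rate, n=len(times), n_events=n_events)


def _numeric_candidates(col: np.ndarray, max_candidates: int = 50) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) < 2:
        return np.empty(0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if len(mids) > max_candidates:
        qs = np.linspace(0, 1, max_candidates + 2)[1:-1]
        mids = np.unique(np.quantile(col, qs))
    return mids


def _categorical_candidates(col: pd.Series, times: np.ndarray, events: np.ndarray):
    """Binary partitions of the levels present: exhaustive for <= 8 levels,
    otherwise prefix splits of the levels ordered by incidence rate."""
    levels = sorted(set(col.astype(str)))
    if len(levels) < 2:
        return
    if len(levels) <= 8:
        from itertools import combinations

        for r in range(1, len(levels) // 2 + 1):
            for subset in combinations(levels, r):
                # avoid testing a partition and its complement twice
                if r == len(levels) - r and levels[0] not in subset:
                    continue
                yield frozenset(subset)
    else:
        rates = {}
        for lev in levels:
            mask = (col.astype(str) == lev).to_numpy()
            tt = times[mask].sum()
            rates[lev] = events[mask].sum() / tt if tt > 0 else 0.0
        ordered = sorted(levels, key=lambda s: (rates[s], s))
        for i in range(1, len(ordered)):
            yield frozenset(ordered[:i])


def survival_tree_fit(
    X: CovariateMatrix,
    outcomes: Sequence[SurvivalOutcome],
    *,
    min_leaf: int = 20,
    max_depth: int = 3,
    p_enter: float = 0.05,
) -> SurvivalTree:
    """Fit a survival tree by recursive binary partitioning.

    At each node the split (covariate, cutpoint or level set) maximising the
    two-sample log-rank statistic is chosen among splits that leave at least
    ``min_leaf`` patients on each side and whose log-rank p-value is below
    ``p_enter`` (a significance gate that keeps noise covariates from
    growing the tree). With fewer than ``2 * min_leaf`` patients the result
    is a single leaf.
    """
    times, events = outcomes_to_arrays(outcomes)
    frame = X.frame.reset_index(drop=True)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        t, e = times[idx], events[idx]
        if depth >= max_depth or len(idx) < 2 * min_leaf or e.sum() == 0:
            return _leaf_from(t, e)
        best = None  # (chi2, feature, threshold, left_levels, left_mask)
        sub = frame.iloc[idx]
        for name in frame.columns:
            col = sub[name]
            if name in X.categorical:
                for left_set in _categorical_candidates(col, t, e) or []:
                    mask = col.astype(str).isin(left_set).to_numpy()
                    cand = _evaluate_split(t, e, mask, min_leaf, p_enter)
                    if cand is not None and (best is None or cand > best[0]):
                        best = (cand, name, None, left_set, mask)
            else:
                vals = col.to_numpy(float)
                for thr in _numeric_candidates(vals):
                    mask = vals <= thr
                    cand = _evaluate_split(t, e, mask, min_leaf, p_enter)
                    if cand is not None and (best is None or cand > best[0]):
                        best = (cand, name, float(thr), None, mask)
        if best is None:
            return _leaf_from(t, e)
        _, name, thr, left_set, mask = best
        right_set = None
        if left_set is not None:
            observed = frozenset(sub[name].astype(str))
            right_set = observed - left_set
        node = TreeNode(feature=name, threshold=thr, left_levels=left_set, right_levels=right_set)
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        # keep node-level summaries for inspection
        node.n = len(idx)
        node.n_events = int(e.sum())
        return node

    root = build(np.arange(len(times)), 0)
    return SurvivalTree(
        root=root,
        feature_names=list(frame.columns),
        categorical=dict(X.categorical),
        min_leaf=min_leaf,
        max_depth=max_depth,
    )


def _evaluate_split(times, events, left_mask, min_leaf, p_enter) -> float | None:
    n_left = int(left_mask.sum())
    if n_left < min_leaf or len(times) - n_left < min_leaf:
        return None
    outcomes = arrays_to_outcomes(times, events)
    try:
        chi2, p = log_rank_test(outcomes, left_mask.astype(int))
    except DegenerateGroupingError:
        return None
    if chi2 <= 0 or p >= p_enter:
        return None
    return chi2


def tree_incidence_rate(tree: SurvivalTree, X: CovariateMatrix) -> np.ndarray:
    """Route each patient down the tree and return the training incidence
    rate of the leaf it lands in.

    Raises :class:`RoutingError` (naming the sample row) when a categorical
    value was never seen on either side of a split during training.
    """
    frame = X.frame.reset_index(drop=True)
    missing = [f for f in tree.feature_names if f not in frame.columns]
    if missing:
        raise DesignError(f"covariates absent from data: {missing}")
    rates = np.empty(len(frame))
    for i in range(len(frame)):
        node = tree.root
        while not node.is_leaf:
            val = frame.iloc[i][node.feature]
            if node.left_levels is not None:
                sval = str(val)
                if sval in node.left_levels:
                    node = node.left
                elif sval in node.right_levels:
                    node = node.right
                else:
                    raise RoutingError(
                        f"sample row {i}: unseen level {sval!r} for {node.feature!r}"
                    )
            else:
                node = node.left if float(val) <= node.threshold else node.right
        rates[i] = node.incidence_rate
    return rates
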