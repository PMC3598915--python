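"""The eight survival risk prediction models A-H.

Two clinical models, two gene-expression models, and their four additive
combinations:

=====  ==========================================================
kind   design entering a multivariate Cox fit
=====  ==========================================================
A      clinical covariates (age, gender, stage, histology)
B      leaf incidence rate of a clinical survival tree (univariate)
C      first k=5 principal-component scores of the selected genes
D      the k=10 smallest-p genes from univariate Cox screening
E      A + C   (joint refit on the union of the parents' columns)
F      A + D
G      B + C
H      B + D
=====  ==========================================================

Gene selection fits a univariate Cox model per gene and keeps genes with
Wald p below a threshold, ordered by ascending p. "Additively combined"
means one joint Cox refit over the union of the parents' design columns,
producing a single linear predictor ``beta^T x`` (each combined model
reports one score vector and one hazard ratio).

A fitted :class:`RiskModel` freezes everything prediction needs — the
coefficient vector, the clinical encoding, the gene signature, the PC
means/loadings, the survival tree — so it can be shipped to another center
and applied to that center's patients (``predict_risk``), or its signature
alone can be transplanted and the coefficients re-estimated locally
(``apply_signature``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConvergenceError,
    DesignError,
    EmptySignatureError,
    InputError,
    SignatureCoverageError,
)
from .simulate import CenterDataset
from .survival import (
    CovariateMatrix,
    CoxFit,
    SurvivalTree,
    cox_fit,
    cox_linear_predictor,
    infer_reference_levels,
    outcomes_to_arrays,
    survival_tree_fit,
    tree_incidence_rate,
)

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "GeneSignature",
    "PCLoadings",
    "RiskModel",
    "select_genes",
    "fit_risk_model",
    "predict_risk",
    "apply_signature",
]

MODEL_KINDS = ("A", "B", "C", "D", "E", "F", "G", "H")
_CLINICAL_KINDS = frozenset("AB")
_GENE_PARENT = {"C": "C", "D": "D", "E": "C", "F": "D", "G": "C", "H": "D"}
_CLIN_PARENT = {"E": "A", "F": "A", "G": "B", "H": "B"}


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters shared by all model constructors.

    ``selection_threshold`` is the univariate-Cox Wald p cutoff for gene
    screening; ``k_pc`` the number of principal-component meta-genes
    (Model C); ``k_top`` the number of top-ranked genes (Model D); the
    ``tree_*`` parameters control the clinical survival tree (Model B).
    """

    selection_threshold: float = 0.001
    k_pc: int = 5
    k_top: int = 10
    tree_min_leaf: int = 20
    tree_max_depth: int = 3
    tree_p_enter: float = 0.05
    clinical_columns: tuple[str, ...] | None = None  # None = all columns
    ties: str = "efron"


@dataclass
class GeneSignature:
    """Genes selected by univariate Cox screening, ordered by ascending
    Wald p (exact ties broken by gene id for determinism)."""

    gene_ids: list[str]
    p_values: np.ndarray
    selection_threshold: float

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]


@dataclass
class PCLoadings:
    """Training-frozen PCA transform for the signature genes: per-gene
    training means and an orthonormal |signature| x k loading matrix."""

    gene_ids: list[str]
    gene_means: np.ndarray
    loading_matrix: np.ndarray
    k: int

    def project(self, expression: pd.DataFrame) -> np.ndarray:
        """PC scores (patients x k) of new expression data under the
        training centering and loadings."""
        missing = [g for g in self.gene_ids if g not in expression.index]
        if missing:
            raise SignatureCoverageError(f"genes absent from data: {missing}")
        sub = expression.loc[self.gene_ids].to_numpy(float)
        centered = sub - self.gene_means[:, None]
        return centered.T @ self.loading_matrix


@dataclass
class RiskModel:
    """A fitted risk prediction model of kind A-H."""

    kind: str
    beta: np.ndarray
    design_names: list[str]
    training_center: str
    training_median: float
    cox: CoxFit | None = None
    clinical_columns: list[str] = field(default_factory=list)
    clinical_references: dict[str, str] = field(default_factory=dict)
    clinical_levels: dict[str, list[str]] = field(default_factory=dict)
    signature: GeneSignature | None = None
    pc: PCLoadings | None = None
    top_genes: list[str] = field(default_factory=list)
    tree: SurvivalTree | None = None

    @property
    def uses_genes(self) -> bool:
        return self.kind not in _CLINICAL_KINDS


def select_genes(
    expression: pd.DataFrame,
    outcomes,
    threshold: float,
    *,
    ties: str = "efron",
) -> GeneSignature:
    """Univariate Cox screening of every gene.

    Fits outcome ~ expression(g) for each gene g and keeps genes whose Wald
    p-value is at or below ``threshold``, ordered by ascending p (ties by
    gene id). Raises :class:`EmptySignatureError` when nothing passes.
    """
    if not (0 < threshold <= 1):
        raise InputError("threshold must be in (0, 1]")
    times, events = outcomes_to_arrays(outcomes)
    if events.sum() < 2:
        raise InputError("gene selection requires at least 2 events")
    pvals = np.ones(expression.shape[0])
    mat = expression.to_numpy(float)
    for g in range(mat.shape[0]):
        x = mat[g]
        if x.max() == x.min():
            continue
        try:
            fit = cox_fit(x[:, None], outcomes, ties=ties)
        except (DesignError, np.linalg.LinAlgError):
            continue
        if fit.converged and np.isfinite(fit.se[0]) and fit.se[0] > 0:
            pvals[g] = fit.wald_p[0]
    keep = np.flatnonzero(pvals <= threshold)
    if keep.size == 0:
        raise EmptySignatureError(
            f"no gene passed p <= {threshold}; relax the selection threshold"
        )
    ids = np.asarray(expression.index)[keep]
    order = np.lexsort((ids, pvals[keep]))
    return GeneSignature(
        gene_ids=[str(i) for i in ids[order]],
        p_values=pvals[keep][order],
        selection_threshold=threshold,
    )


def _clinical_matrix(data: CenterDataset, config: ModelConfig) -> CovariateMatrix:
    cols = list(config.clinical_columns) if config.clinical_columns else data.clinical.column_names
    return data.clinical.subset(cols)


def _expand_clinical(
    frame: pd.DataFrame,
    columns: list[str],
    references: dict[str, str],
    levels_map: dict[str, list[str]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design for the clinical block.

    ``levels_map`` freezes the non-reference indicator levels per column at
    training time, so the design width is identical on any test center; an
    unseen level at prediction time raises :class:`DesignError`.
    """
    derive = levels_map is None
    levels_map = {} if derive else levels_map
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in columns:
        col = frame[name]
        if name in references:
            svals = col.astype(str)
            ref = references[name]
            if derive:
                levels_map[name] = [l for l in sorted(set(svals)) if l != ref]
            else:
                unseen = set(svals) - set(levels_map[name]) - {ref}
                if unseen:
                    raise DesignError(
                        f"unseen level(s) {sorted(unseen)} for clinical covariate {name!r}"
                    )
            for lev in levels_map[name]:
                cols.append((svals == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    return np.column_stack(cols), names, levels_map


def _pc_fit(expression: pd.DataFrame, signature: GeneSignature, k: int) -> PCLoadings:
    sub = expression.loc[signature.gene_ids].to_numpy(float)
    means = sub.mean(axis=1)
    centered = (sub - means[:, None]).T  # patients x genes
    # no variance scaling: log-scale expression values are already comparable
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    k_eff = int(min(k, vt.shape[0]))
    return PCLoadings(
        gene_ids=list(signature.gene_ids),
        gene_means=means,
        loading_matrix=vt[:k_eff].T,
        k=k_eff,
    )


def _gene_design(
    kind: str,
    data: CenterDataset,
    signature: GeneSignature,
    config: ModelConfig,
    pc: PCLoadings | None,
) -> tuple[np.ndarray, list[str], PCLoadings | None, list[str]]:
    """Design columns contributed by the gene parent (C or D)."""
    parent = _GENE_PARENT[kind]
    if parent == "C":
        if pc is None:
            pc = _pc_fit(data.expression, signature, config.k_pc)
        scores = pc.project(data.expression)
        names = [f"PC{i + 1}" for i in range(pc.k)]
        return scores, names, pc, []
    genes = signature.top(config.k_top)
    if len(genes) < config.k_top:
        warnings.warn(
            f"model {kind}: only {len(genes)} genes passed selection "
            f"(k_top={config.k_top}); using all of them",
            stacklevel=3,
        )
    missing = [g for g in genes if g not in data.expression.index]
    if missing:
        raise SignatureCoverageError(f"genes absent from data: {missing}")
    vals = data.expression.loc[genes].to_numpy(float).T
    return vals, list(genes), None, list(genes)


def fit_risk_model(
    kind: str,
    data: CenterDataset,
    config: ModelConfig = ModelConfig(),
    *,
    signature: GeneSignature | None = None,
) -> RiskModel:
    """Fit one of the eight models on a center's data.

    ``signature`` overrides gene selection with a pre-selected signature
    (used by :func:`apply_signature`); when None the model screens genes on
    its own training data.
    """
    if kind not in MODEL_KINDS:
        raise InputError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    clinical_columns: list[str] = []
    references: dict[str, str] = {}
    tree = None
    pc = None
    top_genes: list[str] = []

    needs_clinical = kind in ("A", "E", "F")
    needs_tree = kind in ("B", "G", "H")
    needs_genes = kind in _GENE_PARENT

    cm = _clinical_matrix(data, config)
    levels_map: dict[str, list[str]] = {}
    if needs_clinical:
        clinical_columns = cm.column_names
        references = infer_reference_levels(cm.frame, list(cm.categorical))
        vals, nm, levels_map = _expand_clinical(cm.frame, clinical_columns, references)
        blocks.append(vals)
        names.extend(nm)
    if needs_tree:
        tree = survival_tree_fit(
            cm,
            data.outcomes,
            min_leaf=config.tree_min_leaf,
            max_depth=config.tree_max_depth,
            p_enter=config.tree_p_enter,
        )
        rates = tree_incidence_rate(tree, cm)
        blocks.append(rates[:, None])
        names.append("incidence_rate")
    if needs_genes:
        if signature is None:
            signature = select_genes(
                data.expression, data.outcomes, config.selection_threshold, ties=config.ties
            )
        vals, nm, pc, top_genes = _gene_design(kind, data, signature, config, None)
        blocks.append(vals)
        names.extend(nm)

    design = np.column_stack(blocks)
    try:
        fit = cox_fit(design, data.outcomes, ties=config.ties, names=names)
    except DesignError as err:
        if needs_tree and tree is not None and tree.n_leaves == 1:
            raise ConvergenceError(
                f"model {kind}: clinical survival tree found no admissible split, "
                "so the incidence-rate covariate is constant"
            ) from err
        raise
    if not fit.converged:
        raise ConvergenceError(
            f"model {kind} on {data.center_id}: Cox fit did not converge "
            f"(|beta|={np.linalg.norm(fit.beta):.3g}, n={fit.n}, events={fit.n_events})"
        )
    scores = cox_linear_predictor(fit.beta, design)
    return RiskModel(
        kind=kind,
        beta=fit.beta,
        design_names=names,
        training_center=data.center_id,
        training_median=float(np.median(scores)),
        cox=fit,
        clinical_columns=clinical_columns,
        clinical_references=references,
        clinical_levels=levels_map,
        signature=signature if needs_genes else None,
        pc=pc,
        top_genes=top_genes,
        tree=tree,
    )


def _build_design(model: RiskModel, data: CenterDataset, config: ModelConfig | None = None) -> np.ndarray:
    blocks: list[np.ndarray] = []
    if model.kind in ("A", "E", "F"):
        vals, _, _ = _expand_clinical(
            data.clinical.frame,
            model.clinical_columns,
            model.clinical_references,
            model.clinical_levels,
        )
        blocks.append(vals)
    if model.tree is not None:
        cm = data.clinical.subset(model.tree.feature_names)
        blocks.append(tree_incidence_rate(model.tree, cm)[:, None])
    if model.pc is not None:
        blocks.append(model.pc.project(data.expression))
    if model.top_genes:
        missing = [g for g in model.top_genes if g not in data.expression.index]
        if missing:
            raise SignatureCoverageError(f"genes absent from data: {missing}")
        blocks.append(data.expression.loc[model.top_genes].to_numpy(float).T)
    return np.column_stack(blocks)


def predict_risk(model: RiskModel, data: CenterDataset) -> np.ndarray:
    """Risk scores ``beta_train^T x_test`` for every patient in ``data``,
    using the model's frozen transformations (training gene means and PC
    loadings; the training survival tree; the training clinical encoding)."""
    design = _build_design(model, data)
    return cox_linear_predictor(model.beta, design)


def apply_signature(
    foreign_model: RiskModel, data: CenterDataset, config: ModelConfig = ModelConfig()
) -> RiskModel:
    """Refit a model of ``foreign_model``'s kind on ``data`` re-using the
    foreign gene signature verbatim (no local gene selection; PC loadings,
    gene means and all coefficients are re-estimated on ``data``).

    For the clinical-only kinds A and B there is no signature to transfer,
    so the result is exactly :func:`fit_risk_model` on ``data``.
    """
    if foreign_model.kind in _CLINICAL_KINDS:
        return fit_risk_model(foreign_model.kind, data, config)
    if foreign_model.signature is None:
        raise InputError("foreign model carries no gene signature")
    missing = [g for g in foreign_model.signature.gene_ids if g not in data.expression.index]
    if missing:
        raise SignatureCoverageError(f"genes absent from data: {missing}")
    return fit_risk_model(foreign_model.kind, data, config, signature=foreign_model.signature)
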