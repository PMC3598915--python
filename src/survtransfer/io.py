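"""File I/O: center datasets, model serialization, reports.

Clinical tables and expression matrices are delimited text (TSV by
default; comma-delimited files are detected from the header). The clinical
table has one row per sample with columns ``sample_id``, ``time``,
``event`` (coded 1 = event, 0 = censored — other codings are rejected, not
guessed) plus covariates; the expression table is genes x samples with a
gene-id first column and sample ids in the header, the microarray
convention.

Reading intersects the samples present in both files, drops any gene with
a missing value, then any sample with a missing clinical value, and logs
the counts dropped. Fitted models serialize to JSON documents that round-
trip bit-exactly, so one center can ship its model to another.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, SchemaError
from .models import GeneSignature, PCLoadings, RiskModel
from .simulate import CenterDataset, GroundTruth
from .survival import (
    CovariateMatrix,
    CoxFit,
    SurvivalTree,
    TreeNode,
    arrays_to_outcomes,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_ground_truth",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

REQUIRED_CLINICAL = ("sample_id", "time", "event")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset(
    clinical_path: str | Path,
    expression_path: str | Path,
    *,
    center_id: str | None = None,
    categorical: dict[str, str] | None = None,
) -> CenterDataset:
    """Read one center from a clinical table and an expression matrix.

    ``categorical`` maps clinical column names to their reference level;
    when omitted, non-numeric covariate columns are treated as categorical
    with the most frequent level as reference.
    """
    clinical_path, expression_path = Path(clinical_path), Path(expression_path)
    clin = pd.read_csv(
        clinical_path, sep=_sniff_sep(clinical_path), dtype={"sample_id": str},
        float_precision="round_trip",
    )
    for col in REQUIRED_CLINICAL:
        if col not in clin.columns:
            raise SchemaError(f"{clinical_path}: missing required column {col!r}")
    if clin["sample_id"].duplicated().any():
        raise SchemaError(f"{clinical_path}: duplicated sample_id values")

    expr = pd.read_csv(
        expression_path, sep=_sniff_sep(expression_path), index_col=0,
        float_precision="round_trip",
    )
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    non_numeric = expr.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    bad = expr.notna() & non_numeric.isna()
    if bad.any().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise SchemaError(f"{expression_path}: non-numeric expression value at gene {g!r}, sample {s!r}")
    expr = non_numeric

    shared = [s for s in clin["sample_id"] if s in set(expr.columns)]
    if not shared:
        raise AlignmentError(
            f"no overlapping samples between {clinical_path.name} and {expression_path.name}"
        )
    n_clin_only = len(clin) - len(shared)
    n_expr_only = expr.shape[1] - len(shared)
    if n_clin_only or n_expr_only:
        log.info(
            "sample intersection: dropped %d clinical-only and %d expression-only samples",
            n_clin_only, n_expr_only,
        )
    clin = clin.set_index("sample_id").loc[shared]
    expr = expr[shared]

    n_genes_before = expr.shape[0]
    expr = expr.dropna(axis=0, how="any")
    if expr.shape[0] < n_genes_before:
        log.info("dropped %d genes with missing values", n_genes_before - expr.shape[0])

    keep = clin.notna().all(axis=1)
    if (~keep).any():
        log.info("dropped %d samples with missing clinical values", int((~keep).sum()))
        clin = clin.loc[keep]
        expr = expr[clin.index.tolist()]

    time = pd.to_numeric(clin["time"], errors="coerce")
    event = pd.to_numeric(clin["event"], errors="coerce")
    if time.isna().any() or (time <= 0).any():
        raise SchemaError(f"{clinical_path}: 'time' must be positive numeric")
    if not event.isin([0, 1]).all():
        raise SchemaError(f"{clinical_path}: 'event' must be coded 1=event, 0=censored")

    covars = clin.drop(columns=["time", "event"]).reset_index(drop=True)
    if categorical is None:
        categorical = {}
        for col in covars.columns:
            if pd.to_numeric(covars[col], errors="coerce").isna().any():
                counts = covars[col].astype(str).value_counts()
                top = counts.max()
                categorical[col] = sorted(counts.index[counts == top])[0]
            else:
                covars[col] = pd.to_numeric(covars[col])
    else:
        for col in covars.columns:
            if col not in categorical:
                covars[col] = pd.to_numeric(covars[col])

    return CenterDataset(
        center_id=center_id or clinical_path.stem,
        clinical=CovariateMatrix(covars, dict(categorical)),
        expression=expr,
        outcomes=arrays_to_outcomes(time.to_numpy(), event.to_numpy().astype(int)),
        sample_ids=list(clin.index),
    )


def write_dataset(dataset: CenterDataset, clinical_path: str | Path, expression_path: str | Path) -> None:
    """Write a center back to the delimited formats :func:`read_dataset` reads."""
    clin = dataset.clinical.frame.copy()
    clin.insert(0, "sample_id", dataset.sample_ids)
    clin.insert(1, "time", dataset.times)
    clin.insert(2, "event", dataset.events)
    clin.to_csv(clinical_path, sep="\t", index=False)
    out = dataset.expression.copy()
    out.index.name = "gene_id"
    out.to_csv(expression_path, sep="\t")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "clinical_effects": truth.clinical_effects,
        "gene_effects": truth.gene_effects.tolist(),
        "prognostic_gene_ids": truth.prognostic_gene_ids,
        "true_scores_per_center": [s.tolist() for s in truth.true_scores_per_center],
        "center_offsets": truth.center_offsets.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Model serialization


def _tree_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {
            "leaf": True,
            "incidence_rate": node.incidence_rate,
            "n": node.n,
            "n_events": node.n_events,
        }
    return {
        "leaf": False,
        "feature": node.feature,
        "threshold": node.threshold,
        "left_levels": sorted(node.left_levels) if node.left_levels is not None else None,
        "right_levels": sorted(node.right_levels) if node.right_levels is not None else None,
        "n": node.n,
        "n_events": node.n_events,
        "left": _tree_to_dict(node.left),
        "right": _tree_to_dict(node.right),
    }


def _tree_from_dict(d: dict) -> TreeNode:
    if d["leaf"]:
        return TreeNode(incidence_rate=d["incidence_rate"], n=d["n"], n_events=d["n_events"])
    return TreeNode(
        feature=d["feature"],
        threshold=d["threshold"],
        left_levels=frozenset(d["left_levels"]) if d["left_levels"] is not None else None,
        right_levels=frozenset(d["right_levels"]) if d["right_levels"] is not None else None,
        n=d["n"],
        n_events=d["n_events"],
        left=_tree_from_dict(d["left"]),
        right=_tree_from_dict(d["right"]),
    )


def model_to_json(model: RiskModel) -> str:
    """Serialize a fitted model to a JSON document.

    Floats are emitted at full ``repr`` precision, so deserialising
    reproduces the exact same doubles (bit-exact round trip).
    """
    doc: dict = {
        "kind": model.kind,
        "beta": model.beta.tolist(),
        "design_names": model.design_names,
        "training_center": model.training_center,
        "training_median": model.training_median,
        "clinical_columns": model.clinical_columns,
        "clinical_references": model.clinical_references,
        "clinical_levels": model.clinical_levels,
        "top_genes": model.top_genes,
    }
    if model.signature is not None:
        doc["signature"] = {
            "gene_ids": model.signature.gene_ids,
            "p_values": model.signature.p_values.tolist(),
            "selection_threshold": model.signature.selection_threshold,
        }
    if model.pc is not None:
        doc["pc"] = {
            "gene_ids": model.pc.gene_ids,
            "gene_means": model.pc.gene_means.tolist(),
            "loading_matrix": model.pc.loading_matrix.tolist(),
            "k": model.pc.k,
        }
    if model.tree is not None:
        doc["tree"] = {
            "root": _tree_to_dict(model.tree.root),
            "feature_names": model.tree.feature_names,
            "categorical": model.tree.categorical,
            "min_leaf": model.tree.min_leaf,
            "max_depth": model.tree.max_depth,
        }
    if model.cox is not None:
        doc["cox"] = {
            "beta": model.cox.beta.tolist(),
            "se": model.cox.se.tolist(),
            "loglik": model.cox.loglik,
            "loglik_null": model.cox.loglik_null,
            "n": model.cox.n,
            "n_events": model.cox.n_events,
            "converged": model.cox.converged,
            "names": model.cox.names,
        }
    return json.dumps(doc)


def model_from_json(text: str) -> RiskModel:
    doc = json.loads(text)
    signature = None
    if "signature" in doc:
        signature = GeneSignature(
            gene_ids=doc["signature"]["gene_ids"],
            p_values=np.array(doc["signature"]["p_values"]),
            selection_threshold=doc["signature"]["selection_threshold"],
        )
    pc = None
    if "pc" in doc:
        pc = PCLoadings(
            gene_ids=doc["pc"]["gene_ids"],
            gene_means=np.array(doc["pc"]["gene_means"]),
            loading_matrix=np.array(doc["pc"]["loading_matrix"]),
            k=doc["pc"]["k"],
        )
    tree = None
    if "tree" in doc:
        tree = SurvivalTree(
            root=_tree_from_dict(doc["tree"]["root"]),
            feature_names=doc["tree"]["feature_names"],
            categorical=doc["tree"]["categorical"],
            min_leaf=doc["tree"]["min_leaf"],
            max_depth=doc["tree"]["max_depth"],
        )
    cox = None
    if "cox" in doc:
        cox = CoxFit(
            beta=np.array(doc["cox"]["beta"]),
            se=np.array(doc["cox"]["se"]),
            loglik=doc["cox"]["loglik"],
            loglik_null=doc["cox"]["loglik_null"],
            n=doc["cox"]["n"],
            n_events=doc["cox"]["n_events"],
            converged=doc["cox"]["converged"],
            names=doc["cox"]["names"],
        )
    return RiskModel(
        kind=doc["kind"],
        beta=np.array(doc["beta"]),
        design_names=doc["design_names"],
        training_center=doc["training_center"],
        training_median=doc["training_median"],
        cox=cox,
        clinical_columns=doc["clinical_columns"],
        clinical_references=doc["clinical_references"],
        clinical_levels=doc["clinical_levels"],
        signature=signature,
        pc=pc,
        top_genes=doc["top_genes"],
        tree=tree,
    )


def save_model(model: RiskModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model))


def load_model(path: str | Path) -> RiskModel:
    return model_from_json(Path(path).read_text())
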