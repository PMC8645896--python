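"""End-to-end training workflow.

curate -> featurize -> SVC-L1 select -> GBM rank -> top-k -> grid-search
-> train -> evaluate, with an 80/20 stratified train/validation split and
five-fold cross-validation on the training side.  Feature selection and
scaling only ever see training data; the honest cross-validation mode
refits the whole selection stage inside every fold, while the frozen mode
reuses the one selection fitted on the full training split (cheaper, and
mirrors protocols that select once up front).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .applications import ModelBundle
from .descriptors import REGISTRY_VERSION, EncoderConfig, encode_all
from .modeling import (
    DEFAULT_GRIDS,
    EvalEntry,
    EvalReport,
    ModelSpec,
    cross_validate,
    evaluate,
    grid_search,
    kfold,
    labels_to_binary,
    predict_scores,
    split_dataset,
    train,
)
from .seqio import CurationConfig, LabeledDataset, curate_dataset
from .selection import SelectionConfig, select_and_rank, take_top_k


@dataclass
class PipelineResult:
    bundle: ModelBundle
    selection: object
    top_features: list[str]
    cv_report: EvalReport | None
    train_eval: EvalEntry
    validation_eval: EvalEntry
    provenance: dict = field(default_factory=dict)


def _dataset_hash(ds: LabeledDataset) -> str:
    h = hashlib.sha256()
    for pep, label in ds.records:
        h.update(f"{pep.id}\t{pep.seq}\t{label}\n".encode())
    return h.hexdigest()[:16]


def _honest_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    sel_cfg: SelectionConfig,
    top_k: int,
    k: int,
    seed: int,
) -> EvalReport:
    """Five-fold CV refitting selection, ranking and scaling per fold."""
    folds = kfold(y, k=k, seed=seed)
    entries, assignment = [], []
    for tr, te in folds:
        sel = select_and_rank(X.iloc[tr], y[tr], sel_cfg)
        if not sel.selected:
            warnings.warn("fold selected no features; scoring at chance")
            entries.append(evaluate(np.full(len(te), 0.5), y[te]))
            assignment.append({"train": tr.tolist(), "test": te.tolist()})
            continue
        kk = min(top_k, len(sel.ranking))
        feats = take_top_k(sel.ranking, kk)
        model = train(X.iloc[tr][feats], y[tr], spec)
        scores = predict_scores(model, X.iloc[te][feats])
        entries.append(evaluate(scores, y[te]))
        assignment.append({"train": tr.tolist(), "test": te.tolist()})
    return EvalReport(
        folds=entries,
        aggregate=EvalReport.aggregate_folds(entries),
        provenance={"k": k, "seed": seed, "fold_indices": assignment,
                    "selection_refit_per_fold": True},
    )


def run_pipeline(
    ds: LabeledDataset,
    encoder: EncoderConfig = EncoderConfig(),
    curation: CurationConfig = CurationConfig(),
    selection: SelectionConfig | None = None,
    top_k: int = 60,
    model_kind: str = "SVM",
    model_params: dict | None = None,
    grid: dict | None = None,
    do_grid_search: bool = True,
    cv_folds: int = 5,
    run_cv: bool = True,
    frozen_selection: bool = False,
    seed: int = 0,
    threshold: float = 0.5,
) -> PipelineResult:
    """Train and evaluate a defensin classifier end to end.

    With ``model_params`` given, that fixed spec is trained; with
    ``do_grid_search`` the family's grid (``grid`` or the shipped
    default) is searched by mean CV AUROC on the training split.
    ``run_cv=False`` skips the five-fold report (the 80/20 validation
    metrics are always computed).
    """
    sel_cfg = selection or SelectionConfig(seed=seed)

    curated, curation_reports = curate_dataset(ds, curation)
    train_ds, val_ds = split_dataset(curated, train_frac=0.8, seed=seed)

    X_train = encode_all(train_ds.peptides, encoder)
    y_train = labels_to_binary(train_ds.labels)
    X_val = encode_all(val_ds.peptides, encoder)
    y_val = labels_to_binary(val_ds.labels)

    # selection + ranking on the training split only
    sel = select_and_rank(X_train, y_train, sel_cfg)
    if not sel.selected:
        raise RuntimeError("selection produced no features on the training split")
    k_eff = min(top_k, len(sel.ranking))
    if k_eff < top_k:
        warnings.warn(f"only {k_eff} features survived selection (top_k={top_k})")
    top_feats = take_top_k(sel.ranking, k_eff)

    # model spec: fixed when params are given, otherwise grid-searched on
    # the training split
    if model_params is not None:
        spec = ModelSpec(model_kind, model_params, seed=seed)
    elif do_grid_search:
        spec, _ = grid_search(
            X_train[top_feats], y_train, model_kind, grid, k=cv_folds, seed=seed
        )
    else:
        spec = ModelSpec(model_kind, {}, seed=seed)

    # internal validation: five-fold CV on the training split
    cv_report = None
    if run_cv:
        if frozen_selection:
            cv_report = cross_validate(
                X_train[top_feats], y_train, spec, k=cv_folds, seed=seed
            )
            cv_report.provenance["selection_refit_per_fold"] = False
        else:
            cv_report = _honest_cv(
                X_train, y_train, spec, sel_cfg, top_k, cv_folds, seed
            )

    # final model on the full training split; external validation on the 20%
    model = train(X_train[top_feats], y_train, spec)
    model.threshold = threshold
    train_eval = evaluate(predict_scores(model, X_train[top_feats]), y_train, threshold)
    val_eval = evaluate(predict_scores(model, X_val[top_feats]), y_val, threshold)

    bundle = ModelBundle(
        model=model,
        encoder=encoder,
        metadata={
            "length_domain": [curation.min_len, curation.max_len],
            "dataset": ds.name,
        },
    )
    provenance = {
        "dataset_hash": _dataset_hash(curated),
        "registry_version": REGISTRY_VERSION,
        "encoder": encoder.to_dict(),
        "curation_reports": curation_reports,
        "seed": seed,
        "train_ids": [p.id for p in train_ds.peptides],
        "validation_ids": [p.id for p in val_ds.peptides],
        "n_selected": len(sel.selected),
        "selected_features": list(sel.selected),
        "top_features": top_feats,
        "model_spec": {"kind": spec.kind, "params": dict(spec.params), "seed": spec.seed},
    }
    return PipelineResult(
        bundle=bundle,
        selection=sel,
        top_features=top_feats,
        cv_report=cv_report,
        train_eval=train_eval,
        validation_eval=val_eval,
        provenance=provenance,
    )
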