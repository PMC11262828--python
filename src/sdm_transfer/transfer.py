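"""Interpolation, single-site transfer and regional transfer experiments.

Interpolation: within each balanced replicate, every three-fold rotation
screens covariates on the two training folds, fits the shrinkage-selected
GAM, and scores the held-out fold.  Transferability: each of those top models
(fold-trained, per the validation design) predicts every balanced replicate
dataset of each target site, so interpolation and transfer are scored on
comparably balanced evaluation sets.  Regional models pool two sites before
down-sampling and transfer to the third.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SDMTransferError
from .evaluation import metric_set
from .gam_engine import FittedGAM, SmoothSpec, predict, select_smoothing
from .resampling import ReplicateDesign, make_replicates
from .screening import screen
from .synthetic_data import covariate_columns

__all__ = [
    "ExperimentPlan",
    "TopModel",
    "interpolate_eval",
    "transfer_eval",
    "regional_eval",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "source",
    "replicate",
    "fold",
    "context",
    "target_site",
    "sen",
    "spe",
    "tss",
    "auc",
    "n_eval",
    "extrap_frac",
    "dev_expl",
    "adj_r2",
    "n_retained",
    "retained",
]


@dataclass
class ExperimentPlan:
    """One interpolation/transfer experiment.

    ``source`` is a site name (single_site mode) or "A+B" (regional mode);
    ``targets`` are the remaining site(s).  Screening runs per fold rotation
    on the training folds.
    """

    mode: str  # "single_site" | "regional"
    source: str
    targets: tuple[str, ...]
    replicates: list[ReplicateDesign]
    concurvity_threshold: float = 0.3
    classification_threshold: float = 0.5
    basis_dim: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single_site", "regional"):
            raise SDMTransferError(f"unknown experiment mode {self.mode!r}")
        src_sites = set(self.source.split("+"))
        if src_sites & set(self.targets):
            raise SDMTransferError("targets must be disjoint from the source")


@dataclass
class TopModel:
    """A selected model from one replicate and fold rotation."""

    source: str
    replicate: int
    fold: int
    model: FittedGAM
    retained: list[str]


def _metric_row(
    scores, labels, threshold, *, source, replicate, fold, context, target_site,
    extrap_frac=0.0, dev_expl=np.nan, adj_r2=np.nan, retained=(),
) -> dict:
    m = metric_set(scores, labels, threshold)
    return {
        "source": source,
        "replicate": replicate,
        "fold": fold,
        "context": context,
        "target_site": target_site,
        "sen": m.sensitivity,
        "spe": m.specificity,
        "tss": m.tss,
        "auc": m.auc,
        "n_eval": len(labels),
        "extrap_frac": extrap_frac,
        "dev_expl": dev_expl,
        "adj_r2": adj_r2,
        "n_retained": len(retained),
        "retained": ";".join(retained),
    }


def interpolate_eval(plan: ExperimentPlan) -> tuple[pd.DataFrame, list[TopModel]]:
    """Cross-validated interpolation for every replicate and fold rotation.

    Returns the metric records (context "interp") and the fitted top models,
    one per (replicate, fold rotation).
    """
    rows = []
    models: list[TopModel] = []
    for design in plan.replicates:
        covs = covariate_columns(design.records)
        for fold in range(len(design.folds)):
            train = design.training_frame(fold)
            test = design.test_frame(fold)
            retained, _, _ = screen(
                train, covs,
                threshold=plan.concurvity_threshold,
                basis_dim=plan.basis_dim,
            )
            terms = [SmoothSpec(c, basis_dim=plan.basis_dim) for c in retained]
            fit = select_smoothing(train, terms)
            scores, extrap = predict(fit, test, return_extrapolation=True)
            rows.append(
                _metric_row(
                    scores,
                    test["response"].to_numpy(),
                    plan.classification_threshold,
                    source=plan.source,
                    replicate=design.replicate_id,
                    fold=fold,
                    context="interp",
                    target_site=plan.source,
                    extrap_frac=float(extrap.mean()),
                    dev_expl=fit.deviance_explained,
                    adj_r2=fit.adjusted_r2,
                    retained=retained,
                )
            )
            models.append(
                TopModel(
                    source=plan.source,
                    replicate=design.replicate_id,
                    fold=fold,
                    model=fit,
                    retained=retained,
                )
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS), models


def transfer_eval(
    plan: ExperimentPlan,
    models: list[TopModel],
    target_replicates: dict[str, list[ReplicateDesign]],
) -> pd.DataFrame:
    """Score every top model on every balanced replicate of every target site.

    A retained covariate missing from a target's records raises a named
    error: imputing it would fabricate transferability.  Extrapolation
    fractions (predictions outside the source training range of any smooth)
    are reported per evaluation.
    """
    rows = []
    for target in plan.targets:
        if target not in target_replicates:
            raise SDMTransferError(f"no replicate datasets supplied for target {target!r}")
        for top in models:
            for design in target_replicates[target]:
                scores, extrap = predict(
                    top.model, design.records, return_extrapolation=True
                )
                rows.append(
                    _metric_row(
                        scores,
                        design.records["response"].to_numpy(),
                        plan.classification_threshold,
                        source=plan.source,
                        replicate=top.replicate,
                        fold=top.fold,
                        context="transfer",
                        target_site=f"{target}/r{design.replicate_id}",
                        extrap_frac=float(extrap.mean()),
                        retained=top.retained,
                    )
                )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if len(df):
        df["target_site"] = df["target_site"].astype(str)
    return df


def regional_eval(
    pair_records: pd.DataFrame,
    third_site_replicates: dict[str, list[ReplicateDesign]],
    *,
    label: str,
    third_site: str,
    n_replicates: int = 10,
    base_seed: int = 0,
    k_folds: int = 3,
    concurvity_threshold: float = 0.3,
    classification_threshold: float = 0.5,
    basis_dim: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TopModel]]:
    """Pool two sites, interpolate, then transfer to the held-out third site."""
    replicates = make_replicates(
        pair_records, n_replicates, base_seed, k_folds=k_folds, label=label
    )
    plan = ExperimentPlan(
        mode="regional",
        source=label,
        targets=(third_site,),
        replicates=replicates,
        concurvity_threshold=concurvity_threshold,
        classification_threshold=classification_threshold,
        basis_dim=basis_dim,
        seed=base_seed,
    )
    interp, models = interpolate_eval(plan)
    transfer = transfer_eval(plan, models, third_site_replicates)
    return interp, transfer, models
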