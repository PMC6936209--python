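"""Validation harnesses: repeated cross-validation and cross-cohort transfer.

Within-cohort performance is estimated by 5x5 repeated cross-validation,
stratified by event status. Every per-split pipeline is fit strictly on
the training fold: imputation means, the quantile-normalization reference,
the hazard-rank target, feature standardization and the model itself never
see held-out labels or features; held-out samples are projected onto the
training fold's reference at prediction time.

Cross-cohort transfer trains on one whole cohort and tests on another.
There each cohort is quantile-normalized independently against its own
reference (cohorts come from different platforms, and per-dataset
normalization is what makes them comparable); test labels are still used
only for evaluation, never for fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort_io import Cohort, intersect_genes
from .metrics import EvaluationReport, evaluate
from .models import (
    CLINICAL_FEATURES,
    RiskModel,
    fit_clinical,
    fit_gpr,
    predict,
    stack,
)
from .preprocess import (
    clinical_means,
    encode_clinical,
    impute_mean,
    quantile_normalize,
    quantile_reference,
)
from .ranking import guanrank

logger = logging.getLogger("guanrank")

__all__ = [
    "MODEL_KINDS",
    "FittedPipeline",
    "CrossCohortReport",
    "fit_pipeline",
    "fit_predict_split",
    "run_cv",
    "run_cross_cohort",
    "run_cross_cohort_matrix",
]

MODEL_KINDS = ("gpr-guanrank", "gpr-status", "clinical", "stacked")


def _prepared_matrix(cohort: Cohort, top_k: int | None = None):
    """Impute + quantile-normalize a cohort's expression; samples x genes.

    Returns (matrix, gene_ids, gene_means, reference) so held-out samples
    can be projected onto the same preprocessing.
    """
    imputed = impute_mean(cohort.expression)
    gene_means = pd.Series(
        np.nan_to_num(np.nanmean(cohort.expression.values, axis=1), nan=0.0),
        index=cohort.expression.data.index,
    )
    normalized = quantile_normalize(imputed)
    reference = quantile_reference(imputed)
    data = normalized.data
    if top_k is not None and top_k < data.shape[0]:
        keep = data.var(axis=1).nlargest(top_k).index
        data = data.loc[keep]
    return data.T.to_numpy(), list(data.index), gene_means, reference


def _project_matrix(
    cohort: Cohort,
    gene_ids: list[str],
    gene_means: pd.Series,
    reference: np.ndarray,
) -> np.ndarray:
    """Project held-out samples onto a training fold's preprocessing."""
    from .cohort_io import ExpressionMatrix

    frame = cohort.expression.data
    filled = frame.T.fillna(gene_means).T  # fill each gene row with its train mean
    normalized = quantile_normalize(ExpressionMatrix(filled), reference=reference)
    return normalized.data.loc[gene_ids].T.to_numpy()


@dataclass
class FittedPipeline:
    """Everything fit on a training set, ready to score held-out samples."""

    model_kind: str
    gene_ids: list[str]
    gene_means: pd.Series
    reference: np.ndarray
    clin_means: tuple[float, float]
    expr_model: RiskModel | None
    clin_model: RiskModel | None
    stack_w: float

    def predict_cohort(self, cohort: Cohort, independent_preprocessing: bool = False) -> np.ndarray:
        """Risk scores for a cohort's samples (labels untouched).

        With ``independent_preprocessing`` the cohort is imputed and
        quantile-normalized against itself (cross-cohort mode) instead of
        being projected onto the training preprocessing (CV mode).
        """
        if independent_preprocessing:
            X, ids, _, _ = _prepared_matrix(cohort)
            lookup = pd.DataFrame(X.T, index=ids)
            X = lookup.loc[self.gene_ids].to_numpy().T
            clin = encode_clinical(cohort.clinical)
        else:
            X = _project_matrix(cohort, self.gene_ids, self.gene_means, self.reference)
            clin = encode_clinical(cohort.clinical, means=self.clin_means)
        if self.model_kind == "clinical":
            return predict(self.clin_model, clin, list(CLINICAL_FEATURES))
        pred_expr = predict(self.expr_model, X, self.gene_ids)
        if self.model_kind == "stacked":
            pred_clin = predict(self.clin_model, clin, list(CLINICAL_FEATURES))
            return stack(pred_expr, pred_clin, self.stack_w)
        return pred_expr


def fit_pipeline(
    train: Cohort,
    model_kind: str = "gpr-guanrank",
    seed: int = 0,
    n_restarts: int = 5,
    top_k_variance: int | None = None,
    stack_w: float = 0.5,
) -> FittedPipeline:
    """Fit preprocessing + hazard-rank target + model on a training cohort."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    X, gene_ids, gene_means, reference = _prepared_matrix(train, top_k_variance)
    ranks = guanrank(train.labels)
    target = (
        train.statuses.astype(float)
        if model_kind == "gpr-status"
        else ranks.normalized
    )
    expr_model = None
    clin_model = None
    if model_kind in ("gpr-guanrank", "gpr-status", "stacked"):
        expr_model = fit_gpr(
            X, target, feature_ids=gene_ids, kind=model_kind, seed=seed,
            n_restarts=n_restarts,
        )
    if model_kind in ("clinical", "stacked"):
        clin = encode_clinical(train.clinical)
        clin_model = fit_clinical(clin, ranks.normalized)
    return FittedPipeline(
        model_kind=model_kind,
        gene_ids=gene_ids,
        gene_means=gene_means,
        reference=reference,
        clin_means=clinical_means(train.clinical),
        expr_model=expr_model,
        clin_model=clin_model,
        stack_w=stack_w,
    )


def fit_predict_split(
    cohort: Cohort,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    model_kind: str = "gpr-guanrank",
    seed: int = 0,
    **fit_opts,
) -> np.ndarray:
    """Fit on the training indices and score the held-out indices.

    The held-out samples contribute nothing to the fit: their labels are
    never read and their features are only transformed with statistics
    stored from the training fold.
    """
    train = cohort.subset(train_idx)
    test = cohort.subset(test_idx)
    pipeline = fit_pipeline(train, model_kind=model_kind, seed=seed, **fit_opts)
    return pipeline.predict_cohort(test, independent_preprocessing=False)


def _fold_assignments(
    statuses: np.ndarray, folds: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (by event status) fold split; unstratified fallback."""
    idx = np.arange(len(statuses))
    counts = np.bincount(statuses, minlength=2)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        return [(tr, te) for tr, te in splitter.split(idx[:, None], statuses)]
    logger.warning(
        "run_cv: too few samples in one status class (%s) for %d stratified "
        "folds; falling back to unstratified folds",
        counts.tolist(),
        folds,
    )
    splitter = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return [(tr, te) for tr, te in splitter.split(idx[:, None])]


def _safe_metrics(preds: np.ndarray, labels) -> dict[str, float]:
    try:
        report = evaluate(preds, labels)
        return {"c_index": report.c_index, "integrated_auc": report.integrated_auc}
    except ValueError as exc:
        logger.warning("evaluation degenerate on this split: %s", exc)
        return {"c_index": float("nan"), "integrated_auc": float("nan")}


def run_cv(
    cohort: Cohort,
    folds: int = 5,
    repeats: int = 5,
    model_kind: str = "gpr-guanrank",
    seed: int = 0,
    **fit_opts,
) -> pd.DataFrame:
    """Repeated stratified cross-validation; one row per evaluation split.

    Returns a frame with columns (repeat, fold, n_test, c_index,
    integrated_auc); aggregate with ``df[["c_index", "integrated_auc"]]
    .agg(["mean", "std"])``. Fold assignments are reproducible from the
    seed.
    """
    if cohort.n_samples < folds:
        raise ValueError("cohort smaller than the number of folds")
    rows = []
    for rep in range(repeats):
        assignment = _fold_assignments(cohort.statuses, folds, seed * 1000 + rep)
        for fold_no, (train_idx, test_idx) in enumerate(assignment):
            preds = fit_predict_split(
                cohort, train_idx, test_idx, model_kind=model_kind,
                seed=seed, **fit_opts,
            )
            metrics = _safe_metrics(preds, [cohort.labels[i] for i in test_idx])
            rows.append(
                {"repeat": rep, "fold": fold_no, "n_test": len(test_idx), **metrics}
            )
    return pd.DataFrame(rows)


@dataclass
class CrossCohortReport:
    """Outcome of training on one cohort and testing on another."""

    train_name: str
    test_name: str
    sample_ids: list[str]
    predictions: np.ndarray
    report: EvaluationReport


def run_cross_cohort(
    train: Cohort,
    test: Cohort,
    model_kind: str = "stacked",
    seed: int = 0,
    **fit_opts,
) -> CrossCohortReport:
    """Train on one cohort, evaluate on another.

    The two cohorts are first restricted to their shared gene set, then
    each is preprocessed independently (its own imputation means and
    quantile reference). The hazard-rank target and the model come from
    the training cohort alone.
    """
    train_i, test_i = intersect_genes(train, test)
    pipeline = fit_pipeline(train_i, model_kind=model_kind, seed=seed, **fit_opts)
    preds = pipeline.predict_cohort(test_i, independent_preprocessing=True)
    return CrossCohortReport(
        train_name=train.name,
        test_name=test.name,
        sample_ids=test_i.sample_ids,
        predictions=preds,
        report=evaluate(preds, test_i.labels),
    )


def run_cross_cohort_matrix(
    cohorts: Sequence[Cohort],
    model_kind: str = "stacked",
    seed: int = 0,
    **fit_opts,
) -> pd.DataFrame:
    """Every ordered train/test cohort pair (n cohorts -> n(n-1) rows)."""
    rows = []
    for train, test in permutations(cohorts, 2):
        rep = run_cross_cohort(train, test, model_kind=model_kind, seed=seed, **fit_opts)
        rows.append(
            {
                "train": rep.train_name,
                "test": rep.test_name,
                "c_index": rep.report.c_index,
                "integrated_auc": rep.report.integrated_auc,
            }
        )
    return pd.DataFrame(rows)
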