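"""Expression preprocessing and clinical covariate encoding.

Missing expression values are mean-imputed per gene (genes are features;
the mean runs across patients), then every sample column is quantile-
normalized onto one reference distribution so that cohorts profiled on
different platforms become comparable. Each cohort is normalized
independently. Clinical covariates (age, ordinal ISS stage) are encoded
as a plain two-column numeric matrix with mean imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger("guanrank")

__all__ = [
    "impute_mean",
    "quantile_normalize",
    "quantile_reference",
    "apply_quantile_reference",
    "encode_clinical",
    "log2_transform",
]


def impute_mean(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing entry by its gene's mean over observed samples.

    A gene with no observed value at all becomes a constant-zero feature
    (harmless to downstream regressors) and is warned about.
    """
    values = m.values
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=1)
    sums = np.where(observed, values, 0.0).sum(axis=1)
    row_means = np.divide(
        sums, n_obs, out=np.full(len(sums), np.nan), where=n_obs > 0
    )
    all_missing = np.isnan(row_means)
    if all_missing.any():
        logger.warning(
            "impute_mean: %d gene(s) with no observed value filled with 0",
            int(all_missing.sum()),
        )
        row_means[all_missing] = 0.0
    out = np.where(np.isnan(values), row_means[:, None], values)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    )


def quantile_reference(m: ExpressionMatrix) -> np.ndarray:
    """Reference distribution: the mean of the sorted sample columns."""
    values = m.values
    if np.isnan(values).any():
        raise ValueError(
            "quantile normalization requires complete data; run impute_mean first"
        )
    return np.sort(values, axis=0).mean(axis=1)


def _map_column_to_reference(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a column's values by reference quantiles at their ranks.

    Ties share the mean of the reference values at the ranks they occupy.
    """
    order = np.argsort(col, kind="stable")
    out = np.empty_like(reference)
    out[order] = reference
    uniq, inverse = np.unique(col, return_inverse=True)
    if len(uniq) < len(col):  # average reference values within tie groups
        sums = np.bincount(inverse, weights=out)
        counts = np.bincount(inverse)
        out = (sums / counts)[inverse]
    return out


def quantile_normalize(
    m: ExpressionMatrix, reference: np.ndarray | None = None
) -> ExpressionMatrix:
    """Force every sample column onto a common reference distribution.

    The reference defaults to the mean of the sorted columns of ``m``
    itself; pass a stored reference to project held-out samples onto a
    training cohort's distribution. Within-column rank order is preserved;
    tied values receive the mean of their tied reference quantiles.
    """
    values = m.values
    if np.isnan(values).any():
        raise ValueError(
            "quantile normalization requires complete data; run impute_mean first"
        )
    if reference is None:
        reference = quantile_reference(m)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (values.shape[0],):
        raise ValueError(
            f"reference length {reference.shape} does not match gene count "
            f"{values.shape[0]}"
        )
    out = np.column_stack(
        [_map_column_to_reference(values[:, j], reference) for j in range(values.shape[1])]
    )
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    )


def apply_quantile_reference(
    m: ExpressionMatrix, reference: np.ndarray
) -> ExpressionMatrix:
    """Alias for :func:`quantile_normalize` with an explicit stored reference."""
    return quantile_normalize(m, reference=reference)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform for count-scale (RNA-seq) matrices; optional."""
    values = m.values
    if np.nanmin(values) < 0:
        raise ValueError("log2 transform requires non-negative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values + 1.0), index=m.data.index, columns=m.data.columns)
    )


def encode_clinical(
    c: ClinicalTable, means: tuple[float, float] | None = None
) -> np.ndarray:
    """Encode the clinical table as a samples x 2 matrix (age, ISS ordinal).

    Missing entries are imputed with the column mean over samples (or with
    ``means`` computed on a training split, for held-out encoding). An
    all-missing age column falls back to 0 and an all-missing ISS column to
    the ordinal midpoint 2, with a warning; either yields a constant
    feature that an intercepted linear model absorbs.
    """
    age = c.data["age"].to_numpy(dtype=float)
    iss = c.data["iss"].to_numpy(dtype=float)
    if means is not None:
        age_mean, iss_mean = float(means[0]), float(means[1])
    else:
        age_mean = _nanmean_or(age, np.nan)
        iss_mean = _nanmean_or(iss, np.nan)
        if np.isnan(age_mean):
            logger.warning("encode_clinical: all ages missing; filling with 0")
            age_mean = 0.0
        if np.isnan(iss_mean):
            logger.warning(
                "encode_clinical: all ISS stages missing; filling with midpoint 2"
            )
            iss_mean = 2.0
    age = np.where(np.isnan(age), age_mean, age)
    iss = np.where(np.isnan(iss), iss_mean, iss)
    return np.column_stack([age, iss])


def _nanmean_or(x: np.ndarray, fallback: float) -> float:
    """Mean of the observed entries, or ``fallback`` if none are observed."""
    observed = x[~np.isnan(x)]
    return float(observed.mean()) if len(observed) else fallback


def clinical_means(c: ClinicalTable) -> tuple[float, float]:
    """Training-split (age, ISS) means for held-out encoding."""
    return (
        _nanmean_or(c.data["age"].to_numpy(dtype=float), 0.0),
        _nanmean_or(c.data["iss"].to_numpy(dtype=float), 2.0),
    )
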