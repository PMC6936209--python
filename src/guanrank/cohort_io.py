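"""Cohort file I/O and sample/gene alignment.

A cohort bundles three tab-separated tables sharing a sample-id set:

* expression matrix — first column ``gene_id``, remaining columns are
  sample ids, genes as rows (the usual GEP distribution layout);
* clinical table — columns ``sample_id``, ``age`` (years), ``iss`` (1-3);
* survival table — columns ``sample_id``, ``time`` (days), ``status``
  (1 = progression event observed, 0 = right-censored).

Missing clinical values may be written as an empty field or ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("guanrank")

__all__ = [
    "SurvivalLabel",
    "ExpressionMatrix",
    "ClinicalTable",
    "Cohort",
    "read_cohort",
    "intersect_genes",
    "write_scores",
    "read_scores",
]


@dataclass(frozen=True)
class SurvivalLabel:
    """Right-censored time-to-event label for one patient.

    ``time`` is the observed time in days (event time if ``status == 1``,
    censoring time otherwise); ``status`` is 1 for an observed progression
    event and 0 for right censoring.
    """

    sample_id: str
    time: float
    status: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: time must be a positive finite "
                f"number of days, got {self.time!r}"
            )
        if self.status not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id!r}: status must be 0 (censored) or "
                f"1 (event), got {self.status!r}"
            )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values (NaN = missing, pre-imputation)."""

    data: pd.DataFrame  # rows indexed by gene_id, columns by sample_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique()
            logger.warning(
                "expression matrix: %d duplicate gene id(s) (e.g. %s); "
                "keeping first occurrence",
                len(dup),
                dup[0],
            )
            self.data = self.data[~self.data.index.duplicated(keep="first")]
        if self.data.columns.has_duplicates:
            raise ValueError("expression matrix has duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates: age (years) and ordinal ISS stage."""

    data: pd.DataFrame  # indexed by sample_id, columns age, iss (NaN allowed)

    def __post_init__(self) -> None:
        for col in ("age", "iss"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        iss = self.data["iss"].dropna()
        bad = iss[~iss.isin([1, 2, 3])]
        if len(bad):
            raise ValueError(
                f"clinical table: ISS stage must be 1, 2 or 3; sample "
                f"{bad.index[0]!r} has {bad.iloc[0]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class Cohort:
    """Aligned expression, clinical and survival data for one study cohort.

    The three components share an identical, identically-ordered sample-id
    set; construction enforces this.
    """

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    labels: list[SurvivalLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [lab.sample_id for lab in self.labels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in survival labels")
        if self.expression.sample_ids != ids or self.clinical.sample_ids != ids:
            raise ValueError(
                "cohort components must share one identically-ordered "
                "sample id set"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [lab.sample_id for lab in self.labels]

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        return np.array([lab.time for lab in self.labels], dtype=float)

    @property
    def statuses(self) -> np.ndarray:
        return np.array([lab.status for lab in self.labels], dtype=int)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Cohort":
        """New cohort restricted to ``indices`` (sample positions), in order."""
        idx = list(indices)
        ids = [self.labels[i].sample_id for i in idx]
        return Cohort(
            name=name or self.name,
            expression=ExpressionMatrix(self.expression.data[ids]),
            clinical=ClinicalTable(self.clinical.data.loc[ids]),
            labels=[self.labels[i] for i in idx],
        )


def _read_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={0: str})


def read_cohort(
    expr_path: str | Path,
    clinical_path: str | Path,
    survival_path: str | Path,
    name: str = "cohort",
) -> Cohort:
    """Read the three cohort tables and align them on a common sample set.

    Sample order follows the survival file. Samples absent from any of the
    three tables are dropped with a warning; an empty intersection is an
    error. Non-numeric or out-of-range ``time``/``status`` values raise,
    naming the offending row.
    """
    expr = _read_tsv(expr_path, "expression")
    expr = expr.set_index(expr.columns[0])
    expr.index.name = "gene_id"
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)

    clin = _read_tsv(clinical_path, "clinical")
    clin["sample_id"] = clin["sample_id"].astype(str)
    clin = clin.set_index("sample_id")

    surv = _read_tsv(survival_path, "survival")
    for col in ("sample_id", "time", "status"):
        if col not in surv.columns:
            raise ValueError(f"survival file missing column {col!r}")
    surv["sample_id"] = surv["sample_id"].astype(str)

    labels: list[SurvivalLabel] = []
    for pos, row in enumerate(surv.itertuples(index=False)):
        try:
            t = float(row.time)
            s = float(row.status)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"survival row {pos} (sample {row.sample_id!r}): "
                f"non-numeric time/status"
            ) from exc
        if s not in (0.0, 1.0):
            raise ValueError(
                f"survival row {pos} (sample {row.sample_id!r}): "
                f"status must be 0 or 1, got {row.status!r}"
            )
        try:
            labels.append(SurvivalLabel(row.sample_id, t, int(s)))
        except ValueError as exc:
            raise ValueError(f"survival row {pos}: {exc}") from exc

    surv_ids = [lab.sample_id for lab in labels]
    common = [
        sid
        for sid in surv_ids
        if sid in set(expr.columns) and sid in set(clin.index)
    ]
    if not common:
        raise ValueError(
            f"cohort {name!r}: no sample id shared by expression, clinical "
            f"and survival tables"
        )
    n_drop = (
        (len(surv_ids) - len(common))
        + (expr.shape[1] - len(common))
        + (len(clin) - len(common))
    )
    if n_drop:
        logger.warning(
            "cohort %s: dropped samples outside the common id set "
            "(%d survival, %d expression, %d clinical kept of "
            "%d/%d/%d)",
            name,
            len(common),
            len(common),
            len(common),
            len(surv_ids),
            expr.shape[1],
            len(clin),
        )

    keep = {lab.sample_id: lab for lab in labels}
    return Cohort(
        name=name,
        expression=ExpressionMatrix(expr[common]),
        clinical=ClinicalTable(clin.loc[common, ["age", "iss"]]),
        labels=[keep[sid] for sid in common],
    )


def intersect_genes(a: Cohort, b: Cohort) -> tuple[Cohort, Cohort]:
    """Restrict both cohorts to their shared gene set, identically ordered.

    Needed for cross-cohort work: different platforms quantify different
    (18,994-24,128-gene) feature sets. Gene order follows cohort ``a``.
    """
    shared = [g for g in a.expression.gene_ids if g in set(b.expression.gene_ids)]
    if not shared:
        raise ValueError(
            f"cohorts {a.name!r} and {b.name!r} share no gene ids"
        )

    def restrict(c: Cohort) -> Cohort:
        return Cohort(
            name=c.name,
            expression=ExpressionMatrix(c.expression.data.loc[shared]),
            clinical=c.clinical,
            labels=list(c.labels),
        )

    return restrict(a), restrict(b)


def write_scores(path: str | Path, ids: Sequence[str], scores: Sequence[float]) -> None:
    """Write a two-column TSV (sample_id, score) at full float precision."""
    ids = list(ids)
    scores = list(scores)
    if len(ids) != len(scores):
        raise ValueError(
            f"ids and scores length mismatch: {len(ids)} vs {len(scores)}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tscore\n")
        for sid, sc in zip(ids, scores):
            fh.write(f"{sid}\t{float(sc)!r}\n")


def read_scores(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV written by :func:`write_scores`; bit-exact round trip."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    return list(df["sample_id"]), df["score"].to_numpy(dtype=float)
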