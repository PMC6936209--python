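import numpy as np
import pandas as pd
import pytest

from guanrank import (
    ClinicalTable,
    Cohort,
    ExpressionMatrix,
    SimParams,
    SurvivalLabel,
    simulate_cohort,
)


@pytest.fixture
def toy_labels():
    """Four-patient worked cohort: events at days 1 and 3, censorings at 2 and 4."""
    return [
        SurvivalLabel("A", 1, 1),
        SurvivalLabel("B", 2, 0),
        SurvivalLabel("C", 3, 1),
        SurvivalLabel("D", 4, 0),
    ]


@pytest.fixture
def small_cohort():
    """Small simulated cohort with missing expression entries."""
    cohort, _ = simulate_cohort(
        SimParams(n_samples=40, n_genes=30, n_informative=5, seed=11,
                  missing_frac=0.05, name="small")
    )
    return cohort


def make_cohort(expr, ages, iss, times, statuses, name="toy"):
    """Build a cohort from plain arrays (expr is genes x samples)."""
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[1]
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(expr.shape[0])]
    return Cohort(
        name=name,
        expression=ExpressionMatrix(
            pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
        ),
        clinical=ClinicalTable(
            pd.DataFrame({"age": ages, "iss": iss},
                         index=pd.Index(samples, name="sample_id"))
        ),
        labels=[SurvivalLabel(s, float(t), int(st))
                for s, t, st in zip(samples, times, statuses)],
    )


def random_labels(rng, n, censor_frac):
    """Random survival labels with integral-day times and a target censoring mix."""
    times = rng.integers(1, max(3 * n, 10), size=n).astype(float)
    statuses = (rng.random(n) >= censor_frac).astype(int)
    return [SurvivalLabel(f"r{i}", times[i], int(statuses[i])) for i in range(n)]
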