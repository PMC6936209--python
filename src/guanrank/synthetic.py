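"""Synthetic myeloma-like cohorts for end-to-end testing.

The real study cohorts are access-restricted, so every pipeline stage
is exercised on simulated cohorts with the same shape: a gene-by-sample
expression matrix (independent standard-normal genes, a small planted
informative subset), age and ISS stage covariates, and right-censored
progression labels.

The generative model is Weibull proportional hazards: patient i's linear
risk is

    eta_i = effect_size * sum_{g informative} x_gi / sqrt(n_informative)
            + 0.3 * z(age_i) + 0.3 * z(iss_i)

and the latent event time is ``T_i = baseline_scale * exp(-eta_i / k) *
E^(1/k)`` with E ~ Exp(1) and k the Weibull shape, so the hazard ratio per
unit eta is exp(eta). Censoring times are independent exponentials whose
rate is calibrated numerically so the expected censored fraction matches
``censoring_rate``. This is test scaffolding: it makes no attempt at
gene-gene correlation or platform effects, but it reproduces the cohort
summary statistics (size, event rate, age distribution, stage mix) of the
four study populations via the shipped presets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_io import ClinicalTable, Cohort, ExpressionMatrix, SurvivalLabel

__all__ = [
    "SimParams",
    "SimTruth",
    "PRESETS",
    "preset_params",
    "simulate_cohort",
    "cohort_profile",
    "write_cohort",
]


@dataclass(frozen=True)
class SimParams:
    """Generative settings for one synthetic cohort.

    ``effect_size`` is the log-hazard carried by one standard deviation of
    the aggregate informative-gene signal; the two clinical covariates
    contribute 0.3 log-hazard per SD each. ``baseline_scale`` (days) sets
    the median event time for an average-risk patient;
    ``censoring_rate`` is the target expected censored fraction.
    ``panel_seed`` fixes which genes are informative, independently of the
    sampling seed, so cohorts simulated with equal gene counts share one
    planted panel.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_informative: int = 20
    effect_size: float = 1.0
    baseline_scale: float = 700.0
    weibull_shape: float = 1.2
    censoring_rate: float = 0.5
    age_mean: float = 60.0
    age_sd: float = 10.0
    iss_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)
    missing_frac: float = 0.01
    seed: int = 0
    panel_seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not 0 < self.n_informative <= self.n_genes:
            raise ValueError("need 0 < n_informative <= n_genes")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.weibull_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if abs(sum(self.iss_probs) - 1.0) > 1e-9 or min(self.iss_probs) < 0:
            raise ValueError("iss_probs must be a probability 3-simplex")


@dataclass
class SimTruth:
    """Ground truth behind a simulated cohort, for recovery tests."""

    informative_gene_ids: list[str]
    true_linear_risk: np.ndarray  # eta per sample
    true_event_time: np.ndarray  # latent (pre-censoring) event days
    true_censoring_time: np.ndarray | None = None  # raw independent draw


# Cohort-profile presets mirroring the four study populations: size, event
# rate, age distribution, ISS stage mix, typical progression timescale and
# platform gene count. ISS fractions renormalized over the reported stages.
def _preset(n, genes, event_pct, age, sd, iss, median_days, name):
    iss = tuple(np.asarray(iss, dtype=float) / np.sum(iss))
    # invert the marginal Weibull median for an average-risk patient
    scale = median_days / np.log(2) ** (1.0 / 1.2)
    return SimParams(
        n_samples=n,
        n_genes=genes,
        censoring_rate=1.0 - event_pct / 100.0,
        age_mean=age,
        age_sd=sd,
        iss_probs=iss,
        baseline_scale=scale,
        name=name,
    )


PRESETS: dict[str, SimParams] = {
    "uams": _preset(559, 20514, 44.54, 57.18, 9.45, (52.6, 26.1, 21.3), 776.73, "uams"),
    "hovon65": _preset(282, 20514, 66.67, 55.07, 7.72, (40.1, 25.2, 28.7), 558.15, "hovon65"),
    "mmrf": _preset(636, 24128, 32.70, 64.09, 10.86, (32.5, 36.2, 28.0), 389.50, "mmrf"),
    "emtab": _preset(147, 18994, 97.99, 66.40, 9.92, (25.5, 30.2, 40.3), 346.18, "emtab"),
}


def preset_params(name: str, **overrides) -> SimParams:
    """A preset's parameters, optionally overridden (e.g. scaled down).

    ``scale`` multiplies the sample count; any other keyword replaces the
    corresponding field. Cross-cohort experiments should override
    ``n_genes`` to a common value so the presets share one informative
    panel.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[name]
    scale = overrides.pop("scale", None)
    if scale is not None:
        params = replace(params, n_samples=max(int(round(params.n_samples * scale)), 10))
    return replace(params, **overrides) if overrides else params


def _gene_ids(n_genes: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n_genes)]


def _calibrate_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate with expected censored fraction ``target``.

    Solves mean_i(1 - exp(-rho * T_i)) = target; the left side is monotone
    in rho, so a bracketing root find suffices.
    """

    def censored_frac(log_rho: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(log_rho) * event_times))) - target

    lo, hi = -30.0, 10.0
    return float(np.exp(brentq(censored_frac, lo, hi, xtol=1e-12)))


def simulate_cohort(params: SimParams) -> tuple[Cohort, SimTruth]:
    """Draw one cohort and its ground truth; reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    panel_rng = np.random.default_rng(params.panel_seed)
    genes = _gene_ids(params.n_genes)
    informative_idx = np.sort(
        panel_rng.choice(params.n_genes, size=params.n_informative, replace=False)
    )

    n = params.n_samples
    sample_ids = [f"{params.name}-S{i + 1:04d}" for i in range(n)]
    expr = rng.standard_normal((params.n_genes, n))

    age = rng.normal(params.age_mean, params.age_sd, size=n)
    age = np.clip(age, 18.0, 100.0)
    iss = rng.choice([1.0, 2.0, 3.0], size=n, p=params.iss_probs)

    gene_signal = expr[informative_idx].sum(axis=0) / np.sqrt(params.n_informative)
    iss_mean = float(np.dot([1, 2, 3], params.iss_probs))
    iss_var = float(np.dot(np.square([1, 2, 3]), params.iss_probs)) - iss_mean**2
    iss_sd = np.sqrt(iss_var) if iss_var > 0 else 1.0
    eta = (
        params.effect_size * gene_signal
        + 0.3 * (age - params.age_mean) / params.age_sd
        + 0.3 * (iss - iss_mean) / iss_sd
    )

    k = params.weibull_shape
    event_time = (
        params.baseline_scale
        * np.exp(-eta / k)
        * rng.exponential(size=n) ** (1.0 / k)
    )
    event_time = np.maximum(event_time, 1e-3)

    if params.censoring_rate > 0:
        rho = _calibrate_censoring_rate(event_time, params.censoring_rate)
        cens_time = rng.exponential(1.0 / rho, size=n)
        cens_time = np.maximum(cens_time, 1e-3)
        observed = np.minimum(event_time, cens_time)
        status = (event_time <= cens_time).astype(int)
    else:
        cens_time = None
        observed = event_time.copy()
        status = np.ones(n, dtype=int)

    if params.missing_frac > 0:
        mask = rng.random(expr.shape) < params.missing_frac
        expr = np.where(mask, np.nan, expr)

    cohort = Cohort(
        name=params.name,
        expression=ExpressionMatrix(
            pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
        ),
        clinical=ClinicalTable(
            pd.DataFrame(
                {"age": age, "iss": iss},
                index=pd.Index(sample_ids, name="sample_id"),
            )
        ),
        labels=[
            SurvivalLabel(sid, float(t), int(s))
            for sid, t, s in zip(sample_ids, observed, status)
        ],
    )
    truth = SimTruth(
        informative_gene_ids=[genes[i] for i in informative_idx],
        true_linear_risk=eta,
        true_event_time=event_time,
        true_censoring_time=cens_time,
    )
    return cohort, truth


def cohort_profile(c: Cohort) -> dict[str, float]:
    """Descriptive summary matching the usual cohort-characteristics table."""
    if c.n_samples == 0:
        raise ValueError("empty cohort")
    t, s = c.times, c.statuses
    age = c.clinical.data["age"].to_numpy(dtype=float)
    iss = c.clinical.data["iss"].to_numpy(dtype=float)
    events = s == 1
    profile = {
        "n_samples": float(c.n_samples),
        "event_pct": 100.0 * float(events.mean()),
        "median_observed_days": float(np.median(t)),
        "median_event_days": float(np.median(t[events])) if events.any() else float("nan"),
        "age_mean": float(np.nanmean(age)),
        "age_sd": float(np.nanstd(age)),
    }
    for stage in (1, 2, 3):
        profile[f"iss_{stage}_pct"] = 100.0 * float(np.nanmean(iss == stage))
    return profile


def write_cohort(cohort: Cohort, out_dir: str | Path, truth: SimTruth | None = None) -> None:
    """Write the three cohort TSVs (and optionally the ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.data.to_csv(out / "expression.tsv", sep="\t")
    clin = cohort.clinical.data.copy()
    clin.to_csv(out / "clinical.tsv", sep="\t", na_rep="NA")
    surv = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "time": [lab.time for lab in cohort.labels],
            "status": [lab.status for lab in cohort.labels],
        }
    )
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    if truth is not None:
        pd.DataFrame(
            {
                "sample_id": cohort.sample_ids,
                "true_linear_risk": truth.true_linear_risk,
                "true_event_time": truth.true_event_time,
            }
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "informative_genes.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\n")
            for g in truth.informative_gene_ids:
                fh.write(g + "\n")
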