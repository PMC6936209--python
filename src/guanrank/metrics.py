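"""Survival model evaluation: concordance and IPCW time-dependent AUC.

Two metrics are provided. Harrell's C-index is the probability, over
comparable patient pairs, that the patient with the earlier event carries
the higher predicted risk. The time-dependent AUC classifies
event-by-time-t cases against still-at-risk controls at each time on a
grid (by default 14, 16, 18, 20 and 22 months), reweighting observations
by the inverse of the censoring distribution's Kaplan-Meier estimate
(cumulative cases / dynamic controls, Uno-type IPCW). The integrated AUC
averages the grid values with weights proportional to 2 * S(t) * f(t),
where S is the event-survival KM curve and f its discrete density over the
grid cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import SurvivalLabel
from .ranking import KMCurve, km_eval, km_survival

logger = logging.getLogger("guanrank")

__all__ = [
    "DAYS_PER_MONTH",
    "DEFAULT_GRID_MONTHS",
    "AUCGrid",
    "EvaluationReport",
    "concordance_index",
    "censoring_km",
    "auc_at_time",
    "integrated_auc",
    "evaluate",
]

DAYS_PER_MONTH = 30.44
DEFAULT_GRID_MONTHS = (14.0, 16.0, 18.0, 20.0, 22.0)


def _risk_times_status(
    risk: Sequence[float], labels: Sequence[SurvivalLabel]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(labels):
        raise ValueError(
            f"risk vector length {len(risk)} != label count {len(labels)}"
        )
    t = np.array([lab.time for lab in labels], dtype=float)
    s = np.array([lab.status for lab in labels], dtype=int)
    return risk, t, s


def concordance_index(
    risk: Sequence[float], labels: Sequence[SurvivalLabel]
) -> float:
    """Harrell's concordance index of a risk score against censored labels.

    A pair is comparable when the shorter observed time belongs to an
    event; at tied observed times only event-vs-censored pairs are
    comparable (the event patient must be the riskier one). Tied risk
    scores count half. Higher risk is read as earlier expected
    progression.
    """
    risk, t, s = _risk_times_status(risk, labels)
    if len(risk) < 2:
        raise ValueError("need at least two labels")
    n = len(risk)
    # rows i = the (event) patient with the shorter observed time; ordered
    # pairs, so tied-time double-event pairs are never counted and tied-time
    # event/censored pairs are counted once, from the event side
    event_i = (s == 1)[:, None]
    earlier = t[:, None] < t[None, :]
    tied_vs_censored = (t[:, None] == t[None, :]) & (s[None, :] == 0)
    comparable = event_i & (earlier | tied_vs_censored) & ~np.eye(n, dtype=bool)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (no events, or all tied)")
    wins = (risk[:, None] > risk[None, :]) + 0.5 * (risk[:, None] == risk[None, :])
    return float(wins[comparable].sum() / n_comp)


def censoring_km(labels: Sequence[SurvivalLabel]) -> KMCurve:
    """KM estimate of the censoring distribution (statuses flipped)."""
    flipped = [
        SurvivalLabel(lab.sample_id, lab.time, 1 - lab.status) for lab in labels
    ]
    return km_survival(flipped)


def _km_left_eval(curve: KMCurve, t: np.ndarray, floor: bool = True) -> np.ndarray:
    """Left limit S(t-): the curve value just before the step at t."""
    idx = np.searchsorted(curve.times, np.asarray(t, dtype=float), side="left")
    padded = np.concatenate([[1.0], curve.surv])
    out = padded[idx]
    if floor:
        out = np.maximum(out, curve.floor)
    return out


def auc_at_time(
    risk: Sequence[float],
    labels: Sequence[SurvivalLabel],
    t: float,
    G: KMCurve | None = None,
) -> float:
    """IPCW cumulative/dynamic AUC at horizon ``t``.

    Cases are patients with an observed event by t, weighted 1/G(T_i-);
    controls are patients still under observation beyond t, weighted
    1/G(t); G is the censoring distribution's KM curve (floored at its
    smallest positive step). Returns NaN when the horizon admits no case
    or no control.
    """
    risk, times, status = _risk_times_status(risk, labels)
    if G is None:
        G = censoring_km(labels)
    case = (status == 1) & (times <= t)
    control = times > t
    if not case.any() or not control.any():
        return float("nan")
    w_case = 1.0 / _km_left_eval(G, times[case])
    g_t = max(float(km_eval(G, float(t), floor=True)), G.floor)
    w_control = np.full(int(control.sum()), 1.0 / g_t)

    r_case = risk[case][:, None]
    r_ctrl = risk[control][None, :]
    wins = (r_case > r_ctrl) + 0.5 * (r_case == r_ctrl)
    w = w_case[:, None] * w_control[None, :]
    return float((w * wins).sum() / (w_case.sum() * w_control.sum()))


@dataclass
class AUCGrid:
    """Time-dependent AUC over a horizon grid and its weighted integral.

    Only usable grid points (those with at least one case and one control)
    are retained; ``weights`` renormalizes 2 * S(t) * f(t) over them and
    sums to 1.
    """

    eval_times: np.ndarray  # days
    auc: np.ndarray
    weights: np.ndarray
    integrated: float
    dropped_times: np.ndarray = field(default_factory=lambda: np.array([]))


def _survival_density_weights(
    surv_curve: KMCurve, grid_days: np.ndarray
) -> np.ndarray:
    """Unnormalized 2 * S(t_k) * f(t_k) weights over the grid.

    f is discretized as the KM survival mass falling in the cell around
    each grid point; cell edges sit at the midpoints between consecutive
    grid points, extended outward by half the adjacent spacing at the two
    ends (never below 0).
    """
    g = np.asarray(grid_days, dtype=float)
    if len(g) == 1:
        return np.array([1.0])
    mid = (g[:-1] + g[1:]) / 2.0
    lo = max(g[0] - (g[1] - g[0]) / 2.0, 1e-9)
    hi = g[-1] + (g[-1] - g[-2]) / 2.0
    edges = np.concatenate([[lo], mid, [hi]])
    s_edges = np.asarray(km_eval(surv_curve, edges))
    f = s_edges[:-1] - s_edges[1:]
    s_grid = np.asarray(km_eval(surv_curve, g))
    return 2.0 * s_grid * f


def integrated_auc(
    risk: Sequence[float],
    labels: Sequence[SurvivalLabel],
    eval_times_months: Sequence[float] = DEFAULT_GRID_MONTHS,
    days_per_month: float = DAYS_PER_MONTH,
) -> AUCGrid:
    """Time-dependent AUC on a month grid, integrated with 2*S(t)*f(t) weights.

    Grid points where the AUC is undefined (no case or no control) are
    dropped with a warning and the weights renormalized over the rest. If
    the survival-density weights vanish on every usable point (no event
    mass in the grid's span) the average falls back to uniform weights.
    """
    grid_days = np.asarray(eval_times_months, dtype=float) * days_per_month
    if len(grid_days) < 1:
        raise ValueError("empty evaluation grid")
    G = censoring_km(labels)
    auc = np.array([auc_at_time(risk, labels, t, G) for t in grid_days])
    usable = ~np.isnan(auc)
    if not usable.any():
        raise ValueError(
            "time-dependent AUC undefined at every grid point "
            "(no cases or no controls)"
        )
    if (~usable).any():
        logger.warning(
            "integrated_auc: dropping %d grid point(s) with no cases or "
            "no controls",
            int((~usable).sum()),
        )
    surv_curve = km_survival(labels)
    w = _survival_density_weights(surv_curve, grid_days)[usable]
    if w.sum() <= 0:
        logger.warning(
            "integrated_auc: no event mass over the grid; using uniform weights"
        )
        w = np.ones(int(usable.sum()))
    w = w / w.sum()
    kept_auc = auc[usable]
    return AUCGrid(
        eval_times=grid_days[usable],
        auc=kept_auc,
        weights=w,
        integrated=float((w * kept_auc).sum()),
        dropped_times=grid_days[~usable],
    )


@dataclass
class EvaluationReport:
    """Bundle of C-index and integrated AUC for one prediction vector."""

    c_index: float
    auc_grid: AUCGrid

    @property
    def integrated_auc(self) -> float:
        return self.auc_grid.integrated

    def to_flat_dict(self) -> dict[str, float]:
        out = {
            "c_index": self.c_index,
            "integrated_auc": self.auc_grid.integrated,
        }
        for t, a in zip(self.auc_grid.eval_times, self.auc_grid.auc):
            out[f"auc_day_{t:g}"] = a
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for key, val in self.to_flat_dict().items():
                fh.write(f"{key}\t{val!r}\n")


def evaluate(
    risk: Sequence[float],
    labels: Sequence[SurvivalLabel],
    eval_times_months: Sequence[float] = DEFAULT_GRID_MONTHS,
    days_per_month: float = DAYS_PER_MONTH,
) -> EvaluationReport:
    """C-index plus integrated time-dependent AUC for one risk vector."""
    return EvaluationReport(
        c_index=concordance_index(risk, labels),
        auc_grid=integrated_auc(risk, labels, eval_times_months, days_per_month),
    )
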