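"""Linear panel regression: fixed-effects (within) and between-effects estimators.

The fixed-effects model is

    Y_it = alpha_i + beta' x_it + (gamma_t) + e_it

where ``alpha_i`` are entity effects absorbed by within-entity demeaning,
``x_it`` are exposure-status dummies (reference: not_viewed) and the optional
``gamma_t`` are a full set of calendar-month dummies adjusting for secular
national trends. Coefficients are identical to explicit entity-dummy least
squares; standard errors are conventional homoskedastic with the residual
degrees of freedom reduced by the number of absorbed entity effects.
Cluster-robust-by-entity errors are available behind a flag.

The between-effects model regresses entity-mean outcomes on an
entity-constant category variable by ordinary least squares — it measures
cross-entity differences, discarding variation over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exposure import CATEGORY_LEVELS, STATUS_LEVELS


@dataclass(frozen=True)
class EffectEstimate:
    """One regression coefficient with its 95% confidence interval."""

    term: str
    coefficient: float
    ci_low: float
    ci_high: float
    se: float
    n_entities: int
    n_obs: int


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "coef": e.coefficient,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "se": e.se,
                "n_entities": e.n_entities,
                "n_obs": e.n_obs,
            }
            for e in estimates
        ]
    )


def _validate_panel(panel: pd.DataFrame, outcome: str) -> None:
    for col in ("entity", "month", outcome):
        if col not in panel.columns:
            raise ValueError(f"panel is missing column {col!r}")
    if panel.duplicated(["entity", "month"]).any():
        raise ValueError("panel has duplicate (entity, month) rows")


def _design(panel: pd.DataFrame, adjust_month: bool) -> tuple[np.ndarray, list[str]]:
    """Exposure-status dummies (reference not_viewed) plus optional month dummies."""
    cols: list[str] = []
    arrays: list[np.ndarray] = []
    for level in STATUS_LEVELS[1:]:
        d = (panel["status"] == level).to_numpy(float)
        if d.any():
            arrays.append(d)
            cols.append(level)
    if not cols:
        raise ValueError("no exposed entity-months: nothing to estimate")
    if adjust_month:
        months = sorted(panel["month"].unique())
        for m in months[1:]:  # first month is the reference
            arrays.append((panel["month"] == m).to_numpy(float))
            cols.append(f"month[{m}]")
    return np.column_stack(arrays), cols


def _demean_by(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract group means (one- or two-dimensional values)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if values.ndim == 1:
        sums = np.bincount(codes, weights=values, minlength=n_groups)
        return values - (sums / counts)[codes]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        sums = np.bincount(codes, weights=values[:, j], minlength=n_groups)
        out[:, j] = values[:, j] - (sums / counts)[codes]
    return out


def _check_rank(x: np.ndarray, cols: list[str]) -> None:
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        dropped = [cols[i] for i in piv[rank:]]
        raise ValueError(
            f"collinear design after demeaning; involved column(s): {dropped}"
        )


def fit_fixed_effects(
    panel: pd.DataFrame,
    adjust_month: bool = False,
    outcome: str = "outcome",
    cluster: bool = False,
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Within (fixed-effects) estimator of the exposure-status effects.

    Parameters
    ----------
    panel
        Long table with columns ``entity``, ``month``, ``status`` and the
        outcome column. Unbalanced panels are fine; each entity contributes
        its observed months.
    adjust_month
        Add a full set of calendar-month dummies (reference: first month).
    cluster
        Use cluster-robust-by-entity standard errors instead of conventional
        homoskedastic ones.

    Returns estimates for the exposure terms only (month dummies are
    nuisance parameters).
    """
    _validate_panel(panel, outcome)
    panel = panel.sort_values(["entity", "month"]).reset_index(drop=True)
    entities, codes = np.unique(panel["entity"].to_numpy(), return_inverse=True)
    n_entities = len(entities)
    n_months = panel["month"].nunique()
    if n_entities < 2 or n_months < 2:
        raise ValueError("need at least 2 entities and 2 months")

    x, cols = _design(panel, adjust_month)
    y = panel[outcome].to_numpy(float)
    xd = _demean_by(x, codes, n_entities)
    yd = _demean_by(y, codes, n_entities)
    _check_rank(xd, cols)

    k = xd.shape[1]
    n = len(yd)
    dof = n - n_entities - k
    if dof <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({dof})")
    xtx = xd.T @ xd
    beta = np.linalg.solve(xtx, xd.T @ yd)
    resid = yd - xd @ beta
    xtx_inv = np.linalg.inv(xtx)
    if cluster:
        meat = np.zeros((k, k))
        for g in range(n_entities):
            idx = codes == g
            xu = xd[idx].T @ resid[idx]
            meat += np.outer(xu, xu)
        g_ = n_entities
        correction = (g_ / (g_ - 1)) * ((n - 1) / dof)
        cov = correction * xtx_inv @ meat @ xtx_inv
        t_df = g_ - 1
    else:
        sigma2 = resid @ resid / dof
        cov = sigma2 * xtx_inv
        t_df = dof
    se = np.sqrt(np.diag(cov))
    crit = stats.t.ppf(1 - alpha / 2, t_df)

    estimates = []
    for j, name in enumerate(cols):
        if name.startswith("month["):
            continue
        estimates.append(
            EffectEstimate(
                term=name,
                coefficient=float(beta[j]),
                ci_low=float(beta[j] - crit * se[j]),
                ci_high=float(beta[j] + crit * se[j]),
                se=float(se[j]),
                n_entities=n_entities,
                n_obs=n,
            )
        )
    return estimates


def fit_between_effects(
    panel: pd.DataFrame,
    category: str = "category",
    outcome: str = "outcome",
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Between-effects estimator: OLS of entity-mean outcome on category dummies.

    The category must be constant within entity. The reference level is
    ``zero`` when populated, otherwise the lowest populated category in the
    order zero < t1 < t2 < t3 (other category labels sort lexicographically).
    """
    _validate_panel(panel, outcome)
    if category not in panel.columns:
        raise ValueError(f"panel is missing column {category!r}")
    per_entity = panel.groupby("entity").agg(
        mean_outcome=(outcome, "mean"), n_cat=(category, "nunique"), cat=(category, "first")
    )
    if (per_entity["n_cat"] > 1).any():
        bad = list(per_entity.index[per_entity["n_cat"] > 1])
        raise ValueError(f"category varies within entity for: {bad[:10]}")
    levels_present = list(per_entity["cat"].unique())
    known_order = [c for c in CATEGORY_LEVELS if c in levels_present]
    extra = sorted(set(levels_present) - set(CATEGORY_LEVELS))
    order = known_order + extra
    if len(order) < 2:
        raise ValueError("need at least 2 populated categories")
    reference, contrasts = order[0], order[1:]

    y = per_entity["mean_outcome"].to_numpy(float)
    x = np.column_stack(
        [np.ones(len(per_entity))]
        + [(per_entity["cat"] == c).to_numpy(float) for c in contrasts]
    )
    n, k = x.shape
    dof = n - k
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    if dof > 0:
        sigma2 = resid @ resid / dof
        se = np.sqrt(np.diag(sigma2 * xtx_inv))
        crit = stats.t.ppf(1 - alpha / 2, dof)
    else:
        # saturated fit: coefficients are exact contrasts of category means,
        # but there is no residual information for an interval
        se = np.full(k, np.nan)
        crit = np.inf

    n_obs = len(panel)
    return [
        EffectEstimate(
            term=c,
            coefficient=float(beta[j + 1]),
            ci_low=float(beta[j + 1] - crit * se[j + 1]),
            ci_high=float(beta[j + 1] + crit * se[j + 1]),
            se=float(se[j + 1]),
            n_entities=n,
            n_obs=n_obs,
        )
        for j, c in enumerate(contrasts)
    ]


def summarize_periods(panel: pd.DataFrame, outcome: str = "outcome") -> pd.DataFrame:
    """Pooled mean and sample SD of the outcome at each exposure status.

    SD uses ddof=1 and is NaN for a single observation. Empty levels are
    omitted. Columns: status, mean, sd, n_obs.
    """
    _validate_panel(panel, outcome)
    out = (
        panel.groupby("status")[outcome]
        .agg(mean="mean", sd="std", n_obs="count")
        .reindex([s for s in STATUS_LEVELS if s in set(panel["status"])])
        .reset_index()
    )
    return out
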