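"""End-to-end impact analysis: outcomes × exposure × panel models.

Reproduces the structure of a before/after and between-organization
evaluation of a prescribing-feedback service: per-outcome launch dates, a
3-month pre-launch baseline, three-level exposure timelines, fixed-effects
models with and without calendar-month adjustment, between-effects baseline
comparisons by view category, and the savings arithmetic (realized totals,
national extrapolation, achievable fraction, exposure counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exposure as exp_mod
from . import io, lowpriority, measures, panel, ppu

OUTCOMES = ("summary", "ppu", "low_priority")

# Feature launch dates of the original service; the summary measures ran from
# the service's launch, the price-per-unit and low-priority tools came later.
DEFAULT_LAUNCH_MONTHS = {
    "summary": "2015-12",
    "ppu": "2017-08",
    "low_priority": "2017-09",
}


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-level settings: launch dates, window, centile, exclusions."""

    level: str = "practice"                      # "practice" or "group"
    centile: float = 10.0
    launch_months: dict = field(default_factory=lambda: dict(DEFAULT_LAUNCH_MONTHS))
    end_month: str = "2017-11"
    baseline_months: int = 3
    min_list_size: int = 1000
    achievable_factor: float = 0.5

    def __post_init__(self):
        if self.level not in ("practice", "group"):
            raise ValueError("level must be 'practice' or 'group'")
        for outcome, launch in self.launch_months.items():
            if io.shift_month(launch, -self.baseline_months) >= self.end_month:
                raise ValueError(f"baseline window for {outcome!r} starts after end_month")

    @classmethod
    def for_simulation(cls, sim_config, level: str = "practice", **overrides):
        """Launch all features at the simulation's first possible view month."""
        months = sim_config.months()
        launch = months[sim_config.view_start_month]
        return cls(
            level=level,
            launch_months={o: launch for o in OUTCOMES},
            end_month=months[-1],
            **overrides,
        )


def prepare_level(prescribing, list_sizes, pageviews, config: StudyConfig):
    """Apply the small-list exclusion, then aggregate to the analysis level.

    Returns (records, list_sizes, pageviews) at the requested level; the
    page-view log is filtered to the matching org kind.
    """
    records = io.exclude_small_practices(
        prescribing, list_sizes, threshold=config.min_list_size
    )
    if config.level == "group":
        mapping = records[["org_id", "group_id"]].drop_duplicates()
        kept = list_sizes[list_sizes["org_id"].isin(mapping["org_id"])]
        records = io.aggregate_to_group(records)
        lsz = io.aggregate_list_sizes(kept, mapping)
        views = pageviews[pageviews["org_kind"] == "group"].reset_index(drop=True)
    else:
        lsz = list_sizes[list_sizes["org_id"].isin(records["org_id"].unique())]
        lsz = lsz.reset_index(drop=True)
        views = pageviews[pageviews["org_kind"] == "practice"].reset_index(drop=True)
    return records, lsz, views


def compute_outcome(
    outcome_name: str,
    records: pd.DataFrame,
    list_sizes: pd.DataFrame,
    config: StudyConfig,
    measure_defs=None,
    lp_patterns=None,
) -> pd.DataFrame:
    """Per org-month values of one outcome (columns org_id, month, value)."""
    if outcome_name == "ppu":
        return ppu.ppu_pipeline(records, list_sizes, centile=config.centile)
    if outcome_name == "low_priority":
        if lp_patterns is None:
            raise ValueError("low_priority outcome needs a product list")
        return lowpriority.low_priority_spend(records, lp_patterns, list_sizes)
    if outcome_name == "summary":
        if measure_defs is None:
            raise ValueError("summary outcome needs measure definitions")
        return measures.mean_measure_score(measures.measure_scores(records, measure_defs))
    raise ValueError(f"unknown outcome {outcome_name!r}")


def _analysis_window(config: StudyConfig, outcome_name: str, data_months) -> list[str]:
    launch = config.launch_months[outcome_name]
    start = io.shift_month(launch, -config.baseline_months)
    available = set(data_months)
    return [m for m in io.month_span(start, config.end_month) if m in available]


def build_panel(outcome_df: pd.DataFrame, timeline: pd.DataFrame) -> pd.DataFrame:
    """Merge outcome values with exposure status into a model-ready panel."""
    merged = outcome_df.merge(timeline, on=["org_id", "month"], how="inner")
    return merged.rename(columns={"org_id": "entity", "value": "outcome"})[
        ["entity", "month", "outcome", "status"]
    ]


def run_before_after(
    prescribing,
    list_sizes,
    pageviews,
    outcome_name: str,
    config: StudyConfig,
    measure_defs=None,
    lp_patterns=None,
) -> dict:
    """Fixed-effects before/after analysis of one outcome.

    Returns a dict with the layout of the before/after results tables:
    ``table`` (one row per exposure level: Mean (SD), univariable and
    month-adjusted Change with 95% CI), the underlying ``panel``,
    ``timeline`` and the raw estimate lists.
    """
    records, lsz, views = prepare_level(prescribing, list_sizes, pageviews, config)
    window = _analysis_window(config, outcome_name, records["month"].unique())
    records = records[records["month"].isin(window)].reset_index(drop=True)
    outcome_df = compute_outcome(outcome_name, records, lsz, config,
                                 measure_defs, lp_patterns)
    universe = sorted(records["org_id"].unique())
    monthly = exp_mod.feature_views(views, outcome_name)
    timeline = exp_mod.code_timeline(monthly, window, orgs=universe)
    pdl = build_panel(outcome_df, timeline)
    uni = panel.fit_fixed_effects(pdl, adjust_month=False)
    adj = panel.fit_fixed_effects(pdl, adjust_month=True)
    summary = panel.summarize_periods(pdl)

    uni_d = {e.term: e for e in uni}
    adj_d = {e.term: e for e in adj}
    rows = []
    for _, srow in summary.iterrows():
        status = srow["status"]
        u, a = uni_d.get(status), adj_d.get(status)
        rows.append(
            {
                "status": status,
                "mean": srow["mean"],
                "sd": srow["sd"],
                "n_obs": srow["n_obs"],
                "coef_univariable": u.coefficient if u else np.nan,
                "ci_low_univariable": u.ci_low if u else np.nan,
                "ci_high_univariable": u.ci_high if u else np.nan,
                "coef_adjusted": a.coefficient if a else np.nan,
                "ci_low_adjusted": a.ci_low if a else np.nan,
                "ci_high_adjusted": a.ci_high if a else np.nan,
            }
        )
    return {
        "outcome": outcome_name,
        "table": pd.DataFrame(rows),
        "panel": pdl,
        "timeline": timeline,
        "univariable": uni,
        "adjusted": adj,
        "list_sizes": lsz,
        "records": records,
    }


def run_between(
    prescribing,
    list_sizes,
    pageviews,
    outcome_name: str,
    config: StudyConfig,
    measure_defs=None,
    lp_patterns=None,
) -> dict:
    """Between-effects baseline comparison of one outcome by view category.

    The outcome is averaged over the baseline window (the months before the
    feature launch); organizations are categorized by total views over the
    full analysis window.
    """
    records, lsz, views = prepare_level(prescribing, list_sizes, pageviews, config)
    window = _analysis_window(config, outcome_name, records["month"].unique())
    launch = config.launch_months[outcome_name]
    baseline = [m for m in window if m < launch]
    if not baseline:
        raise ValueError(f"no baseline months before launch {launch} in the data")
    base_records = records[records["month"].isin(baseline)].reset_index(drop=True)
    outcome_df = compute_outcome(outcome_name, base_records, lsz, config,
                                 measure_defs, lp_patterns)
    universe = sorted(records["org_id"].unique())
    monthly = exp_mod.feature_views(views, outcome_name)
    totals = exp_mod.total_views(monthly, window, orgs=universe)
    categories = exp_mod.view_categories(totals)
    pdl = (
        outcome_df.merge(categories, on="org_id", how="inner")
        .rename(columns={"org_id": "entity", "value": "outcome"})
    )[["entity", "month", "outcome", "category", "total_views"]]
    estimates = panel.fit_between_effects(pdl)

    per_entity = pdl.groupby(["entity", "category"], as_index=False)["outcome"].mean()
    est_d = {e.term: e for e in estimates}
    n_total = per_entity["entity"].nunique()
    rows = []
    for cat in [c for c in exp_mod.CATEGORY_LEVELS if c in set(per_entity["category"])]:
        sub = per_entity.loc[per_entity["category"] == cat, "outcome"]
        e = est_d.get(cat)
        rows.append(
            {
                "category": cat,
                "n": len(sub),
                "pct": round(100.0 * len(sub) / n_total,
                             1 if config.level == "group" else 2),
                "mean": sub.mean(),
                "sd": sub.std(),
                "coef": e.coefficient if e else np.nan,
                "ci_low": e.ci_low if e else np.nan,
                "ci_high": e.ci_high if e else np.nan,
            }
        )
    return {
        "outcome": outcome_name,
        "table": pd.DataFrame(rows),
        "panel": pdl,
        "categories": categories,
        "estimates": estimates,
    }


EXPOSED_STATUSES = ("month_first_viewed", "after_first_view")


def realized_savings(
    estimate: panel.EffectEstimate,
    timeline: pd.DataFrame,
    list_sizes: pd.DataFrame,
    statuses=EXPOSED_STATUSES,
) -> dict:
    """Total realized saving: |change per 1,000| × population of exposed months.

    A negative change in available savings is money saved, so the point
    estimate's absolute value is scaled by each exposed entity-month's list
    size; the CI endpoints are transformed identically (and reported
    low-to-high on the savings scale).
    """
    exposed = timeline[timeline["status"].isin(statuses)]
    merged = exposed.merge(list_sizes, on=["org_id", "month"], how="left")
    if merged["list_size"].isna().any():
        pairs = merged.loc[merged["list_size"].isna(), ["org_id", "month"]]
        raise ValueError(
            f"missing list size for exposed org-month(s): "
            f"{sorted(set(map(tuple, pairs.itertuples(index=False))))[:10]}"
        )
    scale = merged["list_size"].sum() / 1000.0
    endpoints = sorted([abs(estimate.ci_low) * scale, abs(estimate.ci_high) * scale])
    return {
        "total": abs(estimate.coefficient) * scale,
        "ci_low": endpoints[0],
        "ci_high": endpoints[1],
        "n_exposed_entity_months": len(merged),
    }


def extrapolate_national(
    estimate: panel.EffectEstimate,
    all_org_list_sizes: pd.DataFrame,
    months_per_year: int = 12,
) -> float:
    """Annual saving if every organization realized the per-1,000 change.

    Uses each organization's mean list size over the data.
    """
    per_org = all_org_list_sizes.groupby("org_id")["list_size"].mean()
    return abs(estimate.coefficient) * per_org.sum() / 1000.0 * months_per_year


def achievable_fraction(
    realized: float, available: float, achievable_factor: float = 0.5
) -> float:
    """Percent of plausibly-achievable savings actually realized.

    Roughly half of the algorithm's available savings are considered
    achievable in practice, so the fraction is 100 × realized /
    (achievable_factor × available).
    """
    if available <= 0:
        raise ValueError(f"available savings must be positive, got {available}")
    return 100.0 * realized / (achievable_factor * available)


def available_savings_total(
    records: pd.DataFrame,
    timeline: pd.DataFrame,
    centile: float = 10.0,
    statuses=EXPOSED_STATUSES,
) -> float:
    """Total available saving (GBP) summed over exposed entity-months."""
    prices = ppu.compute_unit_prices(records)
    refs = ppu.reference_prices(prices, centile=centile)
    savings = ppu.available_savings(prices, refs)
    exposed = timeline[timeline["status"].isin(statuses)][["org_id", "month"]]
    merged = savings.merge(exposed, on=["org_id", "month"], how="inner")
    return float(merged["available_saving"].sum())


def exposure_summary(
    timelines: dict[str, pd.DataFrame], n_universe: int, level: str = "practice"
) -> pd.DataFrame:
    """Counts and percentages of organizations ever exposed, per outcome.

    Percentages are rounded to 1 decimal place at group level and 2 at
    practice level, matching reporting convention.
    """
    decimals = 1 if level == "group" else 2
    rows = []
    for outcome_name, timeline in timelines.items():
        exposed = timeline.loc[
            timeline["status"] != "not_viewed", "org_id"
        ].nunique()
        rows.append(
            {
                "outcome": outcome_name,
                "n_exposed": exposed,
                "n_universe": n_universe,
                "pct": round(100.0 * exposed / n_universe, decimals) if n_universe else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    prescribing,
    list_sizes,
    pageviews,
    config: StudyConfig,
    measure_defs,
    lp_patterns,
    outcomes=OUTCOMES,
) -> dict:
    """Full report: before/after and between tables per outcome + savings block."""
    before_after = {}
    between = {}
    for outcome_name in outcomes:
        before_after[outcome_name] = run_before_after(
            prescribing, list_sizes, pageviews, outcome_name, config,
            measure_defs, lp_patterns,
        )
        between[outcome_name] = run_between(
            prescribing, list_sizes, pageviews, outcome_name, config,
            measure_defs, lp_patterns,
        )

    report = {"before_after": before_after, "between": between}
    if "ppu" in before_after:
        res = before_after["ppu"]
        adj = {e.term: e for e in res["adjusted"]}
        est = adj.get("after_first_view")
        if est is not None:
            realized = realized_savings(est, res["timeline"], res["list_sizes"])
            available = available_savings_total(
                res["records"], res["timeline"], centile=config.centile
            )
            report["savings"] = {
                "realized": realized,
                "available_total": available,
                "achievable_fraction_pct": (
                    achievable_fraction(realized["total"], available,
                                        config.achievable_factor)
                    if available > 0 else float("nan")
                ),
                "national_annual_extrapolation": extrapolate_national(
                    est, res["list_sizes"]
                ),
            }
    universe = {
        name: res["timeline"]["org_id"].nunique()
        for name, res in before_after.items()
    }
    n_universe = max(universe.values()) if universe else 0
    report["exposure_summary"] = exposure_summary(
        {name: res["timeline"] for name, res in before_after.items()},
        n_universe,
        level=config.level,
    )
    return report
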