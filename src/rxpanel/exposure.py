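"""Exposure coding from monthly page-view logs.

Two exposure variables are derived from the view log. The three-level
timeline classifies each organization-month as ``not_viewed``,
``month_first_viewed`` (the first month with more than one view — at least
two views in the same calendar month, so one-off visits do not count), or
``after_first_view`` (every later month to the end of follow-up). The
view-count categories split organizations into zero-view plus tertiles of
total views among those viewed.

For the price-per-unit and low-priority outcomes the exposure is restricted
to views of the corresponding feature pages; the summary (measure-score)
outcome uses all page views for the organization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FEATURES

STATUS_LEVELS = ("not_viewed", "month_first_viewed", "after_first_view")
CATEGORY_LEVELS = ("zero", "t1", "t2", "t3")

FIRST_VIEW_MIN_VIEWS = 2  # ">1 view" within a single calendar month


def feature_views(pageviews: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Monthly view counts per org for one feature.

    ``feature="summary"`` counts all page views for the organization
    (the site-wide exposure used for the measure-score outcome); other
    features count only their own pages.
    Columns: org_id, month, views.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    rows = pageviews if feature == "summary" else pageviews[pageviews["feature"] == feature]
    out = (
        rows.groupby(["org_id", "month"], as_index=False)["views"]
        .sum()
        .sort_values(["org_id", "month"], ignore_index=True)
    )
    return out


def code_timeline(
    monthly_views: pd.DataFrame,
    months: list[str],
    orgs: list[str] | None = None,
) -> pd.DataFrame:
    """Three-level exposure status per org-month over the analysis window.

    The first month in ``months`` with at least two views marks
    ``month_first_viewed``; all later months are ``after_first_view``; all
    earlier months (and every month for never-qualifying orgs) are
    ``not_viewed``. Single-view months never trigger exposure. Views outside
    ``months`` are ignored.
    """
    if orgs is None:
        orgs = sorted(monthly_views["org_id"].unique())
    months = list(months)
    order = {m: i for i, m in enumerate(months)}
    in_window = monthly_views[monthly_views["month"].isin(order)]
    qualifying = in_window[in_window["views"] >= FIRST_VIEW_MIN_VIEWS]
    first = qualifying.groupby("org_id")["month"].min()

    n = len(months)
    frames = []
    for org in orgs:
        status = np.full(n, "not_viewed", dtype=object)
        if org in first.index:
            i = order[first.loc[org]]
            status[i] = "month_first_viewed"
            status[i + 1 :] = "after_first_view"
        frames.append(
            pd.DataFrame({"org_id": org, "month": months, "status": status})
        )
    return pd.concat(frames, ignore_index=True)


def total_views(monthly_views: pd.DataFrame, months: list[str],
                orgs: list[str] | None = None) -> pd.Series:
    """Total views per org over the window (orgs with no rows count 0)."""
    in_window = monthly_views[monthly_views["month"].isin(set(months))]
    totals = in_window.groupby("org_id")["views"].sum()
    if orgs is not None:
        totals = totals.reindex(sorted(orgs), fill_value=0)
    return totals.astype(int)


def view_categories(totals: pd.Series) -> pd.DataFrame:
    """Zero-view category plus tertiles of total views among viewed orgs.

    Boundaries are the 1/3 and 2/3 empirical quantiles of viewed orgs' totals;
    orgs tied at a boundary go to the lower category.
    Columns: org_id, total_views, category.
    """
    out = pd.DataFrame(
        {"org_id": totals.index.astype(str), "total_views": totals.to_numpy()}
    )
    viewed = out["total_views"] > 0
    category = np.full(len(out), "zero", dtype=object)
    if viewed.any():
        v = out.loc[viewed, "total_views"].to_numpy()
        q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
        cat = np.where(v <= q1, "t1", np.where(v <= q2, "t2", "t3"))
        category[viewed.to_numpy()] = cat
    out["category"] = category
    return out.sort_values("org_id", ignore_index=True)
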