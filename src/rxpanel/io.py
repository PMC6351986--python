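"""Tabular schemas and readers for prescribing records, list sizes and page views.

All tables are plain :class:`pandas.DataFrame` objects with documented columns.
Months are ISO ``"YYYY-MM"`` strings throughout, which sort lexicographically
in calendar order.

Columns
-------
prescribing : org_id, group_id, month, product_id, dose_id, quantity, actual_cost
    One row per organization-month-product-dose after canonical aggregation.
list sizes : org_id, month, list_size
    Registered patients per organization-month.
page views : org_kind, org_id, month, feature, views
    Monthly page-view counts per organization and site feature.
"""

from __future__ import annotations

import re

import pandas as pd

PRESCRIBING_COLUMNS = [
    "org_id", "group_id", "month", "product_id", "dose_id", "quantity", "actual_cost",
]
PRESCRIBING_KEY = ["org_id", "group_id", "month", "product_id", "dose_id"]
LISTSIZE_COLUMNS = ["org_id", "month", "list_size"]
PAGEVIEW_COLUMNS = ["org_kind", "org_id", "month", "feature", "views"]

FEATURES = ("summary", "ppu", "low_priority")
ORG_KINDS = ("practice", "group")

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


def shift_month(month: str, k: int) -> str:
    """Return the month ``k`` calendar months after ``month`` (negative = before)."""
    return str(pd.Period(month, freq="M") + k)


def month_range(start: str, n_months: int) -> list[str]:
    """``n_months`` consecutive months starting at ``start``."""
    return [str(p) for p in pd.period_range(start, periods=n_months, freq="M")]


def month_span(start: str, end: str) -> list[str]:
    """All months from ``start`` to ``end`` inclusive."""
    return [str(p) for p in pd.period_range(start, end, freq="M")]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def _check_months(df: pd.DataFrame, what: str) -> None:
    bad = df.index[~df["month"].astype(str).str.match(_MONTH_RE)]
    if len(bad):
        raise ValueError(
            f"{what}: unparseable month (expected YYYY-MM) in row(s) {list(bad[:10])}"
        )


def _check_nonnegative(df: pd.DataFrame, column: str, what: str) -> None:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[values.isna() | (values < 0)]
    if len(bad):
        raise ValueError(f"{what}: negative or non-numeric {column} in row(s) {list(bad[:10])}")


def canonicalize_prescribing(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically aggregate a raw prescribing table.

    Rows sharing the (org, group, month, product, dose) key are summed —
    raw extracts legitimately split rows. Each org must map to exactly one
    group.
    """
    _check_columns(df, PRESCRIBING_COLUMNS, "prescribing")
    df = df[PRESCRIBING_COLUMNS].copy()
    for c in ("org_id", "group_id", "month", "product_id", "dose_id"):
        df[c] = df[c].astype(str)
    _check_months(df, "prescribing")
    _check_nonnegative(df, "quantity", "prescribing")
    _check_nonnegative(df, "actual_cost", "prescribing")
    df["quantity"] = pd.to_numeric(df["quantity"])
    df["actual_cost"] = pd.to_numeric(df["actual_cost"]).astype(float)
    groups_per_org = df.groupby("org_id")["group_id"].nunique()
    multi = groups_per_org[groups_per_org > 1]
    if len(multi):
        raise ValueError(
            f"prescribing: org(s) mapped to more than one group: {list(multi.index)}"
        )
    out = (
        df.groupby(PRESCRIBING_KEY, as_index=False)[["quantity", "actual_cost"]]
        .sum()
        .sort_values(PRESCRIBING_KEY, ignore_index=True)
    )
    return out


def read_prescribing(path) -> pd.DataFrame:
    """Read a prescribing CSV into the canonical table (duplicate keys summed)."""
    return canonicalize_prescribing(pd.read_csv(path, dtype=str))


def write_prescribing(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_list_sizes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, LISTSIZE_COLUMNS, "list sizes")
    df = df[LISTSIZE_COLUMNS].copy()
    df["org_id"] = df["org_id"].astype(str)
    df["month"] = df["month"].astype(str)
    _check_months(df, "list sizes")
    _check_nonnegative(df, "list_size", "list sizes")
    df["list_size"] = pd.to_numeric(df["list_size"]).astype(int)
    if (df["list_size"] <= 0).any():
        bad = df.index[df["list_size"] <= 0]
        raise ValueError(f"list sizes: non-positive list_size in row(s) {list(bad[:10])}")
    if df.duplicated(["org_id", "month"]).any():
        raise ValueError("list sizes: duplicate (org_id, month) rows")
    return df.sort_values(["org_id", "month"], ignore_index=True)


def write_list_sizes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_pageviews(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, PAGEVIEW_COLUMNS, "page views")
    df = df[PAGEVIEW_COLUMNS].copy()
    for c in ("org_kind", "org_id", "month", "feature"):
        df[c] = df[c].astype(str)
    _check_months(df, "page views")
    bad_kind = set(df["org_kind"]) - set(ORG_KINDS)
    if bad_kind:
        raise ValueError(f"page views: unknown org_kind values {sorted(bad_kind)}")
    bad_feat = set(df["feature"]) - set(FEATURES)
    if bad_feat:
        raise ValueError(f"page views: unknown feature values {sorted(bad_feat)}")
    _check_nonnegative(df, "views", "page views")
    df["views"] = pd.to_numeric(df["views"]).astype(int)
    # one row per (org_kind, org_id, month, feature)
    df = (
        df.groupby(["org_kind", "org_id", "month", "feature"], as_index=False)["views"]
        .sum()
        .sort_values(["org_kind", "org_id", "month", "feature"], ignore_index=True)
    )
    return df


def write_pageviews(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def exclude_small_practices(
    records: pd.DataFrame, list_sizes: pd.DataFrame, threshold: int = 1000
) -> pd.DataFrame:
    """Drop all rows of any org-month whose registered list is below ``threshold``.

    Very small lists indicate atypical organizations. The rule is applied per
    org-month: an organization re-enters in months where its list has grown to
    the threshold. With ``threshold=0`` the input is returned unchanged.
    """
    if threshold <= 0:
        return records.copy()
    merged = records.merge(list_sizes, on=["org_id", "month"], how="left")
    missing = merged.loc[merged["list_size"].isna(), ["org_id", "month"]]
    if len(missing):
        pairs = sorted(set(map(tuple, missing.itertuples(index=False))))
        raise ValueError(f"no list size for org-month(s): {pairs[:10]}")
    keep = merged["list_size"] >= threshold
    return records.loc[keep.to_numpy()].reset_index(drop=True)


def aggregate_to_group(records: pd.DataFrame) -> pd.DataFrame:
    """Sum practice-level prescribing to the parent-group level.

    Returns a table in the same schema whose ``org_id`` is the group id, so
    all downstream stages can run unchanged at either analysis level.
    """
    groups_per_org = records.groupby("org_id")["group_id"].nunique()
    multi = groups_per_org[groups_per_org > 1]
    if len(multi):
        raise ValueError(f"org(s) mapped to more than one group: {list(multi.index)}")
    if records["group_id"].isna().any() or (records["group_id"] == "").any():
        raise ValueError("org(s) with no group mapping")
    out = (
        records.groupby(["group_id", "month", "product_id", "dose_id"], as_index=False)[
            ["quantity", "actual_cost"]
        ].sum()
    )
    out.insert(0, "org_id", out["group_id"])
    return out[PRESCRIBING_COLUMNS].sort_values(PRESCRIBING_KEY, ignore_index=True)


def aggregate_list_sizes(
    list_sizes: pd.DataFrame, org_to_group: pd.DataFrame
) -> pd.DataFrame:
    """Group-level list size = sum of member practice list sizes per month.

    ``org_to_group`` has columns ``org_id, group_id`` (e.g. the deduplicated
    pair columns of a prescribing table).
    """
    mapping = org_to_group[["org_id", "group_id"]].drop_duplicates()
    if mapping["org_id"].duplicated().any():
        dup = mapping.loc[mapping["org_id"].duplicated(), "org_id"]
        raise ValueError(f"org(s) mapped to more than one group: {sorted(set(dup))}")
    merged = list_sizes.merge(mapping, on="org_id", how="left")
    if merged["group_id"].isna().any():
        orgs = sorted(set(merged.loc[merged["group_id"].isna(), "org_id"]))
        raise ValueError(f"org(s) with no group mapping: {orgs[:10]}")
    out = (
        merged.groupby(["group_id", "month"], as_index=False)["list_size"]
        .sum()
        .rename(columns={"group_id": "org_id"})
    )
    return out[LISTSIZE_COLUMNS].sort_values(["org_id", "month"], ignore_index=True)
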