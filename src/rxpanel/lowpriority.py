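"""Spend on policy-designated low-priority products, per 1,000 patients per month."""

from __future__ import annotations

import fnmatch

import pandas as pd


def load_product_list(path) -> list[str]:
    """Read one product-id glob pattern per line; blank lines and # comments ignored."""
    with open(path) as fh:
        patterns = [
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        ]
    return patterns


def low_priority_spend(
    records: pd.DataFrame, product_list: list[str], list_sizes: pd.DataFrame
) -> pd.DataFrame:
    """Total actual cost of listed products per 1,000 patients per org-month.

    Every org-month present in ``records`` appears in the output; org-months
    prescribing none of the listed products get 0.
    Columns: org_id, month, value (GBP per 1,000 patients per month).
    """
    if not product_list:
        raise ValueError("low-priority product list is empty")
    unique = records["product_id"].unique()
    matched = {
        p for p in unique if any(fnmatch.fnmatch(p, pat) for pat in product_list)
    }
    universe = records[["org_id", "month"]].drop_duplicates()
    spend = (
        records[records["product_id"].isin(matched)]
        .groupby(["org_id", "month"], as_index=False)["actual_cost"]
        .sum()
    )
    merged = universe.merge(spend, on=["org_id", "month"], how="left").fillna(
        {"actual_cost": 0.0}
    )
    merged = merged.merge(list_sizes, on=["org_id", "month"], how="left")
    if merged["list_size"].isna().any():
        pairs = merged.loc[merged["list_size"].isna(), ["org_id", "month"]]
        raise ValueError(
            f"missing list size for org-month(s): "
            f"{sorted(set(map(tuple, pairs.itertuples(index=False))))[:10]}"
        )
    merged["value"] = 1000.0 * merged["actual_cost"] / merged["list_size"]
    return merged[["org_id", "month", "value"]].sort_values(
        ["org_id", "month"], ignore_index=True
    )
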