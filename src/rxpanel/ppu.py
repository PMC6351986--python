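"""Price-per-unit (PPU) cost-savings algorithm.

For every dose of every product in every month the mean price per unit paid
by each organization is compared with the price achieved by the 10th-centile
organization nationally. The excess, multiplied by the quantity dispensed, is
the saving that would be available were the organization to attain the
reference price. Savings are summed per organization-month and expressed per
1,000 registered patients.

The per-cell PPU is the organization's pooled cost divided by pooled
quantity for the month — i.e. the quantity-weighted mean unit price.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNIT_PRICE_COLUMNS = ["org_id", "month", "product_id", "dose_id", "ppu", "quantity"]
CELL = ["month", "product_id", "dose_id"]


def compute_unit_prices(records: pd.DataFrame) -> pd.DataFrame:
    """One unit price per org-month-product-dose; rows with zero quantity are skipped."""
    if (records["quantity"] < 0).any() or (records["actual_cost"] < 0).any():
        raise ValueError("negative quantity or cost in prescribing records")
    grouped = records.groupby(
        ["org_id", "month", "product_id", "dose_id"], as_index=False
    )[["quantity", "actual_cost"]].sum()
    grouped = grouped[grouped["quantity"] > 0].copy()
    grouped["ppu"] = grouped["actual_cost"] / grouped["quantity"]
    return grouped[UNIT_PRICE_COLUMNS].reset_index(drop=True)


def reference_prices(unit_prices: pd.DataFrame, centile: float = 10.0) -> pd.DataFrame:
    """Per month-product-dose reference price at the given centile of org PPUs.

    Uses linear interpolation between order statistics (numpy's default
    quantile convention). Columns: month, product_id, dose_id, ref_ppu.
    """
    if not 0 <= centile <= 100:
        raise ValueError(f"centile must be in [0, 100], got {centile}")
    if len(unit_prices) == 0:
        raise ValueError("no unit prices supplied")
    out = (
        unit_prices.groupby(CELL)["ppu"]
        .quantile(centile / 100.0)
        .rename("ref_ppu")
        .reset_index()
    )
    return out


def available_savings(
    unit_prices: pd.DataFrame, ref_prices: pd.DataFrame
) -> pd.DataFrame:
    """Available saving per org-month-product-dose: max(0, ppu − ref) × quantity."""
    merged = unit_prices.merge(ref_prices, on=CELL, how="left")
    if merged["ref_ppu"].isna().any():
        cells = (
            merged.loc[merged["ref_ppu"].isna(), CELL]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValueError(f"missing reference price for cell(s): {list(cells)[:10]}")
    merged["available_saving"] = (
        np.clip(merged["ppu"] - merged["ref_ppu"], 0.0, None) * merged["quantity"]
    )
    return merged[
        ["org_id", "month", "product_id", "dose_id", "available_saving"]
    ].reset_index(drop=True)


def rank_opportunities(
    opportunities: pd.DataFrame, top_k: int | None = None
) -> pd.DataFrame:
    """Order each org-month's savings opportunities, largest first.

    Ties on available_saving are broken by (product_id, dose_id)
    lexicographically; ``top_k`` truncates each org-month's list.
    """
    if top_k is not None and top_k < 0:
        raise ValueError(f"top_k must be non-negative, got {top_k}")
    ordered = opportunities.sort_values(
        ["org_id", "month", "available_saving", "product_id", "dose_id"],
        ascending=[True, True, False, True, True],
        ignore_index=True,
    )
    if top_k is not None:
        ordered = ordered.groupby(["org_id", "month"], as_index=False, sort=False).head(
            top_k
        ).reset_index(drop=True)
    return ordered


def ppu_outcome(
    opportunities: pd.DataFrame, list_sizes: pd.DataFrame
) -> pd.DataFrame:
    """Total available saving per 1,000 registered patients per org-month.

    Columns: org_id, month, value (GBP per 1,000 patients per month).
    """
    totals = opportunities.groupby(["org_id", "month"], as_index=False)[
        "available_saving"
    ].sum()
    merged = totals.merge(list_sizes, on=["org_id", "month"], how="left")
    if merged["list_size"].isna().any():
        pairs = merged.loc[merged["list_size"].isna(), ["org_id", "month"]]
        raise ValueError(
            f"missing list size for org-month(s): "
            f"{sorted(set(map(tuple, pairs.itertuples(index=False))))[:10]}"
        )
    merged["value"] = 1000.0 * merged["available_saving"] / merged["list_size"]
    return merged[["org_id", "month", "value"]].sort_values(
        ["org_id", "month"], ignore_index=True
    )


def ppu_pipeline(
    records: pd.DataFrame, list_sizes: pd.DataFrame, centile: float = 10.0
) -> pd.DataFrame:
    """Records → unit prices → reference prices → savings → per-1,000 outcome."""
    prices = compute_unit_prices(records)
    refs = reference_prices(prices, centile=centile)
    savings = available_savings(prices, refs)
    return ppu_outcome(savings, list_sizes)
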