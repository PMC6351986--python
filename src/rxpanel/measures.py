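"""Prescribing-quality measures: ratios, within-month percentile ranks, mean score.

A measure is a numerator/denominator pair of selectors over products, each
summing either quantity or cost. Per month, every organization's ratio is
converted to a percentile rank across organizations (0–100, higher = worse
prescribing), and the summary score is the arithmetic mean percentile across
all included measures.

The percentile convention is ``100 × (rank − 1) / (n − 1)`` with mean ranks
for ties, so the monthly scores span 0–100 and average 50.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALUE_FIELDS = ("quantity", "cost")


@dataclass(frozen=True)
class Selector:
    """Product patterns (fnmatch globs) plus the value field to sum."""

    products: tuple[str, ...]
    field: str = "quantity"

    def __post_init__(self):
        if self.field not in VALUE_FIELDS:
            raise ValueError(f"selector field must be one of {VALUE_FIELDS}")

    def mask(self, product_ids: pd.Series) -> pd.Series:
        unique = product_ids.unique()
        matched = {
            p for p in unique if any(fnmatch.fnmatch(p, pat) for pat in self.products)
        }
        return product_ids.isin(matched)

    def column(self) -> str:
        return "quantity" if self.field == "quantity" else "actual_cost"


@dataclass(frozen=True)
class MeasureDefinition:
    measure_id: str
    numerator: Selector
    denominator: Selector
    higher_is_worse: bool = True
    excluded: bool = False


def load_measures(path) -> list[MeasureDefinition]:
    """Read measure definitions from YAML (see ``measures.yaml`` schema in docs)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(
            MeasureDefinition(
                measure_id=str(item["measure_id"]),
                numerator=Selector(
                    tuple(item["numerator"]["products"]),
                    item["numerator"].get("field", "quantity"),
                ),
                denominator=Selector(
                    tuple(item["denominator"]["products"]),
                    item["denominator"].get("field", "quantity"),
                ),
                higher_is_worse=bool(item.get("higher_is_worse", True)),
                excluded=bool(item.get("excluded", False)),
            )
        )
    if not any(not d.excluded for d in defs):
        raise ValueError("at least one included measure is required")
    return defs


def measure_ratios(records: pd.DataFrame, definition: MeasureDefinition) -> pd.DataFrame:
    """Per org-month numerator/denominator ratio for one measure.

    Org-months with a zero denominator are skipped (logged), not imputed.
    Columns: org_id, month, ratio.
    """
    key = ["org_id", "month"]
    num_rows = records[definition.numerator.mask(records["product_id"])]
    den_rows = records[definition.denominator.mask(records["product_id"])]
    den = den_rows.groupby(key)[definition.denominator.column()].sum().rename("den")
    num = num_rows.groupby(key)[definition.numerator.column()].sum().rename("num")
    joined = den.to_frame().join(num, how="left").fillna({"num": 0.0})
    zero = joined["den"] == 0
    if zero.any():
        logger.info(
            "measure %s: skipping %d org-month(s) with zero denominator",
            definition.measure_id,
            int(zero.sum()),
        )
        joined = joined[~zero]
    joined = joined.reset_index()
    joined["ratio"] = joined["num"] / joined["den"]
    return joined[["org_id", "month", "ratio"]]


def percentile_ranks(ratios: pd.DataFrame, higher_is_worse: bool = True) -> pd.DataFrame:
    """Within-month percentile rank of each org's ratio, oriented so higher = worse.

    Requires at least two organizations per month.
    """
    def _one_month(group: pd.Series) -> pd.Series:
        n = len(group)
        if n < 2:
            raise ValueError(
                f"percentile rank needs >=2 orgs per month, got {n}"
            )
        pct = 100.0 * (group.rank(method="average") - 1) / (n - 1)
        return pct if higher_is_worse else 100.0 - pct

    out = ratios.copy()
    out["percentile"] = out.groupby("month")["ratio"].transform(_one_month)
    return out[["org_id", "month", "ratio", "percentile"]]


def measure_scores(
    records: pd.DataFrame, definitions: list[MeasureDefinition]
) -> pd.DataFrame:
    """Ratio and percentile for every included measure × org-month."""
    frames = []
    for d in definitions:
        if d.excluded:
            continue
        scored = percentile_ranks(measure_ratios(records, d), d.higher_is_worse)
        scored.insert(2, "measure_id", d.measure_id)
        frames.append(scored)
    if not frames:
        raise ValueError("no included measures")
    return pd.concat(frames, ignore_index=True)


def mean_measure_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean percentile across included measures per org-month.

    Columns: org_id, month, value (0–100, higher = worse). Org-months with no
    defined measure percentile are simply absent.
    """
    out = (
        scores.groupby(["org_id", "month"], as_index=False)["percentile"]
        .mean()
        .rename(columns={"percentile": "value"})
    )
    return out.sort_values(["org_id", "month"], ignore_index=True)
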