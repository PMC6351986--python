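import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rxpanel import ppu
from conftest import listsize_frame, prescribing_frame


def unit_price_frame(rows):
    return pd.DataFrame(
        rows, columns=["org_id", "month", "product_id", "dose_id", "ppu", "quantity"]
    )


class TestUnitPrices:
    def test_definition_and_zero_cases(self):
        records = prescribing_frame(
            [
                ("A", "G1", "2017-01", "P1", "d0", 100, 20.0),   # ppu 0.20
                ("B", "G1", "2017-01", "P1", "d0", 0, 0.0),      # skipped
                ("C", "G1", "2017-01", "P1", "d0", 50, 0.0),     # ppu 0
            ]
        )
        out = ppu.compute_unit_prices(records)
        assert set(out["org_id"]) == {"A", "C"}
        assert dict(zip(out["org_id"], out["ppu"])) == pytest.approx(
            {"A": 0.20, "C": 0.0}
        )

    def test_pooled_ratio_equals_quantity_weighted_mean(self):
        # two raw sub-rows for the same cell: ppu is pooled cost over pooled qty
        records = prescribing_frame(
            [
                ("A", "G1", "2017-01", "P1", "d0", 10, 30.0),
                ("A", "G1", "2017-01", "P1", "d0", 90, 45.0),
            ]
        )
        out = ppu.compute_unit_prices(records)
        assert out.loc[0, "ppu"] == pytest.approx(75.0 / 100)

    def test_negative_inputs_rejected(self):
        records = prescribing_frame([("A", "G1", "2017-01", "P1", "d0", -1, 1.0)])
        with pytest.raises(ValueError, match="negative"):
            ppu.compute_unit_prices(records)


class TestReferencePrice:
    @pytest.mark.parametrize(
        "ppus,expected",
        [([1.0, 2.0, 3.0], 1.2), ([2.0, 2.0, 2.0], 2.0), ([5.0], 5.0)],
    )
    def test_tenth_centile_with_linear_interpolation(self, ppus, expected):
        prices = unit_price_frame(
            [(f"O{i}", "2017-01", "P1", "d0", v, 10) for i, v in enumerate(ppus)]
        )
        out = ppu.reference_prices(prices, centile=10)
        assert out.loc[0, "ref_ppu"] == pytest.approx(expected)

    def test_reference_lies_within_observed_range(self):
        rng = np.random.default_rng(0)
        ppus = rng.lognormal(0, 1, 25)
        prices = unit_price_frame(
            [(f"O{i}", "2017-01", "P1", "d0", v, 1) for i, v in enumerate(ppus)]
        )
        for centile in (0, 10, 50, 90, 100):
            ref = ppu.reference_prices(prices, centile=centile).loc[0, "ref_ppu"]
            assert ppus.min() <= ref <= ppus.max()

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            ppu.reference_prices(unit_price_frame([]))


class TestAvailableSavings:
    def test_excess_times_quantity_and_clipping(self):
        prices = unit_price_frame(
            [
                ("A", "2017-01", "P1", "d0", 2.0, 100),
                ("B", "2017-01", "P1", "d0", 1.0, 100),
            ]
        )
        refs = pd.DataFrame(
            {"month": ["2017-01"], "product_id": ["P1"], "dose_id": ["d0"],
             "ref_ppu": [1.2]}
        )
        out = ppu.available_savings(prices, refs)
        savings = dict(zip(out["org_id"], out["available_saving"]))
        assert savings["A"] == pytest.approx(80.0)
        assert savings["B"] == 0.0  # below reference: nothing to save

    def test_uniform_prices_give_zero_savings_everywhere(self):
        prices = unit_price_frame(
            [(f"O{i}", "2017-01", "P1", "d0", 2.0, 50) for i in range(4)]
        )
        refs = ppu.reference_prices(prices, centile=10)
        out = ppu.available_savings(prices, refs)
        assert (out["available_saving"] == 0).all()

    def test_missing_reference_for_populated_cell_is_an_error(self):
        prices = unit_price_frame([("A", "2017-01", "P1", "d0", 2.0, 100)])
        refs = pd.DataFrame(
            {"month": ["2017-02"], "product_id": ["P1"], "dose_id": ["d0"],
             "ref_ppu": [1.0]}
        )
        with pytest.raises(ValueError, match="missing reference"):
            ppu.available_savings(prices, refs)


class TestRankAndOutcome:
    def opportunities(self):
        return pd.DataFrame(
            {
                "org_id": "A", "month": "2017-01",
                "product_id": ["PA", "PB", "PC"], "dose_id": "d0",
                "available_saving": [80.0, 5.0, 80.0],
            }
        )

    def test_tie_break_by_product_then_truncation(self):
        ranked = ppu.rank_opportunities(self.opportunities())
        assert list(ranked["product_id"]) == ["PA", "PC", "PB"]
        top1 = ppu.rank_opportunities(self.opportunities(), top_k=1)
        assert list(top1["product_id"]) == ["PA"]

    def test_negative_top_k_rejected(self):
        with pytest.raises(ValueError):
            ppu.rank_opportunities(self.opportunities(), top_k=-1)

    @pytest.mark.parametrize(
        "total,list_size,expected", [(80.0, 2000, 40.0), (0.0, 2000, 0.0), (80.0, 1000, 80.0)]
    )
    def test_rate_per_thousand(self, total, list_size, expected):
        opps = pd.DataFrame(
            {"org_id": ["A"], "month": ["2017-01"], "product_id": ["P1"],
             "dose_id": ["d0"], "available_saving": [total]}
        )
        sizes = listsize_frame([("A", "2017-01", list_size)])
        out = ppu.ppu_outcome(opps, sizes)
        assert out.loc[0, "value"] == pytest.approx(expected)

    def test_missing_list_size_is_an_error(self):
        with pytest.raises(ValueError, match="missing list size"):
            ppu.ppu_outcome(self.opportunities(), listsize_frame([]))


@given(scale=st.floats(min_value=0.01, max_value=100.0))
def test_scaling_costs_scales_savings_and_rates_equally(scale):
    records = prescribing_frame(
        [
            ("A", "G1", "2017-01", "P1", "d0", 100, 20.0),
            ("B", "G1", "2017-01", "P1", "d0", 200, 80.0),
            ("C", "G1", "2017-01", "P1", "d0", 50, 45.0),
        ]
    )
    sizes = listsize_frame([(o, "2017-01", 2000) for o in "ABC"])
    base = ppu.ppu_pipeline(records, sizes)
    scaled_records = records.assign(actual_cost=records["actual_cost"] * scale)
    scaled = ppu.ppu_pipeline(scaled_records, sizes)
    np.testing.assert_allclose(scaled["value"], base["value"] * scale, rtol=1e-9)


@given(
    centiles=st.lists(
        st.floats(min_value=0, max_value=100), min_size=2, max_size=2, unique=True
    )
)
def test_raising_the_centile_never_increases_savings(centiles):
    # a higher centile is a laxer benchmark price, so every org's excess over
    # it (and hence its available saving) can only shrink
    lo, hi = sorted(centiles)
    rng = np.random.default_rng(42)
    records = prescribing_frame(
        [
            (f"O{i}", "G1", "2017-01", "P1", "d0", 50, float(c))
            for i, c in enumerate(rng.lognormal(2, 0.5, 8))
        ]
    )
    prices = ppu.compute_unit_prices(records)
    sav_lo = ppu.available_savings(prices, ppu.reference_prices(prices, lo))
    sav_hi = ppu.available_savings(prices, ppu.reference_prices(prices, hi))
    assert (sav_lo["available_saving"] - sav_hi["available_saving"] >= -1e-12).all()


def test_cheapest_org_has_zero_saving_at_low_centile():
    rng = np.random.default_rng(7)
    n = 6
    records = prescribing_frame(
        [
            (f"O{i}", "G1", "2017-01", "P1", "d0", 50, float(c))
            for i, c in enumerate(rng.lognormal(2, 0.5, n))
        ]
    )
    prices = ppu.compute_unit_prices(records)
    cheapest = prices.loc[prices["ppu"].idxmin(), "org_id"]
    savings = ppu.available_savings(prices, ppu.reference_prices(prices, 100 / n))
    row = savings[savings["org_id"] == cheapest]
    assert row["available_saving"].iloc[0] == 0.0
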