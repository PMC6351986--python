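import numpy as np
import pandas as pd
import pytest

from rxpanel import panel


def make_panel(rows):
    return pd.DataFrame(rows, columns=["entity", "month", "outcome", "status"])


TWO_BY_TWO = make_panel(
    [
        ("A", "2017-01", 10.0, "not_viewed"),
        ("A", "2017-02", 6.0, "month_first_viewed"),
        ("B", "2017-01", 10.0, "not_viewed"),
        ("B", "2017-02", 10.0, "not_viewed"),
    ]
)


class TestFixedEffects:
    def test_two_by_two_panel_recovers_minus_four(self):
        est = panel.fit_fixed_effects(TWO_BY_TWO)
        assert len(est) == 1
        assert est[0].term == "month_first_viewed"
        assert est[0].coefficient == pytest.approx(-4.0)
        assert est[0].n_entities == 2 and est[0].n_obs == 4
        assert est[0].ci_low <= est[0].coefficient <= est[0].ci_high

    def test_constant_outcome_gives_zero_coefficients(self):
        pdl = TWO_BY_TWO.assign(outcome=5.0)
        est = panel.fit_fixed_effects(pdl)
        assert est[0].coefficient == pytest.approx(0.0, abs=1e-12)

    def test_entity_constant_shift_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(0)
        pdl = _random_panel(rng, 8, 6)
        base = panel.fit_fixed_effects(pdl, adjust_month=True)
        shifts = {e: rng.normal(0, 50) for e in pdl["entity"].unique()}
        shifted = pdl.assign(outcome=pdl["outcome"] + pdl["entity"].map(shifts))
        moved = panel.fit_fixed_effects(shifted, adjust_month=True)
        for a, b in zip(base, moved):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-9)

    def test_month_constant_shift_moves_univariable_but_not_adjusted(self):
        rng = np.random.default_rng(1)
        pdl = _random_panel(rng, 8, 6)
        months = sorted(pdl["month"].unique())
        shifts = {m: 10.0 * i for i, m in enumerate(months)}  # a strong trend
        shifted = pdl.assign(outcome=pdl["outcome"] + pdl["month"].map(shifts))
        adj_base = panel.fit_fixed_effects(pdl, adjust_month=True)
        adj_shift = panel.fit_fixed_effects(shifted, adjust_month=True)
        uni_base = panel.fit_fixed_effects(pdl, adjust_month=False)
        uni_shift = panel.fit_fixed_effects(shifted, adjust_month=False)
        for a, b in zip(adj_base, adj_shift):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-9)
        assert abs(uni_base[0].coefficient - uni_shift[0].coefficient) > 1.0

    def test_saturating_collinearity_is_reported(self):
        # both entities exposed in the same (second of two) month: the month
        # dummy and the exposure dummy coincide after demeaning
        pdl = make_panel(
            [
                ("A", "2017-01", 1.0, "not_viewed"),
                ("A", "2017-02", 2.0, "month_first_viewed"),
                ("B", "2017-01", 1.5, "not_viewed"),
                ("B", "2017-02", 2.5, "month_first_viewed"),
            ]
        )
        with pytest.raises(ValueError, match="collinear"):
            panel.fit_fixed_effects(pdl, adjust_month=True)

    def test_duplicate_entity_month_rejected(self):
        dup = pd.concat([TWO_BY_TWO, TWO_BY_TWO.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            panel.fit_fixed_effects(dup)

    def test_cluster_flag_changes_errors_not_coefficients(self):
        rng = np.random.default_rng(2)
        pdl = _random_panel(rng, 10, 8)
        conv = panel.fit_fixed_effects(pdl, adjust_month=True)
        clus = panel.fit_fixed_effects(pdl, adjust_month=True, cluster=True)
        for a, b in zip(conv, clus):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-10)
            assert a.se != b.se


class TestBetweenEffects:
    def test_difference_of_category_means(self):
        rows = []
        for i in range(4):
            cat = "zero" if i < 2 else "t1"
            base = 100.0 if cat == "zero" else 140.0
            for m in ("2017-01", "2017-02"):
                rows.append((f"O{i}", m, base, cat))
        pdl = pd.DataFrame(rows, columns=["entity", "month", "outcome", "category"])
        est = panel.fit_between_effects(pdl)
        assert len(est) == 1
        assert est[0].term == "t1"
        assert est[0].coefficient == pytest.approx(40.0)

    def test_identical_means_give_zero(self):
        rows = [("A", "2017-01", 7.0, "zero"), ("B", "2017-01", 7.0, "t1")]
        pdl = pd.DataFrame(rows, columns=["entity", "month", "outcome", "category"])
        est = panel.fit_between_effects(pdl)
        assert est[0].coefficient == pytest.approx(0.0, abs=1e-12)

    def test_reference_falls_back_to_lowest_populated_category(self):
        rows = [
            ("A", "2017-01", 1.0, "t1"), ("B", "2017-01", 2.0, "t2"),
            ("C", "2017-01", 3.0, "t3"),
        ]
        pdl = pd.DataFrame(rows, columns=["entity", "month", "outcome", "category"])
        est = panel.fit_between_effects(pdl)
        assert [e.term for e in est] == ["t2", "t3"]

    def test_single_category_is_an_error(self):
        rows = [("A", "2017-01", 1.0, "zero"), ("B", "2017-01", 2.0, "zero")]
        pdl = pd.DataFrame(rows, columns=["entity", "month", "outcome", "category"])
        with pytest.raises(ValueError, match="categories"):
            panel.fit_between_effects(pdl)

    def test_category_varying_within_entity_is_an_error(self):
        rows = [("A", "2017-01", 1.0, "zero"), ("A", "2017-02", 2.0, "t1"),
                ("B", "2017-01", 1.0, "t1")]
        pdl = pd.DataFrame(rows, columns=["entity", "month", "outcome", "category"])
        with pytest.raises(ValueError, match="varies"):
            panel.fit_between_effects(pdl)


class TestSummarizePeriods:
    def test_mean_and_sample_sd(self):
        pdl = make_panel(
            [("A", "2017-01", 1.0, "not_viewed"),
             ("A", "2017-02", 2.0, "not_viewed"),
             ("B", "2017-01", 3.0, "not_viewed"),
             ("B", "2017-02", 9.0, "after_first_view")]
        )
        out = panel.summarize_periods(pdl).set_index("status")
        assert out.loc["not_viewed", "mean"] == pytest.approx(2.0)
        assert out.loc["not_viewed", "sd"] == pytest.approx(1.0)
        # single observation: SD undefined, reported as NaN
        assert np.isnan(out.loc["after_first_view", "sd"])

    def test_level_means_recombine_to_grand_mean(self):
        rng = np.random.default_rng(3)
        pdl = _random_panel(rng, 6, 5)
        out = panel.summarize_periods(pdl)
        recombined = (out["mean"] * out["n_obs"]).sum() / out["n_obs"].sum()
        assert recombined == pytest.approx(pdl["outcome"].mean())


def _random_panel(rng, n_entities, n_months):
    """Unbalanced-friendly random panel with staggered exposure."""
    months = [f"2017-{m:02d}" for m in range(1, n_months + 1)]
    rows = []
    for i in range(n_entities):
        first = rng.integers(1, n_months) if rng.random() < 0.6 else None
        for t, m in enumerate(months):
            if first is None or t < first:
                status = "not_viewed"
            elif t == first:
                status = "month_first_viewed"
            else:
                status = "after_first_view"
            y = 10 * i + 0.5 * t + rng.normal(0, 1) - 3.0 * (status != "not_viewed")
            rows.append((f"E{i}", m, y, status))
    return make_panel(rows)
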