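"""Synthetic prescribing panels with known ground truth.

The generator emulates the joint structure the impact analysis must untangle:

* cross-organization price dispersion within product-dose cells (log-normal
  per-organization price multipliers),
* a secular downward trend in unit prices, and hence in available savings,
* selection of less price-efficient organizations into being viewed (the
  log-odds of ever being viewed rise with standardized log-inefficiency), and
* an injected post-viewing effect: from the first-viewed month onward a
  viewed organization's price multiplier shrinks toward the national
  10th-centile level by an amount recalibrated each month so its
  price-per-unit savings outcome moves by approximately ``viewing_effect``
  per 1,000 patients.

The effect touches only products outside the low-priority list, so the
low-priority spend and measure-score outcomes remain null — viewing changes
what an organization pays for its ordinary products, not what it prescribes.

A single global seed drives every draw through a fixed sub-seed scheme
(:class:`numpy.random.SeedSequence` spawning one child stream per stage), so
the same seed reproduces each stage byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import month_range
from .measures import MeasureDefinition, Selector


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic prescribing panel.

    Defaults give a 200-practice, 18-month panel whose price-per-unit
    outcome sits near £400 per 1,000 patients per month with an injected
    after-viewing change of −£40.42 — the scale of a realistic national
    prescribing panel, shrunk to desk size.
    """

    n_groups: int = 20
    practices_per_group: int = 10
    n_months: int = 18
    n_products: int = 20
    start_month: str = "2016-04"
    baseline_ppu_mean: float = 1.00      # GBP per dispensed unit, national mean
    price_dispersion_sd: float = 0.20    # log-scale SD of org price multipliers
    inefficiency_product_sd: float = 0.35  # log-scale SD of per-(org, product) price deviations
    secular_trend: float = 0.99          # multiplicative monthly price drift
    viewing_effect: float = -40.42       # GBP per 1,000 patients, from first view
    selection_strength: float = 1.0      # log-odds of viewing per SD of inefficiency
    base_view_prob: float = 0.4          # viewing probability at average efficiency
    view_start_month: int = 6            # earliest month index views can occur
    mean_list_size: float = 5500.0
    list_size_sd: float = 0.45           # log-scale SD of practice list sizes
    small_practice_fraction: float = 0.02  # drawn uniform 300–999 patients
    items_per_patient: float = 1.0       # dispensed units per patient per month
    mix_sd: float = 0.3                  # log-scale SD of org product-mix tilt
    price_noise_sd: float = 0.05         # log-scale SD of per-row price noise
    lp_fraction: float = 0.2             # share of products on the low-priority list
    n_measures: int = 5
    seed: int = 0

    def months(self) -> list[str]:
        return month_range(self.start_month, self.n_months)

    @property
    def n_orgs(self) -> int:
        return self.n_groups * self.practices_per_group

    def validate(self) -> None:
        for name in ("n_groups", "practices_per_group", "n_months", "n_products",
                     "n_measures"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.view_start_month < self.n_months:
            raise ValueError("view_start_month must lie inside the month window")
        if self.secular_trend <= 0 or self.baseline_ppu_mean <= 0:
            raise ValueError("trend and baseline price must be positive")


def low_priority_products(config: SimulationConfig) -> list[str]:
    """Product ids designated low-priority (the last lp_fraction of products)."""
    n_lp = int(round(config.lp_fraction * config.n_products))
    return [f"P{j:03d}" for j in range(config.n_products - n_lp, config.n_products)]


def default_measure_definitions(config: SimulationConfig) -> list[MeasureDefinition]:
    """Quantity-share measures over pairs of non-low-priority products.

    Measure k takes the first product of its pair as the "costly variant"
    numerator and the pair as denominator, mirroring proportion-style
    prescribing measures (e.g. share of a drug class given as a high-cost
    presentation).
    """
    n_lp = int(round(config.lp_fraction * config.n_products))
    ordinary = [f"P{j:03d}" for j in range(config.n_products - n_lp)]
    defs = []
    for k in range(config.n_measures):
        a = ordinary[(2 * k) % len(ordinary)]
        b = ordinary[(2 * k + 1) % len(ordinary)]
        defs.append(
            MeasureDefinition(
                measure_id=f"M{k:02d}",
                numerator=Selector((a,), "quantity"),
                denominator=Selector((a, b), "quantity"),
                higher_is_worse=True,
            )
        )
    return defs


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_panel(config: SimulationConfig):
    """Generate (prescribing, list_sizes, pageviews, ground_truth) tables.

    Ground truth columns: org_id, group_id, ever_viewed, first_view_month
    (empty string if never viewed), baseline_inefficiency, true_effect.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_select, rng_views, rng_qty, rng_price = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    n_orgs, n_months, n_products = config.n_orgs, config.n_months, config.n_products
    months = config.months()
    org_ids = np.array([f"ORG{i:04d}" for i in range(n_orgs)])
    group_ids = np.array(
        [f"G{i // config.practices_per_group:03d}" for i in range(n_orgs)]
    )
    product_ids = np.array([f"P{j:03d}" for j in range(n_products)])
    lp_set = set(low_priority_products(config))
    is_lp = np.array([p in lp_set for p in product_ids])

    # --- structure: list sizes, product prices/weights, org multipliers & mix
    sigma = config.price_dispersion_sd
    mu_m = -0.5 * sigma**2
    list_size = np.maximum(
        100,
        np.round(
            rng_struct.lognormal(
                math.log(config.mean_list_size) - 0.5 * config.list_size_sd**2,
                config.list_size_sd,
                n_orgs,
            )
        ),
    ).astype(int)
    small = rng_struct.random(n_orgs) < config.small_practice_fraction
    list_size[small] = rng_struct.integers(300, 1000, small.sum())

    sd_p = 0.5  # log-scale spread of national product prices
    base_price = rng_struct.lognormal(
        math.log(config.baseline_ppu_mean) - 0.5 * sd_p**2, sd_p, n_products
    )
    weights = rng_struct.dirichlet(np.full(n_products, 2.0))
    multiplier = rng_struct.lognormal(mu_m, sigma, n_orgs)
    z = (np.log(multiplier) - mu_m) / sigma if sigma > 0 else np.zeros(n_orgs)
    mix = weights[None, :] * rng_struct.lognormal(
        -0.5 * config.mix_sd**2, config.mix_sd, (n_orgs, n_products)
    )
    mix /= mix.sum(axis=1, keepdims=True)
    lam = list_size[:, None] * config.items_per_patient * mix  # expected quantities

    # --- selection into viewing and first-view months
    logit_base = math.log(config.base_view_prob / (1 - config.base_view_prob))
    p_viewed = _sigmoid(logit_base + config.selection_strength * z)
    ever_viewed = rng_select.random(n_orgs) < p_viewed
    first_view = np.full(n_orgs, -1)
    first_view[ever_viewed] = rng_select.integers(
        config.view_start_month, n_months, ever_viewed.sum()
    )

    # --- per-(org, product) price deviations: organizations overpay on
    # particular presentations rather than uniformly, so every org keeps some
    # savings headroom (the premise of a per-product savings tool)
    sigma_u = config.inefficiency_product_sd
    u_dev = rng_struct.lognormal(-0.5 * sigma_u**2, sigma_u, (n_orgs, n_products))

    # --- injected post-viewing effect on the org-level multiplier
    z10 = stats.norm.ppf(0.10)
    sigma_s = math.hypot(sigma, sigma_u)
    c10 = math.exp(-0.5 * sigma_s**2 + z10 * sigma_s)  # population 10th-centile ppu multiplier
    trend_t = config.secular_trend ** np.arange(n_months)
    # sensitivity of the per-1,000 savings outcome to the org multiplier runs
    # only through product cells currently priced above the reference:
    # h(m) = E[u 1{m u > c10}] for lognormal u
    if sigma_u > 0:
        h_sens = stats.norm.cdf(
            (0.5 * sigma_u**2 - math.log(c10) + np.log(multiplier)) / sigma_u
        )
    else:
        h_sens = (multiplier > c10).astype(float)
    denom = (lam[:, ~is_lp] * base_price[None, ~is_lp]).sum(axis=1)  # (n_orgs,)
    m_org = np.tile(multiplier[:, None], (1, n_months))
    if config.viewing_effect != 0.0:
        for i in np.nonzero(ever_viewed)[0]:
            t0 = first_view[i]
            delta_m = (
                config.viewing_effect
                * list_size[i]
                / (1000.0 * denom[i] * max(h_sens[i], 1e-6) * trend_t[t0:])
            )
            m_org[i, t0:] = np.maximum(multiplier[i] + delta_m, 0.05)

    # low-priority products keep the untreated multiplier: viewing changes
    # what an org pays for ordinary products, not its low-priority habits
    m_eff = np.where(
        is_lp[None, None, :],
        multiplier[:, None, None],
        m_org[:, :, None],
    ) * u_dev[:, None, :]

    # --- quantities, prices, costs
    qty = rng_qty.poisson(lam[:, None, :].repeat(n_months, axis=1))
    noise = rng_price.lognormal(
        -0.5 * config.price_noise_sd**2,
        config.price_noise_sd,
        (n_orgs, n_months, n_products),
    )
    unit_price = (
        base_price[None, None, :] * trend_t[None, :, None] * m_eff * noise
    )
    cost = qty * unit_price

    org_ix, month_ix, prod_ix = np.nonzero(qty > 0)
    prescribing = pd.DataFrame(
        {
            "org_id": org_ids[org_ix],
            "group_id": group_ids[org_ix],
            "month": np.array(months)[month_ix],
            "product_id": product_ids[prod_ix],
            "dose_id": "d0",
            "quantity": qty[org_ix, month_ix, prod_ix],
            "actual_cost": np.round(cost[org_ix, month_ix, prod_ix], 6),
        }
    ).sort_values(
        ["org_id", "group_id", "month", "product_id", "dose_id"], ignore_index=True
    )

    list_sizes = pd.DataFrame(
        {
            "org_id": np.repeat(org_ids, n_months),
            "month": np.tile(months, n_orgs),
            "list_size": np.repeat(list_size, n_months),
        }
    )

    pageviews = _simulate_pageviews(
        config, rng_views, org_ids, group_ids, months, ever_viewed, first_view, z
    )

    truth = pd.DataFrame(
        {
            "org_id": org_ids,
            "group_id": group_ids,
            "ever_viewed": ever_viewed,
            "first_view_month": [
                months[t] if t >= 0 else "" for t in first_view
            ],
            "baseline_inefficiency": multiplier,
            "true_effect": config.viewing_effect,
        }
    )
    return prescribing, list_sizes, pageviews, truth


def _simulate_pageviews(config, rng, org_ids, group_ids, months, ever_viewed,
                        first_view, z):
    """Monthly view counts per practice and feature, plus group-level sums.

    The price-per-unit feature drives the ground-truth exposure: the first
    qualifying month gets >=2 views, later months a Poisson stream whose rate
    rises mildly with inefficiency, and pre-exposure months may contain stray
    single views (which must not trigger exposure). Summary and low-priority
    views are nuisance traffic with no injected effect.
    """
    n_orgs, n_months = len(org_ids), len(months)
    t_start = config.view_start_month
    views = np.zeros((n_orgs, n_months, 3), dtype=int)  # features: summary, ppu, lp

    after_rate = 1.2 * np.exp(0.3 * z)
    for i in range(n_orgs):
        if ever_viewed[i]:
            t0 = first_view[i]
            stray = rng.random(t0 - t_start) < 0.15
            views[i, t_start:t0, 1] = stray.astype(int)
            views[i, t0, 1] = 2 + rng.poisson(2.0)
            if t0 + 1 < n_months:
                views[i, t0 + 1:, 1] = rng.poisson(after_rate[i], n_months - t0 - 1)
    summary_user = rng.random(n_orgs) < 0.6
    views[summary_user, t_start:, 0] = rng.poisson(
        1.0, (int(summary_user.sum()), n_months - t_start)
    )
    lp_user = rng.random(n_orgs) < 0.3
    views[lp_user, t_start:, 2] = rng.poisson(
        0.8, (int(lp_user.sum()), n_months - t_start)
    )

    feature_names = np.array(["summary", "ppu", "low_priority"])
    org_ix, month_ix, feat_ix = np.nonzero(views)
    practice_rows = pd.DataFrame(
        {
            "org_kind": "practice",
            "org_id": org_ids[org_ix],
            "month": np.array(months)[month_ix],
            "feature": feature_names[feat_ix],
            "views": views[org_ix, month_ix, feat_ix],
        }
    )
    group_rows = (
        practice_rows.assign(org_id=group_ids[org_ix], org_kind="group")
        .groupby(["org_kind", "org_id", "month", "feature"], as_index=False)["views"]
        .sum()
    )
    out = pd.concat([practice_rows, group_rows], ignore_index=True)
    return out.sort_values(
        ["org_kind", "org_id", "month", "feature"], ignore_index=True
    )


def simulate_null_with_trend(config: SimulationConfig):
    """Same panel with the viewing effect forced to zero (secular trend kept).

    Used to show that the univariable before/after estimator is biased by an
    active trend while the month-adjusted one is not.
    """
    return simulate_panel(replace(config, viewing_effect=0.0))
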