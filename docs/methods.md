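# Methods

## The evaluation design

The package evaluates a prescribing-feedback web service with observational
panel methods, at two organizational levels (practice, and practice data
aggregated to parent commissioning groups). Practices with a registered list
below 1,000 patients are excluded per organization-month (the rule is
re-assessed monthly, so an organization re-enters if its list grows — the
least destructive reading of a threshold stated without a time dimension).

Three monthly outcomes are computed per organization:

* **PPU available savings per 1,000 patients.** For each
  (month, product, dose) cell, each organization's price per unit is its
  pooled actual cost divided by pooled quantity (the quantity-weighted mean
  unit price, not a mean of sub-row ratios). The reference price is the
  10th centile of the per-organization PPU distribution in the cell,
  computed by linear interpolation between order statistics (numpy/pandas
  default; the original service's convention is unknown, so the centile and
  the convention are explicit parameters). Savings are
  max(0, ppu − ref) × quantity — clipped at zero because an organization
  already cheaper than the reference has nothing to save — summed per
  organization-month and scaled by 1000/list_size. Reference prices are
  computed over the organizational level being analysed, and include the
  index organization in its own cell (negligible for realistic n).
* **Mean measure percentile.** Measure ratios are numerator/denominator
  sums of quantity or cost over product selectors. Within each month a
  ratio is ranked across organizations as 100 × (rank − 1)/(n − 1), mean
  ranks for ties, oriented so higher = worse. The convention gives scores
  spanning 0–100 with a monthly mean of 50, matching how such scores are
  reported; it is switchable since the original is undocumented. Zero
  denominators skip that organization-month-measure (logged, not imputed);
  the summary score is the arithmetic mean over included measures.
* **Low-priority spend per 1,000 patients**: total actual cost over a
  configured product-pattern list. The list is configuration, not code: the
  real-world list is policy content that changes over time.

**Exposure.** The first month with **at least two** page views of the
organization's pages marks `month_first_viewed` ("more than one view",
within a single calendar month — single stray visits never trigger
exposure, and do not accumulate across months); later months are
`after_first_view`. View-count categories are zero plus tertiles of total
views among viewed organizations (all views count toward the total,
including pre-exposure single views); boundary ties go to the lower
tertile. The PPU and low-priority outcomes use views of their own feature
pages; the measure-score outcome uses all page views. Views outside the
analysis window are ignored.

**Analysis windows.** Each outcome has a feature launch month; the window
runs from 3 months before launch (the baseline) to the end of follow-up.
The between-effects analysis uses only the baseline months, with view
categories computed over the whole window.

## Estimators

`fit_fixed_effects` is the within estimator: exposure-status dummies
(reference `not_viewed`), optional full calendar-month dummies (reference:
first month), all demeaned within entity, then least squares. Coefficients
are identical to explicit entity-dummy OLS (verified against statsmodels to
1e−8 in the tests). Confidence intervals use conventional homoskedastic
standard errors with residual degrees of freedom reduced by the number of
absorbed entities, Student-t critical values; cluster-robust-by-entity
errors (CR1 small-sample correction, t with G−1 degrees of freedom) are
available via `cluster=True`. Rank deficiency after demeaning (e.g. every
entity exposed in the same month with month dummies present) raises an
error naming the involved columns, detected by pivoted QR.

`fit_between_effects` averages the outcome per entity and regresses on
view-category dummies by OLS. The reference is the zero-view category when
populated, otherwise the lowest populated tertile. An exactly saturated fit
(as many entities as parameters) returns the exact coefficients with NaN
standard errors and infinite intervals: the contrast exists, the residual
variance does not.

Unbalanced panels are supported throughout; a duplicate (entity, month) is
an error. `summarize_periods` reports pooled mean and sample SD (ddof = 1;
NaN for a single observation) per exposure level.

**Savings arithmetic.** Realized savings multiply the absolute adjusted
after-view change by the exposed organization-months' populations
(Σ list_size/1000 over `month_first_viewed` and `after_first_view` months);
a negative change in available savings is money saved. CI endpoints are
transformed identically and reported low-to-high on the savings scale.
National extrapolation scales the coefficient by every organization's mean
list size and 12 months/year. The achievable fraction is
100 × realized / (0.5 × available): roughly half of algorithmically
available savings are treated as practically attainable.

## The synthetic-data generator

`simulate_panel` emits a complete study with known ground truth. Structure,
with defaults chosen to mimic a national prescribing panel at desk scale:

* 20 groups × 10 practices × 18 months × 20 products; constant practice
  list sizes, lognormal around 5,500 patients (log-SD 0.45), 2% drawn
  small (300–999) to exercise the exclusion rule.
* Unit prices: national product price (lognormal, mean £1.00/unit,
  log-SD 0.5) × secular trend 0.99<sup>t</sup> (1%/month decline) ×
  organization multiplier m<sub>i</sub> (lognormal, mean 1, log-SD 0.20) ×
  per-(organization, product) deviation (lognormal, mean 1, log-SD 0.35) ×
  per-row noise (log-SD 0.05). The product-level deviation matters:
  organizations overpay on particular presentations rather than uniformly,
  so every organization keeps some savings headroom — with purely
  org-level multipliers, ~10% of organizations sit below the reference and
  an injected effect of realistic size is unattainable by construction.
* Quantities: Poisson with rate list_size × 1 item/patient/month ×
  an org-specific product mix (Dirichlet weights tilted per organization),
  giving both count noise and cross-organization ratio variation for the
  measures.
* Selection: the log-odds of ever being viewed are
  logit(0.4) + 1.0 × z<sub>i</sub>, with z<sub>i</sub> the standardized log
  inefficiency — less efficient organizations are likelier to be viewed, as
  observed in practice. First-view months are uniform over the feature
  window; the post-view monthly view rate rises mildly with inefficiency
  (0.3 z on the log rate), producing a monotone gradient across view
  tertiles. Stray single pre-exposure views occur (15%/month) and must not
  trigger exposure. Summary and low-priority page views are independent
  nuisance traffic; group-level rows are member-practice sums.
* Injected effect: from its first-viewed month, a viewed organization's
  org-level multiplier shrinks toward the cheap end by
  δ·L/(1000·Σ<sub>j∉LP</sub> λ<sub>j</sub>p<sub>j</sub>·h(m)·trend<sup>t</sup>),
  where h(m) = E[u·1{mu > c10}] restricts the sensitivity to product cells
  currently priced above the reference; recalibrated each month so the
  expected PPU outcome drop stays ≈ δ (default −40.42 per 1,000). Only
  non-low-priority products move: viewing changes what an organization pays
  for ordinary products, leaving the low-priority and measure outcomes
  null. `simulate_null_with_trend` is the same panel with δ = 0.
* One global seed drives every stage through spawned `SeedSequence`
  streams (structure, selection, views, quantities, price noise), so output
  is byte-identical per seed and stages are independently reproducible.

**What the generator does not emulate:** real product coding, seasonality,
practice births/deaths/mergers, serially correlated prescribing shocks,
list-size drift, or any behavioral response other than the injected price
step (the step, not a ramp, matches the three-level exposure coding).
Passing tests therefore validate the pipeline's statistical machinery, not
the clinical realism of any particular measure set.

## Known limitations

* **Trend × selection interaction.** The secular trend multiplies prices,
  so each organization's available savings decline in proportion to its own
  level, while the model adjusts for calendar time additively. When
  selection is active, viewed organizations have higher savings levels and
  hence steeper absolute declines; the month-adjusted estimate then
  overstates the true effect (≈ −47 to −51 for a true −40.42 under the
  defaults). Estimator-calibration tests (parameter recovery, null
  coverage) therefore run with selection off, isolating the injected
  effect; the selection property is tested separately. An evaluation of
  real data has the same vulnerability, which no calendar adjustment
  removes.
* **Inference under org-specific trends.** The same mechanism leaves
  serially correlated residuals, for which conventional SEs are too small;
  the trend-active null test uses the entity-clustered intervals the
  package provides.
* **Reference-price endogeneity.** Treated organizations lowering prices
  shift the empirical 10th centile for everyone; the common component is
  absorbed by month dummies but a small differential component attenuates
  estimates.
* The exposure is a proxy: page views cannot be attributed to the viewed
  organization's own staff.

## Problem sizes used by the test suite

Oracle-equivalence suites use randomized panels up to 20 entities × 12
months (50 draws) and 5-org × 3-product × 2-dose × 4-month prescribing
fixtures (100 draws). Parameter recovery averages 50 replicates of the
default 200-practice × 18-month study; null-coverage and selection suites
use 100 replicates each (50-practice × 12-month panels for coverage, the
default size for selection). The whole suite runs in well under two minutes
on one core.
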