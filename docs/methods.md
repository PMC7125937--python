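# Methods

## Model

`heatmort` estimates heat-attributable premature deaths on a grid as

```
deaths(cell, day) = pop(cell) · rate(day) · (RR(cell, day) − 1)
```

The attributable fraction is implemented literally as `RR − 1`; the
conventional epidemiological form `(RR − 1)/RR` is available through
`af_convention="rr_minus_1_over_rr"` for sensitivity analysis but is not
the default, because the default is the form the generalized-function
workflow was calibrated with. For RR close to 1 the two differ by a few
percent at most.

### Baseline mortality

An annual all-cause rate (deaths per person per year, default 0.0083 —
typical of the contiguous United States around 2010) is split across
months by twelve positive shares summing to one, and deaths are assumed
evenly distributed within each month. The daily rate on a day in month
*m* is therefore `annual_rate · share_m / days_m`; summed over the year
this reproduces the annual rate exactly, a conservation property the
tests assert.

### Generalized exposure-response function

City fits use ordinary least squares of RR on `(1, T, T²)` (variant A)
or of `RR − 1` on `(T, T²)` (variant B, forced through RR = 1 at T = 0),
restricted to samples at or above the optimal temperature. The hot-side
restriction is a deliberate choice: the generalization is defined for
heat exposure, and cold-side samples would distort the quadratic. The
coefficient-on-SMT regressions are unweighted OLS; each line is stored as
a (slope, x-intercept) pair and always evaluated as
`slope · (SMT − x_intercept)`.

Numerical notes:

* City fits use `numpy.linalg.lstsq`; designs with fewer than three
  distinct exceedance values raise a degenerate-input error rather than
  returning an ill-conditioned solution.
* An x-intercept is only defined when the regression slope is nonzero;
  slopes below `1e-12 · max(1, |intercept|)` raise a non-identifiability
  error.
* The clamp `RR ← max(RR, 1)` applies only on the hot side; below OT the
  function is identically 1, with no continuity correction needed since
  both branches equal 1 at T = 0 up to the (discarded) variant-A offset.
* Evaluations where SMT exceeds the quadratic term's x-intercept (30.9 °C
  for the primary preset) make the curve concave — risk eventually
  *decreasing* with temperature. These are evaluated as-is, never
  clamped above or rejected, and counted in run metadata
  (`smt_above_quad_xint`), since they are rare in realistic present-day
  climates but become more common in strongly warmed futures.
* Observed-curve lookups interpolate linearly between the 0.1 °C samples;
  temperatures above the tabulated range hold the last value (flat
  extrapolation) and are counted (`erf_lookup_above_range`); the cold
  side returns 1.

### Exposure fields

OT is the 84th percentile of the *full* daily temperature distribution
over a period (the percentile convention cited for minimum-mortality
temperatures refers to the annual distribution), computed with linear
interpolation between closest order statistics (the "type 7" convention);
the percentile and the convention are configurable. SMT is the plain mean
over June–August days. Periods are explicit decade windows, defaults
2010–2019 (reference) and 2090–2099 (future), and each period's fields
come from that period's own data. Cells with more than 5% missing daily
values fail loudly with the offending cell list.

OT ≥ SMT is typical but deliberately not asserted — in low-seasonality
climates the 84th annual percentile can fall below the summer mean.

### Adaptation scenarios

Five scenarios control which period's OT/SMT feed the RR evaluation:
`none` (reference OT and SMT), `smt` (future SMT, reference OT — risk
curves flatten as summers warm), `lagged_ot` (average of the baseline
response and the 100%-shifted-OT response), `both_lagged`, and
`both_nonlagged`. The lagged average is applied to *responses* (death
fields from two full engine runs with weights ½, ½), not to the OT field
itself; averaging the fields instead is available as a sensitivity switch
(`average_fields`) and, because the engine is nonlinear in OT, gives
slightly different totals. The half-change weight generalizes to a
`lag_fraction` parameter; values other than 0.5 are explicitly
experimental. Under `smt` adaptation the OT stays at reference values:
adaptation there changes the curve's shape, not the threshold. In the
`both_lagged` scenario only OT is lagged; SMT adapts fully.

### Uncertainty

Fractional error sources assumed independent combine in quadrature. The
default components are the generalization bias 0.14 (the mean absolute
relative error of generalized-vs-observed evaluations) and 0.35 for the
ERF and temperature-projection uncertainty of summed multi-city
estimates; they combine to 0.377, reported as 38%. Confidence intervals
are `central · (1 ± combined)` with each bound rounded (half away from
zero) to a granularity of 1,000 deaths for national totals. The 0.35
component is a configured constant taken from the source epidemiology,
not recomputed. No Monte-Carlo propagation of coefficient uncertainty is
attempted; the published workflow uses scalar fractions.

## Synthetic data

The generator emulates the statistical structure of the real inputs so
the whole pipeline is testable without external downloads:

* **Daily temperature** — per cell: annual-mean surface (default a
  south-to-north gradient, 19 °C down to 12 °C), a sinusoidal seasonal
  cycle peaking mid-July (day 196; amplitude default 9 °C), a linear
  warming trend in °C/decade measured from a fixed reference year (so
  disjoint decades generated separately sit on one trajectory), and AR(1)
  noise with stationary standard deviation 3 °C and lag-1 correlation
  0.7 — typical midlatitude daily residual statistics. Defaults put
  summer means in roughly 20–27 °C, matching the range spanned by the ten
  benchmark cities. A 365-day no-leap calendar is used throughout.
* **City curves** — sampled at 0.1 °C increments from OT to OT + 10 °C
  from a *known* generalized quadratic (defaults: the primary published
  constants) at the ten benchmark SMTs, plus optional i.i.d. Gaussian RR
  noise truncated at RR ≥ 0. Since the synthetic spec carries no
  independent OT, the curve's OT is set to SMT + 2 °C; only `temp − OT`
  enters any fit, so the choice is inert.
* **Population** — lognormal cell weights apportioned to an exact integer
  total by largest remainder (default 320 million).
* **Monthly mortality weights** — month lengths scaled by a cosine
  peaking mid-January with fractional amplitude `winter_excess`
  (default 0.15, a typical Northern-Hemisphere winter excess). This is a
  stylized stand-in; the observed monthly weights behind the real
  analysis are not public as a printed table.
* **Region masks** — contiguous latitude-band "states" and one grid cell
  per city box.

What the generator does **not** emulate: spatial correlation of weather
across cells (cells are independent AR(1) draws), real coastlines or
geography, humidity or heat-index effects, demographic structure, and
any spatial redistribution of population over the century (population
growth is a single national factor per decade, default 1.4 for the
2090s). Passing tests therefore demonstrate the correctness of the
machinery and the internal consistency of the method, not the accuracy
of any specific national death estimate.

## Problem sizes

The test suite and worked examples run on deliberately small fixtures:
grids of 4×4 to 6×6 cells with 2–5-year windows for unit and invariant
tests, and a 20×20 grid with two full decades (reference plus a future
decade carrying +4 °C of summer warming) for the end-to-end projection
exercising all five adaptation scenarios. At these sizes the whole suite
completes in seconds while every code path — generation, fitting,
exposure, projection, aggregation, uncertainty — runs unmodified.

## Known limitations

* The generalization is accurate for large-scale sums, not for single
  locations: city-level biases of tens of percent are expected and are
  part of the uncertainty budget, not a defect the code tries to fix.
* The quadratic shape cannot represent risk curves that bend downward
  near their hottest observed temperatures (the warm-coastal pattern);
  such shapes are retained as data but fit imperfectly.
* Cold-related mortality is out of scope; the engine never counts days
  below OT.
* Confidence intervals are symmetric scalar fractions; correlated errors
  across cities or asymmetric likelihoods are not modelled.
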