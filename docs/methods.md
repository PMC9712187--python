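# Methods

## Model overview

`upfburden` implements a comparative risk assessment (CRA) of the
cardiovascular disease burden attributable to ultra-processed food (UPF)
intake, where exposure is the share of total dietary energy contributed
by UPF (% energy). The model has three stages:

1. **Exposure.** Each age–sex stratum's intake is a log-normal
   distribution moment-matched to the stratum mean and SD of the UPF
   energy share, truncated to (0, 100] % and renormalised.
2. **Dose–response.** Each outcome (ischaemic heart disease, stroke) has
   a log-linear relative-risk curve anchored at RR = 1 at the
   theoretical minimum risk exposure level (TMREL, default 0 % energy)
   and at a pooled meta-analytic RR at a reference intake (default
   22.0 % energy: RR = 1.29 [1.12–1.48] for CHD, 1.34 [1.07–1.68] for
   stroke). Above the reference intake the same log-linear slope is
   extrapolated to 100 %.
3. **Impact.** For each outcome o and stratum (a, s), the potential
   impact fraction of shifting the exposure density P(x) to a
   counterfactual P′(x) is

   PIF_oas = [∫₀^m RR_oa(x)P_as(x)dx − ∫₀^m RR_oa(x)P′_as(x)dx] / ∫₀^m RR_oa(x)P_as(x)dx

   with m = 100 % energy. Attributable events are PAF × baseline events
   (PAF = PIF against a point mass at the TMREL); averted events under a
   scenario are PIF × baseline events. Cells are summed over age bands
   within sex, over sexes, and over the two outcomes to total CVD,
   separately for deaths, incident cases and DALYs.

The model is static: it has no time dimension, no lag between exposure
change and risk change, and no recurrence of events. Only ages 30–69
(premature events) are modelled; loaders reject rows outside that range
outright rather than dropping them silently.

## Counterfactual scenarios

* `proportional_reduction(r)` — every individual's intake scales by
  (1 − r); for a log-normal this shifts the log-location by ln(1 − r)
  and preserves the coefficient of variation. r = 1 collapses to a
  point mass at zero intake, in which case averted = attributable
  exactly (verified as a test invariant).
* `first_quintile` — each stratum's distribution is truncated at its own
  20th percentile and renormalised: everyone adopts the intake pattern
  of the current bottom quintile. The phrase "reduced to the first
  quintile" admits a second reading — every individual placed exactly at
  the bottom-quintile mean — which is available as
  `mode="point_mass_q1_mean"`; the truncation reading is the default
  because it preserves within-quintile heterogeneity rather than
  inventing a degenerate distribution.

## Numerical choices

* **Quadrature.** ∫RR·P is evaluated by composite trapezoid on a
  uniform grid with step 0.1 % energy (matching the resolution at which
  the RR curve is conventionally tabulated) over [0, min(support, m)].
  For smooth log-normal densities the numerator/denominator errors
  cancel in the PIF ratio and the result agrees with a 0.001 %-step
  reference to ~1e-8 relative. A truncated density (first-quintile
  counterfactual) has a jump at the cut point that destroys this
  cancellation (~5e-4 relative at step 0.1), so truncated supports are
  integrated on a 10× refined grid aligned to end exactly at the cut,
  restoring ~5e-6 agreement. Point masses bypass quadrature entirely
  and use the closed form PIF = 1 − RR(x′)/RR(x), avoiding
  delta-function discretisation artefacts.
* **Exposure support.** Mass above 100 % energy (≲1e-5 for realistic
  parameters) is truncated and renormalised. Moment matching is exact
  for the untruncated parent; truncation perturbs means/quantiles at
  the 1e-5–1e-3 relative level depending on (mean, CV), which tests
  account for by comparing against analytic truncated-log-normal
  moments.
* **Rounding.** Nearest-hundred, half away from zero, applied only in
  reporting columns/printout — never inside computation. Percentage
  shares are integers, half-up, with denominators kept alongside.

## Uncertainty propagation

Monte Carlo with n = 5,000 draws by default (configurable), one seeded
`numpy` generator, reporting the median and 2.5th/97.5th percentiles per
aggregate. Per iteration the engine draws:

* one pooled RR per outcome from a log-normal whose 95 % interval
  matches the published CI (log-SD = CI log-width / 3.92) — shared
  across strata within the iteration, matching the common meta-analytic
  parameter;
* one count per event row from a normal matched to the 95 % UI
  (SD = width / 3.92), truncated at zero. GBD-style intervals carry no
  shape information, so a symmetric family is the neutral choice;
  prevalence/incidence uncertainty enters the model only through these
  event counts, and the corresponding config flag is an alias for
  event perturbation;
* one mean per stratum from a normal with the supplied standard error,
  truncated to (0, 100); the stratum SD is held fixed (survey design
  effects are not modelled).

Each draw re-runs the identical deterministic core, so disabling all
perturbation flags reproduces the deterministic run exactly and output
is a pure function of (inputs, seed, n_draws). The median — not the
mean — is the central estimate, consistent with reporting practice for
CRA uncertainty intervals.

## Deterministic sensitivity analyses

Six alternative parametrizations re-run the pipeline: TMREL raised to
10.0 % (±4.1) or 12.0 % (±5.0) of energy; reference intake moved to
20.0 % (±8.2) or 24.0 % (±10.6); pooled RRs scaled by 0.9 or 1.1. The
"±SD" components are carried as scenario metadata only — the central
threshold is what re-anchors the curve, as nothing in the anchor
construction consumes a spread. Because the PIF is monotone in the RR,
a 10 % higher RR must *increase* attributable events (our runs:
roughly +30 % on the synthetic bundle); published CRA tables have been
known to transpose the ± labels on this row, so the package asserts the
monotone direction rather than any particular printed sign.

## Synthetic study population

The generator emulates the *structure* of a national dietary survey and
GBD-style burden tables, not any real dataset: 8 five-year age bands
(30–69) × 2 sexes; intake means declining linearly with age from 21 %
to 13 % of energy with CV 0.45 (population-weighted mean ≈ 17 %);
populations declining 6 % per band from 8.6 M with a slight female
excess; event rates per 100k doubling every 10 years of age, male excess
for CHD, with mild log-normal jitter (SD 0.08) so counts are not exactly
collinear with age; symmetric 95 % UIs at ±20 % of the value. Defaults
were chosen once as field-plausible magnitudes; the scenario *fractions*
(averted/attributable) are insensitive to the absolute scales, which is
what makes them a meaningful recovery check (they land at 11 %, 22 %,
53 % for 10/20/50 % reductions, and ~53 % for the first-quintile
counterfactual under the truncation reading).

What the generator does **not** emulate: survey weighting and design
effects, usual-intake measurement-error correction, asymmetric GBD
intervals, correlation between intake and event rates beyond the shared
age structure. Passing recovery tests therefore demonstrate numerical
correctness of the pipeline on distributions of the assumed family, not
robustness to real-data pathologies.

Ground truth ships with each bundle, computed by an independent oracle:
`scipy.stats` frozen distributions integrated at a 0.001 % step, sharing
no code with the PIF engine. Deterministic pipeline totals must match
it to 1e-4 relative; Monte Carlo medians to 2 % at n = 5,000. A
Monte-Carlo *integration* cross-check (10⁶ common-random-number
exposure draws) is also run, at a 1e-3 relative tolerance set by the
sampling noise of that estimator at that draw count.

## Problem sizes and determinism

Default runs use 16 strata × 2 outcomes × 3 metrics (96 event rows),
1,001-point integration grids, and 5,000 Monte Carlo draws (~1 min on
one core; the heaviest test uses exactly this). All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; reruns
with the same manifest are bit-identical.

## Known limitations

* The log-normal exposure family is an assumption; survey documentation
  describing a "log-linear" mean/SD summary does not pin down a family,
  and only two moments are available to fit.
* Log-linear extrapolation of the RR beyond the 22 % anchor is the only
  slope-preserving continuation but is unvalidated above the range of
  the underlying cohort evidence.
* Symmetric normal event-count draws understate the right skew typical
  of GBD uncertainty intervals.
* The first-quintile scenario's published counterpart could not be
  confirmed analytically under either reading of the wording; it is
  reported but not used as a calibration point.
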