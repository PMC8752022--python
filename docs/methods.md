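# Methods

`mhecosim` assesses how a workforce policy — moving or hiring full-time
equivalent (FTE) professionals in community mental-health centres — is
expected to change the performance of a regional mental-health care
ecosystem. The ecosystem is a set of catchment areas (decision-making units,
DMUs), each described by its adult population, outpatient utilization
(frequentation), inpatient activity (days of stay, discharges, readmissions),
outpatient service availability and workforce rates. The reference system is
the 13-area ecosystem of Gipuzkoa (Basque Country, Spain).

The analysis chains four components:

1. **Structural regression.** Expert-identified causal relationships between
   care variables are fitted with two log-linearizable families:
   exponential, `y = α·exp(β·z)`, and product-unit (power law),
   `y = α·x₁^β₁·…·x_p^β_p`. Fitting is least squares on the log scale.
2. **Causal network.** A time-layered DAG orders decisions (time *t*:
   workforce, availability, population) before their short-lag consequence
   (*t+t₁*: frequentation) and long-lag consequences (*t+t₁+t₂*: stay,
   discharges, readmissions). Fitted models are attached to downstream nodes.
3. **Uncertainty propagation.** After applying the policy's FTE deltas, each
   downstream variable is replaced by a uniform distribution whose limits are
   the attached model's 95% prediction interval at the parents' current
   values.
4. **Monte Carlo DEA.** 500 replicates sample every cell independently from
   its uniform interval and score all areas with variable-returns-to-scale
   (BCC) data envelopment analysis under one or both orientations. Replicate
   scores are aggregated into five indicators: mean RTE, P(RTE > 0.75), RTE
   error, stability and Shannon entropy, reported per area and globally, pre
   and post policy.

## Regression details

- Exponential fits regress `ln y` on `[1, z]`; product-unit fits regress
  `ln y` on `[1, ln x₁, …, ln x_p]`. Both run through ordinary least squares
  (optionally weighted, which recovers a generalized-least-squares variant if
  a weighting is ever specified); no iterative fitting on the original scale
  is attempted.
- 95% confidence intervals use the t distribution with `n − p − 1` degrees of
  freedom on the linearized scale; α's interval is the exponential of the
  intercept's interval. α's point estimate is the plain back-transform
  `exp(intercept)` without smearing correction.
- R² and the F statistic are reported on the linearized scale (they satisfy
  `F = R²/(1−R²)·(n−p−1)/p` exactly); a diagnostic R² on the original scale
  is stored alongside.
- Prediction intervals (for a *new observation*, not the mean) define the
  propagation bounds, because the propagated uncertainty concerns the
  dependent variable itself. They are recomputed from stored sufficient
  statistics — coefficients, `(X'X)⁻¹`, residual variance `σ²`, degrees of
  freedom — so a deserialized model predicts identically without refitting.
- Degenerate fits (zero residuals, or `n = p + 1`) return R² = 1 with an
  infinite-F sentinel and zero-width intervals rather than erroring.
- Model selection (`select_best`) minimizes residual variance on the
  linearized scale; ties break on fewer parameters, then declaration order.

### Composite regressors and scaling

Frequentation and stay respond to a *composite* regressor: population ×
workforce headcount, the product of the care demand and supply factors.
Because only dimensionless fit statistics pin down such relationships, the
scale of the composite is a modelling convention. This package uses
population in **tens of thousands of adults × FTE headcount**
(`composite_pop_divisor = 10 000`, configurable), chosen so that the shipped
structural coefficients reproduce realistic magnitudes across the whole
population range (see generator calibration below). The discharges composite
is frequentation (raw visits) × headcount divided by 1 000. All scale choices
live in `VariableTransform` objects stored inside each fitted model, so
every downstream consumer applies them consistently. R², product-unit
exponents and the frequentation α are invariant to these divisors.

## Synthetic ecosystem generator

The generator emulates the statistical structure the analysis assumes, so
the full pipeline runs and is testable with no external data:

| parameter | default | meaning |
|---|---|---|
| `n_areas` | 13 | catchment areas (mirrors the reference ecosystem) |
| `population_range` | (21 593, 78 400) | uniform adult population per area |
| `availability_range` | (1.25, 4.53) | outpatient services per 100 000 adults |
| workforce law | `2.381·e^(0.0196·Pop/1000)` | FTE headcount vs population |
| frequentation law | `5.7767·e^(0.0196·composite)` (thousands of visits) | outpatient visits |
| stay law | `433.39·e^(0.0204·composite)` (days) | inpatient days of stay |
| discharges law | `5.372·(Freq·FTE/1000)^0.5697` | inpatient discharges |
| `noise_sigma` | 0.12 | sd of multiplicative lognormal noise (log scale) |
| `readmission_rate` | 0.083 | mean readmissions per discharge |
| `readmission_dispersion` | 4.0 | negative-binomial size parameter |

Choices and rationale:

- **Lognormal noise** matches the log scale of all structural fits and keeps
  every generated quantity positive. `noise_sigma = 0.12` makes the log-scale
  residual variance of the frequentation fit consistent with an R² near 0.92
  given the observed dispersion of frequentation across areas.
- **Readmissions** carry no structural model (no statistical relationship to
  outpatient provision exists); they are drawn negative-binomially with mean
  `0.083 × discharges` and dispersion 4 — parameters consistent with a mean
  near 6 readmissions per area and a variance well above Poisson — then
  truncated at the discharge count. By construction they are independent of
  availability.
- **Profession mix**: psychiatrist, psychologist and nurse rates are fixed
  shares (5.93 : 2.11 : 3.93 of a 13.89 total) of the total per-100k rate.
- **Calibration of the composite divisor**: with the divisor at 10 000, the
  noise-free laws evaluated across the population range give frequentation
  ≈ 6 700–31 600 visits, stay ≈ 500–2 500 days and discharges ≈ 33–151 —
  bracketing the reference system's observed ranges. The divisor is fixed
  once in the defaults and is not a tuning knob of the analysis.
- With 13 areas the generator uses the real Gipuzkoa area names so the
  shipped policy applies out of the box; other sizes get `area_NN` labels.

What the generator does *not* emulate: spatial correlation between areas,
year-to-year dynamics, heterogeneous profession mixes, or outliers beyond
lognormal tails. Passing tests therefore demonstrate correctness of the
machinery and calibration of its statistics under the stated data-generating
process, not conclusions about any real ecosystem.

## Causal network and propagation

Topology (12 edges): population → workforce; {population, workforce} →
frequentation; {availability, population, workforce} → stay;
{availability, frequentation, workforce} → discharges;
{availability, stay, workforce} → readmissions. Acyclicity and time-layer
ordering (edges never point to an earlier layer) are validated on every
build and mutation.

- Decision and exogenous variables (layer *t*) receive degenerate bounds
  `[v, v]`; they are under managerial control, not model uncertainty.
- Modelled nodes store their prediction-interval bounds; the *midpoint*
  `(lo+hi)/2` feeds deeper layers. Deterministic midpoint chaining keeps
  propagation a pure function; nested sampling of parent uncertainty is a
  documented extension point, off by default.
- Stay can be driven either by the composite model or by the availability
  power law; by default `select_best` decides (the composite form fits
  better on both reference and synthetic data). Note the composite stay
  model has a *positive* exponent — more outpatient activity propagates
  into longer total stay — which runs against the balance-of-care
  expectation that outpatient reinforcement shortens inpatient stay. The
  pipeline propagates the fitted sign and emits a warning instead of forcing
  the expected direction.
- Readmissions, lacking a model, keep their observed value ± a 10% relative
  half-width (configurable), identical pre and post policy.
- Psychiatrist-specific interventions also move the total-professionals
  headcount one-for-one, and per-100k rates are recomputed from headcounts.

## DEA

The BCC envelopment program is solved per area with HiGHS (via
`scipy.optimize.linprog`): input orientation minimizes the radial input
contraction θ; output orientation maximizes the expansion φ and reports
1/φ so both orientations share the (0, 1] scale. Numerical choices:

- cells below `1e-6 ×` their column mean are floored there before solving
  (zero inputs make the envelopment LP degenerate); floor events are logged;
- solver feasibility tolerances 1e-9; scores are clipped into [0, 1] with
  clipping logged (observed clip magnitudes are ~1e-10 rounding);
- efficient DMUs (score 1) canonically report themselves as their own peer —
  λ = self is always an optimal solution at score 1;
- the per-area programs are independent, so `rte_all` batches them into one
  block-diagonal LP call (identical results, verified against per-area
  solves; roughly 7× faster at 13 DMUs).

## Monte Carlo engine and indicators

One seeded RNG stream is consumed replicate-major: the whole table is drawn
before any scenario is scored, so adding scenarios never perturbs earlier
draws. Cells are sampled independently (the propagation step specifies only
marginal uniform distributions); cross-variable correlation injection is an
extension point. Pre- and post-policy runs share the same seed (common
random numbers), making the pre/post difference a paired comparison.

Indicator definitions (defaults in brackets):

- **mean RTE**: arithmetic mean over replicates × scenarios (× areas for the
  global row), per orientation.
- **P(RTE > 0.75)** [threshold 0.75]: fraction of replicate × scenario
  scores strictly above the threshold.
- **RTE error**: standard error of the replicate-mean RTE,
  `sd(replicate means)/√R`.
- **Stability** [δ = 0.05]: per area × scenario, the percentage of
  replicates whose score lies within ±δ of the replicate median, averaged;
  100% when scores never move. Even-length medians use the *lower middle
  order statistic* — a fixed, documented convention.
- **Shannon entropy** [10 bins]: replicate scores are binned equal-width
  over [0, 1]; `H = −Σ p ln p` over nonempty bins, normalized by the
  feasible maximum `ln(n_bins)` and averaged; an alternative normalization
  by `ln(#occupied bins)` sits behind a flag. 0% = all scores in one bin
  (homogeneous management), 100% = uniform fill.

Stability and entropy are this package's operationalizations of those
indicator names; published values computed with other proprietary formulas
are not comparable beyond range, endpoint and direction-of-change behaviour.

Percent variations in comparison reports are always computed on unrounded
indicator values; display rounding (2 decimals for RTE-scale values, 4 for
RTE error) happens only at rendering. A zero pre value yields an
undefined-variation flag (NaN), never a division error.

## Problem sizes and reproducibility

The default study configuration — 13 areas, 15 scenarios, 500 replicates,
input orientation — solves 97 500 envelopment LPs in well under a minute on
one CPU; test-suite simulations use the same configuration where the check
concerns the study scale and smaller replicate counts elsewhere. All
randomness descends from a single manifest seed: the generator consumes it
directly and the MC engine uses `(seed + 1) & 0x7fffffff`. Identical seeds
reproduce tables, scores and reports bit-for-bit.

## Known limitations

- The causal network supports structural propagation only — no conditional
  probability tables or belief propagation.
- Propagation chains midpoints rather than full parent distributions.
- The uniform-interval sampler ignores cross-variable correlation within a
  replicate.
- Scenario compositions are configurable stand-ins; the indicator values of
  any specific real-world study depend on its (often unpublished) scenario
  designs.
- No confounding adjustment: the fitted relationships formalize expert
  claims statistically; they are exploratory, not causal identification.
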