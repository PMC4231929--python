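# Methods

## The model

`crabrisk` estimates the commercial shellfish harvest value that Puget Sound
(Washington State, USA) could lose if the European green crab, *Carcinus
maenas*, establishes in its nearshore harvest grounds. This is a
*value-at-risk* analysis: a statement of what could plausibly be lost under
stated scenarios, not a prediction of expected loss.

The ecological core is a static bioenergetic consumption kernel. For one
shellfish species group (hardshell clams, oysters, or mussels), the biomass
consumed by crabs in one year is

    consumption (kg/yr) = Area x Den x Cal x Diet / CalKg

where

| symbol | meaning | unit | default |
|---|---|---|---|
| `Area`  | commercial harvest ground | km² | 523.71 ± 75 (uniform) |
| `Den`   | adult crab density | crabs km⁻² | 10,000 / 50,000 / 100,000 |
| `Cal`   | annual calorie intake per crab | cal crab⁻¹ yr⁻¹ | calibrated (below) |
| `Diet`  | fraction of one crab's diet that is the focal species | — | 0.20–0.35 (uniform) |
| `CalKg` | calorie density of landed wet weight | cal kg⁻¹ | per species (below) |

The model is static (no time dynamics), spatially homogeneous (one pooled
harvest ground), and ignores prey switching, recruitment feedbacks and any
density–intake correlation (high crab densities plausibly depress per-crab
intake through competition; the scenario grid spans that possibility instead
of modelling it).

## Uncertainty scheme

Two mechanisms, by the width of the underlying data range:

* **Scenarios** for the two widest-ranging parameters. `Den` takes low /
  medium / high values (10⁴ is the native-range average, 10⁵ a native-range
  maximum; invaded ranges can run higher). `Cal` takes low / medium / high
  per-species values. Both are held fixed inside a cell, giving a 3 × 3 grid.
* **Randomisation within scenarios** for the narrower ranges: `Area`, `Diet`
  and `CalKg` are drawn independently from uniform distributions, 10,000
  times per cell by default, with a seeded `numpy` generator.

Each cell reports the sample mean and the 2.5th–97.5th percentile band of the
consumption distribution. With uniform *input* ranges rather than sampling
error, a standard-error-of-the-mean interval would shrink toward zero with
`n_reps` and carry no information; the percentile band is the quantity that
can support the published-style uncertainty envelopes. Uniform draws are
implemented as `lo + (hi − lo) · u` so that, at a fixed seed, widening a
range rescales the same variates monotonically — intervals can only widen.

Post-invasion harvest is `max(0, baseline − mean consumption)`; biomass loss
is capped at the species baseline (removing the harvest, not the species),
and revenue is assumed to fall in parallel with harvested biomass, so the
revenue loss fraction equals the biomass loss fraction per species. Mean
consumption (not a band edge) drives the headline outcome; the band is
reported alongside.

Species diets are sampled independently, so the implied joint diet can
nominally exceed 1 (3 × 0.35 = 1.05); this mirrors the per-species treatment
of the source analysis and slightly overstates joint consumption in the
extreme tail.

## Calorie densities (energetics)

Literature values give flesh energy as cal per mg of ash-free dry weight
(AFDW): clams 6.15, oysters 4.85, mussels 5.47 cal mg⁻¹. AFDW:wet-weight
conversions (clams 5.2–6.4, oysters 1.7, mussels 2.5–6.7) are interpreted as
**AFDW as a percent of wet weight**, so

    CalKg = cal/mg AFDW x (percent/100) x 1e6 mg/kg

giving, e.g., oysters a fixed 82,450 cal kg⁻¹ and mussels 136,750–366,490
cal kg⁻¹. The direction of the conversion is not fixed by the sources; the
percent reading is the documented assumption here. Its absolute scale is
absorbed by calibration: doubling all `CalKg` midpoints exactly doubles every
calibrated `Cal` and leaves forward losses unchanged (tested).

## Calibration of per-crab intake

The low/medium/high `Cal` values were never published, but the kernel is
linear in `Cal`, so published scenario losses identify it. At central
parameter values (`Area` and `Diet` at range midpoints, `CalKg` at the
species-range midpoint — the expectation of each uniform),

    Cal = loss_kg x CalKg / (Area x Den x Diet).

For each (species, calorie level) the three published density cells are
combined by least squares through the origin of `loss = k · Den`
(`k = Σ d·l / Σ d²`), because the published cells are rounded to 0.01 × 10⁶
kg. Cells whose published post-invasion harvest is zero are *floored*: they
censor the loss (a lower bound on intake only) and are excluded; if every
cell of a group is floored, calibration fails with an error naming the group.
On noiseless synthetic loss tables the procedure recovers the true intakes to
machine precision (the linear system is exactly identified), which is the
calibration module's primary correctness check.

**Finding: the published scenario table is internally inconsistent with the
kernel.** In the published table the low- and high-density cells of every
species sit close to a common `loss ∝ Den` line (ratio ≈ 1:10), but the
medium-density cells for clams and mussels fall far below it (e.g. clams at
the medium calorie diet: losses 0.11 / 0.17 / 1.13 × 10⁶ kg at densities
1 : 5 : 10 — the medium cell "should" be ≈ 0.55). Oyster rows are consistent.
Consequences, all deliberate behaviour of this package:

* no single intake per (species, calorie level) can reproduce every
  published cell to its printed rounding; the corresponding acceptance test
  is parametrised per row and fails for the inconsistent rows by design;
* the least-squares fit is dominated by the (mutually consistent) high
  density cells, so forward-simulated medium-density totals overshoot the
  published medium-column totals;
* with the floored mussel high/high cell excluded, the fitted mussel intake
  is *not* strictly increasing across calorie levels (high ≈ 11.6k < medium
  ≈ 13.8k cal/yr); `calibrate_levels` emits a `CalibrationWarning` rather
  than failing, and `ScenarioLevels.calories_monotone()` exposes the check.

Quantities derived *directly* from the published table (loss fractions, the
economic cascade) are unaffected by this inconsistency.

## Economic cascade (benefit transfer)

Secondary values for Puget Sound shellfish are unavailable, so they are
transferred from British Columbia's 2005 shellfishery: harvesting 139,
processing 71, distribution 32, labour income 95 (USD M), employment 2,580
person-years. With `scale = ps_harvesting / 139`:

* processing = 71 · scale (the 51% harvesting:processing margin ratio),
* distribution = 0.15 · (harvesting + processing),
* labour and employment = BC value · scale.

A scenario revenue-loss fraction `L` scales harvesting, processing, labour
and employment by `(1 − L)`; distribution is recomputed from the scaled
components, which makes it scale by exactly `(1 − L)` too (an invariant
tested for every reported cascade). Losses compose multiplicatively:
applying `a` then `b` equals applying `1 − (1−a)(1−b)`. Employment is kept
as an unrounded float internally and rounded to whole person-years only in
reports and summaries. No currency (CAD 2005 → USD 2009) or inflation
adjustment is applied — the transfer uses ratios directly, reproducing the
source procedure.

The pipeline's harvesting value is the exact sum of the canonical species
revenue totals, $37.25 M. (The published grand-total row prints $37.26 M,
which does not equal the sum of its own published species rows; the exact-sum
convention is used everywhere, and every downstream quantity agrees with the
published values within their printed rounding either way.)

## Sensitivity surface

To cover parameter combinations between grid cells, `Den` and `Cal` range
freely and uniformly from 0 to their high estimates (`Cal` high = the maximum
calibrated high-level intake across species; one common intake axis for all
species). The *total* diet fraction on harvested shellfish spans 0.60–1.00
and is split equally across the three species groups — the symmetric default,
configurable, since no species split is published. Each of 10,000 samples
draws density, intake, total diet, area and per-species `CalKg`; per-species
consumption is capped at the species baseline (consistent with the grid's
floor) and summed. With all bounds collapsed to fixed values the surface
kernel equals the scenario grid's cell total (tested).

## Synthetic data

The generator produces study-shaped inputs with known truth, for tests and
parameter-recovery experiments; it emulates structure, not the actual data:

* per-area biomass is log-uniform around a per-species geometric scale
  (defaults 3.5 × 10⁵ / 1.5 × 10⁵ / 5 × 10⁴ kg for clams/oysters/mussels,
  dispersion ± 0.75 decades), because the real per-area biomass spans about
  two orders of magnitude; grand totals land within a factor of ~3 of the
  real 6.046 × 10⁶ kg for ≥ 95% of seeds (tested over 120 seeds);
* prices are uniform within per-species ranges matching the real spread;
* revenue is *exactly* price × biomass, making the revenue invariant strict
  where the published table is internally inconsistent;
* synthetic loss tables come from the forward kernel at central parameters
  with known true intakes, floored at species baselines with the censoring
  flag set.

What passing synthetic tests do **not** show: anything about unmodelled
features of real invasions — spatial refuges, prey switching, recruitment
feedbacks, density-dependent intake, or reporting error in real landings
statistics.

## Numerical and design choices

* One seeded `numpy.random.Generator` per grid call; cells are evaluated in
  fixed (species, density, calorie) order, so results are independent of
  evaluation laziness and bit-reproducible given the seed.
* Percentiles use `numpy.percentile` linear interpolation; the band is
  clamped to contain the mean (interpolation can differ by one ulp on
  near-constant samples).
* Degenerate inputs: zero-width uniform ranges collapse the MC exactly onto
  the deterministic kernel; zero intake or zero density give exactly zero
  consumption; `CalKg = 0` is a domain error; a zero total harvest makes the
  average price undefined and is signalled explicitly.
* Default problem sizes — 10,000 replicates × 27 cells plus 10,000 surface
  samples — were chosen to match the source design and run in well under a
  second on one CPU (vectorised kernels), so no reduced "test mode" exists.
* Monetary values are stored in USD (cascade in USD M), biomass in kg;
  display formatting converts to the 10⁶ units used in reports.

## Known limitations

* The calibrated intakes inherit the internal inconsistency of the published
  scenario table (above); medium-density forward simulations overshoot the
  published medium column, and the mussel intake ordering is non-monotone.
* The AFDW-percent interpretation of the wet-weight conversions is an
  assumption; only ratios of losses are insensitive to it pre-calibration.
* Benefit transfer assumes BC's value ratios apply unchanged to Puget Sound
  and that employment scales linearly with revenue.
* The model excludes price elasticity, recreational and cultural harvest
  value, and ecosystem-service effects (filtration, eutrophication), so the
  monetary value-at-risk is an underestimate of total value exposed.
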