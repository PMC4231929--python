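# crabrisk

Value-at-risk for Puget Sound's commercial shellfish harvest under invasion
by the European green crab, *Carcinus maenas*.

Green crab is a generalist predator that feeds heavily on bivalves and has
damaged shellfisheries in every region it has invaded. It has not yet
established in Puget Sound, whose hardshell clam, oyster and mussel harvest
was worth about $37 M in landed revenue in 2009. `crabrisk` asks: if it
arrives, how much harvest biomass, revenue, secondary economic value and
employment could plausibly be lost? The answer is a value-at-risk — a range
under explicit scenarios — not a prediction.

The package is aimed at invasion ecologists and resource economists who want
a reproducible, tested implementation of this style of pre-invasion
assessment, with every parameter overridable.

## The model

Annual consumption of one shellfish species group by the invading population:

    Consumption = (Area × Den × Cal × Diet) / Cal kg⁻¹

with harvest area *Area* ~ U(523.71 ± 75) km², crab density *Den* ∈
{10⁴, 5·10⁴, 10⁵} km⁻² (low/medium/high scenarios), per-crab annual intake
*Cal* at three calibrated per-species levels, per-species diet fraction
*Diet* ~ U(0.20, 0.35), and the calorie density of landed wet weight
*Cal kg⁻¹* ~ U(species range) derived from cal mg⁻¹ ash-free dry weight and
AFDW:wet-weight conversions. Area, Diet and Cal kg⁻¹ are resampled 10,000
times per scenario cell (seeded); each cell reports mean consumption and the
2.5–97.5 percentile band. Post-invasion harvest is the baseline minus mean
consumption, floored at zero, with revenue falling in parallel with biomass.

Secondary values are transferred from British Columbia's 2005 shellfishery
(harvesting $139 M, processing $71 M, labour $95 M, 2,580 person-years):
processing scales with the BC processing:harvesting ratio, distribution is
15% of harvesting plus processing, and labour/employment scale with revenue.
Scenario loss fractions propagate through the whole cascade.

The unpublished *Cal* levels are back-solved from published scenario losses
by least squares, exploiting the kernel's linearity in *Cal* (see
`docs/methods.md`, including a documented internal inconsistency of the
published scenario table that this calibration exposes).

## Worked example

```python
import crabrisk as cr
from crabrisk import Level

table = cr.packaged_baseline()                       # 2009 harvest, 3 species x 6 areas
grand = table.grand_total()
print(f"baseline: {grand.harvest_kg/1e6:.3f}e6 kg, ${grand.revenue_usd/1e6:.2f}M, "
      f"${grand.avg_price_usd_per_kg:.2f}/kg")

levels = cr.calibrated_levels()                      # back-solved intake levels
grid = cr.scenario_grid(table, levels, mc=cr.MCSettings(n_reps=10_000, seed=1))
cell = grid.cell_totals[(Level.HIGH, Level.HIGH)]
print(f"high/high MC loss: {cell.loss_kg/1e6:.2f}e6 kg, ${cell.loss_usd/1e6:.2f}M "
      f"({100*cell.revenue_loss_fraction:.1f}%)")

ref = cr.packaged_reference_totals()                 # published per-cell losses
frac = float(ref[(ref.calorie_level == "high")
                 & (ref.density_level == "high")].revenue_loss_fraction.iloc[0])
base = cr.baseline_cascade(grand.revenue_usd / 1e6)
after = cr.apply_loss(base, frac)
s = cr.loss_summary(base, after)
print(f"jobs lost: {s.jobs_lost_py} PYs, secondary loss ${s.secondary_loss_usd_m:.1f}M")
```

prints

```
baseline: 6.046e6 kg, $37.25M, $6.16/kg
high/high MC loss: 3.23e6 kg, $20.07M (53.9%)
jobs lost: 442 PYs, secondary loss $17.5M
```

Reading: the 2009 baseline is 6.046 million kg worth $37.25 M at an average
$6.16/kg. Under the most severe scenario (100,000 crabs km⁻², high calorie
diet), the calibrated Monte-Carlo grid puts mean consumption at 3.23 million
kg (a 53.9% revenue loss); applying the *published* high/high revenue-loss
fraction (63.9%) to the benefit-transfer cascade costs 442 jobs and $17.5 M
in processing plus distribution value per year. (`calibrated_levels()` warns
that the fitted mussel intake is not monotone across calorie levels — a
documented property of the published scenario table it is fitted to.)

The same analysis from the shell:

```sh
crabrisk baseline                      # harvest totals
crabrisk calibrate                     # back-solved intake levels -> YAML
crabrisk run --seed 1 --plot           # scenario grid + cascade + figures
crabrisk sensitivity --seed 1 --plot   # density x intake loss surface
crabrisk synth --seed 4                # known-truth synthetic harvest table
```

All outputs carry a provenance header (config hash + seed); identical config
and seed reproduce identical files.

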