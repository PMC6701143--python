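# Methods

## Carbon-balance model

The fermentation is treated as a closed carbon ledger. The substrate side is
the *glucose equivalent* GE = dry-starch loading × 1.11 + added glucose
(g l⁻¹); the 1.11 factor is the mass gain of hydrolysis (one water across
each glycosidic bond: 180/162 ≈ 1.111). Available carbon is
C_avail = GE × 6/180 mol l⁻¹. The product side sums the measured analytes on
a mol-carbon basis, analyte constants (carbon atoms, molar mass):
maltose (12, 342), glucose (6, 180), glycerol (3, 92), acetic acid (2, 60),
ethanol (2, 46), CO₂ (1, 44). The estimated carbon conversion is
100 × product carbon / C_avail.

Two conventions deserve note:

* **Ethanol is included in the product sum.** The per-analyte list is the
  full set of six carbon sinks; excluding ethanol would make a
  near-complete fermentation appear to convert only ~33 % of the carbon.
  Conservation closure is the defining property: a profile holding the full
  glucose equivalent as ethanol + CO₂ in the fermentative 2:1 carbon split
  (ethanol = GE·92/180, CO₂ = GE·88/180 g l⁻¹) scores exactly 100 %.
* **CO₂ is inferred, not measured.** Fermentative metabolism produces one
  CO₂ per ethanol, so CO₂ (g l⁻¹) = ethanol × 44/46. Consequently the CO₂
  carbon contribution is always exactly half the ethanol carbon
  contribution. A measured CO₂ value, when present in the input, takes
  precedence.

Ethanol yield is reported as percent of a theoretical maximum of
0.50 g ethanol per g glucose. The strict stoichiometric bound is 0.511 g/g;
0.50 is the reporting convention this package defaults to because it is what
the reference tables it ships were computed with — the factor is an explicit
argument everywhere it enters. Productivity is titre divided by total
elapsed hours since inoculation (not an interval rate).

Rounding conventions follow the field's table style: conversions and yields
to the nearest integer percent, productivities, totals and CO₂ to two
decimals, glucose equivalents to one. All functions return full precision;
rounding happens only in report rendering (`FermentationSummary.as_report_row`,
TSV output). Integer rounding is half-away-from-zero.

Conversions above 100 % are physically impossible but arise from measurement
noise on near-complete fermentations; values above 105 % emit a
`CarbonBalanceWarning` and are never clipped, so data problems stay visible.

## Copy-number estimation

A gene integrated in k copies accumulates ≈ k× the read depth of a
single-copy locus. The estimator is target coverage divided by the
unweighted arithmetic mean of the housekeeping panel (ACT1, ALG9, PGK1,
TFC1 — constitutively single-copy in S. cerevisiae). Per-gene weights (e.g.
gene lengths) are accepted but default to uniform, since lengths are rarely
reported with coverage summaries. The integer call rounds the ratio half
away from zero; the fractional ratio is always carried so borderline calls
are visible. An explicit numeric denominator (for instance a genome-wide
scaffold-average depth) can replace the panel mean.

The packaged reference coverages are printed as integers; recomputed ratios
therefore differ from the originally published fractional ratios in the
second decimal (e.g. 245/34.25 = 7.15 vs a published 7.20 computed from
unrounded coverages). Tests compare at ±0.05 for this reason; the integer
calls are unaffected.

## Enzyme activity

One unit releases 1 µmol glucose per minute; activities are per ml
supernatant: U ml⁻¹ = µmol / min / ml, a linear endpoint formula (kinetic
fitting of absorbance curves is out of scope — assays enter as µmol
released). Substrate form (raw vs soluble starch), loading, temperature and
detection chemistry (reducing-sugar vs glucose-only) are carried as labels
and affect grouping/reporting only.

## Synthetic data

The fermentation generator is deliberately minimal scaffolding — the least
structure under which the carbon-balance statistic has a known ground truth,
not a mechanistic claim. Hydrolysed carbon fraction follows a logistic
h(t) = 1/(1+e^{−k(t−t₀)}); defaults t₀ = 48 h, k = 0.05 h⁻¹ place the
half-point at the end of the observed enzyme-production lag and give
h(192) ≈ 0.999 at the customary 192-h endpoint. Hydrolysed carbon is split
by fixed fractions among ethanol+CO₂ (0.97), glycerol (0.02), acetic acid
(0.005), residual glucose (0.003) and maltose (0.002) — patterned on a
near-complete 192-h industrial fermentation; the ethanol+CO₂ share is
subdivided 2:1 on carbon (fermentation stoichiometry), making the noiseless
conversion equal 100·h(t) identically (tested at 10⁻⁹ relative tolerance).
Gaussian noise (default σ = 0.5 g l⁻¹, the scale of HPLC triplicate scatter)
is added per measured analyte and clipped at zero; CO₂ is not emitted, since
in practice it is deduced from ethanol downstream. Clipping introduces a
small positive bias on trace analytes — at σ = 2 g l⁻¹ the mean recovered
conversion is within 1 point of truth over 200 replicates, which is the
documented operating range.

What the generator does not emulate: temperature-dependent fermentation
arrest, enzyme kinetics and dosage effects, correlated analyte errors, or
time-varying partitioning. Passing recovery tests therefore demonstrates the
correctness of the accounting, not robustness to those real-data features.

The coverage generator draws each gene's depth as the mean of `gene_length`
Poisson(base_depth × copies) positions (copies = 1 for the panel). At the
reference scale (depth ≥ 30, gene length 10⁴, k ≤ 10) integer recovery is
≥ 99 % over 1000 seeded replicates; the standard error of a mean depth is
√(λ/L), so miscalls essentially vanish at realistic gene lengths. All
randomness flows from one numpy Generator seeded by a single integer; equal
seeds give identical outputs.

## Numerical and design choices

* Validation is eager: dataclasses reject negative concentrations,
  non-positive durations/volumes, inverted dry/as-is loadings, partitions
  not summing to 1 (±10⁻¹²) at construction, with named errors; CSV readers
  name the offending row and column. Unknown CSV columns are rejected so a
  misspelled analyte cannot silently drop out of the balance.
* Time-course validation applies per strain: a cross-sectional table (many
  strains at one endpoint) is valid, duplicate times within one strain are
  not.
* TSV reports are rendered from rounded values with a fixed field order, so
  identical inputs give byte-identical output; JSON reports carry full
  precision and round-trip losslessly.
* CLI exit codes: 0 success, 2 validation/usage, 3 I/O; warnings go to the
  log on stderr, never stdout.

## Problem sizes

Everything here is desk-scale arithmetic on printed summary tables
(≤ 12 columns × 6 analytes); the statistical checks use 200 noisy
fermentation replicates and 1000 coverage tables of 10⁴ positions per gene,
which complete in seconds.

## Known limitations

* The percent-of-theoretical yield depends on the 0.50 vs 0.511 convention
  (a ~2 % relative difference); cross-study comparisons must match factors.
* Copy-number ratios assume uniform mappability and no CNV in the
  housekeeping panel; a panel gene falling in a duplicated region would
  bias all calls downward.
* The carbon balance cannot distinguish unhydrolysed starch from hydrolysed
  but unaccounted carbon (biomass, minor metabolites are not modelled);
  "conversion" is recovery in the six tracked sinks.
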