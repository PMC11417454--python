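# Methods

This note documents the models, conventions, and design choices behind
`antioxdb`, in the order data flows through the pipeline.

## Taxonomy and units

The default registry holds 48 components in five classes; the 37 flavonoids
carry one of seven subclasses.  Units are fixed **per component** (μg/100 g
for retinol and the five carotenoids, mg/100 g for everything else) and
enforced when tables are read, so a table cannot mix scales for one
component.  All TAC arithmetic happens after conversion to mg/100 g; unit
conversion is a pure power-of-1000 rescaling.

Seven components are stored but never enter TAC: retinol, gallocatechin,
formononetin, the 4–6 and 7–10 proanthocyanidin oligomers, proanthocyanidin
polymers (no confirmed VCEAC values), and the total-isoflavone aggregate
column.  The aggregate is additionally flagged `is_aggregate` and excluded
from class/subclass sums so its members are not double counted — the
isoflavone subclass total is the sum of the five individual isoflavones.
Thearubigin is treated as TAC-eligible and therefore requires an explicit
entry in any user-supplied VCEAC table.

**Missing vs zero.**  A logical zero is data (a food that cannot contain the
compound); a missing cell is absence of data.  Coverage counts zeros as
data.  TAC treats missing amounts as zero contributions — a deliberate
convention, surfaced by the `n_missing_contributors` column of
`table_tac` and the `missing_contributors` field of intake profiles, so
consumers can see how much of a TAC value rests on absent data.

## Database construction

The method order is fixed and not configurable (direct match → moisture
conversion → recipe → similar food → logical zero → missing); rebuilding
from the same inputs yields an identical table and ledger.  Specific
conventions:

- **Name canonicalisation** is case-folding plus whitespace collapsing.  No
  fuzzy matching: judgment calls (which cultivar represents "potato") belong
  in the input mapping, not in string heuristics.
- **Varieties**: multiple same-(name, form) records within the chosen source
  are averaged arithmetically (`variety_average`).  Pinning one variety by
  consumption statistics is expressed by editing the source extract, not by
  an automated rule.
- **Moisture conversion** uses the dry-matter ratio
  `(100 − w_target)/(100 − w_source)`, requires both water contents, and
  rejects water contents outside [0, 100).  When several sources offer
  other-form records, lane priority picks the source first; within a source
  the donor form follows the fixed preference raw → boiled → blanched →
  dried → prepared, and varieties are converted individually then averaged.
- **Recipes** are normalised per 100 g of combined raw ingredient mass;
  cooking yield and nutrient retention are not modelled.  Any ingredient
  missing the component makes the dish cell missing (conservative, logged).
  Dishes may nest; cycles are rejected.  Because logical zeros run last, a
  dish containing an animal ingredient is missing (not zero) for flavonoids
  even though the ingredient's cell later becomes a logical zero — the
  conservative reading of the fixed method order.
- **Similar-food scoring** is lexicographic — same genus > same family >
  same plant part > same color, ties broken by food id.  The underlying
  criteria list carries no published weights, so the lexicographic rule is
  this package's own deterministic choice; user-supplied donor mappings can
  override it by pre-filling cells.  Donors are foods whose value came from
  a source (directly, by conversion, or by recipe), never from another
  substitution, so substitution chains cannot form.
- **Default zero rules**: carotenoids and flavonoids are zeroed in the
  animal-based groups (meats, processed meats, fish and shellfish, eggs,
  dairy, fats and oils); the five tea flavan-3-ols (theaflavin, thearubigin
  and the three theaflavin gallates) are zeroed everywhere except
  "Beverages and drinks".  Rules never overwrite existing data.
- **Glycosides**: source records flagged `basis=glycoside` are converted at
  ingest by the molecular-weight ratio `m_aglycone/m_glycoside`; the
  molecular-weight table is plain numbers, no chemistry is performed.

## TAC

`food_tac` and `diet_tac` are the same weighted sum on different bases
(mg/100 g vs mg/day).  The sum is linear, non-negative for non-negative
inputs, additive over foods, and commutes with recipe composition (a dish's
TAC equals the ingredient-weight-weighted mean of ingredient TACs).  A
VCEAC table must cover every eligible component that has a non-missing
amount; vitamin C is pinned to 1.0 by definition of the scale.  VCEAC values
are an input table, never constants baked into the code.

## FFQ scoring

The nine frequency categories map to times/day as
(0, 0.0329, 0.0822, 0.2143, 0.5, 0.7857, 1, 2, 3) — i.e. never, 1/month,
2–3/month, 1–2/week, 3–4/week, 5–6/week, 1/day, 2/day, 3/day.  These
printed-instrument constants are a package default that a design file may
override but must then state.  A chosen portion scales the item's reference
recipe proportionally (portion grams / total recipe grams).  Seasonal items
are multiplied by months/12; non-seasonal items always use factor 1, and a
seasonal item answered without a duration defaults to 12 months.

Items with a missing frequency contribute zero intake and count toward the
missing-item rule.  Class totals are reported in the printed units (retinol
μg/day, all other classes mg/day, μg components divided by 1000); the
flavonoid class total is computed as the sum of the seven subclass totals,
so that identity holds exactly rather than to rounding.

**Exclusions.**  Percentiles of cohort energy use linear interpolation
between order statistics (`numpy.percentile` default) computed on the full
input cohort; comparisons are strict (`<` lower, `>` upper), and the
missing-item rule is strict (`> 10`).  On continuous energy this retains
95% of participants by construction.  Re-applying the filter with the same
percentile *values* (not recomputed ranks) removes nobody; the
`energy_bounds` argument exists for exactly that.  The audit records counts
per criterion and their overlap, and audits pool additively across cohorts.

**Energy** is computed from a per-item energy density (kcal/100 g) carried
by the FFQ design, through the same frequency × portion × duration
arithmetic as the components.

## Rounding

Printed coverage percentages and class totals use half-up decimal rounding
(`decimal.ROUND_HALF_UP` on the shortest float repr), not the half-even
rounding of `round`/numpy — half-up is the convention the printed food
tables follow.  Subclass coverage aggregates unrounded component coverages
and rounds once; the flavonoid class total aggregates the seven subclass
coverages at their printed one-decimal precision.  This two-stage rule is an
inference verified arithmetically against the published aggregates; the one
published isoflavone aggregate that no unweighted mean of its printed
component coverages reproduces is reported as computed, not special-cased.

## Synthetic data

The generator emulates the structure of the real inputs, not their content:

- **Scale defaults** follow the study conditions: 412 foods, 106 FFQ items,
  three vitamins-lane sources (KMFDS > USDA SR28 > JMEXT) and four
  flavonoid-lane sources (USDA flavonoid > isoflavone > proanthocyanidin >
  Phenol-Explorer), 3–4 portion options per item, a 15% seasonal-item
  fraction, and a log-normal reference energy distribution with mean 1,678
  and SD 516 kcal/day (μ = 7.3802, σ = 0.3006 on the log scale).
- **Composition truth** is log-normal per class around realistic medians
  (e.g. carotenoids ~300 μg/100 g, flavonoids ~3 mg/100 g); animal foods
  have true zeros for carotenoids/flavonoids, tea compounds occur only in
  the two beverage foods, and the total-isoflavone column is the sum of its
  members.  Sources observe the truth exactly (no inter-laboratory noise)
  with component-specific missingness — a simplification that lets tests
  assert exact recovery through every deterministic pathway: direct matches,
  variety pairs averaging to the truth, dried forms generated by the exact
  moisture formula, dishes by exact recipe sums, and Phenol-Explorer records
  stored on the glycoside basis with public molecular weights.
- **Similar-food donors** are guaranteed: foods planted as absent from all
  sources share a genus with a recorded food.  Beverages carry no botanical
  attributes so tea compounds cannot leak into produce via substitution.
- **Cohorts** sample frequencies from a skewed 9-category distribution
  (mean ≈ 0.14 servings/day/item), portions uniformly, and durations
  uniformly from {3, 6, 9, 12}.  Item energy densities (uniform 15–80
  kcal/100 g) were chosen once so that a full 106-item design yields cohort
  energy means near the reference distribution.  Planted rule violators
  (participants with >10 missing items, or maximal-response energy outliers)
  are reported by id so exclusion audits can be checked against the plan.
- **Ground truth profiles** are computed by a deliberately naive
  re-summation (plain per-item loops over the built table) that shares no
  code with the vectorized scorer; the dual-path agreement tested at 1e-9
  relative is therefore evidence against scoring bugs, not a tautology.

What passing tests on synthetic data do **not** show: correctness of any
real-world food matching judgment (human adjudication is out of scope and
modelled as deterministic rules), realistic correlations between components,
inter-source disagreement, or reproduction of the published cohort intake
levels, which require the original cohort data.  The default per-source
missingness (45% for flavonoids, 2–10% for vitamins) mimics the sparsity
pattern of real flavonoid sources, but seven overlapping synthetic sources
plus substitution yield higher final coverage than a real build.

## Problem sizes

The test suite runs on a 20-food/8-item "tiny" scenario (with 30–500
participant cohorts for the cohort properties and 10,000 energy draws for
the exclusion rate); the acceptance script builds the full 412-food,
106-item configuration and scores a 200-participant cohort against the
naive oracle.  These sizes keep the whole suite in seconds while exercising
every pathway; all operations scale linearly in foods × components and
participants × items.

## Known limitations

- Cooking yield/retention factors are not modelled; recipe values are per
  100 g of raw ingredient mass.
- The similarity rule is a stated convention, not a validated model of food
  similarity.
- Coverage aggregation for the isoflavone subclass is ambiguous in the
  published material (see Rounding above).
- TAC's missing-as-zero convention biases TAC downward for poorly covered
  foods; use the missing-contributor counts before comparing foods with
  very different coverage.
- The exclusion filter's percentile bounds are estimated from the analysed
  cohort itself; on small cohorts the retained fraction deviates from the
  nominal 95%.
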