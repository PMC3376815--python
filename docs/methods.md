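# Methods

## The costing model

`ihrcost` implements ingredients-based (unit cost × quantity) costing for
the 8 IHR (2005) core capacities plus points of entry. A country template
holds:

- **Country parameters** — population, number of provinces, number of
  functional districts, number of designated points of entry. Defaults are
  the model Southeast Asian "Country X": 60,000,000 / 64 / 600 / 6.
  Population and administrative counts are independent parameters; the
  template does not enforce the ≈1 million-persons-per-province heuristic
  that would make them redundant (64 × 1M ≈ 64M ≠ 60M in the source
  material itself).
- **Cost lines** — each attached to exactly one country-level indicator of
  the IHR Monitoring Framework taxonomy (which fixes the
  line → indicator → capacity mapping and operationalizes the rule that an
  input shared by several capacities is counted once, under its most
  immediately relevant indicator). A line carries a system level (central,
  intermediate, peripheral, community, point of entry), an input class
  (physical infrastructure, human capabilities, tools and processes), a
  scaling driver, a fixed unit cost and an annual operating unit-cost range.

All money is integer whole 2005 US dollars. Fixed costs are one-time
capital; operating costs are annual recurrent costs, reported as a
low–high interval. No annualization or discounting of capital is applied:
the model prices "build it, then run it per year". Costs are payer-neutral
(no payer attribution, no tariffs or fees) and are *additional to* an
assumed baseline of essential health services, which the model does not
price.

### Quantity resolution

- `constant` → offset (e.g. 1 command-and-control centre sized for 40
  personnel; 16 field-epidemiology trainees per year).
- `per_population` → `ceil(population / ratio) + offset`. The ceiling
  reflects indivisible staff: any started block of population needs one
  more whole worker. At the Country X default the flagship norm is exact
  (60,000,000 / 200,000 = 300 field epidemiologists) so the rounding rule
  is invisible there, but it is fixed and tested (population 200,001 → 2).
- `per_province` / `per_district` / `per_point_of_entry` →
  `ratio × count + offset` (e.g. 2 rapid response teams per province plus 2
  central teams → 130), with a ceiling only if a fractional ratio makes the
  product non-integral.

Quantities are always whole numbers and monotone non-decreasing in every
parameter. Prorated shares of an input (fractions of office space,
utilities) belong in the unit cost, not the quantity.

### Roll-up and rounding

Subtotals by capacity, system level and input class, and the grand totals,
are plain integer sums — exact, order-independent, and conserved (each
grand total equals the sum of its subtotals for every grouping; the
combined range is fixed + operating bound-wise). The only places fractions
appear are coverage adjustment and currency normalization; both are
computed in exact rational arithmetic and rounded **half-up to whole
dollars per line before summation**, which makes every reported total
reproducible bit-exactly regardless of grouping or line order.

### Gap (incremental) costing

A coverage profile maps line ids (or indicator ids, applying to all their
lines) to the fraction of that input already in place; unmapped lines
default to 0. Each line's cost is scaled by (1 − fraction). Coverage
applies to the fixed and operating components alike — under full-cost
accounting an input already in place needs neither capital nor incremental
recurrent spending. An alternative stance, reducing only the capital
component while keeping full recurrent costs, is available as
`coverage_fixed_only=True` but is not the default. Gap totals are
pointwise monotone: more coverage never increases any reported figure.

### Currency normalization

`to_2005_usd(amount, source_year, deflators)` divides by a caller-supplied
price-level factor relative to 2005 and rounds half-up. The package ships
no deflator series of its own — the choice of series is an analytical
decision, not a library constant.

### Single-cell reconstruction

Published cost tables occasionally contain a cell inconsistent with their
printed column total. Given the column's cells, the printed total and a
designated suspect cell, `reconstruct_inconsistent_cell` returns the unique
replacement value making the column sum to the total, and refuses (raises)
when no non-negative single-cell repair exists — evidence of a multi-cell
inconsistency. In the packaged Country X summary the operating-high column
is short by exactly 500,000 as printed; designating the coordination cell
(printed 88,868, consistent with a dropped leading "5") reconstructs
588,868, the value the coarse fixture stores with a provenance note. The
fixed and operating-low columns reconcile as printed — the test suite
checks this rather than assuming it.

### Sensitivity

Ceiling rounding makes totals piecewise-constant step functions of the
parameters, so grid sweeps (`one_way_sweep`) are the primary interface.
The `elasticity` convenience perturbs one parameter by +1% (rounded to a
whole count, and by at least one unit), recomputes the combined low total,
and reports the ratio of relative changes to 4 decimals; it is 0 for
purely constant templates, 1 for a single divisible per-population line,
and in between for realistic mixes.

## The packaged Country X templates

**Coarse** (9 lines, one per category, constant driver, quantity 1):
a direct transcription of the published Country X cost summary — fixed
costs and operating ranges per capacity — with the single reconstructed
cell noted above. Two oddities of the source are transcribed as printed
and flagged in notes: risk communications and human resources both carry
fixed cost 4,389 (possibly a transcription artifact), and the coarse
template's roll-up is the authoritative acceptance surface.

**Fine** (50 lines): scaling drivers and quantities follow the published
staffing and input descriptions (300 epidemiologists at 1 per 200,000;
120,000 community health workers at 1 per 500; 130 rapid response teams;
4-person teams at each of 6 points of entry; 16 FETP trainees; a 40-person
command centre; a 24/7 event-monitoring centre carrying zero capital cost
because it shares infrastructure with the command centre). The true
line-item unit costs behind the published totals are not available, so the
fine template's unit costs are **calibrated-illustrative**: each line has a
plausible relative weight, and each category's published fixed total,
operating-low total and high-minus-low spread are apportioned over its
lines by a largest-remainder integer scheme — exact rational shares floored
to whole-dollar unit costs, the remainder handed out by descending
fractional part, with any residue no multi-unit line can absorb whole
landing on a designated quantity-1 line. Apportioning the high column as a
non-negative spread over the low guarantees low ≤ high per line, and the
scheme leaves zero residual, so fine and coarse category totals agree
bit-exactly (tested). One amount, the community-health-worker monthly
allowance, is wholly calibrated — no figure for it is published. Line
notes distinguish sourced quantities from calibrated unit costs throughout.

## The random-template generator

`random_template(seed, n_lines)` emulates the *structure* of real
templates for property testing: taxonomy-valid category/indicator pairs, a
documented driver mix (40% constant, 25% per-population with ratios from
500 to 200,000, 35% administrative), and unit costs uniform up to 10⁹ with
low ≤ high by construction, all deterministic in the seed. It does not
emulate realistic cost *magnitudes or correlations* (real templates
concentrate cost in a few lines, e.g. stockpiles and laboratories), so
passing oracle tests demonstrates arithmetic correctness of the roll-up on
arbitrary valid input, not realism of any particular template. Problem
sizes in the suite (up to 200 lines per template, 100 seeded templates in
the oracle batch) keep the whole run within seconds while exercising every
driver kind and magnitude range.

## Numerical and design choices

- Integer money end to end; Python's arbitrary-precision integers make
  overflow impossible.
- Half-up rounding (ties upward) everywhere a fraction must become dollars,
  applied per line before summation; documented so totals are bit-reproducible.
- `community` is a distinct system level even though organograms group it
  under peripheral, because community-health-worker lines scale with
  population rather than district counts and deserve their own bucket.
- Validation is a pure function returning all violations at once;
  construction is permissive so that invalid files can be parsed, reported
  in full, and round-tripped in tests.
- Template files: YAML canonical, JSON equivalent, one fixed key order;
  rewriting an unchanged template is byte-identical. Unknown schema
  versions are rejected, never coerced.
- Degenerate inputs are defined, not special-cased: empty templates roll up
  to zero, zero parameters with zero offsets give zero quantities, coverage
  1.0 gives zero cost, and a degenerate operating range (low = high) is legal.

## Limitations

- The fine template is illustrative: its per-line unit costs are an
  apportionment consistent with the published category totals, not observed
  prices; analyses that depend on *within*-category cost composition should
  treat it as a worked example only.
- Whether the large preparedness operating cost (dominated by the national
  stockpile) recurs annually or represents periodic replenishment is not
  stated in the source material; it is modeled as annual, as the published
  summary implies.
- No multi-year phasing, discounting, inflation forecasting, payer/donor
  attribution, or probabilistic uncertainty beyond the printed low–high
  bounds; facility-location optimization is out of scope — the engine
  counts units, it does not place them.
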