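# ihrcost

Ingredients-based costing of the IHR (2005) core public health capacities.

The International Health Regulations (2005) oblige all WHO member states to
build capacities to detect, assess, report and respond to public health
events: national legislation and financing, coordination and National Focal
Point communications, surveillance, response, preparedness, risk
communications, human resources, laboratories, and public health functions
at designated points of entry. `ihrcost` is for health economists and
public health planners who need to turn an itemized capacity template into
a national budget figure: it estimates cost as

```
cost(line) = quantity(driver, country) × unit cost        (whole 2005 $US)
total      = Σ lines, rolled up by capacity / system level / input class
```

where each cost line carries a one-time **fixed** (capital) unit cost, an
annual **operating** unit-cost range *(low, high)*, and a **scaling driver**
that resolves its quantity from country parameters — a constant (one
command-and-control centre, 16 field-epidemiology trainees per year), a
per-population norm (`ceil(population / ratio)`, e.g. 1 field
epidemiologist per 200,000 persons), or an administrative rule (2 rapid
response teams per province plus 2 central ones). All arithmetic is integer
whole dollars, so totals are exact and independent of summation order.

On top of the roll-up the package provides:

- **Gap (incremental) costing** — a coverage profile states the fraction of
  each input already in place; the report then prices only the remainder.
- **One-way sensitivity** — parameter sweeps and finite-difference
  elasticities of the totals with respect to population and administrative
  structure.
- **Consistency tooling** — currency normalization to 2005 $US and a
  single-cell reconstruction procedure for published cost columns that do
  not sum to their printed total.
- **Packaged "Country X" templates** — a model Southeast Asian country
  (60 million persons, 64 provinces, 600 districts, 6 points of entry):
  a *coarse* template transcribing the published category cost summary, and
  a *fine* ~50-line template with real scaling drivers whose unit costs are
  calibrated so its category roll-ups match the coarse totals bit-exactly.

## Worked example

```python
from ihrcost import country_x_coarse, rollup

report = rollup(country_x_coarse())
print(report.render_table())
```

prints

```
Group                                                 Fixed $US   Operating $US
----------------------------------------------------  ----------  -----------------------
national_legislation_policy_and_financing                 75,000                      0-0
coordination_and_national_focal_point_communications     823,102          347,959-588,868
surveillance                                           5,261,764    26,238,293-69,606,113
response                                              20,480,332      3,981,294-5,215,857
preparedness                                           2,889,166  103,726,507-103,786,408
risk_communications                                        4,389      1,868,869-2,141,939
human_resources                                            4,389          620,649-653,009
laboratories                                          49,619,443    13,742,692-20,057,218
points_of_entry                                          153,062        838,851-1,435,767
TOTAL                                                 79,310,647  151,365,114-203,485,179
TOTAL fixed + operating                                           230,675,761-282,795,826
```

Fixed costs are one-time capital; operating is the annual recurrent
low–high range; the last row adds the fixed total to each operating bound —
the full published cost envelope of implementing IHR (2005) in the model
country. The coordination operating high shown (588,868) is the
reconstructed value: the published cell (88,868) is inconsistent with the
published column total, and `reconstruct_inconsistent_cell` recovers the
unique single-cell repair (see `examples/05_reconstruct_published_cell.py`).

The `examples/` directory holds one short script per capability — full-cost
roll-up, staffing-rule resolution, gap analysis, sensitivity sweeps, and
the column reconstruction — each printing its numbers with a note on what
they mean. A thin CLI wraps the same operations:

```
ihrcost cost template.yaml --format json
ihrcost validate template.yaml
ihrcost gap template.yaml coverage.yaml
ihrcost sweep template.yaml --param population --grid 30000000,60000000
```

Templates are YAML (canonical) or JSON documents; see
`src/ihrcost/data/country_x_coarse.yaml` for the format and
`docs/methods.md` for the model's assumptions, calibration and limitations.

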