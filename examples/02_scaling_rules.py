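"""Resolve staffing quantities from country parameters via scaling drivers.

Shows how the published staffing norms become headcounts for the default
Country X (60M persons, 64 provinces, 600 districts, 6 points of entry),
and how the same rules rescale for a smaller country.
"""

from ihrcost import CountryParams, ScalingDriver, resolve_quantity

rules = [
    ("Field epidemiologists (1 per 200,000 population)",
     ScalingDriver.per_population(200_000)),
    ("Community health workers (1 per 500 population)",
     ScalingDriver.per_population(500)),
    ("Rapid response teams (2 per province + 2 central)",
     ScalingDriver.per_province(2, offset=2)),
    ("Point-of-entry response staff (4 per designated PoE)",
     ScalingDriver.per_point_of_entry(4)),
    ("Field epidemiology trainees (fixed annual intake)",
     ScalingDriver.constant(16)),
]

country_x = CountryParams()
small = CountryParams(population=8_000_000, n_provinces=12, n_districts=90,
                      n_points_of_entry=2)

print(f"{'input':55s} {'Country X':>10s} {'8M country':>11s}")
for label, driver in rules:
    print(f"{label:55s} {resolve_quantity(driver, country_x):>10,} "
          f"{resolve_quantity(driver, small):>11,}")
print()
print("Quantities are whole units: per-population rules use a ceiling, so any")
print("started block of population requires one more whole worker.")
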