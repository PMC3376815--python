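"""One-way sensitivity: how totals move with population and structure.

Sweeps the fine Country X template over a population grid and prints the
elasticity of the combined low total to each country parameter (the %-change
in total per %-change in the parameter, at the default point).
"""

from ihrcost import CountryParams, country_x_fine, elasticity, one_way_sweep

fine = country_x_fine()

sweep = one_way_sweep(fine, "population", [15_000_000, 30_000_000,
                                           60_000_000, 120_000_000])
print("population sweep (2005 $US):")
print(sweep.to_csv())

print("elasticities of the combined (fixed + operating low) total:")
for parameter in CountryParams.FIELDS:
    print(f"  {parameter:20s} {elasticity(fine, parameter):7.4f}")
print()
print("An elasticity of 1 would mean the total scales proportionally with the")
print("parameter; 0 means no dependence. Values in between reflect the mix of")
print("constant (national-level) and population/administratively driven lines.")
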