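"""Incremental (gap) costing: cost only what is not already in place.

Most countries already run part of a surveillance system; the first step in
planning is costing the gap between current status and full implementation.
A CoverageProfile states the fraction of each input already in place; the
roll-up then reports the cost of completing the remainder.
"""

from ihrcost import CoverageProfile, country_x_fine, rollup

fine = country_x_fine()

# Suppose Country X already has 80% of its routine surveillance workforce,
# all of its legal review done, and half of its laboratory capacity.
coverage = CoverageProfile(
    by_indicator={
        "indicator_based_surveillance": 0.8,
        "legislation": 1.0,
        "laboratory_diagnostics": 0.5,
    },
)

full = rollup(fine)
gap = rollup(fine, coverage)

print(f"{'':38s}{'full build':>16s}{'gap only':>16s}")
print(f"{'Fixed (one-time capital)':38s}{full.grand_fixed:>16,}{gap.grand_fixed:>16,}")
print(f"{'Operating low (annual)':38s}{full.grand_operating.low:>16,}"
      f"{gap.grand_operating.low:>16,}")
print(f"{'Operating high (annual)':38s}{full.grand_operating.high:>16,}"
      f"{gap.grand_operating.high:>16,}")
print()
print("The gap column is what completing the capacities would still cost, in")
print("2005 $US: inputs fully in place contribute nothing; partly covered")
print("inputs contribute their uncovered share, rounded half-up per line.")
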