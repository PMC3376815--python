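"""Repair the inconsistent cell in the published Country X cost summary.

As printed, the operating-high column of the published summary does not sum
to its printed total: the coordination cell reads 88,868 while the other
eight cells plus the printed total imply 588,868 (a dropped leading digit).
This script runs the documented single-cell reconstruction procedure.
"""

from ihrcost import reconstruct_inconsistent_cell
from ihrcost.fixtures import TABLE2_OPERATING_HIGH_PRINTED, TABLE2_TOTALS

cats = list(TABLE2_OPERATING_HIGH_PRINTED)
cells = [TABLE2_OPERATING_HIGH_PRINTED[c] for c in cats]
printed_total = TABLE2_TOTALS["operating_high"]

print(f"printed cells sum to {sum(cells):,}; printed total is {printed_total:,}")

suspect = cats.index("coordination_and_national_focal_point_communications")
index, corrected = reconstruct_inconsistent_cell(cells, printed_total,
                                                 suspect=suspect)
print(f"suspect cell: {cats[index]} (printed {cells[index]:,})")
print(f"reconstructed value: {corrected:,}")

cells[index] = corrected
print(f"repaired column sums to {sum(cells):,} — matches the printed total:",
      sum(cells) == printed_total)
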