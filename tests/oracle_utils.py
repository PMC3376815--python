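"""Independent brute-force oracles for roll-up tests.

Deliberately naive and written without reusing the library's scaling or
aggregation code paths: quantities from plain ``math.ceil`` arithmetic,
totals from a flat loop with Python sums. Used to cross-check ``rollup``
bit-for-bit on random templates.
"""

from __future__ import annotations

import math
from fractions import Fraction


def naive_quantity(line, params) -> int:
    kind = getattr(line.driver.kind, "value", line.driver.kind)
    ratio, offset = line.driver.ratio, line.driver.offset
    if kind == "constant":
        return offset
    if kind == "per_population":
        if params.population == 0:
            return offset
        return math.ceil(Fraction(params.population) / Fraction(ratio)) + offset
    count = {"per_province": params.n_provinces,
             "per_district": params.n_districts,
             "per_point_of_entry": params.n_points_of_entry}[kind]
    return math.ceil(Fraction(ratio) * count) + offset


def _half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def naive_totals(template, coverage=None):
    """(grand_fixed, grand_low, grand_high, per_category dict) by flat summation."""
    grand = [0, 0, 0]
    per_cat: dict[str, list[int]] = {}
    for line in template.lines:
        q = naive_quantity(line, template.params)
        fixed = q * line.unit_fixed
        low = q * line.unit_operating.low
        high = q * line.unit_operating.high
        if coverage is not None:
            keep = 1 - Fraction(coverage.fraction_for(line))
            fixed = _half_up(keep * fixed)
            low = _half_up(keep * low)
            high = _half_up(keep * high)
        cat = per_cat.setdefault(str(line.category), [0, 0, 0])
        for acc, v in ((grand, (fixed, low, high)), (cat, (fixed, low, high))):
            acc[0] += v[0]
            acc[1] += v[1]
            acc[2] += v[2]
    return grand[0], grand[1], grand[2], per_cat
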