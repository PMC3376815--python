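"""Exact roll-up of resolved costs, gap-adjusted costing, and consistency checks.

All arithmetic is integer whole dollars: a line's cost is quantity x unit
cost, subtotals are plain sums, and the grand totals equal the sum of their
subtotals bit-exactly for every grouping (category, system level, input
class) and any line order. The combined grand range pairs the fixed total
with the operating low and high respectively.

Scaling that introduces fractions — coverage adjustment and currency
normalisation — is done in exact rational arithmetic and rounded half-up to
whole dollars *per line before summation*, so totals are reproducible
bit-exactly regardless of grouping or order.

``reconstruct_inconsistent_cell`` is the documented procedure for repairing
a published column in which exactly one cell disagrees with the printed
column total: it recovers the unique value for a designated suspect cell
that makes the column sum to the printed total.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    CostLine,
    CountryTemplate,
    Money,
    MoneyRange,
    ZERO_RANGE,
)
from .scaling import ResolvedLine, resolve_template
from .taxonomy import CATEGORY_IDS, INDICATOR_BY_ID

__all__ = [
    "CoverageProfile",
    "CostReport",
    "line_cost",
    "apply_coverage",
    "rollup",
    "to_2005_usd",
    "reconstruct_inconsistent_cell",
    "round_half_up",
]

GROUP_DIMENSIONS = ("category", "level", "input_class")


def round_half_up(x: Fraction | int) -> int:
    """Round to the nearest integer, ties away from zero upward (2.5 -> 3)."""
    f = Fraction(x)
    return (2 * f.numerator + f.denominator) // (2 * f.denominator)


def line_cost(resolved: ResolvedLine) -> tuple[Money, MoneyRange]:
    """(fixed, operating) cost of one resolved line: quantity x unit costs."""
    q = resolved.quantity
    line = resolved.line
    return q * line.unit_fixed, line.unit_operating.scaled(q)


@dataclass(frozen=True)
class CoverageProfile:
    """Fraction of each input already in place, for incremental (gap) costing.

    ``by_line`` maps line ids to fractions in [0, 1]; ``by_indicator`` maps
    indicator ids and applies to every line under that indicator. A line-level
    entry overrides an indicator-level one; unmapped lines default to 0
    (nothing in place, full cost applies).
    """

    by_line: Mapping[str, float] = field(default_factory=dict)
    by_indicator: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scope, mapping in (("line", self.by_line), ("indicator", self.by_indicator)):
            for key, frac in mapping.items():
                if not (isinstance(frac, (int, float)) and 0.0 <= frac <= 1.0):
                    raise ValueError(
                        f"coverage fraction for {scope} {key!r} must be in [0, 1], "
                        f"got {frac!r}")

    def fraction_for(self, line: CostLine) -> float:
        if line.id in self.by_line:
            return self.by_line[line.id]
        return self.by_indicator.get(str(line.indicator), 0.0)

    def check_against(self, template: CountryTemplate) -> None:
        """Raise if the profile references a line id or indicator id that the
        template (or the taxonomy) does not contain."""
        known_lines = {ln.id for ln in template.lines}
        for key in self.by_line:
            if key not in known_lines:
                raise ValueError(f"coverage references unknown line id {key!r}")
        for key in self.by_indicator:
            if key not in INDICATOR_BY_ID:
                raise ValueError(f"coverage references unknown indicator id {key!r}")


def apply_coverage(fixed: Money, operating: MoneyRange, fraction: float,
                   *, fixed_only: bool = False) -> tuple[Money, MoneyRange]:
    """Scale a line's costs by the share of capacity still missing.

    Each component is multiplied by ``(1 - fraction)`` and rounded half-up to
    whole dollars; fraction 0 is the identity and fraction 1 yields zeros.
    With ``fixed_only=True`` only the capital component is reduced and the
    operating range passes through unchanged (for the accounting stance in
    which existing capacity still incurs full recurrent cost).
    """
    if not (isinstance(fraction, (int, float)) and 0.0 <= fraction <= 1.0):
        raise ValueError(f"coverage fraction must be in [0, 1], got {fraction!r}")
    keep = 1 - Fraction(fraction)
    new_fixed = round_half_up(keep * fixed)
    if fixed_only:
        return new_fixed, operating
    return new_fixed, MoneyRange(round_half_up(keep * operating.low),
                                 round_half_up(keep * operating.high))


@dataclass(frozen=True)
class GroupCost:
    """Fixed total and operating range for one roll-up group."""

    fixed: Money
    operating: MoneyRange

    @property
    def combined(self) -> MoneyRange:
        return MoneyRange(self.fixed + self.operating.low,
                          self.fixed + self.operating.high)


_ZERO_GROUP = GroupCost(0, ZERO_RANGE)


@dataclass(frozen=True)
class CostReport:
    """Roll-up of a template: subtotals per group and exact grand totals.

    ``by_category`` always covers all 9 categories (zero-valued entries for
    categories without lines); ``by_level`` and ``by_input_class`` are
    present only when requested. Invariant (tested, not assumed): each grand
    total equals the sum of its subtotals exactly, and
    ``grand_combined = grand_fixed + grand_operating`` bound-wise.
    """

    by_category: dict[str, GroupCost]
    grand_fixed: Money
    grand_operating: MoneyRange
    by_level: dict[str, GroupCost] | None = None
    by_input_class: dict[str, GroupCost] | None = None

    @property
    def grand_combined(self) -> MoneyRange:
        return MoneyRange(self.grand_fixed + self.grand_operating.low,
                          self.grand_fixed + self.grand_operating.high)

    # -- serialisation ----------------------------------------------------

    def _rows(self) -> list[tuple[str, Money, Money, Money]]:
        rows = [(f"category:{k}", g.fixed, g.operating.low, g.operating.high)
                for k, g in self.by_category.items()]
        for prefix, groups in (("level", self.by_level),
                               ("input_class", self.by_input_class)):
            if groups is not None:
                rows += [(f"{prefix}:{k}", g.fixed, g.operating.low, g.operating.high)
                         for k, g in groups.items()]
        rows.append(("total", self.grand_fixed,
                     self.grand_operating.low, self.grand_operating.high))
        return rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows(),
                            columns=["group", "fixed", "operating_low", "operating_high"])

    def to_csv(self) -> str:
        """CSV with fixed column order: group, fixed, operating_low, operating_high."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["group", "fixed", "operating_low", "operating_high"])
        writer.writerows(self._rows())
        return buf.getvalue()

    def to_dict(self) -> dict:
        def grp(groups: dict[str, GroupCost]) -> dict:
            return {k: {"fixed": g.fixed,
                        "operating": {"low": g.operating.low, "high": g.operating.high}}
                    for k, g in groups.items()}

        out: dict = {"by_category": grp(self.by_category)}
        if self.by_level is not None:
            out["by_level"] = grp(self.by_level)
        if self.by_input_class is not None:
            out["by_input_class"] = grp(self.by_input_class)
        out["grand"] = {
            "fixed": self.grand_fixed,
            "operating": {"low": self.grand_operating.low,
                          "high": self.grand_operating.high},
            "combined": {"low": self.grand_combined.low,
                         "high": self.grand_combined.high},
        }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def render_table(self) -> str:
        """Human-readable aligned table with thousands separators."""
        def fmt(g: GroupCost) -> tuple[str, str]:
            return f"{g.fixed:,}", f"{g.operating.low:,}-{g.operating.high:,}"

        rows = [(k, *fmt(g)) for k, g in self.by_category.items()]
        for prefix, groups in (("level", self.by_level),
                               ("input_class", self.by_input_class)):
            if groups is not None:
                rows += [(f"[{prefix}] {k}", *fmt(g)) for k, g in groups.items()]
        rows.append(("TOTAL", f"{self.grand_fixed:,}",
                     f"{self.grand_operating.low:,}-{self.grand_operating.high:,}"))
        rows.append(("TOTAL fixed + operating", "",
                     f"{self.grand_combined.low:,}-{self.grand_combined.high:,}"))
        header = ("Group", "Fixed $US", "Operating $US")
        widths = [max(len(r[i]) for r in rows + [header]) for i in range(3)]
        lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths)),
                 "  ".join("-" * w for w in widths)]
        for name, fx, op in rows:
            lines.append("  ".join((name.ljust(widths[0]),
                                    fx.rjust(widths[1]), op.rjust(widths[2]))))
        return "\n".join(lines)


def _accumulate(groups: dict[str, GroupCost], key: str,
                fixed: Money, operating: MoneyRange) -> None:
    g = groups.get(key, _ZERO_GROUP)
    groups[key] = GroupCost(g.fixed + fixed, g.operating + operating)


def rollup(template: CountryTemplate,
           coverage: CoverageProfile | None = None,
           group_by: Sequence[str] = ("category",),
           *, coverage_fixed_only: bool = False) -> CostReport:
    """Roll a validated template up to subtotals and grand totals.

    With a :class:`CoverageProfile`, each line's cost is first reduced by the
    fraction already in place (rounded half-up per line), giving the
    incremental (gap) cost of completing the capacity. ``group_by`` selects
    optional extra breakdowns from ``{"category", "level", "input_class"}``;
    the per-category breakdown is always produced.
    """
    for dim in group_by:
        if dim not in GROUP_DIMENSIONS:
            raise ValueError(f"unknown grouping dimension {dim!r}; "
                             f"expected a subset of {GROUP_DIMENSIONS}")
    if coverage is not None:
        coverage.check_against(template)

    by_category: dict[str, GroupCost] = {cid: _ZERO_GROUP for cid in CATEGORY_IDS}
    by_level: dict[str, GroupCost] = {}
    by_input_class: dict[str, GroupCost] = {}
    grand_fixed = 0
    grand_operating = ZERO_RANGE

    for resolved in resolve_template(template):
        fixed, operating = line_cost(resolved)
        if coverage is not None:
            fixed, operating = apply_coverage(
                fixed, operating, coverage.fraction_for(resolved.line),
                fixed_only=coverage_fixed_only)
        line = resolved.line
        _accumulate(by_category, str(line.category), fixed, operating)
        if "level" in group_by:
            _accumulate(by_level, str(line.level.value if hasattr(line.level, "value")
                                      else line.level), fixed, operating)
        if "input_class" in group_by:
            _accumulate(by_input_class,
                        str(line.input_class.value if hasattr(line.input_class, "value")
                            else line.input_class), fixed, operating)
        grand_fixed += fixed
        grand_operating = grand_operating + operating

    return CostReport(
        by_category=by_category,
        grand_fixed=grand_fixed,
        grand_operating=grand_operating,
        by_level=by_level if "level" in group_by else None,
        by_input_class=by_input_class if "input_class" in group_by else None,
    )


def to_2005_usd(amount: int, source_year: int,
                deflators: Mapping[int, float]) -> Money:
    """Normalise a whole-dollar amount from ``source_year`` to 2005 $US.

    ``deflators`` gives, per year, the price-level factor relative to 2005
    (2005 -> 1.0); the amount is divided by it and rounded half-up. A
    missing year or non-positive deflator is an error, as is a negative
    amount.
    """
    if not isinstance(amount, int) or isinstance(amount, bool) or amount < 0:
        raise ValueError(f"amount must be a non-negative integer, got {amount!r}")
    if source_year not in deflators:
        raise ValueError(f"no deflator for source year {source_year}")
    deflator = deflators[source_year]
    if deflator <= 0:
        raise ValueError(f"deflator for {source_year} must be > 0, got {deflator!r}")
    return round_half_up(Fraction(amount) / Fraction(deflator))


def reconstruct_inconsistent_cell(
        cells: Sequence[Money], printed_total: Money,
        suspect: int | None = None) -> tuple[int, Money] | None:
    """Repair a published column where one cell disagrees with its printed total.

    Returns ``None`` if the cells already sum to ``printed_total``. Otherwise
    the caller designates the suspect cell index and the unique replacement
    value ``cells[suspect] + (printed_total - sum(cells))`` is returned as
    ``(suspect, corrected_value)``. If the correction would be negative no
    single-cell repair exists (the inconsistency involves multiple cells) and
    a ``ValueError`` is raised; likewise if the column is inconsistent but no
    suspect was designated.
    """
    total = sum(cells)
    if total == printed_total:
        return None
    if suspect is None:
        raise ValueError(
            f"column sums to {total}, not the printed {printed_total}; "
            "designate the suspect cell index to reconstruct")
    if not 0 <= suspect < len(cells):
        raise ValueError(f"suspect index {suspect} out of range")
    corrected = cells[suspect] + (printed_total - total)
    if corrected < 0:
        raise ValueError(
            "no single-cell correction exists: the other cells alone exceed "
            f"the printed total (correction would be {corrected})")
    return suspect, corrected
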