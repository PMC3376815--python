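"""Domain types for ingredients-based capacity costing.

The unit of costing is a :class:`CountryTemplate`: country-level demographic
and administrative drivers (:class:`CountryParams`) plus a set of
:class:`CostLine` items, each attached to one country-level indicator of the
IHR Monitoring Framework taxonomy. A line carries a one-time fixed (capital)
unit cost and an annual operating unit-cost range, both in whole 2005 US
dollars, and a :class:`ScalingDriver` saying how many units the country
needs (a constant, or so many per population / province / district / point
of entry).

Money is integer whole dollars throughout: published figures are printed to
the dollar, and integer arithmetic keeps roll-ups exact and independent of
summation order.

Types here are permissive containers — an invalid template (e.g. an
operating range with low > high) can be constructed and round-tripped
through files. :func:`validate_template` is the single gate: it returns a
list of :class:`Violation` describing every broken invariant, and an empty
list means the template is well-formed. All downstream operations state
"template validates" as their precondition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

from .taxonomy import CATEGORY_BY_ID, INDICATOR_BY_ID

__all__ = [
    "Money",
    "MoneyRange",
    "SystemLevel",
    "InputClass",
    "DriverKind",
    "ScalingDriver",
    "CostLine",
    "CountryParams",
    "CountryTemplate",
    "Violation",
    "validate_template",
]

#: Whole 2005 US dollars. Plain int; non-negativity is checked by
#: validate_template, and Python ints never overflow.
Money = int


@dataclass(frozen=True)
class MoneyRange:
    """A (low, high) pair of whole-dollar amounts; degenerate ranges allowed."""

    low: Money
    high: Money

    @classmethod
    def exact(cls, amount: Money) -> "MoneyRange":
        return cls(amount, amount)

    def scaled(self, quantity: int) -> "MoneyRange":
        return MoneyRange(self.low * quantity, self.high * quantity)

    def __add__(self, other: "MoneyRange") -> "MoneyRange":
        return MoneyRange(self.low + other.low, self.high + other.high)


ZERO_RANGE = MoneyRange(0, 0)


class SystemLevel(str, Enum):
    """Tier of the national public health system an input sits at.

    ``community`` is distinct from ``peripheral`` even though organograms
    group community structures under the peripheral tier: community-health-
    worker lines scale with population, not with district counts, and
    deserve their own roll-up bucket.
    """

    CENTRAL = "central"
    INTERMEDIATE = "intermediate"
    PERIPHERAL = "peripheral"
    COMMUNITY = "community"
    POINT_OF_ENTRY = "point_of_entry"


class InputClass(str, Enum):
    """Ingredient class: facilities/equipment, workforce, or tools/processes."""

    PHYSICAL_INFRASTRUCTURE = "physical_infrastructure"
    HUMAN_CAPABILITIES = "human_capabilities"
    TOOLS_PROCESSES = "tools_processes"


class DriverKind(str, Enum):
    CONSTANT = "constant"
    PER_POPULATION = "per_population"
    PER_PROVINCE = "per_province"
    PER_DISTRICT = "per_district"
    PER_POINT_OF_ENTRY = "per_point_of_entry"


@dataclass(frozen=True)
class ScalingDriver:
    """Rule resolving a line's quantity from country parameters.

    ``ratio`` means persons-per-unit for ``per_population`` (e.g. one field
    epidemiologist per 200,000 population) and units-per-admin-unit for the
    administrative kinds (e.g. 2 rapid response teams per province).
    ``offset`` is an additive constant (e.g. "plus 2 central teams");
    ``constant`` drivers use only the offset.
    """

    kind: DriverKind | str
    ratio: int | float | None = None
    offset: int = 0

    @classmethod
    def constant(cls, count: int) -> "ScalingDriver":
        return cls(DriverKind.CONSTANT, None, count)

    @classmethod
    def per_population(cls, persons_per_unit: int | float, offset: int = 0) -> "ScalingDriver":
        return cls(DriverKind.PER_POPULATION, persons_per_unit, offset)

    @classmethod
    def per_province(cls, units_per_province: int | float, offset: int = 0) -> "ScalingDriver":
        return cls(DriverKind.PER_PROVINCE, units_per_province, offset)

    @classmethod
    def per_district(cls, units_per_district: int | float, offset: int = 0) -> "ScalingDriver":
        return cls(DriverKind.PER_DISTRICT, units_per_district, offset)

    @classmethod
    def per_point_of_entry(cls, units_per_poe: int | float, offset: int = 0) -> "ScalingDriver":
        return cls(DriverKind.PER_POINT_OF_ENTRY, units_per_poe, offset)


@dataclass(frozen=True)
class CostLine:
    """One costed input, attached to exactly one indicator (no double counting).

    ``unit_fixed`` is the one-time capital cost per resolved unit;
    ``unit_operating`` the annual recurrent cost range per resolved unit.
    ``note`` carries free-text provenance (printed value, derived,
    calibrated-illustrative, ...) and is preserved verbatim by file I/O.
    """

    id: str
    category: str
    indicator: str
    level: SystemLevel | str
    input_class: InputClass | str
    driver: ScalingDriver
    unit_fixed: Money
    unit_operating: MoneyRange
    note: str = ""


@dataclass(frozen=True)
class CountryParams:
    """Demographic and administrative scaling drivers.

    Defaults are the model Southeast Asian "Country X": 60 million persons,
    64 provinces, 600 functional districts, 6 designated points of entry.
    Population and administrative counts are deliberately independent
    parameters (the ~1M-persons-per-province heuristic is not enforced).
    """

    population: int = 60_000_000
    n_provinces: int = 64
    n_districts: int = 600
    n_points_of_entry: int = 6

    FIELDS = ("population", "n_provinces", "n_districts", "n_points_of_entry")

    def with_value(self, parameter: str, value: int) -> "CountryParams":
        if parameter not in self.FIELDS:
            raise ValueError(f"unknown country parameter {parameter!r}")
        return replace(self, **{parameter: value})


@dataclass(frozen=True)
class CountryTemplate:
    """A country's full cost template: parameters + cost lines + metadata."""

    params: CountryParams
    lines: tuple[CostLine, ...]
    name: str = ""
    currency_year: int = 2005
    notes: str = ""

    def line(self, line_id: str) -> CostLine:
        for ln in self.lines:
            if ln.id == line_id:
                return ln
        raise KeyError(line_id)


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the rule, a human-readable message, and the
    offending line id (None for template-level problems)."""

    rule: str
    message: str
    line_id: str | None = None

    def __str__(self) -> str:
        where = f"line {self.line_id!r}: " if self.line_id else ""
        return f"{where}{self.message} [{self.rule}]"


def _is_nonneg_int(x: object) -> bool:
    return isinstance(x, int) and not isinstance(x, bool) and x >= 0


def _enum_value(x: object) -> object:
    return x.value if isinstance(x, Enum) else x


_RATIO_KINDS = {
    DriverKind.PER_POPULATION.value,
    DriverKind.PER_PROVINCE.value,
    DriverKind.PER_DISTRICT.value,
    DriverKind.PER_POINT_OF_ENTRY.value,
}


def _check_money(amount: object, what: str, line_id: str, out: list[Violation]) -> None:
    if not _is_nonneg_int(amount):
        out.append(Violation("money >= 0 and integer",
                             f"{what} must be a non-negative whole-dollar integer, "
                             f"got {amount!r}", line_id))


def validate_template(template: CountryTemplate) -> list[Violation]:
    """Check every structural invariant; return all violations (never raise).

    Pure and idempotent: two calls on the same value return identical lists,
    and an empty list means the template satisfies every invariant (unique
    line ids, known taxonomy references, valid enumerations, non-negative
    integer money with low <= high, positive ratios, non-negative offsets
    and country parameters).
    """
    out: list[Violation] = []

    for f in CountryParams.FIELDS:
        v = getattr(template.params, f)
        if not _is_nonneg_int(v):
            out.append(Violation("params >= 0",
                                 f"country parameter {f} must be a non-negative "
                                 f"integer, got {v!r}"))

    seen: set[str] = set()
    for ln in template.lines:
        if ln.id in seen:
            out.append(Violation("unique line ids", f"duplicate id {ln.id!r}", ln.id))
        seen.add(ln.id)

        if ln.category not in CATEGORY_BY_ID:
            out.append(Violation("known category",
                                 f"unknown category {ln.category!r}", ln.id))
        ind = INDICATOR_BY_ID.get(str(_enum_value(ln.indicator)))
        if ind is None:
            out.append(Violation("known indicator",
                                 f"unknown indicator {ln.indicator!r}", ln.id))
        elif ind.category != ln.category:
            out.append(Violation("indicator belongs to category",
                                 f"indicator {ln.indicator!r} belongs to category "
                                 f"{ind.category!r}, not {ln.category!r}", ln.id))

        if _enum_value(ln.level) not in SystemLevel._value2member_map_:
            out.append(Violation("known system level",
                                 f"unknown system level {ln.level!r}", ln.id))
        if _enum_value(ln.input_class) not in InputClass._value2member_map_:
            out.append(Violation("known input class",
                                 f"unknown input class {ln.input_class!r}", ln.id))

        kind = _enum_value(ln.driver.kind)
        if kind not in DriverKind._value2member_map_:
            out.append(Violation("known driver kind",
                                 f"unknown driver kind {ln.driver.kind!r}", ln.id))
        else:
            if kind in _RATIO_KINDS:
                r = ln.driver.ratio
                if not isinstance(r, (int, float)) or isinstance(r, bool) or r <= 0:
                    out.append(Violation("ratio > 0",
                                         f"driver ratio must be > 0 for {kind}, "
                                         f"got {r!r}", ln.id))
        if not _is_nonneg_int(ln.driver.offset):
            out.append(Violation("offset >= 0",
                                 f"driver offset must be a non-negative integer, "
                                 f"got {ln.driver.offset!r}", ln.id))

        _check_money(ln.unit_fixed, "unit_fixed", ln.id, out)
        op = ln.unit_operating
        _check_money(op.low, "unit_operating.low", ln.id, out)
        _check_money(op.high, "unit_operating.high", ln.id, out)
        if _is_nonneg_int(op.low) and _is_nonneg_int(op.high) and op.low > op.high:
            out.append(Violation("low <= high",
                                 f"operating range has low {op.low} > high {op.high}",
                                 ln.id))

    return out
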