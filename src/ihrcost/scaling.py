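"""Resolve cost-line quantities from country parameters.

Each cost line's scaling driver turns demographic/administrative parameters
into a whole-number quantity: headcounts, site counts, team counts. Rules:

* ``constant`` — the offset itself (e.g. 1 command-and-control centre,
  16 field-epidemiology trainees per year).
* ``per_population`` — ``ceil(population / ratio) + offset``. Ceiling,
  because staffing norms like "1 field epidemiologist per 200,000
  population" require one whole worker for any started block; at the
  Country X defaults (60,000,000 / 200,000 = 300) the division is exact and
  the rounding rule is invisible.
* ``per_province`` / ``per_district`` / ``per_point_of_entry`` —
  ``ratio * count + offset`` (e.g. 2 rapid response teams per province plus
  2 central teams -> 2*64 + 2 = 130), with a ceiling applied only if a
  fractional ratio makes the product non-integral.

Quantities are always integers: prorated shares of an input (office space,
utilities) belong in the unit cost, not the quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import CostLine, CountryParams, CountryTemplate, DriverKind, ScalingDriver

__all__ = ["ResolvedLine", "resolve_quantity", "resolve_template"]


@dataclass(frozen=True)
class ResolvedLine:
    """A cost line together with its resolved unit count."""

    line: CostLine
    quantity: int


def _ceil_div(numerator: int, ratio: int | float) -> int:
    if isinstance(ratio, int):
        return -(-numerator // ratio)
    return math.ceil(numerator / ratio)


def _ceil_mul(ratio: int | float, count: int) -> int:
    if isinstance(ratio, int):
        return ratio * count
    return math.ceil(ratio * count)


def resolve_quantity(driver: ScalingDriver, params: CountryParams) -> int:
    """Number of units this driver requires under the given parameters.

    Raises ``ValueError`` for an unknown driver kind (malformed template).
    The result is 0 whenever the relevant parameter is 0 and the offset is 0,
    and is non-decreasing in every parameter.
    """
    try:
        kind = DriverKind(driver.kind)
    except ValueError:
        raise ValueError(f"unknown driver kind {driver.kind!r}") from None

    offset = driver.offset
    if kind is DriverKind.CONSTANT:
        return offset
    if kind is DriverKind.PER_POPULATION:
        if params.population == 0:
            return offset
        return _ceil_div(params.population, driver.ratio) + offset
    if kind is DriverKind.PER_PROVINCE:
        return _ceil_mul(driver.ratio, params.n_provinces) + offset
    if kind is DriverKind.PER_DISTRICT:
        return _ceil_mul(driver.ratio, params.n_districts) + offset
    if kind is DriverKind.PER_POINT_OF_ENTRY:
        return _ceil_mul(driver.ratio, params.n_points_of_entry) + offset
    raise ValueError(f"unknown driver kind {driver.kind!r}")  # pragma: no cover


def resolve_template(template: CountryTemplate) -> list[ResolvedLine]:
    """Resolve every line of a validated template, preserving input order.

    Resolution errors are re-raised with the offending line id attached.
    """
    resolved: list[ResolvedLine] = []
    for line in template.lines:
        try:
            q = resolve_quantity(line.driver, template.params)
        except ValueError as exc:
            raise ValueError(f"line {line.id!r}: {exc}") from exc
        resolved.append(ResolvedLine(line, q))
    return resolved
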