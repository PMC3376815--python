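"""One-way sensitivity of cost totals to country parameters.

Because per-population quantities use a ceiling rule, totals are piecewise
constant in the parameters; grid sweeps are therefore the primary interface
and the elasticity is a forward finite difference on integer-rounded totals,
not a derivative.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aggregation import rollup
from .model import CountryParams, CountryTemplate, MoneyRange

__all__ = ["SweepPoint", "SweepResult", "one_way_sweep", "elasticity"]


@dataclass(frozen=True)
class SweepPoint:
    value: int
    fixed: int
    operating: MoneyRange


@dataclass(frozen=True)
class SweepResult:
    """Grand totals at each grid value of one country parameter, in grid order."""

    parameter: str
    points: tuple[SweepPoint, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.value, p.fixed, p.operating.low, p.operating.high) for p in self.points],
            columns=["parameter_value", "fixed", "operating_low", "operating_high"])

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["parameter_value", "fixed", "operating_low", "operating_high"])
        for p in self.points:
            writer.writerow([p.value, p.fixed, p.operating.low, p.operating.high])
        return buf.getvalue()


def one_way_sweep(template: CountryTemplate, parameter: str,
                  grid: Sequence[int]) -> SweepResult:
    """Grand totals with ``parameter`` substituted by each grid value in turn.

    All other parameters stay fixed; an unknown parameter name is an error.
    A pure function of its inputs: re-running on a reloaded template gives
    identical results.
    """
    if parameter not in CountryParams.FIELDS:
        raise ValueError(f"unknown country parameter {parameter!r}; "
                         f"expected one of {CountryParams.FIELDS}")
    points = []
    for value in grid:
        if value < 0:
            raise ValueError(f"grid value must be non-negative, got {value!r}")
        swapped = CountryTemplate(
            params=template.params.with_value(parameter, value),
            lines=template.lines, name=template.name,
            currency_year=template.currency_year, notes=template.notes)
        report = rollup(swapped)
        points.append(SweepPoint(value, report.grand_fixed, report.grand_operating))
    return SweepResult(parameter, tuple(points))


def elasticity(template: CountryTemplate, parameter: str) -> float:
    """Arc elasticity of the grand combined low total to one parameter.

    The parameter is perturbed by +1% (rounded to a whole count, since all
    parameters are counts of persons or administrative units) and the
    elasticity is (relative change in total) / (relative change actually
    applied), reported to 4 decimal places. Requires a positive base
    parameter value and a positive base total.
    """
    if parameter not in CountryParams.FIELDS:
        raise ValueError(f"unknown country parameter {parameter!r}")
    base_value = getattr(template.params, parameter)
    if base_value <= 0:
        raise ValueError(f"parameter {parameter} must be > 0 for elasticity")
    base_total = rollup(template).grand_combined.low
    if base_total <= 0:
        raise ValueError("base grand combined low total must be > 0 for elasticity")

    perturbed_value = max(base_value + 1, round(base_value * 1.01))
    sweep = one_way_sweep(template, parameter, [perturbed_value])
    new_total = sweep.points[0].fixed + sweep.points[0].operating.low

    rel_total = (new_total - base_total) / base_total
    rel_param = (perturbed_value - base_value) / base_value
    return round(rel_total / rel_param, 4)
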