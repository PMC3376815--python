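"""Quantity resolution: staffing norms, ceiling rounding, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihrcost import (
    CountryParams,
    ScalingDriver,
    country_x_fine,
    resolve_quantity,
    resolve_template,
)

DEFAULTS = CountryParams()
ZERO = CountryParams(0, 0, 0, 0)


@pytest.mark.parametrize("driver, params, expected", [
    # published staffing norm: 1 field epidemiologist per 200,000 -> 300
    (ScalingDriver.per_population(200_000), DEFAULTS, 300),
    # 1 community health worker per 500 population
    (ScalingDriver.per_population(500), DEFAULTS, 120_000),
    # 2 rapid response teams per province plus 2 central teams
    (ScalingDriver.per_province(2, offset=2), DEFAULTS, 130),
    # 4-person team at each of the 6 points of entry
    (ScalingDriver.per_point_of_entry(4), DEFAULTS, 24),
    (ScalingDriver.constant(16), DEFAULTS, 16),
    (ScalingDriver.per_district(1), DEFAULTS, 600),
    # ceiling: one whole worker per started population block
    (ScalingDriver.per_population(200_000), CountryParams(population=200_001), 2),
    (ScalingDriver.per_population(200_000), CountryParams(population=1), 1),
    # all-zero parameters resolve to zero without an offset
    (ScalingDriver.per_population(500), ZERO, 0),
    (ScalingDriver.per_province(3), ZERO, 0),
    (ScalingDriver.constant(0), ZERO, 0),
])
def test_resolve_quantity(driver, params, expected):
    assert resolve_quantity(driver, params) == expected


def test_unknown_driver_kind_raises():
    with pytest.raises(ValueError, match="unknown driver kind"):
        resolve_quantity(ScalingDriver("per_household", 10, 0), DEFAULTS)


def test_resolve_template_attaches_line_id_to_errors(fine):
    broken = fine.lines[0]
    from dataclasses import replace
    bad = replace(fine, lines=(replace(broken, driver=ScalingDriver("bogus", 1, 0)),))
    with pytest.raises(ValueError, match=broken.id):
        resolve_template(bad)


def test_resolve_template_preserves_order_and_matches_per_line(fine):
    resolved = resolve_template(fine)
    assert [r.line.id for r in resolved] == [ln.id for ln in fine.lines]
    for r in resolved:
        assert r.quantity == resolve_quantity(r.line.driver, fine.params)


def test_coarse_template_all_quantities_one(coarse):
    assert all(r.quantity == 1 for r in resolve_template(coarse))


@given(
    ratio=st.integers(min_value=1, max_value=10**6),
    blocks=st.integers(min_value=0, max_value=10**4),
)
@settings(max_examples=100, derandomize=True)
def test_exact_division_has_no_rounding_artifact(ratio, blocks):
    """When the ratio divides the population, the quantity is exactly p/r."""
    params = CountryParams(population=ratio * blocks)
    driver = ScalingDriver.per_population(ratio)
    assert resolve_quantity(driver, params) == blocks


_params_st = st.builds(
    CountryParams,
    population=st.integers(0, 10**9),
    n_provinces=st.integers(0, 1000),
    n_districts=st.integers(0, 10**4),
    n_points_of_entry=st.integers(0, 100),
)
_driver_st = st.one_of(
    st.builds(ScalingDriver.constant, st.integers(0, 100)),
    st.builds(ScalingDriver.per_population, st.integers(1, 10**6), st.integers(0, 10)),
    st.builds(ScalingDriver.per_province, st.integers(1, 10), st.integers(0, 10)),
    st.builds(ScalingDriver.per_district, st.integers(1, 10), st.integers(0, 10)),
    st.builds(ScalingDriver.per_point_of_entry, st.integers(1, 10), st.integers(0, 10)),
)


@given(driver=_driver_st, a=_params_st, b=_params_st)
@settings(max_examples=200, derandomize=True)
def test_quantity_monotone_in_every_parameter(driver, a, b):
    """Pointwise-larger country parameters never reduce any quantity."""
    lo = CountryParams(*(min(x, y) for x, y in
                         zip((a.population, a.n_provinces, a.n_districts,
                              a.n_points_of_entry),
                             (b.population, b.n_provinces, b.n_districts,
                              b.n_points_of_entry))))
    hi = CountryParams(*(max(x, y) for x, y in
                         zip((a.population, a.n_provinces, a.n_districts,
                              a.n_points_of_entry),
                             (b.population, b.n_provinces, b.n_districts,
                              b.n_points_of_entry))))
    assert resolve_quantity(driver, lo) <= resolve_quantity(driver, hi)
    assert resolve_quantity(driver, lo) >= 0
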