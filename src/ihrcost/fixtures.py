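"""Packaged Country X templates and a seeded random-template generator.

Two templates for the model Southeast Asian country ("Country X": 60 million
persons, 64 provinces, 600 districts, 6 designated points of entry) ship as
YAML package data:

``country_x_coarse``
    One cost line per category, transcribing the published Country X cost
    summary: fixed costs and low-high operating ranges for the 8 core
    capacities plus points of entry. The coordination operating-high cell is
    stored as 588,868 — the single-cell reconstruction of the printed
    88,868, which is inconsistent with the printed column total (see
    :func:`ihrcost.aggregation.reconstruct_inconsistent_cell`); every other
    figure is as printed. The as-printed cells are also exported
    (``TABLE2_FIXED`` etc.) so the reconstruction can be re-run.

``country_x_fine``
    ~50 illustrative cost lines with real scaling drivers taken from the
    published staffing rules (1 field epidemiologist per 200,000 population;
    1 community health worker per 500; 2 five-member rapid response teams
    per province plus 2 central; 4-person teams at each point of entry; 16
    field-epidemiology trainees per year; a 40-person command-and-control
    centre; ...). The true line-item unit costs behind the published
    category totals are not available, so unit costs here are
    CALIBRATED-ILLUSTRATIVE: plausible relative weights per line,
    apportioned by a largest-remainder integer scheme so that each
    category's roll-up at the default parameters reproduces the coarse
    category totals bit-exactly. Quantities are sourced; unit costs are not.

``random_template`` draws structurally valid templates deterministically
from a seed, for property tests against brute-force oracles.
"""

from __future__ import annotations

import random
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .model import (
    CostLine,
    CountryParams,
    CountryTemplate,
    DriverKind,
    InputClass,
    MoneyRange,
    ScalingDriver,
    SystemLevel,
)
from .scaling import resolve_quantity
from .taxonomy import INDICATORS
from .template_io import template_from_document

__all__ = [
    "TABLE2_FIXED",
    "TABLE2_OPERATING_LOW",
    "TABLE2_OPERATING_HIGH_PRINTED",
    "TABLE2_TOTALS",
    "COORDINATION_HIGH_RECONSTRUCTED",
    "country_x_coarse",
    "country_x_fine",
    "build_country_x_coarse",
    "build_country_x_fine",
    "random_template",
]

_LEG = "national_legislation_policy_and_financing"
_NFP = "coordination_and_national_focal_point_communications"

# Country X cost summary, transcribed as printed (whole 2005 $US).
TABLE2_FIXED: dict[str, int] = {
    _LEG: 75_000,
    _NFP: 823_102,
    "surveillance": 5_261_764,
    "response": 20_480_332,
    "preparedness": 2_889_166,
    "risk_communications": 4_389,
    "human_resources": 4_389,
    "laboratories": 49_619_443,
    "points_of_entry": 153_062,
}

TABLE2_OPERATING_LOW: dict[str, int] = {
    _LEG: 0,
    _NFP: 347_959,
    "surveillance": 26_238_293,
    "response": 3_981_294,
    "preparedness": 103_726_507,
    "risk_communications": 1_868_869,
    "human_resources": 620_649,
    "laboratories": 13_742_692,
    "points_of_entry": 838_851,
}

#: Operating-high cells exactly as printed. The coordination cell (88,868)
#: does not reconcile with the printed column total; the coarse fixture
#: stores the reconstructed value instead.
TABLE2_OPERATING_HIGH_PRINTED: dict[str, int] = {
    _LEG: 0,
    _NFP: 88_868,
    "surveillance": 69_606_113,
    "response": 5_215_857,
    "preparedness": 103_786_408,
    "risk_communications": 2_141_939,
    "human_resources": 653_009,
    "laboratories": 20_057_218,
    "points_of_entry": 1_435_767,
}

TABLE2_TOTALS: dict[str, int] = {
    "fixed": 79_310_647,
    "operating_low": 151_365_114,
    "operating_high": 203_485_179,
    "combined_low": 230_675_761,
    "combined_high": 282_795_826,
}

#: Single-cell reconstruction of the coordination operating high:
#: printed column total minus the other eight printed high cells.
COORDINATION_HIGH_RECONSTRUCTED = 588_868

_COARSE_INDICATOR = {
    _LEG: "legislation",
    _NFP: "nfp_operations",
    "surveillance": "indicator_based_surveillance",
    "response": "rapid_response",
    "preparedness": "emergency_preparedness",
    "risk_communications": "public_communications",
    "human_resources": "human_resource_capacity",
    "laboratories": "laboratory_diagnostics",
    "points_of_entry": "poe_surveillance",
}


def build_country_x_coarse() -> CountryTemplate:
    """Construct the coarse template in memory (source of the packaged YAML)."""
    lines = []
    for cat, fixed in TABLE2_FIXED.items():
        low = TABLE2_OPERATING_LOW[cat]
        high = TABLE2_OPERATING_HIGH_PRINTED[cat]
        note = "category total as printed in the Country X cost summary"
        if cat == _NFP:
            high = COORDINATION_HIGH_RECONSTRUCTED
            note = ("operating high reconstructed to 588,868: the printed cell "
                    "(88,868) is inconsistent with the printed operating-high "
                    "column total of 203,485,179; fixed and operating-low are "
                    "as printed")
        lines.append(CostLine(
            id=f"{cat}__all",
            category=cat,
            indicator=_COARSE_INDICATOR[cat],
            level=SystemLevel.CENTRAL,
            input_class=InputClass.TOOLS_PROCESSES,
            driver=ScalingDriver.constant(1),
            unit_fixed=fixed,
            unit_operating=MoneyRange(low, high),
            note=note,
        ))
    return CountryTemplate(
        params=CountryParams(),
        lines=tuple(lines),
        name="country_x_coarse",
        notes=("Model Southeast Asian country, one aggregate line per cost "
               "category; each line attached to a representative indicator of "
               "its category. Risk communications and human resources both "
               "carry fixed cost 4,389 as printed (possibly a transcription "
               "artifact in the source table; transcribed verbatim)."),
    )


def _apportion_units(total: int,
                     items: Sequence[tuple[str, int, int]]) -> dict[str, int]:
    """Distribute an integer dollar total over lines as integer unit costs.

    ``items`` are ``(line_id, quantity, weight)``; the result maps line id to
    a unit cost such that ``sum(quantity * unit) == total`` exactly.
    Largest-remainder scheme: exact rational shares proportional to weight,
    floored to whole-dollar units, then +1 unit handed out in decreasing
    order of fractional remainder while the leftover covers that line's
    quantity; whatever no line can absorb whole lands on a quantity-1 line,
    which each weighted component is required to contain.
    """
    units = {lid: 0 for lid, _, _ in items}
    if total == 0:
        return units
    active = [(lid, q, w) for lid, q, w in items if w > 0 and q > 0]
    if not active:
        raise ValueError(f"positive total {total} but no weighted lines")
    if not any(q == 1 for _, q, _ in active):
        raise ValueError("apportionment needs a quantity-1 line per component")
    wsum = sum(w for _, _, w in active)
    ideal = {lid: Fraction(total * w, wsum * q) for lid, q, w in active}
    for lid, q, _ in active:
        units[lid] = ideal[lid].numerator // ideal[lid].denominator
    leftover = total - sum(units[lid] * q for lid, q, _ in active)
    order = sorted(active, key=lambda t: (ideal[t[0]] - units[t[0]], t[0]),
                   reverse=True)
    for lid, q, _ in order:
        if leftover >= q:
            units[lid] += 1
            leftover -= q
    if leftover:
        lid1 = next(lid for lid, q, _ in order if q == 1)
        units[lid1] += leftover
    return units


# Fine-template skeleton: (id, category, indicator, level, input_class,
# driver, fixed-weight, operating-low-weight, operating-high-extra-weight,
# note). Drivers are sourced from the published Country X staffing and
# input descriptions; weights are illustrative and only set each line's
# share of its category's published totals.
_C, _I, _P = SystemLevel.CENTRAL, SystemLevel.INTERMEDIATE, SystemLevel.PERIPHERAL
_CM, _POE = SystemLevel.COMMUNITY, SystemLevel.POINT_OF_ENTRY
_PH, _HC, _TP = (InputClass.PHYSICAL_INFRASTRUCTURE, InputClass.HUMAN_CAPABILITIES,
                 InputClass.TOOLS_PROCESSES)
_D = ScalingDriver

_SOURCED = "driver sourced from the published Country X description"
_CAL = "unit costs calibrated-illustrative (apportioned from category totals)"

_FINE_SKELETON: list[tuple] = [
    # --- national legislation, policy and financing -----------------------
    ("legal_review_consultancy", _LEG, "legislation", _C, _HC, _D.constant(1),
     100, 0, 0,
     "legal expertise to review and revise national public health law; "
     "fixed cost 75,000 as published; no recurrent cost"),
    # --- coordination and NFP communications ------------------------------
    ("nfp_office_establishment", _NFP, "nfp_operations", _C, _PH, _D.constant(1),
     35, 0, 0, f"{_SOURCED}; {_CAL}"),
    ("nfp_ict_equipment", _NFP, "nfp_operations", _C, _PH, _D.constant(1),
     30, 20, 20, f"{_SOURCED}; {_CAL}"),
    ("nfp_vehicles", _NFP, "nfp_operations", _C, _PH, _D.constant(2),
     20, 0, 0, _CAL),
    ("nfp_staff_salaries", _NFP, "nfp_operations", _C, _HC, _D.constant(4),
     0, 50, 50, _CAL),
    ("ihr_stakeholder_meetings", _NFP, "ihr_coordination", _C, _TP, _D.constant(4),
     0, 20, 20, "quarterly multisectoral coordination meetings; " + _CAL),
    ("nfp_communications_services", _NFP, "nfp_operations", _C, _TP, _D.constant(1),
     15, 10, 10, _CAL),
    # --- surveillance -----------------------------------------------------
    ("field_epidemiologists", "surveillance", "indicator_based_surveillance",
     _I, _HC, _D.per_population(200_000),
     0, 25, 20,
     "published staffing norm: 1 field-trained epidemiologist per 200,000 "
     "population (300 at the 60M default); " + _CAL),
    ("community_health_worker_allowances", "surveillance",
     "indicator_based_surveillance", _CM, _HC, _D.per_population(500),
     0, 50, 43,
     "monthly training/travel/communications allowances for 1 village or "
     "community health worker per 500 population; allowance amount is "
     "calibrated, not sourced"),
    ("district_surveillance_officers", "surveillance",
     "indicator_based_surveillance", _P, _HC, _D.per_district(1),
     0, 12, 12, f"{_SOURCED}; {_CAL}"),
    ("province_surveillance_units", "surveillance",
     "indicator_based_surveillance", _I, _HC, _D.per_province(1),
     0, 6, 6, f"{_SOURCED}; {_CAL}"),
    ("district_surveillance_ict", "surveillance", "indicator_based_surveillance",
     _P, _PH, _D.per_district(1),
     45, 2, 4, "ICT linking district offices, facilities and communities; " + _CAL),
    ("province_surveillance_equipment", "surveillance",
     "indicator_based_surveillance", _I, _PH, _D.per_province(1),
     25, 0, 0, _CAL),
    ("national_surveillance_data_centre", "surveillance",
     "indicator_based_surveillance", _C, _PH, _D.constant(1),
     20, 0, 0, _CAL),
    ("event_monitoring_centre_24_7", "surveillance", "event_based_surveillance",
     _C, _PH, _D.constant(1),
     0, 2, 2,
     "24/7/365 event monitoring; shares physical infrastructure, ICT and "
     "utilities with the command-and-control centre, so carries zero fixed "
     "cost here to honour the count-each-input-once rule"),
    ("community_facility_staff_training", "surveillance",
     "event_based_surveillance", _CM, _HC, _D.per_district(1),
     0, 2, 6, "on-site training of community health centre staff; " + _CAL),
    ("hazards_mapping_workshops", "surveillance", "situation_awareness",
     _C, _TP, _D.constant(1),
     10, 1, 2,
     "baseline inventory of community and national health risks via "
     "consultative workshops and field assessments; " + _CAL),
    ("surveillance_reporting_materials", "surveillance",
     "indicator_based_surveillance", _P, _TP, _D.per_district(1),
     0, 0, 7, _CAL),
    # --- response ---------------------------------------------------------
    ("command_control_centre", "response", "rapid_response", _C, _PH,
     _D.constant(1),
     55, 0, 0,
     "dedicated command-and-control centre accommodating up to 40 personnel "
     "during an event; " + _CAL),
    ("command_centre_ict", "response", "rapid_response", _C, _PH, _D.constant(1),
     15, 5, 5, f"{_SOURCED}; {_CAL}"),
    ("rapid_response_teams", "response", "rapid_response", _I, _HC,
     _D.per_province(2, offset=2),
     5, 45, 45,
     "2 trained 5-member multidisciplinary rapid response teams per province "
     "plus 2 central teams (130 at defaults): materials, supplementary "
     "compensation, training and travel; " + _CAL),
    ("rrt_field_equipment", "response", "rapid_response", _I, _PH,
     _D.per_province(2, offset=2),
     10, 0, 0, _CAL),
    ("infection_control_guidance", "response", "infection_control", _C, _TP,
     _D.constant(1),
     2, 5, 5, "development and dissemination of infection-control and "
              "case-management guidance; " + _CAL),
    ("case_management_training", "response", "case_management", _P, _HC,
     _D.per_district(1),
     0, 25, 25, _CAL),
    ("patient_isolation_transport", "response", "case_management", _I, _PH,
     _D.per_province(1),
     13, 5, 5, "systems for isolating and transporting potentially "
               "infectious patients; " + _CAL),
    ("vector_control_programme", "response",
     "disinfection_decontamination_vector_control", _P, _TP, _D.per_district(1),
     0, 15, 15, _CAL),
    # --- preparedness -----------------------------------------------------
    ("national_preparedness_plan", "preparedness", "emergency_preparedness",
     _C, _TP, _D.constant(1),
     30, 1, 40, "development, planning and testing of the national public "
                "health emergency response plan; " + _CAL),
    ("national_risk_assessment", "preparedness", "risk_resource_mapping",
     _C, _TP, _D.constant(1),
     20, 0, 0, _CAL),
    ("national_stockpile_warehouse", "preparedness", "emergency_preparedness",
     _C, _PH, _D.constant(1),
     50, 0, 0, _CAL),
    ("national_stockpile_replenishment", "preparedness", "emergency_preparedness",
     _C, _TP, _D.constant(1),
     0, 97, 40,
     "national stockpile of response materials; dominates the preparedness "
     "operating total; treated as an annual recurrent cost as the published "
     "summary implies (whether it recurs annually or is periodic "
     "replenishment is not stated); " + _CAL),
    ("provincial_simulation_exercises", "preparedness", "emergency_preparedness",
     _I, _HC, _D.per_province(1),
     0, 2, 20, _CAL),
    # --- risk communications ----------------------------------------------
    ("risk_communication_plan", "risk_communications", "public_communications",
     _C, _TP, _D.constant(1),
     100, 5, 10, "development, printing and dissemination of a national risk "
                 "communications plan; " + _CAL),
    ("national_media_purchases", "risk_communications", "public_communications",
     _C, _TP, _D.constant(1),
     0, 45, 40, "broadcast and print media purchase; " + _CAL),
    ("province_communication_workshops", "risk_communications",
     "public_communications", _I, _HC, _D.per_province(1),
     0, 25, 25, "annual training workshops; " + _CAL),
    ("district_print_materials", "risk_communications", "public_communications",
     _P, _TP, _D.per_district(1),
     0, 25, 25, _CAL),
    # --- human resources --------------------------------------------------
    ("workforce_development_strategy", "human_resources",
     "human_resource_capacity", _C, _TP, _D.constant(1),
     100, 5, 10, "coordinated national strategy for public health workforce "
                 "development; " + _CAL),
    ("fetp_trainees", "human_resources", "human_resource_capacity", _C, _HC,
     _D.constant(16),
     0, 85, 80, "full support for field epidemiology training, up to 16 "
                "trainees per year; " + _CAL),
    ("fetp_field_investigation_travel", "human_resources",
     "human_resource_capacity", _C, _TP, _D.constant(16),
     0, 10, 10, "travel support for trainee field investigations; " + _CAL),
    # --- laboratories -----------------------------------------------------
    ("national_reference_laboratory", "laboratories", "laboratory_diagnostics",
     _C, _PH, _D.constant(1),
     30, 0, 0, _CAL),
    ("province_laboratory_upgrades", "laboratories", "laboratory_diagnostics",
     _I, _PH, _D.per_province(1),
     40, 5, 5, "tiered, integrated diagnostic capacity for the priority "
               "disease list; " + _CAL),
    ("district_laboratory_equipment", "laboratories", "laboratory_diagnostics",
     _P, _PH, _D.per_district(1),
     25, 5, 5, _CAL),
    ("laboratory_staff", "laboratories", "laboratory_diagnostics", _I, _HC,
     _D.per_province(4),
     0, 30, 30, _CAL),
    ("reagents_and_consumables", "laboratories", "laboratory_diagnostics",
     _P, _TP, _D.per_district(1),
     0, 40, 40, _CAL),
    ("specimen_transport_system", "laboratories",
     "specimen_collection_transport", _P, _TP, _D.per_district(1),
     0, 10, 10, _CAL),
    ("biosafety_training", "laboratories", "laboratory_biosafety", _I, _HC,
     _D.per_province(1),
     5, 5, 5, _CAL),
    ("laboratory_information_system", "laboratories",
     "laboratory_based_surveillance", _C, _TP, _D.constant(1),
     0, 5, 5, _CAL),
    # --- points of entry --------------------------------------------------
    ("poe_health_offices", "points_of_entry", "poe_surveillance", _POE, _PH,
     _D.per_point_of_entry(1),
     60, 0, 0, "a health office at each of the 6 designated points of "
               "entry; " + _CAL),
    ("poe_response_team_staff", "points_of_entry", "poe_response", _POE, _HC,
     _D.per_point_of_entry(4),
     0, 70, 70, "4-person multidisciplinary public health response team per "
                "point of entry (24 staff at defaults); " + _CAL),
    ("poe_medical_equipment", "points_of_entry", "poe_response", _POE, _PH,
     _D.per_point_of_entry(1),
     25, 10, 10, _CAL),
    ("poe_central_support", "points_of_entry", "poe_surveillance", _C, _TP,
     _D.constant(1),
     15, 20, 20, _CAL),
]


def build_country_x_fine(params: CountryParams | None = None) -> CountryTemplate:
    """Construct the fine template, calibrating unit costs to category totals.

    Calibration resolves each line's quantity at the default Country X
    parameters and apportions each category's published fixed total,
    operating-low total and operating high-minus-low spread across its lines
    by the largest-remainder scheme, so every category roll-up matches the
    coarse fixture bit-exactly (the high spread is apportioned separately and
    added to the low, which also guarantees low <= high per line).
    """
    params = params or CountryParams()
    by_cat: dict[str, list[tuple]] = {}
    for entry in _FINE_SKELETON:
        by_cat.setdefault(entry[1], []).append(entry)

    lines: list[CostLine] = []
    for cat, entries in by_cat.items():
        quantities = {e[0]: resolve_quantity(e[5], params) for e in entries}
        fixed_units = _apportion_units(
            TABLE2_FIXED[cat], [(e[0], quantities[e[0]], e[6]) for e in entries])
        low_units = _apportion_units(
            TABLE2_OPERATING_LOW[cat],
            [(e[0], quantities[e[0]], e[7]) for e in entries])
        high_total = (COORDINATION_HIGH_RECONSTRUCTED if cat == _NFP
                      else TABLE2_OPERATING_HIGH_PRINTED[cat])
        extra_units = _apportion_units(
            high_total - TABLE2_OPERATING_LOW[cat],
            [(e[0], quantities[e[0]], e[8]) for e in entries])
        for (lid, _, indicator, level, input_class, driver, *_rest, note) in entries:
            lines.append(CostLine(
                id=lid, category=cat, indicator=indicator, level=level,
                input_class=input_class, driver=driver,
                unit_fixed=fixed_units[lid],
                unit_operating=MoneyRange(low_units[lid],
                                          low_units[lid] + extra_units[lid]),
                note=note,
            ))
    return CountryTemplate(
        params=params,
        lines=tuple(lines),
        name="country_x_fine",
        notes=("Illustrative fine-grained Country X template: scaling drivers "
               "follow the published staffing and input rules; unit costs are "
               "calibrated so category roll-ups at the default parameters "
               "equal the published category totals exactly. Not the source's "
               "actual line-item unit costs."),
    )


def _load_packaged(name: str) -> CountryTemplate:
    data = resources.files("ihrcost").joinpath("data", f"{name}.yaml")
    doc = yaml.safe_load(data.read_text(encoding="utf-8"))
    return template_from_document(doc, source=f"package data {name}.yaml")


@lru_cache(maxsize=None)
def country_x_coarse() -> CountryTemplate:
    """The packaged coarse Country X template (one line per category)."""
    return _load_packaged("country_x_coarse")


@lru_cache(maxsize=None)
def country_x_fine() -> CountryTemplate:
    """The packaged fine Country X template (~50 calibrated lines)."""
    return _load_packaged("country_x_fine")


_RANDOM_KINDS = (
    (DriverKind.CONSTANT, 40),
    (DriverKind.PER_POPULATION, 25),
    (DriverKind.PER_PROVINCE, 15),
    (DriverKind.PER_DISTRICT, 10),
    (DriverKind.PER_POINT_OF_ENTRY, 10),
)

#: Unit-cost cap for random templates; keeps brute-force oracle tests fast
#: while exercising wide magnitudes.
RANDOM_UNIT_COST_MAX = 1_000_000_000


def random_template(seed: int, n_lines: int,
                    params: CountryParams | None = None) -> CountryTemplate:
    """A structurally valid random template, deterministic in ``seed``.

    Driver kinds are drawn with a documented mix (40% constant, 25%
    per-population, 35% administrative), unit costs uniformly up to
    ``RANDOM_UNIT_COST_MAX`` with low <= high by construction. The result
    always passes :func:`ihrcost.model.validate_template`.
    """
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    rng = random.Random(seed)
    params = params or CountryParams()
    kinds = [k for k, _ in _RANDOM_KINDS]
    weights = [w for _, w in _RANDOM_KINDS]
    lines = []
    for i in range(n_lines):
        indicator = rng.choice(INDICATORS)
        kind = rng.choices(kinds, weights=weights, k=1)[0]
        if kind is DriverKind.CONSTANT:
            driver = ScalingDriver.constant(rng.randint(0, 20))
        elif kind is DriverKind.PER_POPULATION:
            driver = ScalingDriver.per_population(
                rng.choice([500, 1_000, 5_000, 100_000, 200_000]),
                offset=rng.randint(0, 3))
        else:
            driver = ScalingDriver(kind, rng.randint(1, 5), rng.randint(0, 3))
        low = rng.randint(0, RANDOM_UNIT_COST_MAX)
        lines.append(CostLine(
            id=f"rand_{i:04d}",
            category=indicator.category,
            indicator=indicator.id,
            level=rng.choice(list(SystemLevel)),
            input_class=rng.choice(list(InputClass)),
            driver=driver,
            unit_fixed=rng.randint(0, RANDOM_UNIT_COST_MAX),
            unit_operating=MoneyRange(low, low + rng.randint(0, RANDOM_UNIT_COST_MAX)),
        ))
    return CountryTemplate(params=params, lines=tuple(lines),
                           name=f"random_seed_{seed}")
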