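"""Fixed taxonomy of IHR (2005) core capacities and country-level indicators.

The IHR Monitoring Framework defines 8 core capacities plus activities at
designated points of entry; the costing engine treats these 9 as the fixed
set of cost categories. Each category contains one or more country-level
indicators — measurable functional outcomes such as "indicator-based
surveillance includes an early-warning function". Every cost line in a
template is attached to exactly one indicator, which is how the engine
enforces the count-each-input-only-once rule.

Category ids are the snake_case forms of the category labels used in
published cost summaries; they are stable strings and part of the template
file format.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CostCategory:
    """One of the 9 cost categories (8 core capacities + points of entry)."""

    id: str
    name: str


@dataclass(frozen=True)
class Indicator:
    """A country-level indicator; belongs to exactly one category."""

    id: str
    category: str
    description: str


CATEGORIES: tuple[CostCategory, ...] = (
    CostCategory("national_legislation_policy_and_financing",
                 "National legislation, policy, and financing"),
    CostCategory("coordination_and_national_focal_point_communications",
                 "Coordination and National Focal Point communications"),
    CostCategory("surveillance", "Surveillance"),
    CostCategory("response", "Response"),
    CostCategory("preparedness", "Preparedness"),
    CostCategory("risk_communications", "Risk communications"),
    CostCategory("human_resources", "Human resources"),
    CostCategory("laboratories", "Laboratories"),
    CostCategory("points_of_entry", "Points of entry"),
)

CATEGORY_IDS: tuple[str, ...] = tuple(c.id for c in CATEGORIES)
CATEGORY_BY_ID: dict[str, CostCategory] = {c.id: c for c in CATEGORIES}

_LEG = "national_legislation_policy_and_financing"
_NFP = "coordination_and_national_focal_point_communications"

INDICATORS: tuple[Indicator, ...] = (
    Indicator("legislation", _LEG,
              "Laws, regulations and policies sufficient for IHR implementation."),
    Indicator("financing", _LEG,
              "Funding available and accessible for implementing IHR."),
    Indicator("ihr_coordination", _NFP,
              "Mechanism established for multisectoral IHR coordination."),
    Indicator("nfp_operations", _NFP,
              "National Focal Point functions and operations in place."),
    Indicator("indicator_based_surveillance", "surveillance",
              "Routine surveillance with an early-warning function."),
    Indicator("event_based_surveillance", "surveillance",
              "Event-based surveillance established."),
    Indicator("situation_awareness", "surveillance",
              "Coordinated mechanism for integrating IHR-relevant hazard information."),
    Indicator("rapid_response", "response",
              "Public health emergency response mechanisms established."),
    Indicator("case_management", "response",
              "Case-management procedures established for IHR-relevant hazards."),
    Indicator("infection_control", "response",
              "Infection prevention and control at national and hospital levels."),
    Indicator("disinfection_decontamination_vector_control", "response",
              "Programme for disinfection, decontamination and vector control."),
    Indicator("emergency_preparedness", "preparedness",
              "Multihazard national public health emergency preparedness and response plan."),
    Indicator("risk_resource_mapping", "preparedness",
              "Public health risks and resources mapped."),
    Indicator("public_communications", "risk_communications",
              "Mechanisms for effective risk communication during emergencies."),
    Indicator("human_resource_capacity", "human_resources",
              "Human resources available to implement IHR core capacity requirements."),
    Indicator("laboratory_diagnostics", "laboratories",
              "Laboratory services available and accessible for priority health threats."),
    Indicator("specimen_collection_transport", "laboratories",
              "System for collection, packaging and transport of clinical specimens."),
    Indicator("laboratory_biosafety", "laboratories",
              "Laboratory biosafety and biosecurity practices in place."),
    Indicator("laboratory_based_surveillance", "laboratories",
              "Laboratory data management and reporting established."),
    Indicator("poe_surveillance", "points_of_entry",
              "Effective surveillance established at points of entry."),
    Indicator("poe_response", "points_of_entry",
              "Effective response established at points of entry."),
)

INDICATOR_BY_ID: dict[str, Indicator] = {i.id: i for i in INDICATORS}


def indicators_for(category_id: str) -> tuple[Indicator, ...]:
    """All indicators belonging to one category."""
    return tuple(i for i in INDICATORS if i.category == category_id)
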