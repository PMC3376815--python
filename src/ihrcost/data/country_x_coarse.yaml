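schema_version: 1
name: country_x_coarse
currency_year: 2005
notes: Model Southeast Asian country, one aggregate line per cost category; each line attached
  to a representative indicator of its category. Risk communications and human resources both
  carry fixed cost 4,389 as printed (possibly a transcription artifact in the source table;
  transcribed verbatim).
params:
  population: 60000000
  n_provinces: 64
  n_districts: 600
  n_points_of_entry: 6
lines:
- id: national_legislation_policy_and_financing__all
  category: national_legislation_policy_and_financing
  indicator: legislation
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 75000
  unit_operating:
    low: 0
    high: 0
  note: category total as printed in the Country X cost summary
- id: coordination_and_national_focal_point_communications__all
  category: coordination_and_national_focal_point_communications
  indicator: nfp_operations
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 823102
  unit_operating:
    low: 347959
    high: 588868
  note: 'operating high reconstructed to 588,868: the printed cell (88,868) is inconsistent
    with the printed operating-high column total of 203,485,179; fixed and operating-low are
    as printed'
- id: surveillance__all
  category: surveillance
  indicator: indicator_based_surveillance
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 5261764
  unit_operating:
    low: 26238293
    high: 69606113
  note: category total as printed in the Country X cost summary
- id: response__all
  category: response
  indicator: rapid_response
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 20480332
  unit_operating:
    low: 3981294
    high: 5215857
  note: category total as printed in the Country X cost summary
- id: preparedness__all
  category: preparedness
  indicator: emergency_preparedness
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 2889166
  unit_operating:
    low: 103726507
    high: 103786408
  note: category total as printed in the Country X cost summary
- id: risk_communications__all
  category: risk_communications
  indicator: public_communications
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 4389
  unit_operating:
    low: 1868869
    high: 2141939
  note: category total as printed in the Country X cost summary
- id: human_resources__all
  category: human_resources
  indicator: human_resource_capacity
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 4389
  unit_operating:
    low: 620649
    high: 653009
  note: category total as printed in the Country X cost summary
- id: laboratories__all
  category: laboratories
  indicator: laboratory_diagnostics
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 49619443
  unit_operating:
    low: 13742692
    high: 20057218
  note: category total as printed in the Country X cost summary
- id: points_of_entry__all
  category: points_of_entry
  indicator: poe_surveillance
  level: central
  input_class: tools_processes
  driver:
    kind: constant
    offset: 1
  unit_fixed: 153062
  unit_operating:
    low: 838851
    high: 1435767
  note: category total as printed in the Country X cost summary
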