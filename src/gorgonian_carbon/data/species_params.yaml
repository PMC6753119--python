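# Default species parameter config: one entry per species x depth zone.
#
# Allometric coefficients, AFDM per cm, polyp density and reference
# temperatures are published constants.  The literature feeding,
# respiration and growth rates behind the study-area budgets are cited
# in their source papers but not reprinted here, so those fields ship
# as null: supply them yourself, or calibrate effective rates from a
# published compartment-budget table with
# gorgonian_carbon.parameters.effective_parameters_from_totals.
#
# All units are encoded in the field names.
entries:
  - species: Paramuricea clavata
    depth_zone: shallow
    height_to_length: {coefficient_a: 1.06, exponent_b: 1.69, response: linear_length_cm}
    afdm_mg_per_cm: {mean: 18.35, se: 2.33}
    # Polyps are published per size class for this species; only the
    # range endpoints (630 +- 139 smallest class, 26175 +- 5782 largest
    # class) are public.  Supply the full table to use the per-polyp
    # zooplankton channel.
    polyp_table: null
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_day
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 16.0
    # Annual C investment in growth is published per size class for
    # this species (sink_mode per_size_class_table); the table itself
    # must be user-supplied.
    sink_mode: per_size_class_table
    sink_investment_table: null
    c_content_mg_per_cm: null
    growth_cm_height_per_year: null
    mixotrophic: false
  - species: Paramuricea clavata
    depth_zone: deep
    height_to_length: {coefficient_a: 1.06, exponent_b: 1.69, response: linear_length_cm}
    afdm_mg_per_cm: {mean: 18.35, se: 2.33}
    polyp_table: null
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_day
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 14.0
    sink_mode: per_size_class_table
    sink_investment_table: null
    c_content_mg_per_cm: null
    growth_cm_height_per_year: null
    mixotrophic: false
  - species: Eunicella singularis
    depth_zone: shallow
    height_to_length:
      {coefficient_a: 0.2869, exponent_b: 1.9652, response: linear_length_cm,
       r_squared: 0.78, n_fit: 28}
    height_to_area:
      {coefficient_a: 0.0609, exponent_b: 2.4655, response: surface_area_cm2,
       r_squared: 0.81, n_fit: 28}
    afdm_mg_per_cm: {mean: 5.69, se: 0.47}
    polyps_per_cm: {mean: 31.1, se: 1.1}
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_hour
    autotrophic_ug_c_per_cm2_per_day: null
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 16.0
    sink_mode: length_increment
    c_content_mg_per_cm: null
    # Growth: the mean of two published annual height increments is
    # used; the two values are user-supplied (growth_source_values).
    growth_cm_height_per_year: null
    growth_source_values: []
    mixotrophic: true
  - species: Eunicella singularis
    depth_zone: deep
    height_to_length:
      {coefficient_a: 0.4669, exponent_b: 1.8432, response: linear_length_cm,
       r_squared: 0.66, n_fit: 44}
    afdm_mg_per_cm: {mean: 4.43, se: 0.37}
    polyps_per_cm: {mean: 31.1, se: 1.1}
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_hour
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 14.0
    sink_mode: length_increment
    c_content_mg_per_cm: null
    growth_cm_height_per_year: null
    growth_source_values: []
    mixotrophic: false
  - species: Leptogorgia sarmentosa
    depth_zone: shallow
    # Height-to-length coefficient: the published table gives a =
    # 2.1167 while the accompanying text prints a = 0.21167 for the
    # same exponent.  The table value ships as the default (it yields
    # total length > height for this ramified species, as expected);
    # override coefficient_a here to use the text value.  Both are
    # recorded on purpose — the discrepancy is in the source.
    height_to_length:
      {coefficient_a: 2.1167, exponent_b: 1.3684, response: linear_length_cm,
       r_squared: 0.74, n_fit: 16}
    afdm_mg_per_cm: {mean: 2.94, se: 0.67}
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_day
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 16.0
    sink_mode: length_increment
    c_content_mg_per_cm: null
    growth_cm_height_per_year: null
    mixotrophic: false
  - species: Leptogorgia sarmentosa
    depth_zone: deep
    height_to_length:
      {coefficient_a: 2.1167, exponent_b: 1.3684, response: linear_length_cm,
       r_squared: 0.74, n_fit: 16}
    afdm_mg_per_cm: {mean: 2.94, se: 0.67}
    zooplankton_ingestion_ug_c_per_polyp_per_day: null
    seston_ingestion_ug_c_per_g_afdm: null
    seston_timebase: per_day
    respiration_mg_o2_per_g_afdm_per_hour: null
    respiration_reference_temp_c: 16.0
    sink_mode: length_increment
    c_content_mg_per_cm: null
    growth_cm_height_per_year: null
    mixotrophic: false
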