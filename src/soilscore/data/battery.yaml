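# Default indicator battery: 22 soil functions in five categories.
#
# ILLUSTRATIVE PARAMETERS ONLY. The curve anchors below are plausible
# for Dutch-style mineral and peat topsoils but are NOT the
# authoritative national threshold tables, which live in fertilizer
# recommendation knowledge bases. Override this file for real use.
#
# Stratum keys are "soil_type:land_use" with "*" wildcards; resolution
# order is exact, "soil:*", "*:land_use", "*:*".
# Two-anchor curves: score 0.5 at x_half (fertilization advised below),
# 1.0 at x_opt (no further yield response above); x_zero defaults to
# 2*x_half - x_opt (clipped at 0 for increasing curves).

battery:
  # ---- chemical (9) -------------------------------------------------
  - function_id: i_c_n
    label: nitrogen supply capacity
    category: chemical
    required_properties: [n_total]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 1000, x_opt: 2500}
      "peat:*": {kind: two_anchor_increasing, x_half: 3000, x_opt: 8000}
  - function_id: i_c_p
    label: phosphorus availability
    category: chemical
    required_properties: [p_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 20, x_opt: 60}
      "*:grassland": {kind: two_anchor_increasing, x_half: 15, x_opt: 50}
  - function_id: i_c_k
    label: potassium availability
    category: chemical
    required_properties: [k_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 60, x_opt: 180}
  - function_id: i_c_mg
    label: magnesium availability
    category: chemical
    required_properties: [mg_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 40, x_opt: 120}
  - function_id: i_c_cu
    label: copper availability
    category: chemical
    required_properties: [cu_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 1.5, x_opt: 4.5}
  - function_id: i_c_s
    label: sulfur supply
    category: chemical
    required_properties: [s_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 8, x_opt: 24}
  - function_id: i_c_zn
    label: zinc availability
    category: chemical
    required_properties: [zn_avail]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 2.5, x_opt: 7.5}
  - function_id: i_c_cec
    label: cation buffering capacity
    category: chemical
    required_properties: [cec]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 40, x_opt: 150}
      "clay:*": {kind: two_anchor_increasing, x_half: 80, x_opt: 250}
  - function_id: i_c_ph
    label: soil acidity
    category: chemical
    required_properties: [ph]
    curves:
      "sand:*": {kind: optimum_window, low0: 4.2, low1: 5.2, high1: 6.4, high0: 7.6}
      "clay:*": {kind: optimum_window, low0: 5.2, low1: 6.2, high1: 7.8, high0: 8.8}
      "loess:*": {kind: optimum_window, low0: 5.0, low1: 6.0, high1: 7.5, high0: 8.5}
      "peat:*": {kind: optimum_window, low0: 4.0, low1: 4.8, high1: 6.0, high0: 7.2}
      "*:*": {kind: optimum_window, low0: 4.5, low1: 5.5, high1: 7.0, high0: 8.2}

  # ---- physical (8) -------------------------------------------------
  - function_id: i_p_aggstability
    label: aggregate stability
    category: physical
    required_properties: [organic_matter]
    vsa_substitutable: true
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 2.0, x_opt: 6.0}
  - function_id: i_p_crumbleability
    label: crumbleability
    category: physical
    required_properties: [clay]
    curves:
      "*:*": {kind: two_anchor_decreasing, x_zero: 55, x_half: 35, x_opt: 15}
  - function_id: i_p_water
    label: water retention and supply
    category: physical
    required_properties: [organic_matter]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 2.5, x_opt: 8.0}
  - function_id: i_p_winderod
    label: wind erosion resistance
    category: physical
    required_properties: [clay]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 3.0, x_opt: 12.0}
      "peat:*": {kind: two_anchor_increasing, x_half: 1.0, x_opt: 6.0}
  - function_id: i_p_sealing
    label: topsoil sealing resistance
    category: physical
    required_properties: [silt]
    curves:
      "*:*": {kind: two_anchor_decreasing, x_zero: 70, x_half: 45, x_opt: 20}
  - function_id: i_p_compaction
    label: subsoil compaction
    category: physical
    required_properties: [bulk_density]
    vsa_substitutable: true
    curves:
      "*:*": {kind: two_anchor_decreasing, x_zero: 1.8, x_half: 1.5, x_opt: 1.2}
      "peat:*": {kind: two_anchor_decreasing, x_zero: 1.4, x_half: 1.15, x_opt: 0.9}
  - function_id: i_p_droughtstress
    label: drought stress
    category: physical
    required_properties: [groundwater_class]
    curves:
      "*:*":
        kind: categorical_lookup
        table: {I: 1.0, II: 1.0, III: 0.9, IV: 0.7, V: 0.6, VI: 0.4, VII: 0.3, VIII: 0.2}
        default: 0.5
  - function_id: i_p_wetnessstress
    label: wetness stress
    category: physical
    required_properties: [groundwater_class]
    curves:
      "*:*":
        kind: categorical_lookup
        table: {I: 0.1, II: 0.3, III: 0.5, IV: 0.7, V: 0.8, VI: 0.9, VII: 1.0, VIII: 1.0}
        default: 0.5

  # ---- biological (2) -----------------------------------------------
  - function_id: i_b_pmn
    label: soil life activity (potentially mineralizable N)
    category: biological
    required_properties: [pmn]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 30, x_opt: 100}
      "peat:*": {kind: two_anchor_increasing, x_half: 80, x_opt: 250}
  - function_id: i_b_disease
    label: disease resistance
    category: biological
    required_properties: [organic_matter]
    curves:
      "*:*": {kind: two_anchor_increasing, x_half: 1.5, x_opt: 5.0}

  # ---- environmental (2) --------------------------------------------
  - function_id: i_e_ngw
    label: N retention vs. groundwater
    category: environmental
    required_properties: [n_total]
    curves:
      "*:*": {kind: two_anchor_decreasing, x_zero: 5000, x_half: 3000, x_opt: 1000}
      "peat:*": {kind: two_anchor_decreasing, x_zero: 14000, x_half: 9000, x_opt: 4000}
  - function_id: i_e_nsw
    label: P retention vs. surface water
    category: environmental
    required_properties: [p_avail]
    curves:
      "*:*": {kind: two_anchor_decreasing, x_zero: 130, x_half: 80, x_opt: 30}

  # ---- management (1) -----------------------------------------------
  - function_id: i_m_management
    label: sustainable management sub-score (config-supplied)
    category: management
    required_properties: [management_score]
    curves:
      # identity on [0, 1]: the management sub-score is already a grade
      "*:*": {kind: two_anchor_increasing, x_zero: 0.0, x_half: 0.5, x_opt: 1.0}
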